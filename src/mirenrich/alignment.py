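"""Pairwise global alignment, Calpha superposition, and homology filters.

Sequence alignment is Needleman-Wunsch with affine gaps (Gotoh's three-state
recursion), scored with BLOSUM62 / gap open 10 / extend 0.5 by default — the
EMBOSS NEEDLE parameterization.  A gap of length L costs open + extend*L and
end gaps are penalized.  Traceback ties are broken diagonal > up > left so
results are bit-reproducible.

Structural alignment seeds a residue correspondence from the sequence
alignment of the two Calpha traces, superposes with the Kabsch algorithm,
drops pairs with residual distance above a cutoff, and superposes once more.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import DomainRecord, map_structure_to_sequence

_MATRIX_CACHE: dict = {}


@dataclass
class AlignParams:
    """Alignment scoring and family-filter parameters.

    ``matrix=None`` switches to simple match/mismatch scoring (used by the
    enumeration oracles in the test-suite).
    """

    matrix: Optional[str] = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    match: float = 1.0
    mismatch: float = -1.0
    identity_exclusion_pct: float = 50.0
    c2_similarity_cutoff_pct: float = 50.0
    residual_cutoff: float = 5.0  # Angstrom, structure_align pair filter
    min_structure_pairs: int = 20

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")

    def score_fn(self):
        if self.matrix is None:
            match, mismatch = self.match, self.mismatch
            return lambda a, b: match if a == b else mismatch
        key = self.matrix
        if key not in _MATRIX_CACHE:
            _MATRIX_CACHE[key] = substitution_matrices.load(key)
        mat = _MATRIX_CACHE[key]

        def score(a, b, _mat=mat):
            try:
                return float(_mat[a, b])
            except (KeyError, IndexError):
                return float(_mat["X", "X"])

        return score


@dataclass
class AlignmentMap:
    """Residue correspondence between two sequences, 1-based positions.

    ``pairs`` is strictly increasing in both coordinates.  Identity and
    similarity are percentages over alignment columns excluding terminal
    overhangs.
    """

    pairs: list[tuple[int, int]]
    score: float
    identity_pct: float
    similarity_pct: float
    aligned_cols: int
    rmsd: Optional[float] = None  # set by structure_align
    segment_rmsds: Optional[list[float]] = None  # set by segmented_align

    def __post_init__(self) -> None:
        for (a1, b1), (a2, b2) in zip(self.pairs, self.pairs[1:]):
            if a2 <= a1 or b2 <= b1:
                raise ValueError("alignment pairs must be strictly increasing")

    def as_dict(self) -> dict:
        return dict(zip((a for a, _ in self.pairs), (b for _, b in self.pairs)))


@dataclass
class Superposition:
    """Rigid transform carrying point set A onto point set B."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float
    n_pairs: int

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation matrix must have det +1")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# Needleman-Wunsch / Gotoh
# ---------------------------------------------------------------------------

NEG = float("-inf")


def global_align(seqA: str, seqB: str, params: Optional[AlignParams] = None) -> AlignmentMap:
    """Optimal global alignment under affine gap costs.

    Three-state Gotoh DP; the traceback resolves ties by preferring the
    diagonal (match/substitution) move, then up (gap in ``seqB``), then left
    (gap in ``seqA``), both when choosing the final state and at every
    predecessor choice.
    """
    if params is None:
        params = AlignParams()
    if not seqA or not seqB:
        raise ValueError("sequences must be non-empty")
    score = params.score_fn()
    go, ge = params.gap_open, params.gap_extend
    first = go + ge  # opening residue of a gap
    n, m = len(seqA), len(seqB)

    # state 0 = M (diag), 1 = X (up, consumes A), 2 = Y (left, consumes B)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(go + ge * i)
    for j in range(1, m + 1):
        Y[0][j] = -(go + ge * j)

    for i in range(1, n + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        ai = seqA[i - 1]
        for j in range(1, m + 1):
            Mi[j] = score(ai, seqB[j - 1]) + max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            Xi[j] = max(Mp[j] - first, Xp[j] - ge, Yp[j] - first)
            Yi[j] = max(Mi[j - 1] - first, Xi[j - 1] - first, Yi[j - 1] - ge)

    finals = (M[n][m], X[n][m], Y[n][m])
    best = max(finals)
    state = finals.index(best)  # ties: M > X > Y, i.e. diag > up > left

    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            pairs.append((i, j))
            cand = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            state = cand.index(max(cand))
            i, j = i - 1, j - 1
        elif state == 1:
            cand = (M[i - 1][j] - first, X[i - 1][j] - ge, Y[i - 1][j] - first)
            state = cand.index(max(cand))
            i -= 1
        else:
            cand = (M[i][j - 1] - first, X[i][j - 1] - first, Y[i][j - 1] - ge)
            state = cand.index(max(cand))
            j -= 1
    pairs.reverse()

    identity, similarity, cols = _identity_similarity(pairs, seqA, seqB, params)
    return AlignmentMap(pairs, best, identity, similarity, cols)


def _identity_similarity(pairs, seqA, seqB, params):
    if not pairs:
        return 0.0, 0.0, 0
    score = params.score_fn()
    matches = positives = 0
    cols = 0
    prev = None
    for a, b in pairs:
        if prev is not None:
            cols += (a - prev[0] - 1) + (b - prev[1] - 1)  # internal gap columns
        cols += 1
        prev = (a, b)
        ra, rb = seqA[a - 1], seqB[b - 1]
        if ra == rb:
            matches += 1
        if score(ra, rb) > 0:
            positives += 1
    return 100.0 * matches / cols, 100.0 * positives / cols, cols


def identity_and_similarity(
    amap: AlignmentMap, seqA: str, seqB: str, params: Optional[AlignParams] = None
) -> tuple[float, float]:
    """Percent identity and percent similarity of an alignment.

    The denominator is the number of alignment columns between the first and
    last aligned pair (internal gap columns included, terminal overhangs
    excluded); similarity counts columns whose substitution score is positive.
    """
    if params is None:
        params = AlignParams()
    identity, similarity, _ = _identity_similarity(amap.pairs, seqA, seqB, params)
    return identity, similarity


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    coordsA: np.ndarray,
    coordsB: np.ndarray,
    correspondence: Optional[Sequence[tuple[int, int]]] = None,
) -> Superposition:
    """Least-squares rigid superposition of A onto B (Kabsch algorithm).

    ``correspondence`` lists 0-based index pairs (iA, iB); by default the
    points correspond elementwise.  A reflection in the SVD solution is
    corrected so the rotation is proper (det +1).
    """
    coordsA = np.asarray(coordsA, dtype=float)
    coordsB = np.asarray(coordsB, dtype=float)
    if correspondence is None:
        if len(coordsA) != len(coordsB):
            raise ValueError("point sets differ in size and no correspondence given")
        correspondence = [(i, i) for i in range(len(coordsA))]
    if len(correspondence) < 3:
        raise ValueError("need at least 3 corresponding pairs")
    ia = [p[0] for p in correspondence]
    ib = [p[1] for p in correspondence]
    A = coordsA[ia]
    B = coordsB[ib]
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    moved = A @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - B) ** 2, axis=1))))
    return Superposition(R, t, rmsd, len(correspondence))


# ---------------------------------------------------------------------------
# structural alignment with residual filtering
# ---------------------------------------------------------------------------

def _ensure_mapped(record: DomainRecord) -> None:
    if record.structure is None:
        raise ValueError(f"{record.protein_id}: no structure")
    if record.structure.seq_positions is None:
        record.structure.seq_positions = map_structure_to_sequence(
            record.structure.sequence, record.sequence
        )


def structure_align(
    template: DomainRecord, target: DomainRecord, params: Optional[AlignParams] = None
) -> AlignmentMap:
    """Superposition-filtered residue correspondence between two structures.

    Seeds pairs from the global sequence alignment of the Calpha-derived
    sequences, runs one Kabsch round, drops pairs with residual distance
    above ``params.residual_cutoff`` (5 A default), repeats Kabsch once, and
    reports the surviving pairs translated to full-length positions.
    """
    if params is None:
        params = AlignParams()
    _ensure_mapped(template)
    _ensure_mapped(target)
    st, sg = template.structure, target.structure
    seq_map = global_align(st.sequence, sg.sequence, params)
    idx_pairs = [(a - 1, b - 1) for a, b in seq_map.pairs]
    if len(idx_pairs) < params.min_structure_pairs:
        raise ValueError(
            f"only {len(idx_pairs)} seed pairs: unreliable superposition"
        )
    sup1 = kabsch_superpose(st.coords, sg.coords, idx_pairs)
    moved = sup1.apply(st.coords)
    resid = np.linalg.norm(
        moved[[p[0] for p in idx_pairs]] - sg.coords[[p[1] for p in idx_pairs]],
        axis=1,
    )
    survivors = [p for p, r in zip(idx_pairs, resid) if r <= params.residual_cutoff]
    if len(survivors) < params.min_structure_pairs:
        raise ValueError(
            f"only {len(survivors)} pairs within {params.residual_cutoff} A: "
            "unreliable superposition"
        )
    sup2 = kabsch_superpose(st.coords, sg.coords, survivors)

    pairs = []
    for ia, ib in survivors:
        pa = st.seq_positions[ia]
        pb = sg.seq_positions[ib]
        if pa is not None and pb is not None:
            pairs.append((pa, pb))
    identity, similarity, cols = _identity_similarity(
        pairs, template.sequence, target.sequence, params
    )
    return AlignmentMap(
        pairs, seq_map.score, identity, similarity, cols, rmsd=sup2.rmsd
    )


def segmented_align(
    template: DomainRecord,
    target: DomainRecord,
    segments: Sequence[tuple[int, int]],
    params: Optional[AlignParams] = None,
) -> AlignmentMap:
    """Align a kinked domain segment-by-segment against the template.

    Domains with a hinge (F-BAR tips rotate relative to the central module)
    superpose poorly as one rigid body; here each template segment (given in
    template full-length coordinates) gets an independent rigid superposition
    when structures are present.  Without structures the sequence alignment
    is simply partitioned by segment.  Concatenated pairs must stay strictly
    increasing; later-segment conflicting pairs are dropped.
    """
    if params is None:
        params = AlignParams()
    if not segments:
        raise ValueError("empty segment list")
    segs = sorted(tuple(s) for s in segments)
    for (a1, b1), (a2, b2) in zip(segs, segs[1:]):
        if a2 <= b1:
            raise ValueError(f"segments overlap: [{a1},{b1}] and [{a2},{b2}]")

    use_structures = template.structure is not None and target.structure is not None
    if use_structures:
        _ensure_mapped(template)
        _ensure_mapped(target)
        st, sg = template.structure, target.structure
        seed = global_align(st.sequence, sg.sequence, params)
        pos_of = st.seq_positions
        all_pairs: list[tuple[int, int]] = []
        rmsds: list[float] = []
        for a, b in segs:
            seg_idx = [
                (ia - 1, ib - 1)
                for ia, ib in seed.pairs
                if pos_of[ia - 1] is not None and a <= pos_of[ia - 1] <= b
            ]
            if len(seg_idx) < 3:
                continue
            sup = kabsch_superpose(st.coords, sg.coords, seg_idx)
            moved = sup.apply(st.coords)
            resid = np.linalg.norm(
                moved[[p[0] for p in seg_idx]] - sg.coords[[p[1] for p in seg_idx]],
                axis=1,
            )
            surv = [p for p, r in zip(seg_idx, resid) if r <= params.residual_cutoff]
            if len(surv) < 3:
                continue
            sup = kabsch_superpose(st.coords, sg.coords, surv)
            rmsds.append(sup.rmsd)
            for ia, ib in surv:
                pa, pb = st.seq_positions[ia], sg.seq_positions[ib]
                if pa is not None and pb is not None:
                    all_pairs.append((pa, pb))
        score = seed.score
    else:
        seed = global_align(template.sequence, target.sequence, params)
        all_pairs = [
            (pa, pb)
            for pa, pb in seed.pairs
            if any(a <= pa <= b for a, b in segs)
        ]
        rmsds = None
        score = seed.score

    # enforce monotonicity across concatenated segments
    pairs: list[tuple[int, int]] = []
    last_a = last_b = 0
    for pa, pb in sorted(all_pairs):
        if pa > last_a and pb > last_b:
            pairs.append((pa, pb))
            last_a, last_b = pa, pb
    identity, similarity, cols = _identity_similarity(
        pairs, template.sequence, target.sequence, params
    )
    return AlignmentMap(
        pairs, score, identity, similarity, cols, segment_rmsds=rmsds
    )


# ---------------------------------------------------------------------------
# homology clustering and C2 subtype assignment
# ---------------------------------------------------------------------------

def cluster_by_identity(
    records: Sequence[DomainRecord],
    template: DomainRecord,
    params: Optional[AlignParams] = None,
    mode: str = "linkage",
):
    """Cluster family members around the template; exclude distant ones.

    Members below ``params.identity_exclusion_pct`` (50% default) identity to
    the template are excluded — unless, in the default single-linkage mode,
    they reach the threshold against some already-clustered member (``mode=
    "template"`` restricts the comparison to the template alone).  Identities
    are computed over domain sequences.

    Returns ``(cluster, excluded)`` where ``cluster`` is a list of records
    (template first) and ``excluded`` a list of ``(record, best_identity)``.
    """
    if params is None:
        params = AlignParams()
    if mode not in ("linkage", "template"):
        raise ValueError(f"unknown mode {mode!r}")
    thr = params.identity_exclusion_pct

    cluster = [template]
    pending = list(records)
    best_id: dict[str, float] = {r.protein_id: 0.0 for r in pending}
    changed = True
    while changed and pending:
        changed = False
        members = cluster if mode == "linkage" else [template]
        still = []
        for rec in pending:
            joined = False
            for member in members:
                amap = global_align(
                    member.domain_sequence(), rec.domain_sequence(), params
                )
                ident, _ = identity_and_similarity(
                    amap, member.domain_sequence(), rec.domain_sequence(), params
                )
                best_id[rec.protein_id] = max(best_id[rec.protein_id], ident)
                if ident >= thr:
                    cluster.append(rec)
                    joined = True
                    changed = True
                    break
            if not joined:
                still.append(rec)
        pending = still
        if mode == "template":
            break
    excluded = [(rec, best_id[rec.protein_id]) for rec in pending]
    return cluster, excluded


def assign_c2_subtype(
    record: DomainRecord,
    template_a: DomainRecord,
    template_b: DomainRecord,
    params: Optional[AlignParams] = None,
) -> str:
    """Assign a C2 domain to the C2A-like or C2B-like subtype, or reject it.

    Similarity is computed against both subtype templates; below the cutoff
    (50% default) to both marks the domain degenerate (non-functional C2
    fold, excluded from analysis).  An exact tie goes to C2A-like with a
    warning.
    """
    if params is None:
        params = AlignParams()
    sims = []
    for tmpl in (template_a, template_b):
        amap = global_align(tmpl.domain_sequence(), record.domain_sequence(), params)
        _, sim = identity_and_similarity(
            amap, tmpl.domain_sequence(), record.domain_sequence(), params
        )
        sims.append(sim)
    sim_a, sim_b = sims
    cutoff = params.c2_similarity_cutoff_pct
    if sim_a < cutoff and sim_b < cutoff:
        return "degenerate"
    if sim_a == sim_b:
        warnings.warn(
            f"{record.protein_id}: exact similarity tie ({sim_a:.1f}%) between "
            "C2A and C2B templates; assigning C2A-like"
        )
        return "C2A-like"
    return "C2A-like" if sim_a > sim_b else "C2B-like"


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_alignment_fasta(path, amap: AlignmentMap, seqA: str, seqB: str,
                          idA: str = "A", idB: str = "B") -> None:
    """Write the aligned region as standard gapped pairwise FASTA."""
    rowA, rowB = [], []
    prev = None
    for a, b in amap.pairs:
        if prev is not None:
            pa, pb = prev
            for k in range(pa + 1, a):
                rowA.append(seqA[k - 1])
                rowB.append("-")
            for k in range(pb + 1, b):
                rowA.append("-")
                rowB.append(seqB[k - 1])
        rowA.append(seqA[a - 1])
        rowB.append(seqB[b - 1])
        prev = (a, b)
    with open(path, "w") as fh:
        fh.write(f">{idA}\n{''.join(rowA)}\n>{idB}\n{''.join(rowB)}\n")


def write_alignment_pairs(path, amap: AlignmentMap) -> None:
    """Write the residue correspondence as a two-column TSV (1-based)."""
    with open(path, "w") as fh:
        fh.write("# coords: 1-based\nposA\tposB\n")
        for a, b in amap.pairs:
            fh.write(f"{a}\t{b}\n")
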
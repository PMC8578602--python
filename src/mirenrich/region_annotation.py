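"""Template MIR/NBR definitions and their transfer to family members.

A membrane-interaction region (MIR) is the set of residues experimentally
shown to contact the lipid bilayer; everything else in the domain is the
non-binding region (NBR).  MIRs are curated on templates and carried to
homologs through a residue correspondence.  The module also houses the
boundary-perturbation control used to probe sensitivity to the exact MIR
limits, a hydrophobic-moment detector for N-terminal amphipathic (H0)
helices, and a basic-residue charge-density check used to sanity-check
curated definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alignment import AlignmentMap
from .io_formats import DomainRecord

Interval = tuple[int, int]


def _merge(intervals: Sequence[Interval]) -> list[Interval]:
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def _interval_len(intervals: Sequence[Interval]) -> int:
    return sum(b - a + 1 for a, b in intervals)


def _contains(intervals: Sequence[Interval], pos: int) -> bool:
    return any(a <= pos <= b for a, b in intervals)


@dataclass
class RegionAnnotation:
    """MIR/NBR partition of a domain interval (1-based, closed).

    Invariant: the MIR and NBR intervals partition ``domain_range`` exactly.
    """

    domain_range: Interval
    mir_intervals: list[Interval]
    nbr_intervals: list[Interval] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mir_intervals = _merge(self.mir_intervals)
        for a, b in self.mir_intervals:
            if a < self.domain_range[0] or b > self.domain_range[1]:
                raise ValueError(
                    f"MIR [{a},{b}] outside domain_range {self.domain_range}"
                )
        self.nbr_intervals = complement_regions(self.domain_range, self.mir_intervals)

    def region_of(self, pos: int) -> Optional[str]:
        """'MIR', 'NBR', or None for positions outside the domain."""
        if not (self.domain_range[0] <= pos <= self.domain_range[1]):
            return None
        return "MIR" if _contains(self.mir_intervals, pos) else "NBR"

    @property
    def mir_size(self) -> int:
        return _interval_len(self.mir_intervals)

    @property
    def nbr_size(self) -> int:
        return _interval_len(self.nbr_intervals)


@dataclass
class TemplateDefinition:
    """A curated template: domain record + MIR annotation (+ optional kink)."""

    record: DomainRecord
    annotation: RegionAnnotation
    kink_segments: Optional[list[Interval]] = None
    provenance: str = ""


def complement_regions(domain_range: Interval, mir_intervals: Sequence[Interval]) -> list[Interval]:
    """NBR intervals = domain_range minus the MIR intervals."""
    start, end = domain_range
    mir = _merge(mir_intervals)
    for a, b in mir:
        if a < start or b > end:
            raise ValueError(f"MIR [{a},{b}] outside domain_range [{start},{end}]")
    nbr: list[Interval] = []
    cursor = start
    for a, b in mir:
        if a > cursor:
            nbr.append((cursor, a - 1))
        cursor = b + 1
    if cursor <= end:
        nbr.append((cursor, end))
    return nbr


def transfer_annotation(
    template: TemplateDefinition, target: DomainRecord, amap: AlignmentMap
) -> RegionAnnotation:
    """Carry the template's MIR/NBR labels to a target through an alignment.

    Aligned target residues inherit the label of their template partner.
    Target residues with no partner (insertions) become MIR only when both
    nearest aligned flanking residues are MIR — an insertion strictly inside
    a membrane-binding surface most plausibly stays on that surface — and
    NBR otherwise.  The target domain range spans the mapped positions plus
    flanking insertions inside that span.
    """
    tmpl_ann = template.annotation
    t_start, t_end = tmpl_ann.domain_range
    in_domain = [(a, b) for a, b in amap.pairs if t_start <= a <= t_end]
    if not in_domain:
        raise ValueError("alignment has no pairs inside the template domain range")

    lo = min(b for _, b in in_domain)
    hi = max(b for _, b in in_domain)
    labels: dict[int, str] = {}
    for a, b in in_domain:
        labels[b] = tmpl_ann.region_of(a)

    # insertions: flanked-by-MIR rule
    aligned = sorted(labels)
    for left, right in zip(aligned, aligned[1:]):
        if right - left > 1:
            fill = "MIR" if labels[left] == "MIR" and labels[right] == "MIR" else "NBR"
            for pos in range(left + 1, right):
                labels[pos] = fill

    mir_positions = sorted(p for p, lab in labels.items() if lab == "MIR")
    mir_intervals: list[Interval] = []
    for p in mir_positions:
        if mir_intervals and p == mir_intervals[-1][1] + 1:
            mir_intervals[-1] = (mir_intervals[-1][0], p)
        else:
            mir_intervals.append((p, p))
    return RegionAnnotation(
        (lo, hi),
        mir_intervals,
        provenance=f"transferred from {template.record.protein_id}",
    )


def adjust_boundaries(
    ann: RegionAnnotation, delta: int, force: bool = False
) -> RegionAnnotation:
    """Expand (delta > 0) or contract (delta < 0) every MIR interval.

    Each interval grows or shrinks by ``|delta|`` residues on both ends,
    clipped to the domain range; grown intervals that touch are merged and
    intervals contracted to nothing are removed.  Deltas beyond +-2 are
    outside the validated perturbation range and rejected unless ``force``.
    """
    if abs(delta) > 2 and not force:
        raise ValueError(f"delta {delta} outside validated range [-2, 2]")
    if delta == 0:
        return RegionAnnotation(
            ann.domain_range, list(ann.mir_intervals), provenance=ann.provenance
        )
    start, end = ann.domain_range
    new: list[Interval] = []
    for a, b in ann.mir_intervals:
        a2, b2 = a - delta, b + delta
        a2, b2 = max(a2, start), min(b2, end)
        if a2 <= b2:
            new.append((a2, b2))
    return RegionAnnotation(
        ann.domain_range, _merge(new),
        provenance=f"{ann.provenance} (delta {delta:+d})".strip(),
    )


# ---------------------------------------------------------------------------
# N-terminal amphipathic-helix detection (H0)
# ---------------------------------------------------------------------------

# Eisenberg consensus hydrophobicity scale
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
    "X": 0.0,
}


def hydrophobic_moment(segment: str, angle_deg: float = 100.0) -> float:
    """Mean helical hydrophobic moment of a residue segment.

    mu_H = |sum_i h_i * exp(i * delta * i)| / N with delta = 100 deg/residue
    (ideal alpha-helix) and h_i from the Eisenberg consensus scale.
    """
    if not segment:
        return 0.0
    idx = np.arange(len(segment))
    theta = np.deg2rad(angle_deg) * idx
    h = np.array([EISENBERG[c] for c in segment])
    return float(np.hypot((h * np.sin(theta)).sum(), (h * np.cos(theta)).sum())) / len(segment)


def detect_nterm_helix(
    sequence: str,
    domain_start: int,
    window: int = 11,
    threshold: float = 0.25,
    angle_deg: float = 100.0,
) -> Optional[Interval]:
    """Locate a putative N-terminal amphipathic (H0) helix before the domain.

    N-BAR H0 helices are membrane-embedded in situ but often unresolved in
    crystal structures, so they must be found on the sequence: a sliding
    window of mean hydrophobic moment over residues 1..domain_start-1, with
    the longest run of windows at mu_H >= threshold reported as the helix
    interval (union of the run's window footprints).  Returns None when the
    N-terminal stretch is shorter than the window or no window qualifies.
    The caller treats a detected H0 as part of the MIR.
    """
    if domain_start <= 1:
        return None
    stretch = sequence[: domain_start - 1]
    if len(stretch) < window:
        return None
    qualifying = [
        hydrophobic_moment(stretch[i : i + window], angle_deg) >= threshold
        for i in range(len(stretch) - window + 1)
    ]
    best: Optional[tuple[int, int]] = None  # window-index run [first, last]
    run_start = None
    for i, ok in enumerate(qualifying + [False]):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            if best is None or (i - run_start) > (best[1] - best[0] + 1):
                best = (run_start, i - 1)
            run_start = None
    if best is None:
        return None
    return (best[0] + 1, best[1] + window)  # 1-based residue span of the run


def region_charge_density(sequence: str, ann: RegionAnnotation) -> dict[str, float]:
    """Fraction of basic (K/R) residues in the MIR and in the NBR.

    Membrane-interaction surfaces of these domains are strongly basic, so a
    markedly higher MIR density is a quick plausibility check on a curated
    or transferred annotation.
    """
    out = {}
    for name, intervals in (("MIR", ann.mir_intervals), ("NBR", ann.nbr_intervals)):
        n = _interval_len(intervals)
        if n == 0:
            out[name] = float("nan")
            continue
        kr = sum(
            1
            for a, b in intervals
            for c in sequence[a - 1 : b]
            if c in "KR"
        )
        out[name] = kr / n
    return out
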
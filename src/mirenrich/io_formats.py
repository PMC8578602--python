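"""Readers and writers for every external artifact the pipeline touches.

All coordinates are 1-based positions on the full-length protein sequence and
all intervals are closed, matching the UniProt convention used for domain
ranges.  Structure files carry author numbering which routinely drifts from
full-length numbering, so structure residues are re-anchored onto the
sequence by global alignment (:func:`map_structure_to_sequence`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
VALID_LETTERS = set(AA20 + "X")

# parent-letter mapping for the nonstandard residues that show up in real
# PDB entries; anything absent maps to X
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEP": "S", "TPO": "T", "PTR": "Y", "CSO": "C",
    "HYP": "P", "MLY": "K", "ALY": "K", "KCX": "K", "SEC": "C",
    "PYL": "K",
}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class CalphaTrace:
    """One Calpha per residue of a structure chain, in author order.

    ``seq_positions[i]`` is the 1-based full-length sequence position of
    residue ``i`` (``None`` if unmapped); it is filled by
    :func:`map_structure_to_sequence`.
    """

    author_ids: list
    sequence: str
    coords: np.ndarray  # (N, 3) Angstrom
    seq_positions: Optional[list] = None

    def __len__(self) -> int:
        return len(self.sequence)

    def mapped_pairs(self):
        """Yield (full_length_position, coord) for mapped residues."""
        if self.seq_positions is None:
            raise ValueError("structure has not been mapped to a sequence")
        for pos, xyz in zip(self.seq_positions, self.coords):
            if pos is not None:
                yield pos, xyz


@dataclass
class DomainRecord:
    """One family member: full-length sequence plus its domain interval."""

    protein_id: str
    family: str  # BAR | PX | C2 | EHD
    sequence: str
    domain_range: tuple[int, int]
    subtype: Optional[str] = None  # N-BAR | F-BAR | PX-BAR | C2A-like | C2B-like
    structure: Optional[CalphaTrace] = None

    def __post_init__(self) -> None:
        start, end = self.domain_range
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(
                f"{self.protein_id}: domain_range {self.domain_range} outside "
                f"sequence of length {len(self.sequence)}"
            )
        bad = set(self.sequence.upper()) - VALID_LETTERS
        if bad:
            raise ValueError(f"{self.protein_id}: invalid residue letters {sorted(bad)}")
        self.sequence = self.sequence.upper()

    @property
    def domain_length(self) -> int:
        return self.domain_range[1] - self.domain_range[0] + 1

    def domain_sequence(self) -> str:
        s, e = self.domain_range
        return self.sequence[s - 1 : e]


@dataclass
class AcetylationSiteTable:
    """Acetyl-lysine site list emulating a Phosphosite-style export.

    ``table`` has columns protein_id, position (1-based int), residue,
    modification; duplicates by (protein_id, position) are collapsed on read.
    """

    table: pd.DataFrame
    n_input_rows: int = 0

    def __post_init__(self) -> None:
        if self.n_input_rows == 0:
            self.n_input_rows = len(self.table)

    def __len__(self) -> int:
        return len(self.table)

    def for_protein(self, protein_id: str) -> pd.DataFrame:
        return self.table[self.table["protein_id"] == protein_id]


SITE_COLUMNS = ["protein_id", "position", "residue", "modification"]


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, upper-cased sequence) tuples."""
    path = Path(path)
    records = []
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise ParseError(f"{path}:1: FASTA must start with '>'")
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty record {rec.id!r}")
        records.append((rec.id, seq))
    return records


def write_fasta(path, records: Sequence[tuple[str, str]]) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def _residue_one_letter(name: str) -> str:
    return THREE_TO_ONE.get(name.upper(), "X")


def read_structure(path, chain: str) -> CalphaTrace:
    """Read a legacy PDB or mmCIF file and extract one chain's Calpha trace.

    One Calpha per residue in author numbering; altloc '' or 'A' only (single
    deterministic conformer); residues lacking a Calpha are skipped with a
    warning.  The derived one-letter sequence comes from the 3-letter codes.
    """
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    model = structure[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise ParseError(f"{path}: chain {chain!r} not found")
    author_ids, letters, coords = [], [], []
    for res in ch:
        ca = None
        for atom in res:
            if atom.name == "CA" and atom.altloc in ("\0", "", "A"):
                ca = atom
                break
        if ca is None:
            warnings.warn(
                f"{path} chain {chain}: residue {res.name} {res.seqid.num} "
                "has no Calpha; skipped"
            )
            continue
        author_ids.append(res.seqid.num)
        letters.append(_residue_one_letter(res.name))
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
    if not coords:
        raise ParseError(f"{path}: chain {chain!r} has zero Calpha atoms")
    return CalphaTrace(author_ids, "".join(letters), np.asarray(coords, dtype=float))


def read_sites(path, min_evidence: Optional[int] = None) -> AcetylationSiteTable:
    """Read an acetylation-site TSV (protein_id, position, residue, modification).

    Duplicate (protein_id, position) rows are collapsed, keeping the first.
    An optional ``evidence`` column may be present; when ``min_evidence`` is
    given, rows below it are dropped (default: unfiltered).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    n_input = len(df)
    if n_input:
        try:
            df["position"] = df["position"].astype(int)
        except ValueError as exc:
            raise ParseError(f"{path}: non-integer position: {exc}") from exc
        if (df["position"] < 1).any():
            bad = df.loc[df["position"] < 1].iloc[0]
            raise ParseError(
                f"{path}: position must be >= 1 (got {bad['position']} for "
                f"{bad['protein_id']})"
            )
        df["residue"] = df["residue"].str.upper()
        bad_res = set(df["residue"]) - VALID_LETTERS
        if bad_res:
            raise ParseError(f"{path}: unknown residue letters {sorted(bad_res)}")
        if min_evidence is not None and "evidence" in df.columns:
            df = df[df["evidence"].astype(float) >= min_evidence]
        df = df.drop_duplicates(subset=["protein_id", "position"], keep="first")
    else:
        df["position"] = df["position"].astype(int)
    df = df.reset_index(drop=True)
    return AcetylationSiteTable(df, n_input_rows=n_input)


def write_sites(path, sites: AcetylationSiteTable) -> None:
    sites.table.to_csv(path, sep="\t", index=False)


def map_structure_to_sequence(
    struct_sequence: str, full_sequence: str, min_identity_pct: float = 90.0
) -> list[Optional[int]]:
    """Anchor structure residues onto full-length 1-based sequence positions.

    Globally aligns the structure-derived sequence against the full-length
    sequence; structure residues aligned to a sequence position map there,
    unaligned ones (insertions relative to the full sequence) map to None.
    Identity below ``min_identity_pct`` over aligned columns means the chain
    does not belong to this protein and is an error.
    """
    from .alignment import AlignParams, global_align

    if not struct_sequence or not full_sequence:
        raise ValueError("sequences must be non-empty")
    params = AlignParams()
    amap = global_align(struct_sequence, full_sequence, params)
    # identity over paired columns only: missing loops (gaps) are normal in
    # structures and must not trip the wrong-chain check
    if not amap.pairs:
        identity = 0.0
    else:
        matches = sum(
            struct_sequence[a - 1] == full_sequence[b - 1] for a, b in amap.pairs
        )
        identity = 100.0 * matches / len(amap.pairs)
    if identity < min_identity_pct:
        raise ValueError(
            f"structure/sequence identity {identity:.1f}% < {min_identity_pct}%: "
            "wrong chain or protein"
        )
    positions: list[Optional[int]] = [None] * len(struct_sequence)
    for pos_struct, pos_full in amap.pairs:
        positions[pos_struct - 1] = pos_full
    return positions


# ---------------------------------------------------------------------------
# region configuration (template MIR definitions)
# ---------------------------------------------------------------------------

def _validate_intervals(intervals, domain_range, who: str):
    start, end = domain_range
    prev_end = None
    for a, b in intervals:
        if a > b:
            raise ValueError(f"{who}: interval [{a},{b}] inverted")
        if a < start or b > end:
            raise ValueError(
                f"{who}: interval [{a},{b}] outside domain_range [{start},{end}]"
            )
        if prev_end is not None and a <= prev_end:
            raise ValueError(f"{who}: intervals overlap or are unsorted at [{a},{b}]")
        prev_end = b


def read_region_config(path) -> dict:
    """Read a template region-definition config (YAML or JSON).

    Schema::

        coords: 1-based-closed
        templates:
          <protein_id>:
            family: BAR
            domain_range: [start, end]
            mir: [[a, b], ...]
            kink_segments: [[a, b], [c, d]]   # optional
            h0_range: [a, b]                  # optional curated override
            provenance: free text             # optional

    Intervals must be sorted, disjoint, and inside the domain range.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg.get("coords") != "1-based-closed":
        raise ParseError(f"{path}: config must declare coords: 1-based-closed")
    templates = cfg.get("templates", {})
    for name, entry in templates.items():
        dr = tuple(entry["domain_range"])
        mir = [tuple(iv) for iv in entry.get("mir", [])]
        _validate_intervals(mir, dr, f"{path}:{name}")
        entry["domain_range"] = dr
        entry["mir"] = mir
        if "kink_segments" in entry:
            segs = [tuple(iv) for iv in entry["kink_segments"]]
            _validate_intervals(segs, dr, f"{path}:{name} kink_segments")
            entry["kink_segments"] = segs
    return cfg


def write_region_config(path, templates: dict) -> None:
    out = {"coords": "1-based-closed", "templates": {}}
    for name, entry in templates.items():
        e = dict(entry)
        e["domain_range"] = list(entry["domain_range"])
        e["mir"] = [list(iv) for iv in entry["mir"]]
        if "kink_segments" in e:
            e["kink_segments"] = [list(iv) for iv in e["kink_segments"]]
        out["templates"][name] = e
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based, closed intervals on full-length sequence\n")
        yaml.safe_dump(out, fh, sort_keys=True)


def write_region_bed(path, protein_id: str, annotation) -> None:
    """Serialize a region annotation to a BED-like TSV (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("# coords: 1-based-closed\n")
        fh.write("protein_id\tstart\tend\tregion\tprovenance\n")
        for a, b in annotation.mir_intervals:
            fh.write(f"{protein_id}\t{a}\t{b}\tMIR\t{annotation.provenance}\n")
        for a, b in annotation.nbr_intervals:
            fh.write(f"{protein_id}\t{a}\t{b}\tNBR\t{annotation.provenance}\n")
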
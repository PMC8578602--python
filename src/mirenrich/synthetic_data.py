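"""Fully synthetic domain families with a planted MIR:NBR acetylation bias.

The generator emulates the statistical structure the analysis assumes: a
curated template with known membrane-interaction intervals, homologs at a
controlled percent identity (point substitutions plus sparse indels, with
the true region labels book-kept through every edit), and an acetylation
site table in which each MIR lysine is modified with probability
``base_rate * rho`` and each NBR lysine with ``base_rate``.  Toy structures
are ideal helical Calpha traces (3.8 A consecutive spacing) — enough to
exercise superposition and segment logic without claiming realistic folds.

Everything is deterministic given ``SyntheticFamilySpec.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import (
    AA20,
    THREE_TO_ONE,
    AcetylationSiteTable,
    CalphaTrace,
    DomainRecord,
    write_fasta,
    write_region_config,
    write_sites,
)
from .region_annotation import RegionAnnotation, TemplateDefinition

ONE_TO_THREE = {v: k for k, v in reversed(list(THREE_TO_ONE.items())) if len(k) == 3}
NON_K = AA20.replace("K", "")

# ideal alpha-helix Calpha trace: 100 deg turn, 1.5 A rise, radius chosen so
# consecutive Calpha-Calpha distance is exactly 3.8 A
_HELIX_TURN = np.deg2rad(100.0)
_HELIX_RISE = 1.5
_HELIX_RADIUS = np.sqrt(3.8**2 - _HELIX_RISE**2) / (2 * np.sin(_HELIX_TURN / 2))


@dataclass
class SyntheticFamilySpec:
    """Parameters of one synthetic domain family."""

    family: str = "BAR"
    n_domains: int = 10
    domain_length: int = 250
    mir_intervals: list = field(default_factory=lambda: [(20, 60), (120, 170)])
    target_identity_pct: float = 70.0
    indel_rate: float = 0.01
    lysine_fraction: float = 0.12
    base_rate: float = 0.15
    rho: float = 5.0
    seed: int = 0
    with_structures: bool = False
    coord_noise: float = 0.3  # Angstrom, homolog Calpha jitter

    def __post_init__(self) -> None:
        if not 0 < self.base_rate * self.rho <= 1:
            raise ValueError("base_rate * rho must be in (0, 1]")
        if not 0 <= self.indel_rate <= 0.05:
            raise ValueError("indel_rate must be in [0, 0.05]")
        if not 30 <= self.target_identity_pct <= 100:
            raise ValueError("target_identity_pct must be in [30, 100]")
        self.mir_intervals = [tuple(iv) for iv in self.mir_intervals]
        for a, b in self.mir_intervals:
            if a < 1 or b > self.domain_length or a > b:
                raise ValueError(
                    f"MIR interval [{a},{b}] outside [1,{self.domain_length}]"
                )


def _helix_coords(n: int) -> np.ndarray:
    i = np.arange(n)
    theta = _HELIX_TURN * i
    return np.column_stack(
        [_HELIX_RADIUS * np.cos(theta), _HELIX_RADIUS * np.sin(theta), _HELIX_RISE * i]
    )


def _random_sequence(rng: np.random.Generator, length: int, lysine_fraction: float) -> str:
    is_k = rng.random(length) < lysine_fraction
    others = rng.integers(0, len(NON_K), size=length)
    return "".join("K" if k else NON_K[o] for k, o in zip(is_k, others))


def generate_template(spec: SyntheticFamilySpec) -> TemplateDefinition:
    """Random template at the requested lysine composition with its MIRs."""
    rng = np.random.default_rng(spec.seed)
    seq = _random_sequence(rng, spec.domain_length, spec.lysine_fraction)
    structure = None
    if spec.with_structures:
        coords = _helix_coords(spec.domain_length)
        structure = CalphaTrace(
            author_ids=list(range(1, spec.domain_length + 1)),
            sequence=seq,
            coords=coords,
            seq_positions=list(range(1, spec.domain_length + 1)),
        )
    record = DomainRecord(
        protein_id=f"{spec.family}_template",
        family=spec.family,
        sequence=seq,
        domain_range=(1, spec.domain_length),
        structure=structure,
    )
    ann = RegionAnnotation(
        (1, spec.domain_length), list(spec.mir_intervals), provenance="synthetic truth"
    )
    return TemplateDefinition(record, ann, provenance="synthetic template")


def _measure_identity(seq_a: str, seq_b: str) -> float:
    from .alignment import AlignParams, global_align

    amap = global_align(seq_a, seq_b, AlignParams())
    return amap.identity_pct


def mutate_homolog(
    template: TemplateDefinition,
    spec: SyntheticFamilySpec,
    index: int,
    max_retries: int = 25,
) -> tuple[DomainRecord, RegionAnnotation]:
    """Mutate the template into a homolog at the target percent identity.

    Point substitutions at an adaptively tuned rate plus indels at
    ``spec.indel_rate``; the measured identity (global alignment against the
    template) must land within +-3 points of the target or the generation
    errors out.  The true MIR labels are carried through every edit:
    substituted residues keep their label, inserted residues are MIR only
    when flanked by MIR on both sides, deletions shift downstream intervals.
    """
    rng = np.random.default_rng((spec.seed * 100003 + 7919 * (index + 1)) % 2**31)
    tmpl_seq = template.record.sequence
    tmpl_ann = template.annotation
    tmpl_coords = (
        template.record.structure.coords if template.record.structure else None
    )
    sub_rate = 1.0 - spec.target_identity_pct / 100.0
    if spec.target_identity_pct >= 100.0:
        sub_rate = 0.0
    indel_rate = spec.indel_rate if spec.target_identity_pct < 100 else 0.0

    for attempt in range(max_retries):
        letters: list[str] = []
        labels: list[str] = []
        coords: list[np.ndarray] = []
        for pos0, res in enumerate(tmpl_seq):
            label = tmpl_ann.region_of(pos0 + 1)
            r = rng.random()
            if r < indel_rate / 2:  # deletion
                continue
            if r < indel_rate:  # insertion before this residue
                left = labels[-1] if labels else "NBR"
                ins_label = "MIR" if (left == "MIR" and label == "MIR") else "NBR"
                letters.append(AA20[rng.integers(0, 20)])
                labels.append(ins_label)
                if tmpl_coords is not None:
                    prev = coords[-1] if coords else tmpl_coords[pos0] - [0, 0, _HELIX_RISE]
                    coords.append((prev + tmpl_coords[pos0]) / 2)
            if rng.random() < sub_rate:
                choices = AA20.replace(res, "")
                letters.append(choices[rng.integers(0, len(choices))])
            else:
                letters.append(res)
            labels.append(label)
            if tmpl_coords is not None:
                coords.append(tmpl_coords[pos0].copy())
        seq = "".join(letters)
        ident = _measure_identity(tmpl_seq, seq) if sub_rate or indel_rate else 100.0
        if abs(ident - spec.target_identity_pct) <= 3.0:
            break
        # feedback: nudge the substitution rate toward the target (damped,
        # since alignment recovers some chance matches at high sub rates)
        sub_rate = min(
            0.7,
            max(0.0, sub_rate + 0.6 * (ident - spec.target_identity_pct) / 100.0),
        )
    else:
        raise RuntimeError(
            f"could not reach identity {spec.target_identity_pct}% +-3 "
            f"after {max_retries} attempts (last {ident:.1f}%)"
        )

    mir_intervals: list[tuple[int, int]] = []
    for pos0, lab in enumerate(labels):
        if lab == "MIR":
            p = pos0 + 1
            if mir_intervals and p == mir_intervals[-1][1] + 1:
                mir_intervals[-1] = (mir_intervals[-1][0], p)
            else:
                mir_intervals.append((p, p))

    structure = None
    if tmpl_coords is not None:
        arr = np.asarray(coords) + rng.normal(0, spec.coord_noise, (len(coords), 3))
        structure = CalphaTrace(
            author_ids=list(range(1, len(seq) + 1)),
            sequence=seq,
            coords=arr,
            seq_positions=list(range(1, len(seq) + 1)),
        )
    record = DomainRecord(
        protein_id=f"{spec.family}_{index:03d}",
        family=spec.family,
        sequence=seq,
        domain_range=(1, len(seq)),
        structure=structure,
    )
    truth = RegionAnnotation((1, len(seq)), mir_intervals, provenance="synthetic truth")
    return record, truth


def plant_acetylation(
    domains: list[tuple[DomainRecord, RegionAnnotation]],
    spec: SyntheticFamilySpec,
    seed: Optional[int] = None,
) -> AcetylationSiteTable:
    """Bernoulli acetylation per lysine: rate base_rate*rho in the MIR,
    base_rate in the NBR; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    for record, truth in domains:
        for pos0, res in enumerate(record.sequence):
            if res != "K":
                continue
            pos = pos0 + 1
            rate = spec.base_rate * (spec.rho if truth.region_of(pos) == "MIR" else 1.0)
            if rng.random() < rate:
                rows.append((record.protein_id, pos, "K", "ac"))
    df = pd.DataFrame(rows, columns=["protein_id", "position", "residue", "modification"])
    if df.empty:
        df["position"] = df["position"].astype(int)
    return AcetylationSiteTable(df)


@dataclass
class FamilyBundle:
    """In-memory synthetic family: template, members with truth, sites."""

    spec: SyntheticFamilySpec
    template: TemplateDefinition
    members: list  # (DomainRecord, RegionAnnotation truth)
    sites: AcetylationSiteTable


def generate_family(spec: SyntheticFamilySpec) -> FamilyBundle:
    """Template + homologs + planted acetylation table for one family."""
    template = generate_template(spec)
    members = [
        mutate_homolog(template, spec, i) for i in range(spec.n_domains)
    ]
    sites = plant_acetylation(
        [(template.record, template.annotation)] + members, spec,
        seed=(spec.seed * 99991 + 17) % 2**31,
    )
    return FamilyBundle(spec, template, members, sites)


def _write_toy_pdb(path, record: DomainRecord) -> None:
    trace = record.structure
    with open(path, "w") as fh:
        for i, (res, xyz) in enumerate(zip(trace.sequence, trace.coords)):
            name = ONE_TO_THREE.get(res, "UNK")
            fh.write(
                f"ATOM  {i + 1:5d}  CA  {name:>3s} A{trace.author_ids[i]:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


def emit_bundle(specs: list[SyntheticFamilySpec], outdir) -> dict:
    """Write synthetic families to disk in the pipeline's input formats.

    Produces ``sequences.fasta``, ``sites.tsv``, ``regions.yaml``, optional
    ``structures/<id>.pdb`` files, and ``ground_truth.json`` holding the
    true region intervals and planted rates for test harnesses.  Returns the
    manifest dict.  Two runs with the same specs are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_records = []
    site_frames = []
    templates_cfg: dict = {}
    truth: dict = {"families": {}}
    for spec in specs:
        bundle = generate_family(spec)
        all_domains = [(bundle.template.record, bundle.template.annotation)] + bundle.members
        for record, ann in all_domains:
            fasta_records.append((record.protein_id, record.sequence))
            if record.structure is not None:
                sdir = outdir / "structures"
                sdir.mkdir(exist_ok=True)
                _write_toy_pdb(sdir / f"{record.protein_id}.pdb", record)
        site_frames.append(bundle.sites.table)
        templates_cfg[bundle.template.record.protein_id] = {
            "family": spec.family,
            "domain_range": bundle.template.annotation.domain_range,
            "mir": bundle.template.annotation.mir_intervals,
            "provenance": "synthetic template",
        }
        truth["families"][spec.family] = {
            "spec": {
                k: v for k, v in asdict(spec).items() if k != "mir_intervals"
            } | {"mir_intervals": [list(iv) for iv in spec.mir_intervals]},
            "regions": {
                record.protein_id: {
                    "domain_range": list(ann.domain_range),
                    "mir": [list(iv) for iv in ann.mir_intervals],
                }
                for record, ann in all_domains
            },
        }
    write_fasta(outdir / "sequences.fasta", fasta_records)
    sites_df = pd.concat(site_frames, ignore_index=True) if site_frames else pd.DataFrame(
        columns=["protein_id", "position", "residue", "modification"]
    )
    write_sites(outdir / "sites.tsv", AcetylationSiteTable(sites_df))
    write_region_config(outdir / "regions.yaml", templates_cfg)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    manifest = {
        "n_families": len(specs),
        "seeds": [s.seed for s in specs],
        "files": ["sequences.fasta", "sites.tsv", "regions.yaml", "ground_truth.json"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
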
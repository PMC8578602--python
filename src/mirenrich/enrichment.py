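"""Region-wise acetylation tallies and enrichment statistics.

For each domain the acetylated lysines are assigned to the MIR or NBR and
two frequencies are computed per region:

* ``%K_AC``  — acetyl-lysine count / region residue count x 100
* ``%K_AC/K`` — acetyl-lysine count / region lysine count x 100 (controls
  for the higher lysine abundance of membrane-binding surfaces)

and the MIR/NBR fold ratio of each.  Domains are further classified by where
the majority of their acetylation falls (raw site counts, not frequencies)
and whether it is exclusive to one region.  Family summaries pool counts
across domains before normalizing (sum before divide); the all-family
average pools every domain the same way rather than averaging family means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import AcetylationSiteTable, DomainRecord
from .region_annotation import RegionAnnotation, adjust_boundaries


@dataclass
class RegionTally:
    n_residues: int
    n_lysines: int
    n_ack: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_ack <= self.n_lysines <= self.n_residues):
            raise ValueError(
                f"inconsistent tally: {self.n_ack} acK / {self.n_lysines} K / "
                f"{self.n_residues} residues"
            )

    def __add__(self, other: "RegionTally") -> "RegionTally":
        return RegionTally(
            self.n_residues + other.n_residues,
            self.n_lysines + other.n_lysines,
            self.n_ack + other.n_ack,
        )


@dataclass
class RegionCounts:
    """Residue / lysine / acetyl-lysine tallies for the MIR and the NBR."""

    mir: RegionTally
    nbr: RegionTally

    def __add__(self, other: "RegionCounts") -> "RegionCounts":
        return RegionCounts(self.mir + other.mir, self.nbr + other.nbr)

    @property
    def total_ack(self) -> int:
        return self.mir.n_ack + self.nbr.n_ack


@dataclass
class SiteAssignment:
    """Outcome of placing one protein's sites onto a domain annotation."""

    acetylated_positions: set  # in-domain K positions carrying acetylation
    outside_domain: list  # positions outside the domain range
    quarantined: list  # (position, reason) — audit trail, never silently dropped
    n_input_sites: int


@dataclass
class EnrichmentStats:
    """Per-region frequencies and MIR/NBR fold ratios.

    Undefined quantities (empty region, zero NBR numerator/denominator) are
    NaN with the matching ``*_defined`` flag False; they are excluded from
    pooled ratio computations downstream rather than imputed.
    """

    pct_kac_mir: float
    pct_kac_nbr: float
    pct_kac_per_k_mir: float
    pct_kac_per_k_nbr: float
    ratio_kac: float
    ratio_kac_per_k: float
    ratio_kac_defined: bool
    ratio_kac_per_k_defined: bool


@dataclass
class DomainClass:
    """Where a domain's acetylation falls: majority and exclusivity."""

    majority: str  # MIR_majority | NBR_majority | tie
    exclusivity: str  # MIR_only | NBR_only | mixed | none


@dataclass
class PerDomainResult:
    protein_id: str
    family: str
    counts: RegionCounts
    stats: EnrichmentStats
    domain_class: DomainClass
    assignment: Optional[SiteAssignment] = None


@dataclass
class FamilySummary:
    """Pooled counts, frequencies and classification fractions for a family."""

    family: str
    n_domains: int
    pooled_counts: RegionCounts
    pooled_stats: EnrichmentStats
    n_with_sites: int
    n_ties: int
    fraction_mir_majority: float  # over domains with >= 1 site
    fraction_mir_only: float
    fraction_mir_majority_all: float  # over all domains (alt. denominator)
    fraction_mir_only_all: float


def map_sites_to_domain(
    record: DomainRecord, ann: RegionAnnotation, sites: AcetylationSiteTable
) -> SiteAssignment:
    """Place a protein's acetylation sites onto its domain annotation.

    Sites inside the domain range at a lysine are flagged; sites whose
    residue letter disagrees with the sequence, or that fall on a non-lysine
    position or beyond the sequence, are quarantined with a reason; sites
    outside the domain range are tallied separately (they belong to neither
    region).
    """
    rows = sites.for_protein(record.protein_id)
    acetylated: set = set()
    outside: list = []
    quarantined: list = []
    for row in rows.itertuples(index=False):
        pos = int(row.position)
        if pos > len(record.sequence):
            quarantined.append((pos, "position beyond sequence length"))
            continue
        seq_res = record.sequence[pos - 1]
        if seq_res != row.residue.upper():
            quarantined.append(
                (pos, f"site residue {row.residue} != sequence residue {seq_res}")
            )
            continue
        if ann.region_of(pos) is None:
            outside.append(pos)
            continue
        if seq_res != "K":
            quarantined.append((pos, f"acetylation reported on non-lysine {seq_res}"))
            continue
        acetylated.add(pos)
    return SiteAssignment(acetylated, outside, quarantined, len(rows))


def count_regions(
    record: DomainRecord, ann: RegionAnnotation, assignment: SiteAssignment
) -> RegionCounts:
    """Exact per-region residue, lysine, and acetyl-lysine tallies."""
    tallies = {}
    for name, intervals in (("MIR", ann.mir_intervals), ("NBR", ann.nbr_intervals)):
        n_res = n_k = n_ack = 0
        for a, b in intervals:
            for pos in range(a, b + 1):
                n_res += 1
                if record.sequence[pos - 1] == "K":
                    n_k += 1
                    if pos in assignment.acetylated_positions:
                        n_ack += 1
        tallies[name] = RegionTally(n_res, n_k, n_ack)
    return RegionCounts(tallies["MIR"], tallies["NBR"])


def _safe_pct(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def frequency_stats(counts: RegionCounts) -> EnrichmentStats:
    """Per-region frequencies and MIR/NBR ratios from raw tallies."""
    m, n = counts.mir, counts.nbr
    pct_kac_mir = _safe_pct(m.n_ack, m.n_residues)
    pct_kac_nbr = _safe_pct(n.n_ack, n.n_residues)
    pct_pk_mir = _safe_pct(m.n_ack, m.n_lysines)
    pct_pk_nbr = _safe_pct(n.n_ack, n.n_lysines)

    def ratio(mir_val: float, nbr_val: float) -> tuple[float, bool]:
        if math.isnan(mir_val) or math.isnan(nbr_val) or nbr_val == 0:
            return float("nan"), False
        return mir_val / nbr_val, True

    r_kac, d_kac = ratio(pct_kac_mir, pct_kac_nbr)
    r_pk, d_pk = ratio(pct_pk_mir, pct_pk_nbr)
    return EnrichmentStats(
        pct_kac_mir, pct_kac_nbr, pct_pk_mir, pct_pk_nbr, r_kac, r_pk, d_kac, d_pk
    )


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding, halves away from zero (2.45 -> 2.5 at one digit).

    Published summary tables are printed with this convention rather than
    the banker's rounding of Python's builtin ``round``.
    """
    x = float(x)
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def classify_domain(counts: RegionCounts) -> DomainClass:
    """Majority/exclusivity classification from raw acetyl-lysine counts."""
    a, b = counts.mir.n_ack, counts.nbr.n_ack
    if a > b:
        majority = "MIR_majority"
    elif b > a:
        majority = "NBR_majority"
    else:
        majority = "tie"
    if a == 0 and b == 0:
        exclusivity = "none"
    elif b == 0:
        exclusivity = "MIR_only"
    elif a == 0:
        exclusivity = "NBR_only"
    else:
        exclusivity = "mixed"
    return DomainClass(majority, exclusivity)


def aggregate_family(
    results: Sequence[PerDomainResult], family: str
) -> FamilySummary:
    """Pool per-domain results into one family row.

    Counts are summed across domains before normalization.  Classification
    fractions use domains with at least one acetylation site as the primary
    denominator (the all-domains denominator is reported alongside); ties
    are counted separately.
    """
    if not results:
        raise ValueError("at least one domain result required")
    pooled = results[0].counts
    for r in results[1:]:
        pooled = pooled + r.counts
    with_sites = [r for r in results if r.counts.total_ack > 0]
    n_mm = sum(1 for r in with_sites if r.domain_class.majority == "MIR_majority")
    n_mo = sum(1 for r in with_sites if r.domain_class.exclusivity == "MIR_only")
    n_ties = sum(1 for r in with_sites if r.domain_class.majority == "tie")
    n_ws = len(with_sites)
    n_all = len(results)
    return FamilySummary(
        family=family,
        n_domains=n_all,
        pooled_counts=pooled,
        pooled_stats=frequency_stats(pooled),
        n_with_sites=n_ws,
        n_ties=n_ties,
        fraction_mir_majority=n_mm / n_ws if n_ws else float("nan"),
        fraction_mir_only=n_mo / n_ws if n_ws else float("nan"),
        fraction_mir_majority_all=n_mm / n_all,
        fraction_mir_only_all=n_mo / n_all,
    )


def evaluate_domain(
    record: DomainRecord, ann: RegionAnnotation, sites: AcetylationSiteTable
) -> PerDomainResult:
    """Full per-domain evaluation: site placement, tallies, stats, class."""
    assignment = map_sites_to_domain(record, ann, sites)
    counts = count_regions(record, ann, assignment)
    return PerDomainResult(
        record.protein_id,
        record.family,
        counts,
        frequency_stats(counts),
        classify_domain(counts),
        assignment,
    )


def sensitivity_sweep(
    domains: Sequence[tuple[DomainRecord, RegionAnnotation]],
    sites: AcetylationSiteTable,
    deltas: Sequence[int] = (-2, -1, 0, 1, 2),
) -> pd.DataFrame:
    """Recompute the family summaries under MIR boundary perturbations.

    Every MIR interval is expanded/contracted by each ``delta`` and the full
    enrichment recomputed; the delta-0 rows are bit-identical to the base
    run.  Returns one row per (delta, family) plus an all-family Average row
    per delta.
    """
    rows = []
    for delta in deltas:
        per_domain: dict[str, list[PerDomainResult]] = {}
        all_results: list[PerDomainResult] = []
        for record, ann in domains:
            ann_d = adjust_boundaries(ann, delta)
            res = evaluate_domain(record, ann_d, sites)
            per_domain.setdefault(record.family, []).append(res)
            all_results.append(res)
        summaries = [
            aggregate_family(res_list, fam)
            for fam, res_list in sorted(per_domain.items())
        ]
        summaries.append(aggregate_family(all_results, "Average"))
        for s in summaries:
            rows.append(
                {
                    "delta": delta,
                    "family": s.family,
                    "n_domains": s.n_domains,
                    "pct_kac_mir": s.pooled_stats.pct_kac_mir,
                    "pct_kac_nbr": s.pooled_stats.pct_kac_nbr,
                    "ratio_kac": s.pooled_stats.ratio_kac,
                    "pct_kac_per_k_mir": s.pooled_stats.pct_kac_per_k_mir,
                    "pct_kac_per_k_nbr": s.pooled_stats.pct_kac_per_k_nbr,
                    "ratio_kac_per_k": s.pooled_stats.ratio_kac_per_k,
                    "fraction_mir_majority": s.fraction_mir_majority,
                    "fraction_mir_only": s.fraction_mir_only,
                }
            )
    return pd.DataFrame(rows)


def permutation_enrichment_test(
    counts: RegionCounts, n_perm: int = 1000, seed: int = 0
) -> float:
    """One-sided permutation p-value for MIR acetylation enrichment.

    Null model: the domain's observed acetylation marks are reassigned
    uniformly at random (without replacement) among all its lysines; the
    statistic is the MIR acetyl-lysine count.  p is the fraction of
    permutations with a statistic >= observed, with add-one smoothing.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    mir_k, nbr_k = counts.mir.n_lysines, counts.nbr.n_lysines
    total_k = mir_k + nbr_k
    if total_k == 0:
        raise ValueError("domain has no lysines")
    n_ack = counts.total_ack
    obs = counts.mir.n_ack
    rng = np.random.default_rng(seed)
    if n_ack == 0:
        draws = np.zeros(n_perm, dtype=int)
    else:
        # uniform reassignment: the n_ack smallest of total_k random keys
        keys = rng.random((n_perm, total_k))
        chosen = np.argpartition(keys, n_ack - 1, axis=1)[:, :n_ack]
        draws = (chosen < mir_k).sum(axis=1)
    return float((1 + int((draws >= obs).sum())) / (1 + n_perm))


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
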
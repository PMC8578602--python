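"""Model/results objects presenting the region-enrichment analysis.

``MembraneAcetylationModel`` is built from annotated domains (each a
``DomainRecord`` with its MIR/NBR ``RegionAnnotation``) plus an acetylation
site table; ``fit()`` performs the tallies and returns an
``EnrichmentResults`` with per-domain and per-family tables, a printable
summary, the boundary-sensitivity sweep, permutation p-values, and a small
classification plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .enrichment import (
    FamilySummary,
    PerDomainResult,
    aggregate_family,
    benjamini_hochberg,
    evaluate_domain,
    permutation_enrichment_test,
    round_half_up,
    sensitivity_sweep,
)
from .io_formats import AcetylationSiteTable, DomainRecord
from .region_annotation import RegionAnnotation


class MembraneAcetylationModel:
    """Acetylation enrichment in membrane-interaction regions.

    Parameters
    ----------
    domains
        ``(record, annotation)`` pairs; the annotation is a curated template
        definition or one transferred from a template by alignment.
    sites
        Acetylation site table covering the records' protein ids.

    Examples
    --------
    >>> from mirenrich import SyntheticFamilySpec, MembraneAcetylationModel
    >>> spec = SyntheticFamilySpec(family="BAR", n_domains=6, seed=1)
    >>> res = MembraneAcetylationModel.from_synthetic([spec]).fit()
    >>> res.families.loc["Average", "ratio_kac_per_k"] > 1
    np.True_
    """

    def __init__(
        self,
        domains: Sequence[tuple[DomainRecord, RegionAnnotation]],
        sites: AcetylationSiteTable,
    ) -> None:
        if not domains:
            raise ValueError("at least one annotated domain is required")
        self.domains = list(domains)
        self.sites = sites

    @classmethod
    def from_synthetic(cls, specs) -> "MembraneAcetylationModel":
        """Build from synthetic family specs using the ground-truth regions."""
        from .synthetic_data import generate_family

        domains = []
        frames = []
        for spec in specs:
            bundle = generate_family(spec)
            domains.append((bundle.template.record, bundle.template.annotation))
            domains.extend(bundle.members)
            frames.append(bundle.sites.table)
        sites = AcetylationSiteTable(pd.concat(frames, ignore_index=True))
        return cls(domains, sites)

    @classmethod
    def from_files(cls, config) -> "MembraneAcetylationModel":
        """Build from on-disk inputs through the full alignment pipeline."""
        from .cli_pipeline import prepare_domains

        domains, sites, _ = prepare_domains(config)
        return cls(domains, sites)

    def fit(self) -> "EnrichmentResults":
        results = [
            evaluate_domain(record, ann, self.sites)
            for record, ann in self.domains
        ]
        return EnrichmentResults(self, results)


class EnrichmentResults:
    """Fitted enrichment tables plus diagnostics."""

    def __init__(self, model: MembraneAcetylationModel, results: list[PerDomainResult]):
        self.model = model
        self._results = results
        self.per_domain = self._per_domain_frame(results)
        self.family_summaries = self._summaries(results)
        self.families = self._family_frame(self.family_summaries)

    @staticmethod
    def _per_domain_frame(results: list[PerDomainResult]) -> pd.DataFrame:
        rows = []
        for r in results:
            rows.append(
                {
                    "protein_id": r.protein_id,
                    "family": r.family,
                    "mir_residues": r.counts.mir.n_residues,
                    "mir_lysines": r.counts.mir.n_lysines,
                    "mir_ack": r.counts.mir.n_ack,
                    "nbr_residues": r.counts.nbr.n_residues,
                    "nbr_lysines": r.counts.nbr.n_lysines,
                    "nbr_ack": r.counts.nbr.n_ack,
                    "pct_kac_mir": r.stats.pct_kac_mir,
                    "pct_kac_nbr": r.stats.pct_kac_nbr,
                    "pct_kac_per_k_mir": r.stats.pct_kac_per_k_mir,
                    "pct_kac_per_k_nbr": r.stats.pct_kac_per_k_nbr,
                    "ratio_kac": r.stats.ratio_kac,
                    "ratio_kac_per_k": r.stats.ratio_kac_per_k,
                    "majority": r.domain_class.majority,
                    "exclusivity": r.domain_class.exclusivity,
                    "n_quarantined": len(r.assignment.quarantined) if r.assignment else 0,
                    "n_outside_domain": len(r.assignment.outside_domain) if r.assignment else 0,
                }
            )
        return pd.DataFrame(rows).set_index("protein_id")

    @staticmethod
    def _summaries(results: list[PerDomainResult]) -> list[FamilySummary]:
        by_family: dict[str, list[PerDomainResult]] = {}
        for r in results:
            by_family.setdefault(r.family, []).append(r)
        summaries = [
            aggregate_family(lst, fam) for fam, lst in sorted(by_family.items())
        ]
        summaries.append(aggregate_family(results, "Average"))
        return summaries

    @staticmethod
    def _family_frame(summaries: list[FamilySummary]) -> pd.DataFrame:
        rows = []
        for s in summaries:
            rows.append(
                {
                    "family": s.family,
                    "n_domains": s.n_domains,
                    "n_with_sites": s.n_with_sites,
                    "n_ties": s.n_ties,
                    "pct_kac_mir": s.pooled_stats.pct_kac_mir,
                    "pct_kac_nbr": s.pooled_stats.pct_kac_nbr,
                    "ratio_kac": s.pooled_stats.ratio_kac,
                    "pct_kac_per_k_mir": s.pooled_stats.pct_kac_per_k_mir,
                    "pct_kac_per_k_nbr": s.pooled_stats.pct_kac_per_k_nbr,
                    "ratio_kac_per_k": s.pooled_stats.ratio_kac_per_k,
                    "fraction_mir_majority": s.fraction_mir_majority,
                    "fraction_mir_only": s.fraction_mir_only,
                    "fraction_mir_majority_all": s.fraction_mir_majority_all,
                    "fraction_mir_only_all": s.fraction_mir_only_all,
                }
            )
        return pd.DataFrame(rows).set_index("family")

    # -- diagnostics -------------------------------------------------------

    def sensitivity(self, deltas: Sequence[int] = (-2, -1, 0, 1, 2)) -> pd.DataFrame:
        """Family summaries recomputed under MIR boundary perturbations."""
        return sensitivity_sweep(self.model.domains, self.model.sites, deltas)

    def permutation_pvalues(
        self, n_perm: int = 1000, seed: int = 0, adjust: bool = False
    ) -> pd.Series:
        """Per-domain permutation p-values for MIR enrichment.

        Domains without lysines are skipped.  ``adjust=True`` applies a
        Benjamini-Hochberg correction across domains.
        """
        pvals = {}
        for i, r in enumerate(self._results):
            if r.counts.mir.n_lysines + r.counts.nbr.n_lysines == 0:
                continue
            pvals[r.protein_id] = permutation_enrichment_test(
                r.counts, n_perm=n_perm, seed=(seed * 1009 + i) % 2**31
            )
        s = pd.Series(pvals, name="p_mir_enrichment")
        if adjust and len(s):
            s = pd.Series(benjamini_hochberg(s.values), index=s.index, name=s.name)
        return s

    def summary(self) -> str:
        """Printable family table at published precision (half-up rounding:
        per-residue frequencies to 2 decimals, per-lysine to 1)."""
        lines = [
            "Acetylation enrichment in membrane-interaction regions",
            f"domains: {len(self.per_domain)}   acetyl-K sites placed: "
            f"{int(self.per_domain[['mir_ack', 'nbr_ack']].to_numpy().sum())}",
            "",
            f"{'family':<10}{'n':>4}  {'%K_AC':^20}  {'%K_AC/K':^20}",
            f"{'':<10}{'':>4}  {'MIR':>6}{'NBR':>6}{'ratio':>8}  {'MIR':>6}{'NBR':>6}{'ratio':>8}",
        ]
        for fam, row in self.families.iterrows():
            def fmt(v, nd):
                return "nan" if not np.isfinite(v) else f"{round_half_up(v, nd):.{nd}f}"

            lines.append(
                f"{fam:<10}{int(row.n_domains):>4}  "
                f"{fmt(row.pct_kac_mir, 2):>6}{fmt(row.pct_kac_nbr, 2):>6}"
                f"{fmt(row.ratio_kac, 2):>8}  "
                f"{fmt(row.pct_kac_per_k_mir, 1):>6}{fmt(row.pct_kac_per_k_nbr, 1):>6}"
                f"{fmt(row.ratio_kac_per_k, 1):>8}"
            )
        avg = self.families.loc["Average"]
        n_ws = int(avg.n_with_sites)
        lines += [
            "",
            f"domains with >=1 site: {n_ws}; "
            f"MIR-majority: {100 * avg.fraction_mir_majority:.0f}%  "
            f"MIR-only: {100 * avg.fraction_mir_only:.0f}%  "
            f"ties: {int(avg.n_ties)}",
        ]
        return "\n".join(lines)

    def plot_classification(self, ax=None):
        """Bar chart of MIR-majority / MIR-only fractions per family."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        fams = self.families.index.tolist()
        x = np.arange(len(fams))
        ax.bar(x - 0.2, self.families.fraction_mir_majority, width=0.4,
               label="MIR majority")
        ax.bar(x + 0.2, self.families.fraction_mir_only, width=0.4,
               label="MIR only")
        ax.set_xticks(x)
        ax.set_xticklabels(fams)
        ax.set_ylabel("fraction of domains")
        ax.set_ylim(0, 1)
        ax.legend(frameon=False)
        return ax
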
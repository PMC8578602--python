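# mirenrich

Region-wise enrichment of lysine acetylation in peripheral membrane-binding
domains.

## The problem

Peripheral membrane proteins dock onto bilayers through dedicated domains —
BAR, PX, C2 and EHD families — whose membrane-contacting surfaces are rich
in lysines. Acetylation of a lysine neutralizes its positive charge, so if
acetylation regulates membrane binding, acetyl-lysine sites should
concentrate on the membrane-interaction surface rather than being spread
uniformly over the domain.

`mirenrich` tests exactly that. For each domain family a curated *template*
carries literature-defined **membrane-interaction regions (MIRs)**; the rest
of the domain is the **non-binding region (NBR)**. Template definitions are
transferred to every family member by pairwise alignment — Cα superposition
when structures exist (segment-wise across a hinge for kinked F-BAR-like
domains), global sequence alignment otherwise — members below 50% identity
to the template cluster are excluded, and C2 members are assigned to the
C2A-like or C2B-like subtype template (or rejected as degenerate below 50%
similarity to both). Acetyl-lysine sites from a Phosphosite-style export are
then placed onto the transferred regions and tallied.

## The statistics

For each region *R* ∈ {MIR, NBR} with residue count *n_R*, lysine count
*K_R* and acetyl-lysine count *K_AC,R*:

- **%K_AC** = 100 · K_AC,R / n_R   (per-residue frequency)
- **%K_AC/K** = 100 · K_AC,R / K_R  (per-lysine frequency, controlling for
  the higher lysine abundance of membrane-binding surfaces)
- **enrichment ratio** = MIR value / NBR value of either frequency

Per domain, acetylation is classified by *majority* (more raw sites in the
MIR or the NBR, or a tie) and *exclusivity* (MIR-only / NBR-only / mixed).
Family rows pool counts across domains before normalizing (sum, then
divide); the all-family Average row pools every domain the same way. A MIR
boundary perturbation sweep (±1, ±2 residues) checks that conclusions do
not hinge on the exact region limits, and an optional permutation test
draws the null of acetylation assigned uniformly among a domain's lysines.

## Worked example

Real acetylation snapshots are not redistributable, so the package ships a
synthetic generator that plants a known MIR:NBR acetylation rate ratio ρ
over a base per-lysine rate:

```python
from mirenrich import SyntheticFamilySpec, MembraneAcetylationModel

specs = [SyntheticFamilySpec(family=f, n_domains=8, seed=s, rho=5.0)
         for s, f in enumerate(["BAR", "PX"], start=1)]
res = MembraneAcetylationModel.from_synthetic(specs).fit()
print(res.summary())
```

```
Acetylation enrichment in membrane-interaction regions
domains: 18   acetyl-K sites placed: 147

family       n         %K_AC                %K_AC/K
                   MIR   NBR   ratio     MIR   NBR   ratio
BAR          9    4.83  1.48    3.26    72.7  15.9     4.6
PX           9    7.73  1.54    5.00    82.1  13.3     6.2
Average     18    6.28  1.51    4.15    78.2  14.5     5.4

domains with >=1 site: 18; MIR-majority: 89%  MIR-only: 6%  ties: 2
```

The planted fivefold per-lysine bias is recovered in the Average row
(ratio 5.4 here; the estimate is within sampling error of ρ = 5), and most
domains are MIR-majority. `res.sensitivity()` returns the boundary sweep,
`res.permutation_pvalues()` per-domain significance, and
`res.plot_classification()` a bar chart of the classification fractions.

The same analysis runs from files (FASTA + sites TSV + region-config YAML,
with optional PDB/mmCIF structures) through a single config:

```bash
mirenrich simulate --out bundle --seed 7          # synthetic input bundle
mirenrich run config.yaml --out results           # full analysis
mirenrich validate-config config.yaml             # dry-run checks
```

`results/` then holds `per_domain.tsv`, `families.tsv`, `sensitivity.tsv`,
`exclusions.tsv` and a `manifest.json` recording the alignment path and
inclusion decision for every input protein.

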
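# Methods

## Model and procedure

The analysis treats a membrane-binding domain as a 1-based closed interval
on its full-length protein sequence, partitioned exactly into a
membrane-interaction region (MIR, the residues experimentally shown to
contact the bilayer) and its complement, the non-binding region (NBR). MIRs
are curated only on a small number of template domains; every other family
member receives its annotation by homology transfer through a residue
correspondence with the template. The quantity of interest is the
enrichment of acetyl-lysine in the MIR, measured per residue (%K_AC) and
per lysine (%K_AC/K) with the MIR/NBR fold ratio of each; the per-lysine
form controls for the fact that membrane-binding surfaces are themselves
lysine-rich, so a per-residue enrichment alone could reflect composition
rather than targeting.

Assumptions worth stating explicitly:

- Annotation transfer assumes the membrane-binding surface is positionally
  conserved among homologs above the identity threshold; this is the same
  assumption that justifies using templates at all.
- Site tables are treated as binary (a lysine is acetylated or not);
  stoichiometry and evidence counts are ignored by default (an optional
  `min_evidence` filter exists but is off, since no principled default
  exists).
- Counts are pooled across domains before normalization ("sum before
  divide"), so large domains carry proportionally more weight in family
  rows; the all-family Average row pools every domain the same way rather
  than averaging family means, which would weight a 4-member family as
  heavily as a 22-member one.

## Alignment

Sequence alignment is global Needleman–Wunsch with affine gaps (Gotoh's
three-state recursion), BLOSUM62, gap open 10, gap extend 0.5 — the EMBOSS
NEEDLE parameterization, which is also the tool family the C2 subtype
assignment emulates. A gap of length L costs `open + extend·L`; end gaps
are penalized. Traceback ties are broken diagonal > up > left at every
choice point, making outputs bit-reproducible; the test-suite checks score
and traceback against exhaustive enumeration of all alignments on short
pairs. Percent identity and similarity are computed over alignment columns
between the first and last aligned pair (internal gaps count in the
denominator, terminal overhangs do not); similarity counts columns with a
positive substitution score.

Template-versus-member pairwise alignment is used instead of a progressive
multiple alignment: annotation transfer only needs the template↔member
correspondence, and pairwise NW is exactly specifiable and testable against
an independent oracle.

Structural alignment seeds the correspondence from the sequence alignment
of the two Cα-derived sequences, superposes with the Kabsch algorithm
(SVD, reflection corrected to det +1), drops pairs with residual distance
above 5 Å, and superposes once more; fewer than 20 surviving pairs is
treated as an unreliable superposition and is an error. The 5 Å cutoff and
single refinement round mirror common superposition-refinement practice.
For kinked domains (F-BAR tips rotate relative to the central module) each
declared segment gets an independent rigid superposition and the per-segment
maps are concatenated, dropping any later pair that would break
monotonicity.

Family filtering is single-linkage clustering seeded at the template:
members reaching 50% identity to the template, or (in the default linkage
mode) to any already-clustered member, are kept; the rest are excluded and
logged. A stricter template-only mode is a config switch, since reasonable
pipelines differ here. C2 members are scored for similarity against both
the C2A-like and C2B-like templates; below 50% to both marks a degenerate
(non-functional) C2 fold which is excluded, otherwise the member follows
the more similar template, with an exact tie going to C2A-like with a
warning.

## Annotation transfer and controls

Aligned target residues inherit their template partner's label. Insertions
(target residues with no partner) become MIR only when both nearest aligned
flanks are MIR — an insertion strictly inside a membrane-binding surface
most plausibly stays on that surface — and NBR otherwise. This insertion
rule is the largest genuinely open design choice in the transfer step; its
effect is bounded by the boundary-perturbation sweep, which grows or
shrinks every MIR interval by ±1–2 residues (clipping at the domain edge,
merging intervals that touch, deleting intervals contracted to nothing) and
recomputes the full analysis per delta. The delta-0 row is bit-identical to
the base run by construction.

N-terminal amphipathic (H0) helices of N-BAR domains are membrane-embedded
in situ but often unresolved in crystal structures. When enabled, the
detector slides an 11-residue window over the pre-domain stretch and
computes the mean helical hydrophobic moment (Eisenberg consensus scale,
100°/residue); the longest run of windows with μH ≥ 0.25 is reported as
the H0 interval and treated as MIR. Curated per-protein H0 ranges in the
region config take precedence — the window/threshold defaults are a
screening heuristic, not a validated predictor. A basic-residue (K/R)
charge-density readout per region is provided as a plausibility check on
curated or transferred definitions, since these membrane-binding surfaces
are strongly basic.

## Site placement and bookkeeping

Sites are matched by (protein id, 1-based position); duplicates collapse on
read. A site whose stated residue disagrees with the sequence, or that
falls on a non-lysine, is quarantined with a reason rather than silently
dropped; sites outside the domain range are tallied separately. For every
protein, placed + outside + quarantined equals the input row count — an
invariant the test-suite enforces on random inputs.

Printed tables use half-away-from-zero decimal rounding (per-residue
frequencies at 2 decimals, per-lysine at 1), not banker's rounding — this
is the convention the published summary table follows, and three of its
per-residue ratio cells are reproducible only with pre-rounding division,
so those cells are excluded from the worked-example checks.

## Permutation test

The optional significance check reassigns the domain's observed acetylation
marks uniformly without replacement among all its lysines and uses the MIR
acetyl count as the statistic, with add-one smoothing on the p-value. The
null distribution is exactly hypergeometric, which the test-suite exploits
as an independent oracle. P-values across many domains can be
Benjamini–Hochberg adjusted on request; the default is off because the
primary analysis is descriptive.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
random template sequences at a target lysine fraction, homologs produced by
point substitutions (adaptively tuned to land within ±3 points of a target
percent identity, measured by global alignment) plus sparse indels with the
true region labels book-kept through every edit, and acetylation planted
per lysine at rate `base_rate·ρ` in the MIR and `base_rate` in the NBR.
Toy structures are ideal helical Cα traces (100° turn, 1.5 Å rise, exact
3.8 Å consecutive spacing) with optional Gaussian jitter — sufficient to
exercise superposition, residual filtering and segment logic, with no
claim of fold realism.

Defaults, chosen once as plausible study conditions: domain length 250,
lysine fraction 0.12 (these domains are lysine-rich), base rate
0.15/lysine, ρ = 5 (the order of the published ~4.7-fold per-residue
headline enrichment), indel rate 0.01, target identity 70%, two MIR
intervals ([20,60], [120,170], ≈37% of the domain). Each bundle uses a
single seeded RNG stream and is byte-reproducible.

What the generator does *not* emulate — real fold geometry, phylogenetic
correlation among homologs (each member mutates independently from the
template), composition biases around acetylation motifs, and database
artifacts such as isoform position shifts. Passing tests therefore
demonstrate that the pipeline recovers planted signal under its own model
of the data, not that any particular biological dataset shows enrichment.

## Problem sizes and numerical choices

The test-suite and the acceptance script run synthetic studies at 4
families × 10 domains for full-pipeline checks, 50 domains × 250 residues
across multiple seeds for parameter recovery, and 10 domains at 60%
identity for transfer recovery — sizes at which binomial sampling error on
the pooled ratio is a few percent. Degenerate inputs are defined errors,
not silent results: empty sequences, zero-lysine domains in the permutation
test, fewer than 3 points for superposition, fewer than 20 surviving
structural pairs, and boundary deltas beyond ±2 (the validated range)
without `force`. Undefined ratios (zero NBR value) are flagged and excluded
from pooled ratios rather than imputed, with the exclusion count reported.

## Known limitations

- The identity/similarity thresholds (50%) are inherited conventions; no
  attempt is made to optimize them, and borderline members can flip
  between included and excluded with small alignment changes.
- Hinge detection is not automatic: segments must be declared per template
  in the region config.
- The H0 detector is a hydrophobic-moment heuristic; curated ranges should
  be preferred whenever available.
- Transfer quality degrades with identity; below ~50% the correspondence
  itself becomes unreliable, which is precisely why the exclusion filter
  exists.
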
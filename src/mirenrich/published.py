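"""Published reference frequencies for the four-family acetylation survey.

These are the printed per-region acetylation frequencies (percent) from the
published survey of 12 BAR, 12 PX, 22 C2 and 4 EHD domains.  They serve as
worked-example inputs: dividing the printed MIR frequency by the printed NBR
frequency and rounding half-up to the printed precision must reproduce the
printed fold ratio.

Three of the published per-residue ratio cells (BAR 5.21, PX 4.92, C2 4.90)
are not reproducible from their own printed inputs — they were evidently
computed before rounding — so only the self-consistent cells are listed in
``PER_RESIDUE``.
"""

# family -> (MIR %K_AC/K, NBR %K_AC/K, printed ratio); ratios print at 1 decimal
PER_LYSINE = {
    "BAR": (20.5, 9.8, 2.1),
    "PX": (26.3, 9.3, 2.8),
    "C2": (22.9, 10.5, 2.2),
    "EHD": (28.9, 27.8, 1.0),
    "Average": (22.8, 11.3, 2.0),
}

# family -> (MIR %K_AC, NBR %K_AC, printed ratio); ratios print at 2 decimals
PER_RESIDUE = {
    "EHD": (5.85, 1.84, 3.18),
    "Average": (3.30, 0.71, 4.65),
}

# headline classification fractions of the published survey
MIR_MAJORITY_PCT = 82.0
MIR_ONLY_PCT = 60.0


def published_ratio_checks() -> dict:
    """Recompute every self-consistent printed ratio from its printed inputs.

    Returns ``{name: (computed, printed)}`` with the computation done by
    half-up rounding of the MIR/NBR quotient at the printed precision.
    """
    from .enrichment import round_half_up

    out = {}
    for fam, (mir, nbr, printed) in PER_LYSINE.items():
        out[f"per_lysine_{fam}"] = (round_half_up(mir / nbr, 1), printed)
    for fam, (mir, nbr, printed) in PER_RESIDUE.items():
        out[f"per_residue_{fam}"] = (round_half_up(mir / nbr, 2), printed)
    return out
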
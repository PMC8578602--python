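import numpy as np
import pytest

from mirenrich import (
    AcetylationSiteTable,
    DomainRecord,
    RegionAnnotation,
    SyntheticFamilySpec,
)
from mirenrich.synthetic_data import generate_family


@pytest.fixture(scope="session")
def small_family():
    """One synthetic family, modest identity, no structures."""
    spec = SyntheticFamilySpec(
        family="BAR", n_domains=6, seed=11, target_identity_pct=70.0
    )
    return generate_family(spec)


@pytest.fixture(scope="session")
def structural_family():
    """Synthetic family carrying toy helical structures."""
    spec = SyntheticFamilySpec(
        family="EHD", n_domains=4, seed=5, target_identity_pct=80.0,
        with_structures=True,
    )
    return generate_family(spec)


def random_domain(rng: np.random.Generator, length=60):
    """A random annotated domain with random acetylation sites, for
    invariant checks; sites deliberately include mismatches and
    out-of-domain positions."""
    import pandas as pd

    from mirenrich.io_formats import AA20

    n = rng.integers(20, length)
    seq = "".join(AA20[i] for i in rng.integers(0, 20, n))
    lo = int(rng.integers(1, max(2, n // 3)))
    hi = int(rng.integers(lo, n)) if lo < n else lo
    # random disjoint MIR intervals inside [lo, hi]
    mir = []
    pos = lo
    while pos <= hi:
        if rng.random() < 0.4:
            end = min(hi, pos + int(rng.integers(1, 8)))
            mir.append((pos, end))
            pos = end + 2
        else:
            pos += int(rng.integers(1, 5))
    record = DomainRecord(f"R{rng.integers(1e6)}", "BAR", seq, (lo, hi))
    ann = RegionAnnotation((lo, hi), mir)
    n_sites = int(rng.integers(0, 8))
    rows = []
    for _ in range(n_sites):
        p = int(rng.integers(1, n + 1))
        res = seq[p - 1] if rng.random() < 0.8 else "K"
        rows.append((record.protein_id, p, res, "ac"))
    df = pd.DataFrame(rows, columns=["protein_id", "position", "residue", "modification"])
    if df.empty:
        df["position"] = df["position"].astype(int)
    sites = AcetylationSiteTable(df.drop_duplicates(["protein_id", "position"]))
    return record, ann, sites
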
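"""Somatic SNV candidate ranking from paired tumor/blood allele counts.

Each site is a 2×2 table with rows (ref, alt) and columns (tumor,
normal); this orientation is fixed and documented because the Fisher
p-value is orientation-invariant but the read-support filters are not.
The two-tailed p-value is the classical "minimum-likelihood" definition:
the sum of hypergeometric probabilities of all tables with the observed
margins whose probability does not exceed the observed table's. The
implementation works on exact integer numerators over a shared
denominator, so table inclusion is decided without any floating-point
comparison; only the final ratio is rounded to a float.

Candidates are ranked by raw p (the upstream convention); a BH-adjusted
q-value is reported alongside for users, but plays no role in ranking.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd


@lru_cache(maxsize=100_000)
def _comb(n: int, k: int) -> int:
    return comb(n, k)


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher's exact p for the 2×2 table [[a, b], [c, d]].

    By convention a table with any zero margin carries no information and
    returns p = 1.0. Exact up to the final float rounding.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    numers = [_comb(r1, k) * _comb(r2, c1 - k) for k in range(lo, hi + 1)]
    obs = numers[a - lo]
    tail = sum(v for v in numers if v <= obs)
    return float(Fraction(tail, _comb(n, c1)))


def call_somatic_candidates(sites: pd.DataFrame, alpha: float = 0.01,
                            min_alt_t: int = 4, max_alt_n: int = 1) -> pd.DataFrame:
    """Test, filter and rank putative somatic sites.

    ``sites`` needs columns ``chrom pos ref_t alt_t ref_n alt_n``
    (1-based positions). A site passes when p < alpha, tumor alt reads >=
    ``min_alt_t`` and normal alt reads <= ``max_alt_n``. The output is
    sorted by (p ascending, chrom, pos) with ranks 1..n; ties in p break
    deterministically on coordinates.
    """
    if sites.empty:
        return pd.DataFrame(columns=[*sites.columns, "p", "q", "rank", "passes"])
    out = sites.copy().reset_index(drop=True)
    out["p"] = [fisher_two_tailed(r.ref_t, r.ref_n, r.alt_t, r.alt_n)
                for r in out.itertuples()]
    from lipodriver.exprstats import multiple_test_adjust
    out["q"] = multiple_test_adjust(out["p"].to_numpy(), method="BH")
    out = out.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["passes"] = ((out["p"] < alpha)
                     & (out["alt_t"] >= min_alt_t)
                     & (out["alt_n"] <= max_alt_n))
    return out


def mutation_burden(calls: pd.DataFrame) -> int:
    """Number of passing somatic calls for one tumor."""
    if calls.empty:
        return 0
    return int(calls["passes"].sum())


def group_burden(burdens: dict[str, int], labels: dict[str, str] | pd.Series) -> pd.Series:
    """Mean somatic burden per group label."""
    labels = pd.Series(dict(labels))
    df = pd.DataFrame({"burden": pd.Series(burdens), "group": labels})
    df = df.dropna()
    return df.groupby("group")["burden"].mean()
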
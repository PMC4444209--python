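"""Interspecific heterozygote-excess tests and QTL enrichment.

In admixed individuals with alba genome fraction Q, the neutral expectation
for a locus to be an interspecific heterozygote (one allele from each
parental species) is 2Q(1-Q).  A locus under balancing-type selection in
hybrids shows more heterozygous-ancestry calls than this null predicts.
The per-locus test is exact: the number of heterozygous individuals under
the null is Poisson-binomial with success probabilities 2Q_i(1-Q_i), and
the upper-tail probability is computed by dynamic-programming convolution.

Loci flagged for excess are then cross-tabulated against phytochemical QTL
loci with a one-sided Fisher's exact test (are excess loci over-represented
among QTL?).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LocusCline",
    "expected_het",
    "poisson_binomial_tail",
    "het_excess_test",
    "het_excess_table",
    "qtl_enrichment",
]


@dataclass
class LocusCline:
    locus: str
    n: int
    expected: float     # sum_i 2 Q_i (1 - Q_i)
    observed: int       # individuals with LSA == 0.5
    p_upper: float      # P(X >= observed) under the Poisson-binomial null
    excess: bool        # p_upper < alpha


def expected_het(Q: float | np.ndarray) -> float | np.ndarray:
    """Null interspecific-heterozygosity probability 2Q(1-Q)."""
    q = np.asarray(Q, float)
    if ((q < 0) | (q > 1)).any():
        raise ValueError("Q out of [0, 1]")
    out = 2.0 * q * (1.0 - q)
    return float(out) if out.ndim == 0 else out


def poisson_binomial_pmf(probs: np.ndarray) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_i) by convolution."""
    probs = np.asarray(probs, float)
    n = len(probs)
    if n == 0:
        raise ValueError("empty probability vector")
    if n > 5000:
        raise ValueError("exact convolution limited to n <= 5000")
    pmf = np.zeros(n + 1)
    pmf[0] = 1.0
    for k, p in enumerate(probs):
        pmf[1 : k + 2] = pmf[1 : k + 2] * (1.0 - p) + pmf[: k + 1] * p
        pmf[0] *= 1.0 - p
    return pmf


def poisson_binomial_tail(probs: np.ndarray, k: int) -> float:
    """P(X >= k) for the Poisson-binomial sum of Bernoulli(p_i)."""
    pmf = poisson_binomial_pmf(probs)
    if k <= 0:
        return 1.0
    return float(pmf[k:].sum())


def het_excess_test(
    lsa_locus: pd.Series | np.ndarray,
    Q: pd.Series | np.ndarray,
    alpha: float = 0.05,
    locus: str = "",
) -> LocusCline:
    """Exact upper-tail test of interspecific heterozygote excess at one
    locus, conditional on individuals' admixture proportions."""
    x = np.asarray(lsa_locus, float)
    q = np.asarray(Q, float)
    if x.shape != q.shape:
        raise ValueError("LSA and Q must be aligned")
    ok = ~np.isnan(x)
    x, q = x[ok], q[ok]
    if len(x) == 0:
        raise ValueError("no individuals")
    probs = 2.0 * q * (1.0 - q)
    observed = int((x == 0.5).sum())
    p = poisson_binomial_tail(probs, observed)
    return LocusCline(
        locus=locus,
        n=len(x),
        expected=float(probs.sum()),
        observed=observed,
        p_upper=p,
        excess=bool(p < alpha),
    )


def het_excess_table(
    lsa: pd.DataFrame, Q: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Run the excess test at every locus; one row per locus."""
    rows = [
        vars(het_excess_test(lsa[L], Q.loc[lsa.index], alpha=alpha, locus=L))
        for L in lsa.columns
    ]
    return pd.DataFrame(rows)


def qtl_enrichment(
    excess_flags: pd.Series, qtl_loci: set[str] | list[str]
) -> tuple[float, float, pd.DataFrame]:
    """One-sided Fisher's exact test: are heterozygote-excess loci enriched
    among phytochemical QTL?

    ``excess_flags`` is a boolean Series indexed by locus; ``qtl_loci`` the
    loci with at least one mapped QTL.  Returns (sample odds ratio, one-sided
    hypergeometric p, the 2x2 table with QTL status as rows and excess
    status as columns).
    """
    qtl = set(qtl_loci)
    if not qtl:
        raise ValueError("empty QTL locus set")
    unknown = qtl - set(excess_flags.index)
    if unknown:
        raise ValueError(f"QTL loci absent from the tested loci: {sorted(unknown)}")
    is_qtl = excess_flags.index.isin(qtl)
    exc = excess_flags.to_numpy(bool)
    a = int((is_qtl & exc).sum())       # QTL, excess
    b = int((is_qtl & ~exc).sum())      # QTL, no excess
    c = int((~is_qtl & exc).sum())      # non-QTL, excess
    d = int((~is_qtl & ~exc).sum())     # non-QTL, no excess
    table = pd.DataFrame(
        [[a, b], [c, d]],
        index=pd.Index(["qtl", "non_qtl"], name="loci"),
        columns=["excess", "no_excess"],
    )
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p), table


def cross_zone_excess(flag_frames: dict[str, pd.Series], min_zones: int = 2) -> pd.Series:
    """Loci flagged for excess in at least ``min_zones`` locality-stratified
    runs (intersection count across hybrid zones)."""
    flags = pd.DataFrame(flag_frames)
    return flags.sum(axis=1) >= min_zones
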
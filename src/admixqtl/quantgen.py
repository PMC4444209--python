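"""Heritability from open-pollinated families and Mantel genotype-phenotype
correlations.

Heritability uses the one-way random-effects (maternal family) model fit by
REML, which accommodates the unbalanced family sizes.  Because a fraction Cp
of open-pollinated sibs share a father (correlation of paternity), mean sib
relatedness is rbar = Cp/2 + (1-Cp)/4 and the intraclass correlation is
multiplied by 1/rbar rather than the textbook half-sib factor 4:

    h^2 = multiplier * Var(s) / (Var(s) + Var(e)).

With Cp = 0.31, 1/rbar = 3.05, rounded to the factor 3 used in the source
analysis.  h^2 is not truncated at 1 (values > 1 flag maternal effects).

The Mantel statistic correlates pairwise genomic distance |Q_i - Q_j| with
pairwise phenotypic distance |y_i - y_j|; significance is by joint
row/column permutation of one matrix (one-sided, large r).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "HeritabilityEstimate",
    "MantelResult",
    "reml_oneway",
    "reml_loglik",
    "heritability",
    "multiplier_from_cp",
    "value_distance",
    "mantel",
    "heritability_table",
]


@dataclass
class HeritabilityEstimate:
    trait: str
    var_s: float
    var_e: float
    multiplier: float
    h2: float
    n_families: int
    n_individuals: int
    converged: bool = True


@dataclass
class MantelResult:
    trait: str
    r: float
    p: float
    n_permutations: int


# ---------------------------------------------------------------------------
# REML for the one-way random-effects model

def _family_summaries(values: np.ndarray, families: np.ndarray):
    labels, inverse = np.unique(families, return_inverse=True)
    ni = np.bincount(inverse)
    sums = np.bincount(inverse, weights=values)
    means = sums / ni
    ssw = float(((values - means[inverse]) ** 2).sum())
    return labels, ni, means, ssw


def reml_loglik(var_s: float, var_e: float, values, family_labels) -> float:
    """Restricted log-likelihood of the one-way random-effects model.

    y_ij = mu + s_i + e_ij with s_i ~ N(0, var_s), e_ij ~ N(0, var_e);
    the fixed effect mu is profiled out by GLS.  Used directly by the
    optimizer's oracle tests (grid search over the variance components).
    """
    y = np.asarray(values, float)
    fam = np.asarray(family_labels)
    _, ni, means, ssw = _family_summaries(y, fam)
    n = len(y)
    if var_e <= 0 or var_s < 0:
        return -np.inf
    lam = var_s / var_e
    w = ni / (1.0 + ni * lam)
    mu = float((w * means).sum() / w.sum())
    q = ssw + float((w * (means - mu) ** 2).sum())
    return -0.5 * (
        (n - 1) * math.log(2.0 * math.pi)
        + (n - 1) * math.log(var_e)
        + float(np.log1p(ni * lam).sum())
        + math.log(float(w.sum()))  # log X'V^-1 X, its -log(var_e) folded into (n-1)log(var_e)
        + q / var_e
    )


def reml_oneway(values, family_labels, tol: float = 1e-10) -> tuple[float, float]:
    """REML estimates (Var(s), Var(e)) of among- and within-family variance.

    Profiles the likelihood over the variance ratio lambda = Var(s)/Var(e)
    (Var(e) has a closed-form profile), then optimises the 1-D profile on
    log-lambda; the lambda = 0 boundary is checked explicitly.  On balanced
    designs with a positive ANOVA estimate this equals the method-of-moments
    (MSB - MSW)/n0 solution.
    """
    y = np.asarray(values, float)
    fam = np.asarray(family_labels)
    if len(y) != len(fam):
        raise ValueError("values and family_labels differ in length")
    labels, ni, means, ssw = _family_summaries(y, fam)
    if len(labels) < 2:
        raise ValueError("need >= 2 families")
    if (ni < 2).all():
        raise ValueError("all families are singletons")
    n = len(y)
    if np.ptp(y) == 0:
        return 0.0, 0.0  # degenerate: no variance at all

    def profile(lam: float) -> tuple[float, float]:
        """(negative profile REML, profiled var_e) at ratio lam >= 0."""
        w = ni / (1.0 + ni * lam)
        mu = float((w * means).sum() / w.sum())
        q = ssw + float((w * (means - mu) ** 2).sum())
        ve = q / (n - 1)
        nll = 0.5 * (
            (n - 1) * (math.log(ve) + 1.0 + math.log(2.0 * math.pi))
            + float(np.log1p(ni * lam).sum())
            + math.log(float(w.sum()))
        )
        return nll, ve

    res = minimize_scalar(
        lambda t: profile(math.exp(t))[0],
        bounds=(-30.0, 15.0),
        method="bounded",
        options={"xatol": tol},
    )
    lam_hat = math.exp(float(res.x))
    nll_hat, ve_hat = profile(lam_hat)
    nll0, ve0 = profile(0.0)
    if nll0 <= nll_hat:
        return 0.0, ve0
    return lam_hat * ve_hat, ve_hat


def multiplier_from_cp(cp: float) -> tuple[float, int]:
    """Heritability multiplier from the correlation of paternity.

    rbar = Cp/2 + (1-Cp)/4; returns (1/rbar, round(1/rbar)).
    Cp=0 gives the classic half-sib 4; Cp=1 the full-sib 2; Cp=0.31 gives
    3.053, i.e. the rounded factor 3.
    """
    if not 0.0 <= cp <= 1.0:
        raise ValueError("Cp must be in [0, 1]")
    rbar = cp * 0.5 + (1.0 - cp) * 0.25
    mult = 1.0 / rbar
    return mult, int(round(mult))


def heritability(var_s: float, var_e: float, multiplier: float = 3.0) -> float:
    """h^2 = multiplier * Var(s)/(Var(s)+Var(e)); not truncated at 1."""
    total = var_s + var_e
    if total <= 0:
        raise ValueError("zero total variance")
    return multiplier * var_s / total


def heritability_table(
    phenotypes: pd.DataFrame,
    families: pd.Series,
    multiplier: float = 3.0,
) -> pd.DataFrame:
    """Estimate h^2 for every trait; returns one row per trait."""
    fam = families.loc[phenotypes.index]
    rows = []
    for t in phenotypes.columns:
        vs, ve = reml_oneway(phenotypes[t].to_numpy(float), fam.to_numpy())
        est = HeritabilityEstimate(
            trait=t,
            var_s=vs,
            var_e=ve,
            multiplier=multiplier,
            h2=heritability(vs, ve, multiplier) if vs + ve > 0 else float("nan"),
            n_families=fam.nunique(),
            n_individuals=len(fam),
        )
        rows.append(vars(est))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mantel

def value_distance(x: pd.Series | np.ndarray) -> np.ndarray:
    """Pairwise absolute-difference distance matrix d_ij = |x_i - x_j|.

    Applied to admixture proportions Q this is the genomic distance; applied
    to one trait it is the phenotypic distance (larger = less similar, so a
    positive Mantel r corresponds to a positive similarity correlation).
    """
    v = np.asarray(x, float)
    if v.ndim != 1 or len(v) < 3:
        raise ValueError("need a 1-D vector of >= 3 values")
    if np.isnan(v).any():
        raise ValueError("missing values: exclude those individuals first")
    return np.abs(v[:, None] - v[None, :])


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel(
    dist_a: np.ndarray,
    dist_b: np.ndarray,
    n_permutations: int = 9999,
    seed: int = 0,
    method: str = "permutation",
    trait: str = "",
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of upper-triangle entries; the one-sided
    p-value permutes rows and columns of ``dist_b`` jointly:
    p = (#{r_perm >= r_obs} + 1) / (n_permutations + 1).  With
    ``method="exact"`` (n <= 8) all n! relabelings are enumerated and
    p = #{r_perm >= r_obs} / n! (the identity included).
    """
    a = np.asarray(dist_a, float)
    b = np.asarray(dist_b, float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValueError("distance matrices must be symmetric")
    n = a.shape[0]
    ua = _upper(a)
    if ua.std() == 0 or _upper(b).std() == 0:
        raise ValueError("constant distance matrix: r undefined")

    def corr_with(perm: np.ndarray) -> float:
        bb = b[np.ix_(perm, perm)]
        return float(np.corrcoef(ua, _upper(bb))[0, 1])

    r_obs = corr_with(np.arange(n))
    if method == "exact":
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        rs = [corr_with(np.array(p)) for p in itertools.permutations(range(n))]
        count = sum(rp >= r_obs - 1e-12 for rp in rs)
        return MantelResult(trait=trait, r=r_obs, p=count / math.factorial(n),
                            n_permutations=math.factorial(n))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if corr_with(rng.permutation(n)) >= r_obs - 1e-12:
            count += 1
    return MantelResult(
        trait=trait,
        r=r_obs,
        p=(count + 1) / (n_permutations + 1),
        n_permutations=n_permutations,
    )
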
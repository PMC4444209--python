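"""Admixture proportion (Q) and locus-specific ancestry (LSA) from
co-dominant genotypes and parental allele frequencies.

Q is estimated per individual by maximising the independent-loci admixture
likelihood: each observed allele derives from the *P. alba* gene pool with
probability Q and from the *P. tremula* pool otherwise,

    L(Q) = prod_loci prod_alleles [ Q * p_alba(a) + (1 - Q) * p_trem(a) ].

LSA is the per-locus MAP ancestry state under a three-state posterior with
prior {(1-Q)^2, 2Q(1-Q), Q^2} and genotype likelihoods from the parental
frequency vectors.  Orientation is fixed throughout: 0 = tremula, 1 = alba.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "AncestryTable",
    "estimate_Q",
    "estimate_lsa",
    "classify_taxon",
    "TAXON_PRESETS",
    "smoothed_freq_arrays",
]

# Published hybrid-delimitation threshold pairs: the wider pair is used for
# hybrid-only genotype-phenotype correlations, the narrower one for the
# admixed-tree metabolite networks.
TAXON_PRESETS: dict[str, tuple[float, float]] = {
    "mantel_hybrids": (0.01, 0.99),
    "network_hybrids": (0.05, 0.95),
}

LSA_STATES = np.array([0.0, 0.5, 1.0])


@dataclass
class AncestryTable:
    """Estimated ancestry: per-individual Q, per individual x locus MAP LSA
    (0/0.5/1) and its posterior probability."""

    Q: pd.Series
    lsa: pd.DataFrame
    posterior: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.Q.between(0, 1).all():
            raise ValueError("Q out of [0, 1]")


def smoothed_freq_arrays(
    freqs: pd.DataFrame, parental_n: int = 50
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-locus (alba, tremula) frequency arrays with a zero floor.

    Zero frequencies are floored at eps = 1/(2*parental_n + 1) — an allele
    unseen in a parental sample of ``parental_n`` diploids is rare, not
    impossible — then each vector is renormalised.
    """
    eps = 1.0 / (2 * parental_n + 1)
    out = {}
    for locus, grp in freqs.groupby("locus", sort=False):
        grp = grp.sort_values("allele")
        pa = np.maximum(grp["freq_alba"].to_numpy(float), eps)
        pt = np.maximum(grp["freq_tremula"].to_numpy(float), eps)
        out[locus] = (pa / pa.sum(), pt / pt.sum())
    return out


def _allele_freq_vectors(
    genotypes: pd.DataFrame, farr: dict[str, tuple[np.ndarray, np.ndarray]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten one individual-major view: for every (individual, allele copy)
    return p_alba and p_trem of the observed allele, NaN-masked."""
    loci = list(farr.keys())
    n = len(genotypes)
    pa = np.full((n, 2 * len(loci)), np.nan)
    pt = np.full((n, 2 * len(loci)), np.nan)
    obs = np.zeros((n, 2 * len(loci)), dtype=bool)
    for j, locus in enumerate(loci):
        fa, ft = farr[locus]
        for slot in (0, 1):
            col = genotypes[f"{locus}.{slot + 1}"].to_numpy(float)
            ok = ~np.isnan(col)
            idx = (col[ok] - 1).astype(int)
            if idx.size and (idx.min() < 0 or idx.max() >= len(fa)):
                raise ValueError(f"allele code out of range at locus {locus}")
            pa[ok, 2 * j + slot] = fa[idx]
            pt[ok, 2 * j + slot] = ft[idx]
            obs[:, 2 * j + slot] = ok
    return pa, pt, obs


def estimate_Q(
    genotypes: pd.DataFrame,
    parental_freqs: pd.DataFrame,
    parental_n: int = 50,
) -> pd.Series:
    """Maximum-likelihood admixture proportion per individual.

    Missing genotypes contribute nothing to the likelihood.  Raises if an
    individual has no genotyped locus.
    """
    farr = smoothed_freq_arrays(parental_freqs, parental_n)
    pa, pt, obs = _allele_freq_vectors(genotypes, farr)
    qs = np.empty(len(genotypes))
    for i in range(len(genotypes)):
        m = obs[i]
        if not m.any():
            raise ValueError(f"individual {genotypes.index[i]!r} has no genotyped loci")
        a, t = pa[i, m], pt[i, m]

        def nll(q: float) -> float:
            return -np.log(q * a + (1.0 - q) * t).sum()

        res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-10})
        qs[i] = float(np.clip(res.x, 0.0, 1.0))
        # bounded Brent can stall off the boundary when the optimum is at it
        for edge in (0.0, 1.0):
            if nll(edge) < nll(qs[i]):
                qs[i] = edge
    return pd.Series(qs, index=genotypes.index, name="Q")


def _genotype_state_likelihoods(
    a1: float, a2: float, fa: np.ndarray, ft: np.ndarray
) -> np.ndarray:
    """Likelihood of an unordered genotype under ancestry states (0, 0.5, 1)."""
    i, j = int(a1) - 1, int(a2) - 1
    if i == j:
        return np.array([ft[i] ** 2, fa[i] * ft[i], fa[i] ** 2])
    return np.array(
        [
            2.0 * ft[i] * ft[j],
            fa[i] * ft[j] + fa[j] * ft[i],
            2.0 * fa[i] * fa[j],
        ]
    )


def estimate_lsa(
    genotypes: pd.DataFrame,
    parental_freqs: pd.DataFrame,
    Q: pd.Series,
    parental_n: int = 50,
) -> AncestryTable:
    """Per-locus three-state ancestry posterior and MAP call.

    Prior from the individual's Q assuming binomial ancestry,
    {(1-Q)^2, 2Q(1-Q), Q^2}; likelihood from parental allele frequencies.
    A missing genotype leaves the posterior equal to the prior.  Ties in the
    posterior resolve to the lowest state (0 before 0.5 before 1),
    a deterministic convention.
    """
    farr = smoothed_freq_arrays(parental_freqs, parental_n)
    loci = list(farr.keys())
    q = Q.loc[genotypes.index].to_numpy(float)
    prior = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=1)
    lsa = np.empty((len(genotypes), len(loci)))
    post_max = np.empty((len(genotypes), len(loci)))
    for j, locus in enumerate(loci):
        fa, ft = farr[locus]
        c1 = genotypes[f"{locus}.1"].to_numpy(float)
        c2 = genotypes[f"{locus}.2"].to_numpy(float)
        for i in range(len(genotypes)):
            if np.isnan(c1[i]) or np.isnan(c2[i]):
                post = prior[i] / prior[i].sum()
            else:
                lik = _genotype_state_likelihoods(c1[i], c2[i], fa, ft)
                post = prior[i] * lik
                post = post / post.sum()
            k = int(np.argmax(post))
            lsa[i, j] = LSA_STATES[k]
            post_max[i, j] = post[k]
    idx = genotypes.index
    return AncestryTable(
        Q=pd.Series(q, index=idx, name="Q"),
        lsa=pd.DataFrame(lsa, index=idx, columns=loci),
        posterior=pd.DataFrame(post_max, index=idx, columns=loci),
    )


def classify_taxon(
    Q: float | pd.Series,
    lower: float = 0.05,
    upper: float = 0.95,
    preset: str | None = None,
) -> str | pd.Series:
    """Threshold Q into 'tremula-like' / 'hybrid' / 'alba-like'.

    Hybrids are the open interval (lower, upper): Q exactly at a threshold is
    classed as parental-like.  ``preset`` selects one of the published pairs
    in :data:`TAXON_PRESETS`.
    """
    if preset is not None:
        lower, upper = TAXON_PRESETS[preset]
    if not 0.0 <= lower < upper <= 1.0:
        raise ValueError("need 0 <= lower < upper <= 1")
    if isinstance(Q, pd.Series):
        lab = pd.Series("hybrid", index=Q.index, name="taxon")
        lab[Q <= lower] = "tremula-like"
        lab[Q >= upper] = "alba-like"
        return lab
    if Q <= lower:
        return "tremula-like"
    if Q >= upper:
        return "alba-like"
    return "hybrid"
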
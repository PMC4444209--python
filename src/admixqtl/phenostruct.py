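"""Metabolite-table structure: PCA, taxon contrasts, normality annotation,
and Spearman correlation networks.

Relative metabolite abundances are heteroscedastic and mostly non-normal, so
inter-trait association uses rank (Spearman) correlation throughout, and the
default PCA operates on the correlation matrix (traits standardised).
Networks keep trait pairs with rho strictly above a threshold (default 0.5)
at p below a threshold (default 0.001), per taxon subset.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PCAResult",
    "pca",
    "tukey_contrasts",
    "normality_check",
    "spearman_pair",
    "spearman_network",
    "degree_summary",
    "layout_fr",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame            # traits x components
    explained_pct: pd.Series          # percent of total variance
    eigenvalues: np.ndarray = field(repr=False, default=None)


def pca(trait_matrix: pd.DataFrame, scale: bool = True) -> PCAResult:
    """PCA by eigendecomposition of the covariance (scale=False) or
    correlation (scale=True) matrix.

    Missing cells are mean-imputed per trait (logged).  Components are
    ordered by decreasing eigenvalue; the sign of each loading vector is
    fixed so its largest-magnitude entry is positive.
    """
    X = trait_matrix.astype(float).copy()
    if X.shape[0] < 2:
        raise ValueError("need >= 2 individuals")
    n_missing = int(X.isna().sum().sum())
    if n_missing:
        log.info("mean-imputing %d missing phenotype cells", n_missing)
        X = X.fillna(X.mean())
    if X.isna().any().any():
        raise ValueError("trait with all values missing")
    Xc = X - X.mean()
    if scale:
        sd = X.std(ddof=1)
        if (sd == 0).any():
            bad = list(sd.index[sd == 0])
            raise ValueError(f"zero-variance traits with scale=True: {bad}")
        Xc = Xc / sd
    S = np.cov(Xc.to_numpy(), rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    for j in range(evecs.shape[1]):
        k = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    comps = [f"PC{i + 1}" for i in range(len(evals))]
    scores = pd.DataFrame(Xc.to_numpy() @ evecs, index=X.index, columns=comps)
    loadings = pd.DataFrame(evecs, index=X.columns, columns=comps)
    pct = pd.Series(100.0 * evals / evals.sum(), index=comps, name="explained_pct")
    return PCAResult(scores=scores, loadings=loadings, explained_pct=pct, eigenvalues=evals)


# ---------------------------------------------------------------------------
# taxon contrasts

def tukey_contrasts(
    trait: pd.Series, taxon_labels: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA followed by Tukey HSD pairwise contrasts.

    Returns one row per taxon pair with the studentized-range adjusted
    p-value, the mean difference, a reject flag at ``alpha``, and compact
    letter groups (taxa sharing a letter do not differ at alpha).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.concat([trait, taxon_labels], axis=1, keys=["y", "g"]).dropna()
    counts = df["g"].value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("need >= 2 taxa with >= 2 members each")
    res = pairwise_tukeyhsd(df["y"].to_numpy(float), df["g"].to_numpy(), alpha=alpha)
    out = pd.DataFrame(
        res.summary().data[1:],
        columns=[c.strip() for c in res.summary().data[0]],
    )[["group1", "group2", "meandiff", "p-adj", "reject"]]
    out.columns = ["group1", "group2", "mean_diff", "p_adj", "reject"]
    out["p_adj"] = [float(p) for p in res.pvalues]  # full precision
    out["mean_diff"] = res.meandiffs
    out["reject"] = res.reject
    letters = _compact_letters(out, sorted(counts.index))
    out.attrs["letters"] = letters
    return out


def _compact_letters(pairs: pd.DataFrame, groups: list[str]) -> dict[str, str]:
    """Greedy compact-letter display from pairwise reject flags."""
    differ = {
        frozenset((r["group1"], r["group2"])) for _, r in pairs.iterrows() if r["reject"]
    }
    letters: dict[str, str] = {g: "" for g in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    cliques: list[set[str]] = []
    for g in groups:
        placed = False
        for cl in cliques:
            if all(frozenset((g, h)) not in differ for h in cl):
                cl.add(g)
                placed = True
        if not placed:
            cliques.append({g})
    for i, cl in enumerate(cliques):
        for g in cl:
            letters[g] += alphabet[i]
    return letters


def normality_check(trait: pd.Series | np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p.  Annotation only: downstream correlation is
    rank-based regardless of the outcome."""
    x = np.asarray(trait, float)
    x = x[~np.isnan(x)]
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant input")
    w, p = stats.shapiro(x)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# Spearman networks

def spearman_pair(
    x: np.ndarray, y: np.ndarray, seed: int = 0, n_resamples: int = 10_000
) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with a two-sided p-value.

    p by t-approximation for n > 20; exact permutation enumeration for
    n <= 9; seeded Monte-Carlo permutation for 10 <= n <= 20.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 4:
        raise ValueError("need >= 4 observations")
    rho = float(stats.spearmanr(x, y).statistic)
    rx = stats.rankdata(x)

    def rho_of(perm_y: np.ndarray) -> float:
        ry = stats.rankdata(perm_y)
        return float(np.corrcoef(rx, ry)[0, 1])

    if n <= 9:
        count, total = 0, 0
        for perm in itertools.permutations(y):
            total += 1
            if abs(rho_of(np.array(perm))) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    if n <= 20:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_resamples):
            if abs(rho_of(rng.permutation(y))) >= abs(rho) - 1e-12:
                count += 1
        return rho, (count + 1) / (n_resamples + 1)
    res = stats.spearmanr(x, y)
    return rho, float(res.pvalue)


def spearman_network(
    trait_matrix: pd.DataFrame,
    r_threshold: float = 0.5,
    p_threshold: float = 0.001,
    trait_groups: pd.Series | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """All-pairs Spearman correlations filtered to network edges.

    Edges require rho strictly greater than ``r_threshold`` AND p below
    ``p_threshold``.  Constant traits are excluded (logged).  Returns a long
    frame (trait_a, trait_b, rho, p, group_a, group_b).
    """
    if trait_matrix.shape[0] < 4:
        raise ValueError("need >= 4 individuals")
    X = trait_matrix.astype(float)
    keep = [t for t in X.columns if np.ptp(X[t].dropna().to_numpy()) > 0]
    dropped = set(X.columns) - set(keep)
    if dropped:
        log.info("constant traits excluded from network: %s", sorted(dropped))
    X = X[keep]
    rows = []
    for a, b in itertools.combinations(keep, 2):
        sub = X[[a, b]].dropna()
        rho, p = spearman_pair(sub[a].to_numpy(), sub[b].to_numpy(), seed=seed)
        if rho > r_threshold and p < p_threshold:
            rows.append(
                {
                    "trait_a": a,
                    "trait_b": b,
                    "rho": rho,
                    "p": p,
                    "group_a": trait_groups.get(a, "") if trait_groups is not None else "",
                    "group_b": trait_groups.get(b, "") if trait_groups is not None else "",
                }
            )
    return pd.DataFrame(rows, columns=["trait_a", "trait_b", "rho", "p", "group_a", "group_b"])


def degree_summary(
    edges: pd.DataFrame, traits: list[str], trait_groups: pd.Series | None = None
) -> pd.DataFrame:
    """Per-trait degree (number of correlated partners) with group means and
    ranges, mirroring 'average number of correlated pairs' summaries."""
    deg = {t: 0 for t in traits}
    for _, e in edges.iterrows():
        deg[e["trait_a"]] += 1
        deg[e["trait_b"]] += 1
    out = pd.DataFrame({"trait": traits, "degree": [deg[t] for t in traits]})
    if trait_groups is not None:
        out["group"] = out["trait"].map(trait_groups)
    return out


def layout_fr(edges: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Fruchterman-Reingold (force-directed) 2-D coordinates for the network.
    Seed-deterministic; cosmetic output only."""
    import networkx as nx

    if edges.empty:
        raise ValueError("non-empty edge list required")
    G = nx.Graph()
    for _, e in edges.iterrows():
        G.add_edge(e["trait_a"], e["trait_b"], weight=float(e["rho"]))
    pos = nx.spring_layout(G, seed=seed)
    return pd.DataFrame(
        [(t, xy[0], xy[1]) for t, xy in pos.items()], columns=["trait", "x", "y"]
    ).set_index("trait")
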
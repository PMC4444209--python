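"""Admixture mapping of quantitative traits on locus-specific ancestry.

The pipeline mirrors regression-based in-situ QTL mapping in admixed
populations:

1. phenotypes are residualised on sampling locality (one-way fixed-effect
   ANOVA, standardized residuals) to remove among-zone differences;
2. each locus is tested with two Gaussian linear models on ancestry —
   additive (y ~ lsa) and dominant (y ~ lsa + het indicator) — and screened
   against the intercept-only model by an AIC difference of at least 4;
3. candidate loci per trait enter forward-selection / backward-elimination
   model selection at the same AIC threshold;
4. the final multi-locus model is summarised by a likelihood-ratio
   pseudo-R^2 (variance explained) and each retained locus by its mode of
   gene action (additive, dominance toward either species, over-/
   under-dominance).

Log-likelihoods use the maximum-likelihood residual variance, and AIC counts
the residual variance as a parameter: for a model with p mean parameters,
AIC = n*log(2*pi*RSS/n) + n + 2*(p + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QTLRecord",
    "SingleLocusFit",
    "SelectedModel",
    "residualize",
    "fit_single_locus",
    "scan_delta_aic",
    "screen_candidates",
    "select_model",
    "compute_pve",
    "classify_gene_action",
    "map_trait",
    "map_phenotypes",
]

log = logging.getLogger(__name__)

GENE_ACTION_CLASSES = (
    "additive",
    "alba-dominant",
    "tremula-dominant",
    "over-dominant",
    "under-dominant",
)


# ---------------------------------------------------------------------------
# residualisation

def residualize(phenotypes: pd.DataFrame, locality: pd.Series) -> pd.DataFrame:
    """Standardized residuals from one-way ANOVA with locality as factor.

    Per trait: subtract the locality mean and divide by the root mean square
    error (RSS / (n - k) with k localities).  Pooled residuals then have mean
    0 and SD ~= 1; mapping downstream is therefore invariant to affine
    rescaling of the raw phenotypes.
    """
    loc = locality.loc[phenotypes.index]
    counts = loc.value_counts()
    if (counts < 2).any():
        raise ValueError("every locality needs >= 2 individuals")
    k = counts.size
    out = {}
    for t in phenotypes.columns:
        y = phenotypes[t].astype(float)
        resid = y - y.groupby(loc).transform("mean")
        rss = float((resid**2).sum())
        if rss <= 0:
            raise ValueError(f"zero residual variance for trait {t!r}")
        out[t] = resid / np.sqrt(rss / (len(y) - k))
    return pd.DataFrame(out, index=phenotypes.index)


# ---------------------------------------------------------------------------
# single-locus fits

def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return beta, float(r @ r)


def _gaussian_loglik(rss: float, n: int) -> float:
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def _aic(rss: float, n: int, p_mean: int) -> float:
    """AIC with ML variance; parameter count = mean parameters + sigma^2."""
    return -2.0 * _gaussian_loglik(rss, n) + 2.0 * (p_mean + 1)


@dataclass
class SingleLocusFit:
    """AICs and coefficients of the null / additive / dominant fits at one
    locus.  Coefficients: additive (intercept, beta_a); dominant
    (intercept, beta_a, beta_d with beta_d the heterozygote deviation)."""

    trait: str
    locus: str
    n: int
    aic_null: float
    aic_additive: float
    aic_dominant: float
    coef_additive: tuple[float, float]
    coef_dominant: tuple[float, float, float]

    @property
    def best_model(self) -> str:
        return "additive" if self.aic_additive <= self.aic_dominant else "dominant"

    @property
    def delta_aic(self) -> float:
        """AIC improvement of the best ancestry model over the null."""
        return self.aic_null - min(self.aic_additive, self.aic_dominant)


def fit_single_locus(
    residual_y: pd.Series, lsa_locus: pd.Series, trait: str = "", locus: str = ""
) -> SingleLocusFit:
    """Fit null, additive and dominant Gaussian models of one trait on one
    locus's ancestry.  Individuals missing either value are dropped pairwise
    (the null is refit on the same subset, keeping AICs comparable)."""
    df = pd.concat([residual_y, lsa_locus], axis=1, keys=["y", "x"]).dropna()
    y = df["y"].to_numpy(float)
    x = df["x"].to_numpy(float)
    n = len(y)
    if n < 3:
        raise ValueError("need >= 3 individuals with data")
    if not np.isin(x, (0.0, 0.5, 1.0)).all():
        raise ValueError("LSA values must be in {0, 0.5, 1}")
    if np.ptp(x) == 0:
        raise ValueError(f"locus {locus or lsa_locus.name!r} monomorphic for ancestry")
    het = (x == 0.5).astype(float)
    ones = np.ones(n)
    _, rss0 = _ols_rss(ones[:, None], y)
    ba, rssa = _ols_rss(np.column_stack([ones, x]), y)
    bd, rssd = _ols_rss(np.column_stack([ones, x, het]), y)
    return SingleLocusFit(
        trait=trait,
        locus=locus or str(lsa_locus.name),
        n=n,
        aic_null=_aic(rss0, n, 1),
        aic_additive=_aic(rssa, n, 2),
        aic_dominant=_aic(rssd, n, 3),
        coef_additive=(float(ba[0]), float(ba[1])),
        coef_dominant=(float(bd[0]), float(bd[1]), float(bd[2])),
    )


def scan_delta_aic(
    Y: pd.DataFrame, lsa: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised AIC scan of many traits against many loci.

    Returns two traits x loci frames of AIC improvements over the null
    (positive = ancestry model better): one for the additive, one for the
    dominant model.  Assumes complete data (the scalar path handles
    missingness).  Monomorphic loci yield NaN columns.
    """
    Ym = Y.to_numpy(float)
    n, _ = Ym.shape
    Yc = Ym - Ym.mean(axis=0)
    rss0 = (Yc**2).sum(axis=0)
    d_add = np.full((Y.shape[1], lsa.shape[1]), np.nan)
    d_dom = np.full((Y.shape[1], lsa.shape[1]), np.nan)
    ones = np.ones(n)
    for j, locus in enumerate(lsa.columns):
        x = lsa[locus].to_numpy(float)
        if np.ptp(x) == 0:
            log.info("locus %s monomorphic for ancestry; skipped", locus)
            continue
        het = (x == 0.5).astype(float)
        Xa = np.column_stack([ones, x])
        Xd = np.column_stack([ones, x, het])
        for X, store, extra_k in ((Xa, d_add, 1), (Xd, d_dom, 2)):
            B, _, _, _ = np.linalg.lstsq(X, Ym, rcond=None)
            rss = ((Ym - X @ B) ** 2).sum(axis=0)
            with np.errstate(divide="ignore"):
                store[:, j] = n * np.log(rss0 / rss) - 2.0 * extra_k
    idx, cols = Y.columns, lsa.columns
    return (
        pd.DataFrame(d_add, index=idx, columns=cols),
        pd.DataFrame(d_dom, index=idx, columns=cols),
    )


# ---------------------------------------------------------------------------
# screening and model selection

def screen_candidates(
    delta_add: pd.DataFrame, delta_dom: pd.DataFrame, threshold: float = 4.0
) -> pd.DataFrame:
    """Candidate trait x locus pairs: best ancestry model beats the null by
    at least ``threshold`` AIC units (inclusive).  Returns a long frame with
    columns trait, locus, model, delta_aic."""
    best = np.where(delta_add.values >= delta_dom.values, delta_add.values, delta_dom.values)
    model = np.where(delta_add.values >= delta_dom.values, "additive", "dominant")
    rows = []
    ti, li = np.nonzero(np.nan_to_num(best, nan=-np.inf) >= threshold)
    for a, b in zip(ti, li):
        rows.append(
            {
                "trait": delta_add.index[a],
                "locus": delta_add.columns[b],
                "model": model[a, b],
                "delta_aic": float(best[a, b]),
            }
        )
    return pd.DataFrame(rows, columns=["trait", "locus", "model", "delta_aic"])


def _design(x: np.ndarray, model: str) -> np.ndarray:
    if model == "additive":
        return x[:, None]
    return np.column_stack([x, (x == 0.5).astype(float)])


@dataclass
class SelectedModel:
    """Final multi-locus model for one trait."""

    trait: str
    retained: list[str]
    models: dict[str, str]
    aic: float
    loglik: float
    loglik_null: float
    n: int
    coefficients: dict[str, tuple[float, ...]] = field(default_factory=dict)


def select_model(
    residual_y: pd.Series,
    candidate_lsa: pd.DataFrame,
    candidate_models: dict[str, str],
    threshold: float = 4.0,
    trait: str = "",
) -> SelectedModel:
    """Forward-selection / backward-elimination over candidate loci by AIC.

    Forward: repeatedly add the candidate (with its winning single-locus
    coding) that lowers AIC most, while the drop is >= threshold.  Backward:
    repeatedly remove the retained locus whose removal raises AIC least, as
    long as that rise is < threshold.  Ties break on (lower AIC, candidate
    order).  Exact duplicate ancestry columns are dropped up-front (first
    kept).
    """
    y = residual_y.to_numpy(float)
    n = len(y)
    ones = np.ones((n, 1))
    loci = list(candidate_lsa.columns)
    # drop exact duplicates
    kept: list[str] = []
    for L in loci:
        if any(np.array_equal(candidate_lsa[L].values, candidate_lsa[K].values) for K in kept):
            log.info("candidate %s duplicates an earlier candidate; dropped", L)
            continue
        kept.append(L)
    designs = {
        L: _design(candidate_lsa[L].to_numpy(float), candidate_models[L]) for L in kept
    }

    def model_aic(subset: list[str]) -> tuple[float, float, np.ndarray]:
        X = np.hstack([ones] + [designs[L] for L in subset]) if subset else ones
        beta, rss = _ols_rss(X, y)
        p = X.shape[1]
        return _aic(rss, n, p), _gaussian_loglik(rss, n), beta

    aic_null, ll_null, _ = model_aic([])
    current: list[str] = []
    aic_cur = aic_null
    while True:
        trials = [(model_aic(current + [L])[0], i, L) for i, L in enumerate(kept) if L not in current]
        if not trials:
            break
        best_aic, _, best_locus = min(trials)
        if aic_cur - best_aic >= threshold:
            current.append(best_locus)
            aic_cur = best_aic
        else:
            break
    while len(current) > 1:
        trials = [
            (model_aic([M for M in current if M != L])[0], i, L)
            for i, L in enumerate(current)
        ]
        best_aic, _, victim = min(trials)
        if best_aic - aic_cur < threshold:
            current = [M for M in current if M != victim]
            aic_cur = best_aic
        else:
            break
    aic_fin, ll_fin, beta = model_aic(current)
    coefs: dict[str, tuple[float, ...]] = {"intercept": (float(beta[0]),)}
    pos = 1
    for L in current:
        w = designs[L].shape[1]
        coefs[L] = tuple(float(b) for b in beta[pos : pos + w])
        pos += w
    return SelectedModel(
        trait=trait,
        retained=current,
        models={L: candidate_models[L] for L in current},
        aic=aic_fin,
        loglik=ll_fin,
        loglik_null=ll_null,
        n=n,
        coefficients=coefs,
    )


# ---------------------------------------------------------------------------
# variance explained

def compute_pve(loglik_model: float, loglik_null: float, n: int) -> tuple[float, float]:
    """Likelihood-ratio pseudo-R^2 of the final model.

    Returns ``(r2_lr, r2_lr_rescaled)``:
    r2_lr = 1 - exp(-(2/n)(logL_model - logL_null)); the rescaled variant
    divides by the maximum attainable value 1 - exp((2/n)*logL_null).
    The unrescaled value is the primary PVE.
    """
    if loglik_model < loglik_null - 1e-8:
        raise ValueError("model log-likelihood below null: fitting bug")
    r2 = 1.0 - np.exp(-(2.0 / n) * (loglik_model - loglik_null))
    r2max = 1.0 - np.exp((2.0 / n) * loglik_null)
    return float(r2), float(r2 / r2max) if r2max > 0 else float("nan")


# ---------------------------------------------------------------------------
# gene action

def classify_gene_action(
    m0: float,
    m05: float,
    m1: float,
    se05: float,
    tau: float | None = None,
) -> str:
    """Classify the mode of gene action from the three ancestry-class means.

    With a = (m1 - m0)/2 and d = m05 - (m1 + m0)/2: over-dominant if the
    heterozygote mean exceeds both parental-class means by more than tau;
    under-dominant if below both; dominant toward the species whose
    homozygote mean the heterozygote matches within tau; additive otherwise.
    Default tolerance tau = 0.5 * SE(m05).
    """
    if tau is None:
        tau = 0.5 * se05
    hi, lo = max(m0, m1), min(m0, m1)
    if m05 > hi + tau:
        return "over-dominant"
    if m05 < lo - tau:
        return "under-dominant"
    near_alba = abs(m05 - m1) <= tau
    near_trem = abs(m05 - m0) <= tau
    if near_alba and not near_trem:
        return "alba-dominant"
    if near_trem and not near_alba:
        return "tremula-dominant"
    return "additive"


def _gene_action_from_data(y: np.ndarray, x: np.ndarray) -> str:
    means, counts, sds = {}, {}, {}
    for state in (0.0, 0.5, 1.0):
        sel = y[x == state]
        if sel.size == 0:
            return "undeterminable"
        means[state] = float(sel.mean())
        counts[state] = sel.size
        sds[state] = float(sel.std(ddof=1)) if sel.size > 1 else 0.0
    se05 = sds[0.5] / np.sqrt(counts[0.5]) if counts[0.5] > 1 else 0.0
    return classify_gene_action(means[0.0], means[0.5], means[1.0], se05)


# ---------------------------------------------------------------------------
# per-trait and whole-table drivers

@dataclass
class QTLRecord:
    """One trait x locus association retained by the mapping pipeline."""

    trait: str
    locus: str
    chromosome: str
    model: str
    delta_aic: float
    beta_a: float
    beta_d: float
    retained: bool
    pve: float
    pve_rescaled: float
    gene_action: str


def map_trait(
    residual_y: pd.Series,
    lsa: pd.DataFrame,
    threshold: float = 4.0,
    chromosome: pd.Series | None = None,
    trait: str = "",
) -> tuple[list[QTLRecord], SelectedModel | None]:
    """Run screening, model selection, PVE and gene-action classification
    for a single residualised trait.  Returns all candidate records (with a
    retained flag) and the final model (None when no candidate)."""
    d_add, d_dom = scan_delta_aic(residual_y.to_frame("y"), lsa)
    cands = screen_candidates(d_add, d_dom, threshold)
    if cands.empty:
        return [], None
    sel = select_model(
        residual_y,
        lsa[list(cands["locus"])],
        dict(zip(cands["locus"], cands["model"])),
        threshold=threshold,
        trait=trait,
    )
    pve, pve_r = compute_pve(sel.loglik, sel.loglik_null, sel.n)
    y = residual_y.to_numpy(float)
    records = []
    for _, row in cands.iterrows():
        L = row["locus"]
        x = lsa[L].to_numpy(float)
        fit = fit_single_locus(residual_y, lsa[L], trait=trait, locus=L)
        coef = fit.coef_dominant if row["model"] == "dominant" else fit.coef_additive
        retained = L in sel.retained
        records.append(
            QTLRecord(
                trait=trait,
                locus=L,
                chromosome=str(chromosome[L]) if chromosome is not None else "",
                model=row["model"],
                delta_aic=float(row["delta_aic"]),
                beta_a=float(coef[1]),
                beta_d=float(coef[2]) if len(coef) > 2 else 0.0,
                retained=retained,
                pve=pve if retained else float("nan"),
                pve_rescaled=pve_r if retained else float("nan"),
                gene_action=_gene_action_from_data(y, x) if retained else "",
            )
        )
    return records, sel


def map_phenotypes(
    residuals: pd.DataFrame,
    lsa: pd.DataFrame,
    threshold: float = 4.0,
    chromosome: pd.Series | None = None,
) -> pd.DataFrame:
    """Map every trait; returns a long QTL table (one row per candidate)."""
    rows = []
    for t in residuals.columns:
        recs, _ = map_trait(
            residuals[t], lsa, threshold=threshold, chromosome=chromosome, trait=t
        )
        rows += [vars(r) for r in recs]
    cols = list(QTLRecord.__dataclass_fields__)
    return pd.DataFrame(rows, columns=cols)
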
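"""Synthetic hybrid-zone and common-garden data generator.

Emulates the data structure of a two-species *Populus* hybrid-zone study:
three localities, parental-like trees plus admixed trees of mixed hybrid
generations, co-dominant multi-allelic markers with variable parental
allele-frequency differentials (delta), metabolite-like traits organised in
correlated functional groups with sparse additive/dominant QTL, and an
open-pollinated common garden with a known full-sib fraction (correlation
of paternity, Cp).

Every dataset carries a :class:`SimTruth` with the generating values so that
downstream estimators can be tested for parameter recovery.

Conventions: admixture proportion Q is the *P. alba* genome fraction
(Q=1 pure alba, Q=0 pure tremula); locus-specific ancestry takes values
0 (tremula/tremula), 0.5 (interspecific heterozygote), 1 (alba/alba).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QTLSpec",
    "SimConfig",
    "GardenConfig",
    "SimTruth",
    "simulate_parental_freqs",
    "simulate_hybrid_zone",
    "simulate_common_garden",
    "roman_chromosomes",
    "default_hybrid_config",
    "default_garden_config",
    "ancestry_dosage_variance",
]

_ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
    "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX",
    "XX", "XXI", "XXII", "XXIII", "XXIV", "XXV",
]

TRAIT_GROUPS = ("chlorogenic_acid", "salicinoid", "flavonoid")


def roman_chromosomes(n_loci: int, n_chromosomes: int) -> list[str]:
    """Assign loci to chromosomes round-robin, labelled with roman numerals."""
    if n_chromosomes < 1 or n_chromosomes > len(_ROMAN):
        raise ValueError(f"n_chromosomes must be in [1, {len(_ROMAN)}]")
    return [_ROMAN[i % n_chromosomes] for i in range(n_loci)]


@dataclass(frozen=True)
class QTLSpec:
    """One planted QTL: trait, locus index, additive effect ``a`` and
    dominance deviation ``d``, both in residual-SD units.

    Ancestry-class means on the latent scale are -a (tremula-homozygous),
    d (heterozygous) and +a (alba-homozygous), before locality/group terms.
    """

    trait: str
    locus: int
    a: float
    d: float = 0.0


@dataclass
class SimConfig:
    """Hybrid-zone generator configuration.

    ``n_per_taxon_per_locality`` maps locality name -> (n_alba, n_tremula,
    n_hybrid).  ``hybrid_class_weights`` are mixture weights over discrete
    hybrid classes (F1, F2, BC toward alba, BC toward tremula); the paper's
    hybrids are genomic mosaics of several generations, which this mixture
    reproduces qualitatively.  ``group_correlation`` is the loading lambda of
    a shared within-group latent factor; null traits in the same group then
    correlate at lambda^2.
    """

    n_per_taxon_per_locality: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: {
            "Ticino": (17, 16, 55),
            "Danube": (17, 15, 54),
            "Tisza": (17, 15, 54),
        }
    )
    n_loci: int = 77
    n_chromosomes: int = 19
    delta_range: tuple[float, float] = (0.2, 1.0)
    n_alleles_range: tuple[int, int] = (2, 6)
    n_traits_per_group: dict[str, int] = field(
        default_factory=lambda: {"chlorogenic_acid": 8, "salicinoid": 12, "flavonoid": 18}
    )
    qtl_spec: list[QTLSpec] = field(default_factory=list)
    delta_override: dict[int, float] = field(default_factory=dict)
    locality_effects: dict[str, dict[str, float]] | None = None
    group_correlation: float = 0.5
    hybrid_class_weights: tuple[float, float, float, float] = (0.25, 0.35, 0.20, 0.20)
    transform: str = "exp"  # "exp" emulates skewed abundances; "none" = latent scale
    dropout: float = 0.0
    seed: int = 0

    def trait_names(self) -> list[str]:
        names = []
        for group, k in self.n_traits_per_group.items():
            names += [f"{group}_{i + 1:02d}" for i in range(k)]
        return names

    def trait_groups(self) -> pd.Series:
        rows = {}
        for group, k in self.n_traits_per_group.items():
            for i in range(k):
                rows[f"{group}_{i + 1:02d}"] = group
        return pd.Series(rows, name="group")

    def validate(self) -> None:
        lo, hi = self.delta_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("delta_range must satisfy 0 <= lo <= hi <= 1")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0.0 <= self.group_correlation < 1.0:
            raise ValueError("group_correlation must be in [0, 1)")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        if abs(sum(self.hybrid_class_weights) - 1.0) > 1e-9:
            raise ValueError("hybrid_class_weights must sum to 1")
        names = set(self.trait_names())
        for q in self.qtl_spec:
            if q.trait not in names:
                raise ValueError(f"qtl_spec references unknown trait {q.trait!r}")
            if not 0 <= q.locus < self.n_loci:
                raise ValueError(f"qtl_spec references unknown locus {q.locus}")
        if self.transform not in ("exp", "none"):
            raise ValueError("transform must be 'exp' or 'none'")
        for j, d in self.delta_override.items():
            if not (0 <= j < self.n_loci and 0.0 <= d <= 1.0):
                raise ValueError("invalid delta_override entry")


@dataclass
class GardenConfig:
    """Open-pollinated common-garden configuration.

    Among-family variance is ``rbar * h2 * sigma2_p`` with mean sib
    relatedness ``rbar = Cp/2 + (1 - Cp)/4``; the remainder of sigma2_p is
    within-family residual variance.
    """

    n_families: int = 15
    family_size_range: tuple[int, int] = (5, 17)
    cp: float = 0.31
    h2: dict[str, float] = field(default_factory=lambda: {"trait_1": 0.5})
    sigma2_p: float = 1.0
    transform: str = "none"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.cp <= 1.0:
            raise ValueError("Cp must be in [0, 1]")
        for t, h in self.h2.items():
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"true h2 for {t!r} must be in [0, 1]")
        if self.sigma2_p <= 0:
            raise ValueError("sigma2_p must be > 0")
        lo, hi = self.family_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid family_size_range")


@dataclass
class SimTruth:
    """Generating values of a synthetic dataset."""

    Q: pd.Series | None = None
    ancestry: pd.DataFrame | None = None          # individuals x loci, in {0, 0.5, 1}
    qtl: list[QTLSpec] = field(default_factory=list)
    locality_means: pd.DataFrame | None = None    # locality x trait latent shifts
    h2: dict[str, float] = field(default_factory=dict)
    var_family: dict[str, float] = field(default_factory=dict)
    var_residual: dict[str, float] = field(default_factory=dict)
    delta: pd.Series | None = None
    family: pd.Series | None = None


# ---------------------------------------------------------------------------
# parental allele frequencies

def simulate_parental_freqs(
    n_loci: int,
    delta_range: tuple[float, float],
    seed: int,
    n_chromosomes: int = 19,
    n_alleles_range: tuple[int, int] = (2, 6),
    delta_override: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Draw per-locus parental allele-frequency vectors for the two species.

    For each locus a differential ``delta`` is drawn uniformly from
    ``delta_range`` and realised exactly at the most differentiated ("focal")
    allele: freq_alba(focal) - freq_tremula(focal) = delta.  The remaining
    probability mass is split over the other alleles with shared Dirichlet
    weights, so no other allele exceeds the focal differential.

    Returns a long-format frame with columns
    ``locus, chromosome, allele, freq_alba, freq_tremula`` and a per-locus
    ``delta`` column (repeated within locus).
    """
    lo, hi = delta_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("delta_range must be within [0, 1] with lo <= hi")
    rng = np.random.default_rng(seed)
    chroms = roman_chromosomes(n_loci, n_chromosomes)
    rows = []
    for j in range(n_loci):
        locus = f"L{j + 1:03d}"
        delta = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        if delta_override and j in delta_override:
            delta = float(delta_override[j])
        k = int(rng.integers(n_alleles_range[0], n_alleles_range[1] + 1))
        base = float(rng.uniform(0.0, 1.0 - delta))
        p_alba = np.zeros(k)
        p_trem = np.zeros(k)
        p_alba[0] = base + delta
        p_trem[0] = base
        if k > 1:
            w = rng.dirichlet(np.ones(k - 1))
            p_alba[1:] = (1.0 - p_alba[0]) * w
            p_trem[1:] = (1.0 - p_trem[0]) * w
        for a in range(k):
            rows.append(
                {
                    "locus": locus,
                    "chromosome": chroms[j],
                    "allele": a + 1,
                    "freq_alba": p_alba[a],
                    "freq_tremula": p_trem[a],
                    "delta": delta,
                }
            )
    return pd.DataFrame(rows)


def _freq_arrays(freqs: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """locus -> (freq_alba, freq_tremula) arrays indexed by allele-1."""
    out = {}
    for locus, grp in freqs.groupby("locus", sort=False):
        grp = grp.sort_values("allele")
        out[locus] = (
            grp["freq_alba"].to_numpy(float),
            grp["freq_tremula"].to_numpy(float),
        )
    return out


# ---------------------------------------------------------------------------
# hybrid zone

def _draw_hybrid_q(rng: np.random.Generator, weights) -> float:
    """Q of one admixed tree from a mixture of discrete hybrid classes."""
    cls = rng.choice(4, p=np.asarray(weights, float))
    if cls == 0:          # F1
        return 0.5
    if cls == 1:          # F2-like: spread around 0.5
        return float(rng.beta(8.0, 8.0))
    if cls == 2:          # backcross toward alba
        return float(rng.beta(12.0, 4.0))
    return float(rng.beta(4.0, 12.0))  # backcross toward tremula


def simulate_hybrid_zone(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate one multi-locality hybrid-zone dataset.

    Returns ``(genotypes, annotations, freqs, phenotypes, truth)``:

    - genotypes: individuals x 2*loci allele codes (columns ``L001.1`` ...),
      NaN where dropout applies;
    - annotations: per-individual ``locality`` and generating taxon class;
    - freqs: parental allele-frequency table (see simulate_parental_freqs);
    - phenotypes: individuals x traits (non-negative if transform="exp");
    - truth: SimTruth with true Q, per-locus ancestry, QTL, locality means.

    Per-locus true ancestry is drawn independently given Q with
    P(het)=2Q(1-Q), P(alba-hom)=Q^2 (no linkage; markers are sparse).
    Phenotype on the latent scale is
    ``locality + sum_qtl [a*(2*anc-1) + d*1{anc=0.5}] + lambda*group_factor
    + sqrt(1-lambda^2)*N(0,1)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    freqs = simulate_parental_freqs(
        config.n_loci,
        config.delta_range,
        seed=int(rng.integers(2**31 - 1)),
        n_chromosomes=config.n_chromosomes,
        n_alleles_range=config.n_alleles_range,
        delta_override=config.delta_override,
    )
    farr = _freq_arrays(freqs)
    loci = list(farr.keys())

    ids, locality, taxon_true, q_true = [], [], [], []
    for loc, (n_alba, n_trem, n_hyb) in config.n_per_taxon_per_locality.items():
        for taxon, n in (("alba", n_alba), ("tremula", n_trem), ("hybrid", n_hyb)):
            for _ in range(n):
                ids.append(f"{loc}_{len(ids) + 1:04d}")
                locality.append(loc)
                taxon_true.append(taxon)
                if taxon == "alba":
                    q_true.append(1.0)
                elif taxon == "tremula":
                    q_true.append(0.0)
                else:
                    q_true.append(_draw_hybrid_q(rng, config.hybrid_class_weights))
    n = len(ids)
    q = np.array(q_true)

    # ancestry: individuals x loci in {0, 0.5, 1}
    u = rng.random((n, len(loci)))
    p_hom_t = (1.0 - q[:, None]) ** 2
    p_het = 2.0 * q[:, None] * (1.0 - q[:, None])
    anc = np.where(u < p_hom_t, 0.0, np.where(u < p_hom_t + p_het, 0.5, 1.0))

    # genotypes conditional on ancestry
    geno = np.zeros((n, 2 * len(loci)), dtype=float)
    for j, locus in enumerate(loci):
        pa, pt = farr[locus]
        draw_a = np.searchsorted(np.cumsum(pa), rng.random(n))
        draw_a2 = np.searchsorted(np.cumsum(pa), rng.random(n))
        draw_t = np.searchsorted(np.cumsum(pt), rng.random(n))
        draw_t2 = np.searchsorted(np.cumsum(pt), rng.random(n))
        col = anc[:, j]
        a1 = np.where(col == 1.0, draw_a, np.where(col == 0.5, draw_a2, draw_t))
        a2 = np.where(col == 1.0, draw_a2, np.where(col == 0.5, draw_t, draw_t2))
        geno[:, 2 * j] = a1 + 1
        geno[:, 2 * j + 1] = a2 + 1
    if config.dropout > 0:
        mask = rng.random((n, len(loci))) < config.dropout
        for j in range(len(loci)):
            geno[mask[:, j], 2 * j] = np.nan
            geno[mask[:, j], 2 * j + 1] = np.nan

    # phenotypes
    traits = config.trait_names()
    groups = config.trait_groups()
    localities = list(config.n_per_taxon_per_locality.keys())
    loc_eff = pd.DataFrame(0.0, index=localities, columns=traits)
    if config.locality_effects:
        for t, shifts in config.locality_effects.items():
            for loc, v in shifts.items():
                loc_eff.loc[loc, t] = v
    lam = config.group_correlation
    group_factor = {g: rng.standard_normal(n) for g in config.n_traits_per_group}
    qtl_by_trait: dict[str, list[QTLSpec]] = {}
    for qq in config.qtl_spec:
        qtl_by_trait.setdefault(qq.trait, []).append(qq)
    loc_idx = pd.Series(locality, index=ids)
    z = np.zeros((n, len(traits)))
    for ti, t in enumerate(traits):
        y = loc_eff.loc[locality, t].to_numpy()
        for qq in qtl_by_trait.get(t, []):
            col = anc[:, qq.locus]
            y = y + qq.a * (2.0 * col - 1.0) + qq.d * (col == 0.5)
        y = y + lam * group_factor[groups[t]]
        y = y + np.sqrt(1.0 - lam**2) * rng.standard_normal(n)
        z[:, ti] = y
    if config.transform == "exp":
        z = np.exp(z)

    geno_cols = [f"{locus}.{slot}" for locus in loci for slot in (1, 2)]
    genotypes = pd.DataFrame(geno, index=pd.Index(ids, name="id"), columns=geno_cols)
    annotations = pd.DataFrame(
        {"locality": locality, "taxon_true": taxon_true}, index=genotypes.index
    )
    phenotypes = pd.DataFrame(z, index=genotypes.index, columns=traits)
    truth = SimTruth(
        Q=pd.Series(q, index=genotypes.index, name="Q"),
        ancestry=pd.DataFrame(anc, index=genotypes.index, columns=loci),
        qtl=list(config.qtl_spec),
        locality_means=loc_eff,
        delta=freqs.groupby("locus", sort=False)["delta"].first(),
    )
    return genotypes, annotations, freqs, phenotypes, truth


# ---------------------------------------------------------------------------
# common garden

def mean_sib_relatedness(cp: float) -> float:
    """Mean relatedness among open-pollinated sibs with full-sib fraction Cp."""
    return cp * 0.5 + (1.0 - cp) * 0.25


def simulate_common_garden(config: GardenConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate an unbalanced open-pollinated family trial.

    Returns ``(families, phenotypes, truth)`` where families maps individual
    id -> family label.  For each trait with true heritability h2, family
    effects have variance ``rbar*h2*sigma2_p`` and residuals the remainder,
    so a half-sib analysis with multiplier 1/rbar recovers h2 in expectation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rbar = mean_sib_relatedness(config.cp)
    lo, hi = config.family_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_families)
    fam_labels = np.repeat([f"F{i + 1:02d}" for i in range(config.n_families)], sizes)
    n = int(sizes.sum())
    ids = pd.Index([f"cg_{i + 1:04d}" for i in range(n)], name="id")

    pheno = {}
    var_f, var_e = {}, {}
    for trait, h2 in config.h2.items():
        vf = rbar * h2 * config.sigma2_p
        ve = config.sigma2_p - vf
        if ve <= 0:
            raise ValueError(f"implied residual variance <= 0 for {trait!r}")
        fam_eff = rng.normal(0.0, np.sqrt(vf), size=config.n_families)
        y = np.repeat(fam_eff, sizes) + rng.normal(0.0, np.sqrt(ve), size=n)
        if config.transform == "exp":
            y = np.exp(y)
        pheno[trait] = y
        var_f[trait], var_e[trait] = vf, ve
    families = pd.DataFrame({"family": fam_labels}, index=ids)
    phenotypes = pd.DataFrame(pheno, index=ids)
    truth = SimTruth(
        h2=dict(config.h2),
        var_family=var_f,
        var_residual=var_e,
        family=families["family"],
    )
    return families, phenotypes, truth


# ---------------------------------------------------------------------------
# helpers for planted-effect calibration

def ancestry_dosage_variance(config: SimConfig, n_draws: int = 200_000, seed: int = 12345) -> float:
    """Variance of the ancestry dosage x = 2*anc - 1 in {-1, 0, 1} under the
    configured taxon mix and hybrid-class distribution.

    Used to size a planted additive effect for a target variance explained:
    a QTL with effect a on unit residual SD has true R^2 =
    a^2 V / (a^2 V + 1) with V this variance.  Monte-Carlo with a fixed
    internal seed (deterministic, independent of the dataset seed).
    """
    rng = np.random.default_rng(seed)
    counts = np.array([c for c in config.n_per_taxon_per_locality.values()])
    n_alba, n_trem, n_hyb = counts.sum(axis=0)
    total = n_alba + n_trem + n_hyb
    qs = []
    for _ in range(n_draws):
        u = rng.random() * total
        if u < n_alba:
            qs.append(1.0)
        elif u < n_alba + n_trem:
            qs.append(0.0)
        else:
            qs.append(_draw_hybrid_q(rng, config.hybrid_class_weights))
    q = np.asarray(qs)
    ex = 2.0 * q - 1.0
    ex2 = 1.0 - 2.0 * q * (1.0 - q)
    return float(ex2.mean() - ex.mean() ** 2)


def default_hybrid_config(**overrides) -> SimConfig:
    """The default study-like configuration (260 trees, 77 loci, 38 traits)."""
    return SimConfig(**overrides)


def default_garden_config(**overrides) -> GardenConfig:
    return GardenConfig(**overrides)
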
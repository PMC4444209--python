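"""Shared configuration for the numbered analysis scripts.

One synthetic "study" is generated by 01_simulate_study.py and re-used by
every later script: three hybrid zones totalling 260 trees genotyped at 77
microsatellite-like markers on 19 chromosomes, 38 metabolite traits in
three correlated functional groups with a handful of planted QTL, and an
open-pollinated common garden of 15 maternal families (Cp = 0.31).
"""

from pathlib import Path

from admixqtl.simulate import GardenConfig, QTLSpec, SimConfig

REPO = Path(__file__).resolve().parents[1]
DATA = REPO / "results" / "study_data"
RESULTS = REPO / "results"

SEED = 20240901

# Planted QTL (trait, locus index, additive effect a, dominance deviation d),
# effects in residual-SD units; loci 5/20/33/47/60 are forced diagnostic
# (delta = 1) so positional recovery is well defined.
QTL_PLAN = [
    QTLSpec("salicinoid_01", 5, 0.8, 0.0),      # additive
    QTLSpec("salicinoid_02", 20, 0.5, 0.5),     # alba-dominant
    QTLSpec("flavonoid_01", 33, 0.9, 0.0),      # additive, large
    QTLSpec("flavonoid_02", 47, 0.3, 1.0),      # over-dominant
    QTLSpec("chlorogenic_acid_01", 60, 0.6, -0.6),  # tremula-dominant-ish
]


def study_config() -> SimConfig:
    return SimConfig(
        seed=SEED,
        qtl_spec=list(QTL_PLAN),
        delta_override={q.locus: 1.0 for q in QTL_PLAN},
        locality_effects={
            "flavonoid_01": {"Ticino": 0.0, "Danube": 0.6, "Tisza": -0.4},
            "salicinoid_01": {"Ticino": 0.3, "Danube": 0.0, "Tisza": 0.0},
        },
        group_correlation=0.5,
        transform="exp",
    )


def garden_config() -> GardenConfig:
    # heritabilities spanning the range reported for metabolite traits
    h2 = {
        "chlorogenic_acid_01": 0.45,
        "salicinoid_01": 0.35,
        "salicinoid_02": 0.15,
        "flavonoid_01": 0.60,
        "flavonoid_02": 0.30,
    }
    return GardenConfig(seed=SEED + 1, cp=0.31, h2=h2)
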
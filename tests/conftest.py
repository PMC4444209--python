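import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def diagnostic_freqs():
    """Two fully diagnostic biallelic loci: allele 1 fixed in alba,
    allele 2 fixed in tremula."""
    rows = []
    for j, locus in enumerate(["L001", "L002"]):
        rows.append({"locus": locus, "chromosome": "I", "allele": 1,
                     "freq_alba": 1.0, "freq_tremula": 0.0, "delta": 1.0})
        rows.append({"locus": locus, "chromosome": "I", "allele": 2,
                     "freq_alba": 0.0, "freq_tremula": 1.0, "delta": 1.0})
    return pd.DataFrame(rows)


def genotype_frame(allele_pairs: dict[str, list[tuple[int, int]]]) -> pd.DataFrame:
    """Build a genotype table from locus -> [(a1, a2) per individual]."""
    loci = list(allele_pairs)
    n = len(next(iter(allele_pairs.values())))
    data = {}
    for locus in loci:
        data[f"{locus}.1"] = [p[0] for p in allele_pairs[locus]]
        data[f"{locus}.2"] = [p[1] for p in allele_pairs[locus]]
    return pd.DataFrame(data, index=pd.Index([f"ind{i}" for i in range(n)], name="id"),
                        dtype=float)
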
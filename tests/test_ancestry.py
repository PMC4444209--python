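"""Q and LSA estimation: analytic limits, brute-force oracles, and the
orientation-equivariance property."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from admixqtl.ancestry import (
    TAXON_PRESETS,
    classify_taxon,
    estimate_Q,
    estimate_lsa,
    smoothed_freq_arrays,
)
from admixqtl.simulate import SimConfig, simulate_hybrid_zone

from conftest import genotype_frame


def _loglik(q, pa, pt):
    return np.log(q * pa + (1 - q) * pt).sum()


class TestEstimateQ:
    def test_all_alba_alleles_at_diagnostic_loci(self, diagnostic_freqs):
        geno = genotype_frame({"L001": [(1, 1)], "L002": [(1, 1)]})
        q = estimate_Q(geno, diagnostic_freqs)
        assert q.iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_one_allele_of_each_species_gives_half(self, diagnostic_freqs):
        geno = genotype_frame({"L001": [(1, 2)], "L002": [(2, 1)]})
        q = estimate_Q(geno, diagnostic_freqs)
        assert q.iloc[0] == pytest.approx(0.5, abs=1e-6)

    def test_matches_fine_grid_oracle(self):
        # 5 loci with delta = 0.8; oracle = coarse grid then 1e-6 refinement
        freqs = []
        for j in range(5):
            base = 0.05 + 0.02 * j
            freqs += [
                {"locus": f"L{j + 1:03d}", "chromosome": "I", "allele": 1,
                 "freq_alba": base + 0.8, "freq_tremula": base},
                {"locus": f"L{j + 1:03d}", "chromosome": "I", "allele": 2,
                 "freq_alba": 0.2 - base, "freq_tremula": 1.0 - base},
            ]
        freqs = pd.DataFrame(freqs)
        geno = genotype_frame({
            "L001": [(1, 2)], "L002": [(1, 1)], "L003": [(2, 2)],
            "L004": [(1, 2)], "L005": [(1, 1)],
        })
        q_hat = estimate_Q(geno, freqs).iloc[0]
        farr = smoothed_freq_arrays(freqs)
        pa, pt = [], []
        for j, locus in enumerate(farr):
            fa, ft = farr[locus]
            for allele in (geno.iloc[0, 2 * j], geno.iloc[0, 2 * j + 1]):
                pa.append(fa[int(allele) - 1])
                pt.append(ft[int(allele) - 1])
        pa, pt = np.array(pa), np.array(pt)
        coarse = np.linspace(0, 1, 1001)
        q0 = coarse[np.argmax([_loglik(q, pa, pt) for q in coarse])]
        fine = np.clip(np.arange(q0 - 2e-3, q0 + 2e-3, 1e-6), 0, 1)
        q_grid = fine[np.argmax([_loglik(q, pa, pt) for q in fine])]
        assert q_hat == pytest.approx(q_grid, abs=1e-6)
        assert _loglik(q_hat, pa, pt) >= _loglik(q0, pa, pt) - 1e-9

    def test_individual_without_genotypes_rejected(self, diagnostic_freqs):
        geno = genotype_frame({"L001": [(np.nan, np.nan)], "L002": [(np.nan, np.nan)]})
        with pytest.raises(ValueError, match="no genotyped loci"):
            estimate_Q(geno, diagnostic_freqs)

    def test_diagnostic_panel_recovers_mean_true_ancestry(self):
        cfg = SimConfig(seed=21, delta_range=(1.0, 1.0), n_loci=40,
                        n_alleles_range=(2, 2))
        geno, _, freqs, _, truth = simulate_hybrid_zone(cfg)
        q = estimate_Q(geno, freqs)
        anc_mean = truth.ancestry.mean(axis=1)
        assert (q - anc_mean).abs().max() <= 1.0 / (2 * cfg.n_loci) + 1e-9


class TestEstimateLSA:
    def test_diagnostic_het_has_certain_interspecific_call(self, diagnostic_freqs):
        geno = genotype_frame({"L001": [(1, 2)], "L002": [(1, 2)]})
        q = estimate_Q(geno, diagnostic_freqs)
        tab = estimate_lsa(geno, diagnostic_freqs, q)
        assert (tab.lsa.iloc[0] == 0.5).all()
        # the zero-frequency floor (eps = 1/(2n+1)) keeps the posterior just
        # below certainty; it converges to 1 as the parental sample grows
        assert (tab.posterior.iloc[0] > 0.95).all()
        tab_big = estimate_lsa(geno, diagnostic_freqs, q, parental_n=50_000)
        assert (tab_big.posterior.iloc[0] > 0.9999).all()

    def test_uninformative_locus_posterior_equals_prior(self):
        freqs = pd.DataFrame([
            {"locus": "L001", "chromosome": "I", "allele": 1,
             "freq_alba": 0.3, "freq_tremula": 0.3},
            {"locus": "L001", "chromosome": "I", "allele": 2,
             "freq_alba": 0.7, "freq_tremula": 0.7},
        ])
        geno = genotype_frame({"L001": [(1, 2)]})
        q = pd.Series([0.8], index=geno.index)
        tab = estimate_lsa(geno, freqs, q)
        # prior (0.04, 0.32, 0.64): MAP follows Q toward the alba homozygote
        assert tab.lsa.iloc[0, 0] == 1.0
        assert tab.posterior.iloc[0, 0] == pytest.approx(0.64, abs=1e-12)

    def test_posterior_matches_enumeration_oracle(self, rng):
        for trial in range(20):
            k = int(rng.integers(2, 5))
            fa = rng.dirichlet(np.ones(k))
            ft = rng.dirichlet(np.ones(k))
            freqs = pd.DataFrame([
                {"locus": "L001", "chromosome": "I", "allele": a + 1,
                 "freq_alba": fa[a], "freq_tremula": ft[a]}
                for a in range(k)
            ])
            a1, a2 = int(rng.integers(1, k + 1)), int(rng.integers(1, k + 1))
            qv = float(rng.uniform(0.05, 0.95))
            geno = genotype_frame({"L001": [(a1, a2)]})
            tab = estimate_lsa(geno, freqs, pd.Series([qv], index=geno.index))
            # independent 3-state Bayes enumeration
            farr = smoothed_freq_arrays(freqs)
            fa_s, ft_s = farr["L001"]
            i, j = a1 - 1, a2 - 1
            if i == j:
                lik = [ft_s[i] ** 2, fa_s[i] * ft_s[i], fa_s[i] ** 2]
            else:
                lik = [2 * ft_s[i] * ft_s[j],
                       fa_s[i] * ft_s[j] + fa_s[j] * ft_s[i],
                       2 * fa_s[i] * fa_s[j]]
            prior = [(1 - qv) ** 2, 2 * qv * (1 - qv), qv**2]
            post = np.array(prior) * np.array(lik)
            post = post / post.sum()
            state = [0.0, 0.5, 1.0][int(np.argmax(post))]
            assert tab.lsa.iloc[0, 0] == state
            assert tab.posterior.iloc[0, 0] == pytest.approx(post.max(), abs=1e-9)

    def test_missing_genotype_leaves_prior(self, diagnostic_freqs):
        geno = genotype_frame({"L001": [(np.nan, np.nan)], "L002": [(1, 2)]})
        q = pd.Series([0.9], index=geno.index)
        tab = estimate_lsa(geno, diagnostic_freqs, q)
        assert tab.lsa.iloc[0]["L001"] == 1.0          # prior MAP at Q=0.9
        assert tab.posterior.iloc[0]["L001"] == pytest.approx(0.81)

    def test_accuracy_monotone_in_delta_and_perfect_when_diagnostic(self):
        accs = []
        for delta in (0.3, 0.7, 1.0):
            cfg = SimConfig(seed=31, delta_range=(delta, delta), n_loci=30,
                            n_alleles_range=(2, 2))
            geno, _, freqs, _, truth = simulate_hybrid_zone(cfg)
            q = estimate_Q(geno, freqs)
            tab = estimate_lsa(geno, freqs, q)
            accs.append((tab.lsa.values == truth.ancestry.values).mean())
        assert accs[0] <= accs[1] <= accs[2]
        assert accs[2] == 1.0

    def test_orientation_equivariance(self):
        cfg = SimConfig(seed=77, n_loci=12)
        geno, _, freqs, _, _ = simulate_hybrid_zone(cfg)
        geno = geno.iloc[:40]
        swapped = freqs.rename(
            columns={"freq_alba": "freq_tremula", "freq_tremula": "freq_alba"}
        )
        q = estimate_Q(geno, freqs)
        q_sw = estimate_Q(geno, swapped)
        assert np.allclose(q_sw, 1.0 - q, atol=1e-6)
        lsa = estimate_lsa(geno, freqs, q).lsa
        lsa_sw = estimate_lsa(geno, swapped, q_sw).lsa
        assert np.allclose(lsa_sw.values, 1.0 - lsa.values)


class TestClassifyTaxon:
    @pytest.mark.parametrize(
        "q,lower,upper,expected",
        [
            (0.5, 0.05, 0.95, "hybrid"),
            (0.97, 0.05, 0.95, "alba-like"),
            (0.97, 0.01, 0.99, "hybrid"),
            (0.05, 0.05, 0.95, "tremula-like"),   # boundary excluded from hybrids
            (0.95, 0.05, 0.95, "alba-like"),
            (0.0, 0.01, 0.99, "tremula-like"),
        ],
    )
    def test_thresholding(self, q, lower, upper, expected):
        assert classify_taxon(q, lower, upper) == expected

    def test_presets_match_published_pairs(self):
        assert TAXON_PRESETS["network_hybrids"] == (0.05, 0.95)
        assert TAXON_PRESETS["mantel_hybrids"] == (0.01, 0.99)
        assert classify_taxon(0.97, preset="mantel_hybrids") == "hybrid"

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_taxon(0.5, 0.9, 0.1)

    @given(st.floats(0, 1), st.floats(0.01, 0.49))
    def test_series_and_scalar_agree(self, q, lower):
        upper = 1 - lower
        s = classify_taxon(pd.Series([q]), lower, upper)
        assert s.iloc[0] == classify_taxon(q, lower, upper)
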
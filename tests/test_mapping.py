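"""Admixture mapping: residualisation, AIC fits, screening, model selection,
pseudo-R^2 and gene action, each against an independent oracle where one
exists."""

import itertools

import numpy as np
import pandas as pd
import pytest

from admixqtl.mapping import (
    classify_gene_action,
    compute_pve,
    fit_single_locus,
    map_phenotypes,
    map_trait,
    residualize,
    scan_delta_aic,
    screen_candidates,
    select_model,
    _aic,
    _gaussian_loglik,
    _ols_rss,
)


def _mk(y, name="y"):
    return pd.Series(np.asarray(y, float), name=name)


def _lsa_series(values):
    return pd.Series(np.asarray(values, float), name="L001")


class TestResidualize:
    def test_single_locality_gives_plain_z_scores(self, rng):
        y = pd.DataFrame({"t": rng.normal(3, 2, 40)})
        loc = pd.Series(["A"] * 40, index=y.index)
        r = residualize(y, loc)["t"]
        expected = (y["t"] - y["t"].mean()) / y["t"].std(ddof=1)
        assert np.allclose(r, expected, atol=1e-12)

    def test_locality_shift_invariance(self, rng):
        base = rng.normal(0, 1, 60)
        loc = pd.Series(np.repeat(["A", "B"], 30))
        y0 = pd.DataFrame({"t": base})
        y1 = pd.DataFrame({"t": base + np.where(loc == "B", 10.0, 0.0)})
        r0 = residualize(y0, loc)
        r1 = residualize(y1, loc)
        assert np.allclose(r0["t"], r1["t"], atol=1e-9)

    def test_matches_direct_arithmetic_oracle(self, rng):
        n = 90
        loc = pd.Series(rng.choice(["A", "B", "C"], n))
        y = pd.DataFrame({"t": rng.normal(0, 3, n)})
        r = residualize(y, loc)["t"].to_numpy()
        resid = y["t"] - y["t"].groupby(loc).transform("mean")
        rmse = np.sqrt((resid**2).sum() / (n - 3))
        assert np.allclose(r, resid / rmse, atol=1e-9)
        assert abs(r.mean()) < 1e-10


class TestSingleLocusFit:
    def test_linear_signal_prefers_additive_with_no_dominance(self):
        x = _lsa_series([0, 0, 0.5, 0.5, 1, 1] * 5)
        y = _mk(2.0 * x.to_numpy() + 0.001 * np.sin(np.arange(30)))
        f = fit_single_locus(y, x)
        assert f.aic_additive < f.aic_null
        assert f.coef_dominant[2] == pytest.approx(0.0, abs=0.01)

    def test_aic_matches_statsmodels_ols_loglik(self, rng):
        # independent oracle: statsmodels OLS llf with the sigma^2 parameter
        # added to the AIC count
        import statsmodels.api as sm

        x = _lsa_series([0, 0.5, 1, 0.5, 0, 1])
        y = _mk([0.2, 1.1, 2.3, 0.9, -0.4, 1.8])
        f = fit_single_locus(y, x)
        X_add = sm.add_constant(x.to_numpy())
        X_dom = sm.add_constant(np.column_stack([x, (x == 0.5).astype(float)]))
        for aic_mine, X, k in [
            (f.aic_null, np.ones((6, 1)), 1),
            (f.aic_additive, X_add, 2),
            (f.aic_dominant, X_dom, 3),
        ]:
            llf = sm.OLS(y.to_numpy(), X).fit().llf
            assert aic_mine == pytest.approx(-2 * llf + 2 * (k + 1), abs=1e-6)

    def test_monomorphic_locus_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            fit_single_locus(_mk([1, 2, 3, 4]), _lsa_series([1, 1, 1, 1]))

    def test_vectorised_scan_agrees_with_scalar_path(self, rng):
        n = 50
        lsa = pd.DataFrame(
            rng.choice([0.0, 0.5, 1.0], size=(n, 4)), columns=list("ABCD")
        )
        Y = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=["t1", "t2", "t3"])
        d_add, d_dom = scan_delta_aic(Y, lsa)
        for t in Y.columns:
            for L in lsa.columns:
                f = fit_single_locus(Y[t], lsa[L])
                assert d_add.loc[t, L] == pytest.approx(f.aic_null - f.aic_additive, abs=1e-8)
                assert d_dom.loc[t, L] == pytest.approx(f.aic_null - f.aic_dominant, abs=1e-8)


class TestScreening:
    def test_threshold_boundary_is_inclusive(self):
        d_add = pd.DataFrame({"L001": [3.9], "L002": [4.0]}, index=["t"])
        d_dom = pd.DataFrame({"L001": [0.0], "L002": [0.0]}, index=["t"])
        cands = screen_candidates(d_add, d_dom, threshold=4.0)
        assert list(cands["locus"]) == ["L002"]
        assert list(cands["model"]) == ["additive"]

    def test_infinite_threshold_reports_nothing(self, rng):
        d = pd.DataFrame(rng.normal(2, 1, (3, 5)))
        assert screen_candidates(d, d, threshold=np.inf).empty

    def test_zero_threshold_reduces_to_best_model_beats_null(self, rng):
        d_add = pd.DataFrame(rng.normal(0, 2, (2, 6)))
        d_dom = pd.DataFrame(rng.normal(0, 2, (2, 6)))
        cands = screen_candidates(d_add, d_dom, threshold=0.0)
        expect = (np.maximum(d_add.values, d_dom.values) >= 0).sum()
        assert len(cands) == expect


class TestSelectModel:
    def _y_with_effects(self, rng, lsa, effects):
        y = rng.normal(0, 1, len(lsa))
        for L, a in effects.items():
            y = y + a * (2 * lsa[L].to_numpy() - 1)
        return pd.Series(y, index=lsa.index)

    def test_single_candidate_reduces_to_screening(self, rng):
        lsa = pd.DataFrame({"L001": rng.choice([0.0, 0.5, 1.0], 100)})
        y = self._y_with_effects(rng, lsa, {"L001": 1.0})
        f = fit_single_locus(y, lsa["L001"])
        sel = select_model(y, lsa, {"L001": f.best_model}, threshold=4.0)
        assert (f.delta_aic >= 4.0) == (sel.retained == ["L001"])

    def test_two_true_qtl_and_decoy(self, rng):
        n = 260
        lsa = pd.DataFrame(
            rng.choice([0.0, 0.5, 1.0], size=(n, 3)), columns=["La", "Lb", "Ldecoy"]
        )
        y = self._y_with_effects(rng, lsa, {"La": 0.8, "Lb": 0.6})
        sel = select_model(y, lsa, dict.fromkeys(lsa.columns, "additive"), threshold=4.0)
        assert set(sel.retained) == {"La", "Lb"}

    def test_matches_stationary_exhaustive_search(self, rng):
        # oracle: enumerate all subsets; the greedy result must be a
        # forward/backward stationary point and match the best-AIC subset
        # among subsets whose every member contributes >= threshold
        n = 30
        lsa = pd.DataFrame(
            rng.choice([0.0, 0.5, 1.0], size=(n, 3)), columns=["L1", "L2", "L3"]
        )
        y = self._y_with_effects(rng, lsa, {"L1": 1.2, "L2": 0.9})
        models = dict.fromkeys(lsa.columns, "additive")
        sel = select_model(y, lsa, models, threshold=4.0)

        def aic_of(subset):
            X = np.column_stack(
                [np.ones(n)] + [lsa[L].to_numpy() for L in subset]
            )
            _, rss = _ols_rss(X, y.to_numpy())
            return _aic(rss, n, X.shape[1])

        valid = []
        for k in range(4):
            for sub in itertools.combinations(lsa.columns, k):
                sub = list(sub)
                a = aic_of(sub)
                if all(aic_of([m for m in sub if m != L]) - a >= 4.0 for L in sub):
                    valid.append((a, sub))
        best_aic, best_sub = min(valid)
        assert sorted(sel.retained) == sorted(best_sub)
        assert sel.aic == pytest.approx(best_aic, abs=1e-9)

    def test_duplicate_candidate_columns_collapsed(self, rng):
        col = rng.choice([0.0, 0.5, 1.0], 120)
        lsa = pd.DataFrame({"L1": col, "L2": col.copy()})
        y = pd.Series(1.5 * (2 * col - 1) + rng.normal(0, 1, 120))
        sel = select_model(y, lsa, {"L1": "additive", "L2": "additive"}, threshold=4.0)
        assert sel.retained == ["L1"]


class TestPVE:
    def test_null_model_gives_zero(self):
        assert compute_pve(-100.0, -100.0, 50)[0] == 0.0

    def test_equals_ordinary_r_squared_identity(self, rng):
        # for Gaussian ML fits, 1 - exp(-(2/n) dlogL) == 1 - RSS_m/RSS_0
        n = 80
        x = rng.normal(0, 1, n)
        y = 0.7 * x + rng.normal(0, 1, n)
        ones = np.ones((n, 1))
        _, rss0 = _ols_rss(ones, y)
        _, rss1 = _ols_rss(np.column_stack([ones, x]), y)
        ll0 = _gaussian_loglik(rss0, n)
        ll1 = _gaussian_loglik(rss1, n)
        r2, r2_rescaled = compute_pve(ll1, ll0, n)
        assert r2 == pytest.approx(1 - rss1 / rss0, abs=1e-9)
        assert 0 < r2 <= r2_rescaled <= 1

    def test_model_below_null_flags_bug(self):
        with pytest.raises(ValueError):
            compute_pve(-101.0, -100.0, 50)


class TestGeneAction:
    @pytest.mark.parametrize(
        "m0,m05,m1,expected",
        [
            (0.0, 0.5, 1.0, "additive"),
            (0.0, 1.5, 1.0, "over-dominant"),
            (0.0, -0.5, 1.0, "under-dominant"),
            (0.0, 1.0, 1.0, "alba-dominant"),
            (0.0, 0.0, 1.0, "tremula-dominant"),
        ],
    )
    def test_point_classification(self, m0, m05, m1, expected):
        assert classify_gene_action(m0, m05, m1, se05=0.0, tau=0.05) == expected


class TestPipelineInvariances:
    def test_mapping_invariant_to_affine_phenotype_rescaling(self, rng):
        n = 120
        loc = pd.Series(rng.choice(["A", "B"], n))
        lsa = pd.DataFrame(
            rng.choice([0.0, 0.5, 1.0], size=(n, 5)),
            columns=[f"L{j}" for j in range(5)],
        )
        y = pd.DataFrame({"t": 1.0 * (2 * lsa["L2"] - 1) + rng.normal(0, 1, n)})
        res_a = residualize(y, loc)
        res_b = residualize(3.0 * y + 7.0, loc)
        qa = map_phenotypes(res_a, lsa)
        qb = map_phenotypes(res_b, lsa)
        pd.testing.assert_frame_equal(qa, qb, atol=1e-8, check_exact=False)

    def test_infinite_threshold_yields_no_qtl(self, rng):
        lsa = pd.DataFrame({"L1": rng.choice([0.0, 0.5, 1.0], 60)})
        y = pd.Series(2.0 * lsa["L1"] + rng.normal(0, 0.2, 60))
        recs, sel = map_trait(y, lsa, threshold=np.inf)
        assert recs == [] and sel is None
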
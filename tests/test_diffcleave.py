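"""Normalization, dispersion, NB GLM and multiplicity correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from m7gmap.diffcleave import (
    design_matrix,
    estimate_dispersion,
    fit_nb_glm,
    nb_loglik,
    run_interaction_test,
    size_factors,
    wald_bh,
)
from m7gmap.fragments import CountMatrix, FragmentKey, SampleDesign

DESIGN_2X2 = [
    SampleDesign("KO_U", "KO", False, 1),
    SampleDesign("KO_T", "KO", True, 1),
    SampleDesign("WT_U", "WT", False, 1),
    SampleDesign("WT_T", "WT", True, 1),
]


def design_reps(reps=3):
    return [
        SampleDesign(f"{c}_{'T' if t else 'U'}_{r}", c, t, r)
        for c in ("WT", "KO")
        for t in (True, False)
        for r in range(1, reps + 1)
    ]


def frame(rows, design):
    df = pd.DataFrame(rows, columns=[d.sample_id for d in design], dtype=float)
    df.index = [f"ref:{i}-{i + 20}" for i in range(len(df))]
    return df


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        design = DESIGN_2X2
        df = frame([[5, 5, 5, 5], [8, 8, 8, 8], [2, 2, 2, 2]], design)
        f = size_factors(df)
        assert np.allclose(f.to_numpy(), 1.0)

    def test_doubled_column_sqrt2_factors(self):
        rng = np.random.default_rng(0)
        a = rng.integers(5, 100, size=50).astype(float)
        design = DESIGN_2X2[:2]
        df = pd.DataFrame({"KO_U": a, "KO_T": 2 * a})
        f = size_factors(df)
        assert f["KO_U"] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert f["KO_T"] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_single_row_closed_form(self):
        df = pd.DataFrame({"a": [5.0], "b": [20.0]})
        f = size_factors(df)
        assert f["a"] == pytest.approx(0.5)
        assert f["b"] == pytest.approx(2.0)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.integers(1, 200, size=(40, 6)).astype(float))
        f = size_factors(df)
        assert np.exp(np.log(f.to_numpy()).mean()) == pytest.approx(1.0)

    def test_zero_rows_excluded_all_zero_hard_error(self):
        df = pd.DataFrame({"a": [0.0, 5.0], "b": [3.0, 0.0]})
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(df)


class TestDispersion:
    def test_poisson_limit(self):
        rng = np.random.default_rng(2)
        design = design_reps(10)
        mu = 200.0
        counts = rng.poisson(mu, size=(300, len(design)))
        df = frame(counts.tolist(), design)
        f = pd.Series(1.0, index=df.columns)
        alpha = estimate_dispersion(df, design, f)
        assert np.median(alpha) < 0.01

    def test_nb_parameter_recovery(self):
        rng = np.random.default_rng(3)
        design = design_reps(3)
        true_alpha, mu = 0.2, 100.0
        r = 1 / true_alpha
        counts = rng.negative_binomial(r, r / (r + mu), size=(200, len(design)))
        df = frame(counts.tolist(), design)
        f = pd.Series(1.0, index=df.columns)
        alpha = estimate_dispersion(df, design, f)
        assert 0.1 <= np.median(alpha) <= 0.4

    def test_constant_counts_floor(self):
        design = design_reps(3)
        df = frame([[7] * len(design)] * 5, design)
        f = pd.Series(1.0, index=df.columns)
        alpha = estimate_dispersion(df, design, f)
        assert np.allclose(alpha, 1e-8)

    def test_singleton_cells_hard_error(self):
        design = DESIGN_2X2
        df = frame([[5, 6, 7, 8]], design)
        f = pd.Series(1.0, index=df.columns)
        with pytest.raises(ValueError, match="singleton"):
            estimate_dispersion(df, design, f)


class TestNBGLM:
    def test_saturated_2x2_interaction_ln8(self):
        design = DESIGN_2X2
        X = design_matrix(design)
        counts = np.array([10.0, 10.0, 10.0, 80.0])  # KO_U, KO_T, WT_U, WT_T
        fit = fit_nb_glm(counts, X, np.zeros(4), alpha=1e-10)
        assert fit.converged
        assert fit.coefficients[3] == pytest.approx(np.log(8.0), abs=1e-6)
        assert fit.coefficients[3] / np.log(2) == pytest.approx(3.0, abs=1e-6)

    def test_all_cells_equal_null_coefficients(self):
        design = DESIGN_2X2
        X = design_matrix(design)
        fit = fit_nb_glm(np.array([10.0] * 4), X, np.zeros(4), alpha=1e-10)
        assert fit.converged
        assert np.allclose(fit.coefficients[1:], 0.0, atol=1e-8)
        assert fit.coefficients[0] == pytest.approx(np.log(10.0), abs=1e-8)

    def test_poisson_limit_matches_likelihood_grid(self):
        """alpha -> 0 IRLS equals a brute-force Poisson likelihood grid on a
        two-parameter (intercept + treatment) sub-model, to 1e-4."""
        y = np.array([12.0, 9.0, 11.0, 30.0, 25.0, 33.0])
        X = np.column_stack([np.ones(6), np.array([0, 0, 0, 1, 1, 1.0])])
        offset = np.zeros(6)
        fit = fit_nb_glm(y, X, offset, alpha=1e-12)
        # two-stage grid maximizing the Poisson log-likelihood
        b0s = np.linspace(1.0, 4.0, 301)
        b1s = np.linspace(-1.0, 3.0, 401)
        best = None
        for _ in range(3):
            ll = np.array(
                [
                    [
                        nb_loglik(y, np.exp(b0 + b1 * X[:, 1]), 0.0)
                        for b1 in b1s
                    ]
                    for b0 in b0s
                ]
            )
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            best = (b0s[i], b1s[j])
            b0s = np.linspace(best[0] - (b0s[1] - b0s[0]), best[0] + (b0s[1] - b0s[0]), 41)
            b1s = np.linspace(best[1] - (b1s[1] - b1s[0]), best[1] + (b1s[1] - b1s[0]), 41)
        assert fit.coefficients[0] == pytest.approx(best[0], abs=1e-4)
        assert fit.coefficients[1] == pytest.approx(best[1], abs=1e-4)

    def test_matches_statsmodels_nb_glm(self):
        """Independent cross-check at fixed dispersion via statsmodels."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        design = design_reps(3)
        X = design_matrix(design)
        mu = np.exp(X @ np.array([3.0, 0.2, 0.1, 0.8]))
        alpha = 0.1
        r = 1 / alpha
        y = rng.negative_binomial(r, r / (r + mu)).astype(float)
        offset = np.log(np.full(len(design), 1.0))
        fit = fit_nb_glm(y, X, offset, alpha)
        sm_fit = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
        ).fit()
        assert np.allclose(fit.coefficients, sm_fit.params, atol=1e-6)

    def test_offsets_shift_intercept_only(self):
        design = DESIGN_2X2
        X = design_matrix(design)
        y = np.array([10.0, 10.0, 10.0, 80.0])
        fit0 = fit_nb_glm(y, X, np.zeros(4), alpha=1e-10)
        fit1 = fit_nb_glm(y, X, np.full(4, np.log(2.0)), alpha=1e-10)
        assert fit1.coefficients[0] == pytest.approx(
            fit0.coefficients[0] - np.log(2.0), abs=1e-6
        )
        assert fit1.coefficients[3] == pytest.approx(fit0.coefficients[3], abs=1e-6)


class TestWaldBH:
    def _fits(self, zs):
        fits = []
        for z in zs:
            beta = np.array([1.0, 0.0, 0.0, z])
            se = np.ones(4)
            from m7gmap.diffcleave import GLMFit

            fits.append(GLMFit(beta, se, 0.1, True, 5))
        return fits

    def test_bh_hand_example(self):
        from m7gmap.diffcleave import GLMFit

        ps = [0.01, 0.02, 0.03, 0.04]
        zs = [stats.norm.isf(p / 2) for p in ps]
        fits = [GLMFit(np.array([0, 0, 0, z]), np.ones(4), 0.1, True, 3) for z in zs]
        frags = [FragmentKey("r", i, i + 20) for i in range(4)]
        results = wald_bh(fits, frags, [10.0] * 4)
        for r, p in zip(results, ps):
            assert r.p_value == pytest.approx(p, abs=1e-12)
            assert r.p_adjusted == pytest.approx(0.04, abs=1e-12)

    def test_single_p_unchanged(self):
        from m7gmap.diffcleave import GLMFit

        z = stats.norm.isf(0.25)  # two-sided p = 0.5
        fits = [GLMFit(np.array([0, 0, 0, z]), np.ones(4), 0.1, True, 3)]
        results = wald_bh(fits, [FragmentKey("r", 0, 20)], [1.0])
        assert results[0].p_adjusted == pytest.approx(0.5, abs=1e-12)

    def test_nonconverged_excluded_from_family(self):
        from m7gmap.diffcleave import GLMFit

        good = GLMFit(np.array([0, 0, 0, 2.0]), np.ones(4), 0.1, True, 3)
        bad = GLMFit(np.array([0, 0, 0, 50.0]), np.full(4, np.nan), 0.1, False, 100)
        results = wald_bh([good, bad], [FragmentKey("r", 0, 20), FragmentKey("r", 1, 21)],
                          [1.0, 1.0])
        assert np.isfinite(results[0].p_adjusted)
        assert np.isnan(results[1].p_value)

    def test_empty_input(self):
        assert wald_bh([], [], []) == []


class TestRunInteraction:
    def _matrix(self, counts, design):
        df = frame(counts, design)
        return CountMatrix(df=df, design=design, pseudocount_applied=True, filtered=True)

    def test_scale_invariance(self):
        """Doubling one library's counts doubles its size factor (up to the
        geometric-mean rescaling) and leaves interaction estimates intact."""
        rng = np.random.default_rng(5)
        design = design_reps(3)
        mu = rng.integers(20, 200, size=40).astype(float)
        base = np.tile(mu[:, None], (1, len(design)))
        m0 = self._matrix(base.tolist(), design)
        scaled = base.copy()
        scaled[:, 0] *= 2.0
        m1 = self._matrix(scaled.tolist(), design)
        f0, f1 = size_factors(m0.df), size_factors(m1.df)
        ratio = (f1 / f0).to_numpy()
        assert ratio[0] / ratio[1] == pytest.approx(2.0, rel=1e-9)
        r0 = run_interaction_test(m0)
        r1 = run_interaction_test(m1)
        assert np.allclose(
            r0["log2fc_interaction"], r1["log2fc_interaction"], atol=1e-6
        )

    def test_null_z_symmetry(self):
        """Wald z on null NB data is symmetric about zero."""
        rng = np.random.default_rng(6)
        design = design_reps(3)
        n = 1000
        mu = rng.lognormal(np.log(60), 0.5, size=n)
        alpha = 0.1
        r = 1 / alpha
        counts = rng.negative_binomial(
            r, r / (r + mu[:, None]), size=(n, len(design))
        )
        m = self._matrix((counts + 1.0).tolist(), design)
        res = run_interaction_test(m)
        z = res.loc[res["converged"], "wald_z"].to_numpy()
        assert abs(stats.skew(z)) < 0.2
        assert abs(np.mean(z)) < 0.1
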
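"""Spline basis, gene-wise fits, variance moderation, moderated F tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import wallwise as w
from wallwise.containers import NormalizedMatrix
from wallwise.timecourse import D0_CAP, ModerationParams, _trigamma_inverse
from scipy.special import polygamma


def make_norm(log2_values: np.ndarray, design: pd.DataFrame) -> NormalizedMatrix:
    """Build a NormalizedMatrix whose log2 matrix equals ``log2_values``."""
    values = pd.DataFrame(2.0 ** log2_values - 1.0,
                          index=[f"g{i}" for i in range(log2_values.shape[0])],
                          columns=design.index)
    return NormalizedMatrix(values=values,
                            size_factors=pd.Series(1.0, index=design.index),
                            design=design)


def two_condition_design(weeks, n_reps=3, genotype="RTx430", drought="preflowering"):
    rows = []
    for cond in ("control", drought):
        for wk in weeks:
            for r in range(1, n_reps + 1):
                rows.append((f"{cond}_w{wk}_r{r}", genotype, "leaf", cond, wk, r))
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "tissue",
                                       "condition", "week", "replicate"]
                        ).set_index("sample_id")


class TestSplineBasis:
    def test_df1_is_single_increasing_column(self):
        basis = w.build_spline_basis(np.arange(1, 11), df=1)
        assert basis.matrix.shape == (10, 1)
        assert np.all(np.diff(basis.matrix[:, 0]) > 0)

    def test_full_rank_at_df4(self):
        basis = w.build_spline_basis(np.arange(1, 18), df=4)
        assert basis.matrix.shape == (17, 4)
        assert np.linalg.matrix_rank(basis.matrix) == 4

    def test_reproducible(self):
        a = w.build_spline_basis(np.arange(1, 18), df=4)
        b = w.build_spline_basis(np.arange(1, 18), df=4)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_df_must_be_below_distinct_times(self):
        with pytest.raises(ValueError, match="distinct"):
            w.build_spline_basis([1, 2, 3], df=3)

    def test_evaluate_matches_construction(self):
        times = np.arange(1, 18)
        basis = w.build_spline_basis(times, df=4)
        np.testing.assert_allclose(basis.evaluate(times), basis.matrix)


class TestGeneFits:
    def test_no_difference_gives_zero_L_and_equal_rss(self):
        weeks = np.arange(1, 11)
        design = two_condition_design(weeks)
        rng = np.random.default_rng(0)
        base = rng.normal(6, 1, size=(5, 1)) + np.zeros((5, len(design)))
        norm = make_norm(base, design)
        basis = w.build_spline_basis(weeks, df=3)
        fits = w.fit_gene_models(norm, basis, ("control", "preflowering"), "RTx430")
        np.testing.assert_allclose(fits.rss_null, fits.rss_full, atol=1e-18)
        np.testing.assert_allclose(fits.L.to_numpy(), 0.0, atol=1e-8)

    def test_constant_offset_recovered_exactly(self):
        weeks = np.arange(1, 11)
        design = two_condition_design(weeks)
        delta = 1.7
        y = np.full((3, len(design)), 5.0)
        y[:, (design["condition"] == "preflowering").to_numpy()] += delta
        norm = make_norm(y, design)
        basis = w.build_spline_basis(weeks, df=3)
        fits = w.fit_gene_models(norm, basis, ("control", "preflowering"), "RTx430")
        np.testing.assert_allclose(fits.L.to_numpy(), delta, atol=1e-8)

    def test_trajectory_in_model_span_recovered_noiselessly(self):
        """A planted drought trajectory lying in the spline span is
        recovered in L to numerical precision when noise is zero."""
        weeks = np.arange(1, 18)
        design = two_condition_design(weeks)
        basis = w.build_spline_basis(weeks, df=4)
        coef = np.array([0.4, -0.8, 1.1, 0.3])
        traj = basis.evaluate(weeks) @ coef + 0.9
        y = np.full((2, len(design)), 4.0)
        drought = (design["condition"] == "preflowering").to_numpy()
        week_pos = design["week"].to_numpy() - 1
        y[1, drought] += traj[week_pos[drought]]
        norm = make_norm(y, design)
        fits = w.fit_gene_models(norm, basis, ("control", "preflowering"), "RTx430")
        np.testing.assert_allclose(fits.L.iloc[1].to_numpy(), traj, atol=1e-8)
        np.testing.assert_allclose(fits.L.iloc[0].to_numpy(), 0.0, atol=1e-8)

    def test_missing_condition_rejected(self):
        design = two_condition_design(np.arange(1, 6))
        norm = make_norm(np.zeros((2, len(design))), design)
        basis = w.build_spline_basis(np.arange(1, 6), df=2)
        with pytest.raises(ValueError, match="absent"):
            w.fit_gene_models(norm, basis, ("control", "postflowering"), "RTx430")


class TestModeration:
    def test_d0_zero_leaves_variances_untouched(self):
        s2 = np.array([0.5, 1.0, 2.0])
        with pytest.warns(UserWarning, match="fewer than 10"):
            mod = w.moderate_variances(s2, residual_df=4)
        assert mod.d0 == 0.0
        np.testing.assert_array_equal(mod.s2_tilde, s2)

    def test_identical_variances_shrink_fully(self):
        s2 = np.full(200, 0.8)
        mod = w.moderate_variances(s2, residual_df=6)
        assert mod.d0 == D0_CAP
        np.testing.assert_allclose(mod.s2_tilde, mod.s0_squared, rtol=1e-4)

    def test_moderated_between_sample_and_prior(self):
        rng = np.random.default_rng(3)
        s2 = rng.chisquare(4, 500) / 4 * np.exp(rng.normal(0, 0.8, 500))
        mod = w.moderate_variances(s2, residual_df=4)
        lo = np.minimum(s2, mod.s0_squared) - 1e-12
        hi = np.maximum(s2, mod.s0_squared) + 1e-12
        assert np.all((mod.s2_tilde >= lo) & (mod.s2_tilde <= hi))

    def test_prior_recovered_from_scaled_chi_square(self):
        """s^2 ~ s0^2 chi^2_d / d (a single true variance): the estimated
        prior df is large and s0^2 lands within 5% of truth."""
        rng = np.random.default_rng(42)
        d, s0_true = 4, 0.6
        s2 = s0_true * rng.chisquare(d, 10_000) / d
        mod = w.moderate_variances(s2, residual_df=d)
        assert mod.d0 >= 100
        assert mod.s0_squared == pytest.approx(s0_true, rel=0.05)

    def test_trigamma_inverse_round_trip(self):
        for x in (0.1, 0.7, 3.0, 25.0):
            assert _trigamma_inverse(float(polygamma(1, x))) == pytest.approx(x, rel=1e-8)


class TestModeratedF:
    def test_null_gene_without_noise(self):
        weeks = np.arange(1, 9)
        design = two_condition_design(weeks, n_reps=2)
        norm = make_norm(np.full((12, len(design)), 3.0), design)
        basis = w.build_spline_basis(weeks, df=2)
        fits = w.fit_gene_models(norm, basis, ("control", "preflowering"), "RTx430")
        mod = ModerationParams(d0=0.0, s0_squared=1.0, s2_tilde=fits.s2,
                               residual_df=fits.df_resid)
        res = w.compute_de_stats(fits, mod)
        assert (res.table["F"] == 0).all()
        assert (res.table["p"] == 1).all()

    def test_matches_classical_partial_f_oracle(self):
        """With d0=0 the moderated F equals the textbook partial-F statistic
        computed through an independent numpy path, on a 3-gene example."""
        weeks = np.arange(1, 11)
        design = two_condition_design(weeks)
        rng = np.random.default_rng(8)
        y = rng.normal(5, 1, size=(3, len(design)))
        norm = make_norm(y, design)
        basis = w.build_spline_basis(weeks, df=3)
        fits = w.fit_gene_models(norm, basis, ("control", "preflowering"), "RTx430")
        mod = ModerationParams(d0=0.0, s0_squared=1.0, s2_tilde=fits.s2,
                               residual_df=fits.df_resid)
        res = w.compute_de_stats(fits, mod)

        # independent oracle: hat-matrix projections
        B = basis.evaluate(design["week"].to_numpy(dtype=float))
        ind = (design["condition"] == "preflowering").to_numpy(float)[:, None]
        X1 = np.hstack([np.ones_like(ind), B, ind, ind * B])
        X0 = np.hstack([np.ones_like(ind), B])
        for g in range(3):
            yy = norm.log2.iloc[g].to_numpy()
            rss = []
            for X in (X0, X1):
                H = X @ np.linalg.solve(X.T @ X, X.T)
                r = yy - H @ yy
                rss.append(r @ r)
            q = X1.shape[1] - X0.shape[1]
            dfres = len(yy) - X1.shape[1]
            f_oracle = ((rss[0] - rss[1]) / q) / (rss[1] / dfres)
            assert res.table["F"].iloc[g] == pytest.approx(f_oracle, rel=1e-8)
            assert res.table["p"].iloc[g] == pytest.approx(
                stats.f.sf(f_oracle, q, dfres), rel=1e-8)

    def test_f_increases_with_offset_magnitude(self):
        weeks = np.arange(1, 11)
        design = two_condition_design(weeks)
        drought = (design["condition"] == "preflowering").to_numpy()
        rng = np.random.default_rng(2)
        noise = rng.normal(0, 0.3, size=(1, len(design)))
        fs = []
        basis = w.build_spline_basis(weeks, df=3)
        for delta in (0.0, 0.5, 1.0, 2.0):
            y = 5.0 + noise.copy()
            y[0, drought] += delta
            norm = make_norm(y, design)
            fits = w.fit_gene_models(norm, basis, ("control", "preflowering"), "RTx430")
            mod = ModerationParams(d0=0.0, s0_squared=1.0, s2_tilde=fits.s2,
                                   residual_df=fits.df_resid)
            fs.append(float(w.compute_de_stats(fits, mod).table["F"].iloc[0]))
        assert fs == sorted(fs)
        assert fs[-1] > fs[0]

    def test_nesting_invariant_on_simulated_data(self, recovery_run):
        for res_key, res in recovery_run["results"].items():
            assert (res.table["F"].dropna() >= 0).all()


def test_genotype_contrast_exposed(small_sim):
    experiment, _, _ = small_sim
    norm = w.upper_quartile_normalize(w.filter_low_expressed(experiment, 1.0))
    from wallwise.timecourse import genotype_contrast
    results = genotype_contrast(norm, spline_df=3, conditions=("control",))
    table = results["control"].table
    assert set(table["condition"]) == {"control"}
    assert table["p"].between(0, 1).all()
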
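"""Step-selection functions: kernel, strata, conditional logit, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import ks_2samp

from nomadsel import (MoverConfig, build_kernel, classify_selection,
                      fit_clogit, generate_pseudo_steps, simulate_mover,
                      switching_summary)
from nomadsel.ssf import clogit_loglik, _clogit_design
from nomadsel.tracks import steps_for_track
from conftest import make_strata


def _steps_df(lengths, turns, lag=1):
    n = len(lengths)
    return pd.DataFrame({
        "individual_id": "a", "lag_days": lag, "run_id": 0,
        "displacement": lengths, "turn_angle": turns,
        "zero_length": np.asarray(lengths) == 0})


class TestKernel:
    def test_constant_steps_give_constant_draws(self, rng):
        k = build_kernel(_steps_df([7.0] * 40, [0.1] * 40), 1)
        ln, tn = k.sample(rng, 100)
        assert np.all(ln == 7.0) and np.all(tn == 0.1)

    def test_resampled_mean_matches_sample_mean(self, rng):
        lengths = rng.gamma(2.0, 1000.0, 500)
        turns = rng.vonmises(0.0, 1.0, 500)
        k = build_kernel(_steps_df(lengths, turns), 1)
        ln, _ = k.sample(rng, 10_000)
        assert ln.mean() == pytest.approx(lengths.mean(), rel=0.05)

    def test_lag_partition(self):
        df = pd.concat([_steps_df([1.0] * 40, [0.0] * 40, lag=1),
                        _steps_df([9.0] * 40, [0.0] * 40, lag=5)],
                       ignore_index=True)
        k5 = build_kernel(df, 5)
        assert np.all(k5.step_lengths == 9.0)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            build_kernel(_steps_df([1.0] * 10, [0.0] * 10), 1)

    def test_zero_length_steps_excluded_from_lengths(self):
        lengths = [0.0] * 5 + [3.0] * 35
        k = build_kernel(_steps_df(lengths, [0.0] * 40), 1)
        assert np.all(k.step_lengths > 0)


class TestPseudoSteps:
    def test_stratum_row_count(self, hetero_scenes, rng):
        track = simulate_mover(MoverConfig(n_days=60, rng_seed=3), hetero_scenes)
        steps = steps_for_track(track, 1)
        kernel = build_kernel(steps, 1)
        strata = generate_pseudo_steps(steps, kernel, 25, hetero_scenes, rng)
        assert strata.z.shape[1] == 26
        # first step of the run has no previous heading
        assert strata.n_strata <= len(steps) - 1

    def test_constant_landscape_gives_identical_covariates(self, flat_scene, rng):
        xy = np.cumsum(np.ones((40, 2)) * 200, axis=0)
        from conftest import daily_track_df
        from nomadsel.tracks import Track
        steps = steps_for_track(Track("a", daily_track_df(xy)), 1)
        kernel = build_kernel(steps, 1)
        strata = generate_pseudo_steps(steps, kernel, 10, [flat_scene], rng)
        assert strata.n_strata > 0
        assert np.all(strata.z == 0.4)

    def test_pseudo_displacements_match_kernel_distribution(self, hetero_scenes, rng):
        """Two-sample KS between drawn pseudo-step lengths and the kernel."""
        track = simulate_mover(MoverConfig(n_days=400, rng_seed=4), hetero_scenes)
        steps = steps_for_track(track, 1)
        kernel = build_kernel(steps, 1)
        # record pseudo endpoint displacements via their geometry
        g = steps.sort_values(["run_id", "start_time"]).reset_index(drop=True)
        drawn = kernel.sample(rng, 10_000)[0]
        assert ks_2samp(drawn, kernel.step_lengths).pvalue > 0.01


class TestClogit:
    def test_uninformative_stratum_loglik_is_log_choices(self):
        z = np.full((1, 6), 0.3)  # K = 5, all covariates equal
        ll = clogit_loglik(np.array([2.0]), _clogit_design(z, "linear"))
        assert ll == pytest.approx(-np.log(6))
        ll0 = clogit_loglik(np.array([0.0]), _clogit_design(z, "linear"))
        assert ll0 == pytest.approx(-np.log(6))

    def test_known_softmax_probability(self):
        """eta_obs = log 3 with two zero pseudo rows: P(observed) = 3/5."""
        z = np.array([[np.log(3.0), 0.0, 0.0]])
        ll = clogit_loglik(np.array([1.0]), _clogit_design(z, "linear"))
        assert np.exp(ll) == pytest.approx(3.0 / 5.0)

    def test_matches_bruteforce_maximization(self, rng):
        """<= 5 strata, K <= 5: Newton equals scipy maximization to 1e-6."""
        z = rng.uniform(0, 1, (5, 5))
        strata = make_strata(z)
        for shape, p in [("linear", 1), ("quadratic", 2)]:
            fit = fit_clogit(strata, shape, min_strata=1)
            Xs = _clogit_design(z, shape)
            ref = minimize(lambda b: -clogit_loglik(b, Xs), np.zeros(p),
                           method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12,
                                    "maxiter": 20_000})
            got = np.array(list(fit.beta.values()))
            np.testing.assert_allclose(got, ref.x, atol=1e-6)
            assert fit.loglik == pytest.approx(-ref.fun, abs=1e-9)

    def test_matches_statsmodels_conditional_logit(self, rng):
        """Independent oracle: statsmodels ConditionalLogit on long format."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        z = rng.uniform(0, 1, (40, 11))
        z[:, 0] += 0.3 * rng.random(40)  # tilt the observed column
        strata = make_strata(z)
        fit = fit_clogit(strata, "quadratic")
        y = np.zeros(z.size)
        y[::11] = 0  # placeholder; build long-format arrays below
        yl = np.tile(np.r_[1, np.zeros(10)], 40)
        groups = np.repeat(np.arange(40), 11)
        X = np.column_stack([z.ravel(), z.ravel() ** 2])
        sm_fit = ConditionalLogit(yl, X, groups=groups).fit(
            method="newton", tol=1e-10, disp=False)
        np.testing.assert_allclose([fit.beta["z"], fit.beta["z2"]],
                                   sm_fit.params, atol=1e-5)
        np.testing.assert_allclose([fit.se["z"], fit.se["z2"]],
                                   sm_fit.bse, atol=1e-4)

    def test_stratum_constant_shift_invariance(self, rng):
        """Adding a per-stratum constant to the covariate design leaves the
        conditional likelihood unchanged."""
        z = rng.uniform(0, 1, (25, 6))
        beta = np.array([1.7])
        Xs = _clogit_design(z, "linear")
        shifted = Xs + rng.normal(0, 5, (25, 1, 1))
        assert clogit_loglik(beta, shifted) == pytest.approx(
            clogit_loglik(beta, Xs), abs=1e-8)
        centered = Xs - Xs.mean(axis=1, keepdims=True)
        assert clogit_loglik(beta, centered) == pytest.approx(
            clogit_loglik(beta, Xs), abs=1e-8)

    def test_min_strata_enforced(self, rng):
        strata = make_strata(rng.uniform(0, 1, (10, 4)))
        with pytest.raises(ValueError, match="10 strata"):
            fit_clogit(strata, "linear")

    def test_constant_covariate_flagged_not_identifiable(self):
        strata = make_strata(np.full((30, 5), 0.2))
        fit = fit_clogit(strata, "linear")
        assert not fit.converged
        assert fit.loglik == pytest.approx(-30 * np.log(5))


class TestClassification:
    @staticmethod
    def _strata_from_truth(rng, b1, b2, n=200, K=50):
        z = rng.uniform(0, 1, (n, K + 1))
        eta = b1 * z + b2 * z**2
        w = np.exp(eta - eta.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        for s in range(n):  # move the selected column into slot 0
            j = rng.choice(K + 1, p=w[s])
            z[s, [0, j]] = z[s, [j, 0]]
        return make_strata(z)

    def test_quadratic_truth_classified_intermediate_with_peak(self, rng):
        strata = self._strata_from_truth(rng, 13.0, -14.0)
        cls = classify_selection(fit_clogit(strata, "linear"),
                                 fit_clogit(strata, "quadratic"))
        assert cls.category == "intermediate"
        assert cls.peak_covariate == pytest.approx(13 / 28, abs=0.05)

    def test_positive_linear_truth_classified_max(self):
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(3000 + rep)
            strata = self._strata_from_truth(rng, 8.0, 0.0, n=100, K=25)
            cls = classify_selection(fit_clogit(strata, "linear"),
                                     fit_clogit(strata, "quadratic"))
            hits += cls.category == "max"
        assert hits > 25

    def test_negative_linear_truth_classified_min(self, rng):
        strata = self._strata_from_truth(rng, -8.0, 0.0)
        cls = classify_selection(fit_clogit(strata, "linear"),
                                 fit_clogit(strata, "quadratic"))
        assert cls.category == "min"

    def test_upward_parabola_classified_extreme(self, rng):
        strata = self._strata_from_truth(rng, -10.0, 10.0)
        cls = classify_selection(fit_clogit(strata, "linear"),
                                 fit_clogit(strata, "quadratic"))
        assert cls.category == "extreme"

    def test_none_iff_not_significant(self, rng):
        strata = self._strata_from_truth(rng, 0.0, 0.0, n=50, K=10)
        cls = classify_selection(fit_clogit(strata, "linear"),
                                 fit_clogit(strata, "quadratic"))
        assert (cls.category == "none") == (not cls.significant)


class TestSwitching:
    @staticmethod
    def _cls(rows):
        return pd.DataFrame(rows, columns=["individual_id", "year", "category"])

    def test_identical_categories_is_no_switch(self):
        t, frac = switching_summary(self._cls([("a", 2015, "max"),
                                               ("a", 2016, "max")]))
        assert not t["switched"].iloc[0] and frac == 0.0

    def test_change_to_none_counts_as_switch(self):
        t, frac = switching_summary(self._cls([("a", 2015, "max"),
                                               ("a", 2016, "none")]))
        assert t["switched"].iloc[0] and frac == 1.0

    def test_population_fraction_arithmetic(self):
        rows = []
        for i in range(16):
            cat = "min" if i < 6 else "max"
            rows += [(f"g{i}", 2015, "max"), (f"g{i}", 2016, cat)]
        rows.append(("single-year", 2015, "max"))  # not assessable
        t, frac = switching_summary(self._cls(rows))
        assert len(t) == 16
        assert frac == pytest.approx(6 / 16)
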
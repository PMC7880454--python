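"""Weighted logistic GLMM, simplification ladder, AIC shape comparison."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from nomadsel.glmm import RandomTerm, fit_glmm
from nomadsel.rsf import (ModelSpec, compare_shapes, fit_weighted_glmm,
                          multiplier_stability, simplification_ladder)


def simulated_table(rng, b1, b2, n_avail=10_000, n_used=1_000, z_max=0.8,
                    n_individuals=1, n_scenes=1, ind_sd=0.0):
    """Use-availability rows from known truth: availability Uniform(0, z_max),
    used covariates sampled ∝ exp(b1 z + b2 z^2) by rejection."""
    grid = np.linspace(0, z_max, 512)
    M = np.exp(np.max(b1 * grid + b2 * grid**2))
    used_z = []
    # individual intercepts act on each individual's rate of use: individuals
    # with a higher intercept contribute more used points per unit availability
    offsets = rng.normal(0.0, ind_sd, n_individuals)
    p_ind = np.exp(offsets) / np.exp(offsets).sum()
    used_ind = rng.choice(n_individuals, size=n_used, p=p_ind)
    while len(used_z) < n_used:
        cand = rng.uniform(0, z_max, 4 * n_used)
        keep = rng.random(len(cand)) < np.exp(b1 * cand + b2 * cand**2) / M
        used_z.extend(cand[keep][:n_used - len(used_z)])
    z = np.concatenate([used_z, rng.uniform(0, z_max, n_avail)])
    used = np.concatenate([np.ones(n_used), np.zeros(n_avail)])
    ind = np.concatenate([used_ind, rng.integers(0, n_individuals, n_avail)])
    return pd.DataFrame({
        "covariate": z, "used": used,
        "individual_id": [f"i{k}" for k in ind],
        "year": 2015,
        "scene_id": [f"s{k}" for k in rng.integers(0, n_scenes, len(z))],
    })


class TestGLMMEngine:
    def test_no_random_terms_matches_plain_weighted_logistic(self, rng):
        """GLMM with empty random structure equals statsmodels GLM to 1e-6."""
        tbl = simulated_table(rng, 3.0, -2.0, n_avail=4000, n_used=400)
        fit = fit_weighted_glmm(tbl, ModelSpec("quadratic", random_terms=()))
        z = tbl["covariate"].to_numpy()
        X = np.column_stack([np.ones(len(z)), z, z**2])
        w = np.where(tbl["used"] == 1, 1.0, 1000.0)
        glm = sm.GLM(tbl["used"].to_numpy(float), X,
                     family=sm.families.Binomial(), freq_weights=w).fit()
        got = np.array([fit.beta["intercept"], fit.beta["z"], fit.beta["z2"]])
        np.testing.assert_allclose(got, glm.params, atol=1e-6)
        ses = np.array([fit.se["intercept"], fit.se["z"], fit.se["z2"]])
        np.testing.assert_allclose(ses, glm.bse, atol=1e-6)

    def test_aic_identity_holds_exactly(self, rng):
        tbl = simulated_table(rng, 2.0, 0.0, n_avail=2000, n_used=200,
                              n_individuals=4, n_scenes=3)
        for spec in [ModelSpec("linear", random_terms=()),
                     ModelSpec("quadratic",
                               random_terms=("intercept_individual",
                                             "intercept_scene"))]:
            fit = fit_weighted_glmm(tbl, spec)
            k = len(fit.beta) + len(fit.variance_components)
            assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k, abs=1e-9)

    def test_random_intercept_fit_matches_lme4_laplace(self, rng):
        """Independent oracle: R glmer (Laplace) on the same weighted data."""
        n = 2000
        z = rng.uniform(0, 1, n)
        g = rng.integers(0, 10, n)
        u = rng.normal(0, 0.8, 10)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1 + 2 * z + u[g])))).astype(int)
        w = np.where(y == 1, 1, 5)
        res = fit_glmm(np.column_stack([np.ones(n), z]), y.astype(float),
                       w.astype(float), [RandomTerm("ri", g)])
        with tempfile.TemporaryDirectory() as td:
            csv = Path(td) / "d.csv"
            pd.DataFrame({"y": y, "z": z, "g": g, "w": w}).to_csv(csv, index=False)
            r = subprocess.run(
                ["Rscript", "-e",
                 f"suppressMessages(library(lme4));"
                 f"d<-read.csv('{csv}');"
                 f"m<-glmer(y~z+(1|g),data=d,family=binomial,weights=w);"
                 f"cat(fixef(m),sqrt(unlist(VarCorr(m))),as.numeric(logLik(m)))"],
                capture_output=True, text=True, timeout=300)
        assert r.returncode == 0, r.stderr
        b0, b1, sd, ll = map(float, r.stdout.split())
        assert res.beta[0] == pytest.approx(b0, abs=0.02)
        assert res.beta[1] == pytest.approx(b1, abs=0.02)
        assert res.sigma[0] == pytest.approx(sd, abs=0.01)
        assert res.loglik == pytest.approx(ll, abs=0.05)

    def test_recovers_known_quadratic_selection(self, rng):
        tbl = simulated_table(rng, 13.0, -14.0, n_avail=50_000, n_used=2_500)
        fit = fit_weighted_glmm(tbl, ModelSpec("quadratic", random_terms=()))
        assert abs(fit.beta["z"] - 13.0) < 1.96 * fit.se["z"]
        assert abs(fit.beta["z2"] + 14.0) < 1.96 * fit.se["z2"]


class TestLadder:
    def test_non_singular_fit_returned_unchanged(self, rng):
        tbl = simulated_table(rng, 2.0, 0.0, n_avail=5000, n_used=500,
                              n_individuals=8, ind_sd=1.5)
        fit = simplification_ladder(
            tbl, ModelSpec("linear", random_terms=("intercept_individual",)))
        assert fit.audit == []
        assert "intercept_individual" in fit.variance_components

    def test_structurally_zero_component_removed_once(self, rng):
        """Zero between-year heterogeneity: year intercept is dropped, the
        genuinely heterogeneous individual intercept survives."""
        tbl = simulated_table(rng, 2.0, 0.0, n_avail=8000, n_used=800,
                              n_individuals=8, ind_sd=1.5)
        fit = simplification_ladder(
            tbl, ModelSpec("linear", random_terms=("intercept_individual",
                                                   "intercept_year")))
        assert len(fit.audit) == 1 and "intercept_year" in fit.audit[0]
        assert list(fit.variance_components) == ["intercept_individual"]
        assert not fit.singular

    def test_all_zero_components_reach_fixed_effects_floor(self, rng):
        tbl = simulated_table(rng, 2.0, 0.0, n_avail=4000, n_used=400)
        fit = simplification_ladder(
            tbl, ModelSpec("linear", random_terms=("intercept_individual",
                                                   "intercept_year")))
        assert fit.variance_components == {}
        assert len(fit.audit) == 2

    def test_zero_heterogeneity_flags_singular_slope(self, rng):
        """No between-individual slope variance: slope term goes singular in
        most replicates (constructed-zero variance component)."""
        hits = 0
        for rep in range(10):
            r = np.random.default_rng(900 + rep)
            tbl = simulated_table(r, 2.0, 0.0, n_avail=3000, n_used=300,
                                  n_individuals=6)
            fit = fit_weighted_glmm(
                tbl, ModelSpec("linear", random_terms=("slope_individual",)))
            hits += "slope_individual" in fit.singular_terms
        assert hits >= 8


class TestCompareShapes:
    @staticmethod
    def _fit(aic, n_obs=100, k=3):
        from nomadsel.rsf import FitResult
        ll = (2 * k - aic) / 2
        return FitResult("m", {"z": 0.0}, {}, {}, {}, ll, aic, n_obs, True, False)

    def test_equal_aic_gives_half_half_weights(self):
        comp = compare_shapes(self._fit(100.0), self._fit(100.0))
        np.testing.assert_allclose(comp["weight"], [0.5, 0.5])

    def test_large_delta_aic_gives_negligible_weight(self):
        """A 77.1 AIC deficit leaves the runner-up under 0.001 weight."""
        comp = compare_shapes(self._fit(73592.0), self._fit(73514.9))
        runner = comp[comp["hypothesis"] == "linear"].iloc[0]
        assert runner["delta_aic"] == pytest.approx(77.1)
        assert runner["weight"] < 0.001

    def test_weights_match_hand_computation(self):
        comp = compare_shapes(self._fit(102.0), self._fit(100.0))
        raw = np.array([np.exp(0.0), np.exp(-1.0)])
        assert comp.iloc[0]["weight"] == pytest.approx(raw[0] / raw.sum())
        assert comp.iloc[1]["weight"] == pytest.approx(raw[1] / raw.sum())

    def test_differing_row_sets_refused(self):
        with pytest.raises(ValueError, match="not comparable"):
            compare_shapes(self._fit(1.0, n_obs=10), self._fit(1.0, n_obs=11))


class TestMultiplierStability:
    def test_coefficients_stabilize_with_more_pseudo_absences(self, rng):
        used = simulated_table(rng, 5.0, 0.0, n_avail=0, n_used=5000)

        def builder(m):
            avail = pd.DataFrame({
                "covariate": np.random.default_rng(m).uniform(0, 0.8, 5000 * m),
                "used": 0.0, "individual_id": "i0", "year": 2015,
                "scene_id": "s0"})
            return pd.concat([used, avail], ignore_index=True)

        out = multiplier_stability(builder, [10, 20], ModelSpec("linear",
                                                                random_terms=()))
        assert out.attrs["max_rel_delta"] < 0.05

    def test_single_multiplier_trajectory(self, rng):
        tbl = simulated_table(rng, 2.0, 0.0, n_avail=2000, n_used=200)
        out = multiplier_stability(lambda m: tbl, [5],
                                   ModelSpec("linear", random_terms=()))
        assert len(out) == 1
        assert np.isnan(out.attrs["max_rel_delta"])
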
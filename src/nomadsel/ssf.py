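"""Individual-level step-selection functions.

Each observed step is matched with K pseudo-steps the animal could have
taken instead: lengths and turns resampled independently from the pooled
empirical step-length and turn-angle samples at the same lag, applied to
the previous step's heading from the step's start point.  The observed
and pseudo endpoints' covariates form one stratum; conditional logistic
regression maximizes the matched likelihood

    prod_s  exp(eta_obs) / sum_j exp(eta_j),    eta = b1 z (+ b2 z^2),

by Newton iteration on the exact gradient and observed information.

Per entity (individual or individual-year) with at least 20 strata, a
linear and a quadratic model are fitted; significance is a likelihood-
ratio test against the null conditional likelihood at alpha = 0.05, AIC
picks the shape among significant models, and the winning shape is
classified as selection for the maximum, minimum, intermediate (downward
parabola, with its peak covariate value) or extreme (upward parabola)
values — or "none".  Entities observed in several years yield a
switching summary: any change of category across years counts as a
strategy switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .rsf import FitResult
from .scenes import RasterScene, scene_for_date
from .tracks import _wrap_angle

logger = logging.getLogger(__name__)

K_GRID = (25, 50, 100, 200, 400)
MIN_STRATA = 20
MIN_KERNEL_STEPS = 30


@dataclass
class EmpiricalStepKernel:
    """Pooled empirical step-length / turn-angle samples at one lag."""

    lag_days: int
    step_lengths: np.ndarray
    turn_angles: np.ndarray

    def sample(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Independent resampling (with replacement) of lengths and turns."""
        return (rng.choice(self.step_lengths, size=n, replace=True),
                rng.choice(self.turn_angles, size=n, replace=True))


def build_kernel(steps: pd.DataFrame, lag_days: int,
                 min_steps: int = MIN_KERNEL_STEPS) -> EmpiricalStepKernel:
    """Pool steps across individuals into the lag's empirical kernel.

    Zero-length steps carry no heading and are excluded; turn angles come
    from steps whose turn is defined.
    """
    g = steps[steps["lag_days"] == lag_days]
    lengths = g.loc[~g["zero_length"], "displacement"].to_numpy(float)
    turns = g["turn_angle"].to_numpy(float)
    turns = turns[np.isfinite(turns)]
    if len(lengths) < min_steps or len(turns) < min_steps:
        raise ValueError(
            f"too few steps at lag {lag_days}: {len(lengths)} lengths, "
            f"{len(turns)} turns (need >= {min_steps})")
    return EmpiricalStepKernel(lag_days, lengths, turns)


@dataclass
class StepStratumSet:
    """Matched strata for one entity at one lag: z[:, 0] is observed."""

    z: np.ndarray                 # (n_strata, K + 1)
    K: int
    individual_id: str
    season: str
    lag_days: int
    year: int | None = None
    n_dropped: int = 0

    @property
    def n_strata(self) -> int:
        return self.z.shape[0]


def generate_pseudo_steps(
    steps: pd.DataFrame,
    kernel: EmpiricalStepKernel,
    K: int,
    scenes: Sequence[RasterScene],
    rng: np.random.Generator,
    individual_id: str = "",
    season: str = "",
    year: int | None = None,
    max_redraw: int = 10,
) -> StepStratumSet:
    """Build matched strata from observed steps.

    Pseudo endpoints are placed at (resampled length, previous observed
    heading + resampled turn) from the step's start point and read the
    covariate from the scene matching the step's end date.  Steps without
    a defined previous heading are skipped; strata whose observed
    covariate is missing, or that cannot fill K valid pseudo endpoints
    within ``max_redraw`` redraw rounds, are dropped whole.
    """
    g = steps.sort_values(["run_id", "start_time"]).reset_index(drop=True)
    strata, n_dropped = [], 0
    for run_id, run in g.groupby("run_id", sort=True):
        run = run.reset_index(drop=True)
        headings = run["heading"].to_numpy(float)
        for i in range(1, len(run)):
            prev_heading = headings[i - 1]
            if not np.isfinite(prev_heading):
                continue  # no defined heading (zero-length predecessor)
            row = run.iloc[i]
            date = pd.Timestamp(row["end_time"]).date()
            try:
                scene = scene_for_date(scenes, date)
            except ValueError:
                n_dropped += 1
                continue
            z_obs = scene.value_at(float(row["x1"]), float(row["y1"]))
            if not np.isfinite(z_obs):
                n_dropped += 1
                continue
            x0, y0 = float(row["x0"]), float(row["y0"])
            zk = np.full(K, np.nan)
            need = np.arange(K)
            for _ in range(max_redraw + 1):
                if need.size == 0:
                    break
                ln, tn = kernel.sample(rng, need.size)
                h = prev_heading + tn
                zi = scene.value_at(x0 + ln * np.cos(h), y0 + ln * np.sin(h))
                zk[need] = zi
                need = need[~np.isfinite(np.atleast_1d(zi))]
            if need.size:
                n_dropped += 1  # stratum dropped whole, never padded asymmetrically
                continue
            strata.append(np.concatenate([[z_obs], zk]))
    if n_dropped:
        logger.info("%s %s lag %d: dropped %d stratum/strata (nodata or no heading)",
                    individual_id, season, kernel.lag_days, n_dropped)
    z = np.asarray(strata) if strata else np.empty((0, K + 1))
    return StepStratumSet(z=z, K=K, individual_id=individual_id,
                          season=season, lag_days=kernel.lag_days,
                          year=year, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Conditional logistic regression


def _clogit_design(z: np.ndarray, shape: str) -> np.ndarray:
    if shape == "linear":
        return z[..., None]
    if shape == "quadratic":
        return np.stack([z, z**2], axis=-1)
    raise ValueError(f"shape must be linear or quadratic, got {shape}")


def clogit_loglik(beta: np.ndarray, Xs: np.ndarray) -> float:
    """Exact conditional log-likelihood; Xs is (strata, K+1, p), obs at 0."""
    eta = Xs @ beta
    m = eta.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(eta - m).sum(axis=1))
    return float(np.sum(eta[:, 0] - lse))


def fit_clogit(strata: StepStratumSet, shape: str = "quadratic",
               min_strata: int = MIN_STRATA, max_iter: int = 50,
               tol: float = 1e-8) -> FitResult:
    """Newton fit of the matched conditional likelihood.

    Refuses entities with fewer than ``min_strata`` strata.  A covariate
    constant within every stratum is non-identifiable and returns a
    flagged (non-converged) null fit.
    """
    if strata.n_strata < min_strata:
        raise ValueError(
            f"{strata.individual_id or 'entity'}: {strata.n_strata} strata "
            f"< required {min_strata}")
    Xs = _clogit_design(strata.z, shape)
    # stratum-centering: the conditional likelihood is invariant and the
    # numerics are better behaved
    Xc = Xs - Xs.mean(axis=1, keepdims=True)
    p = Xc.shape[-1]
    names = ["z", "z2"][:p]
    null_ll = -float(np.sum(np.log(np.full(strata.n_strata, strata.z.shape[1]))))
    if np.allclose(Xc, 0.0):
        logger.warning("%s: covariate constant within all strata; not identifiable",
                       strata.individual_id)
        return FitResult(
            model_id=f"ssf_{shape}", beta=dict.fromkeys(names, 0.0),
            se=dict.fromkeys(names, np.inf), p_values=dict.fromkeys(names, 1.0),
            variance_components={}, loglik=null_ll, aic=-2 * null_ll + 2 * p,
            n_obs=strata.n_strata, converged=False, singular=False,
            null_loglik=null_ll)
    beta = np.zeros(p)
    ll = clogit_loglik(beta, Xc)
    converged = False
    H = np.eye(p)
    for _ in range(max_iter):
        eta = Xc @ beta
        w = np.exp(eta - eta.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)              # (S, K+1)
        xbar = np.einsum("sk,skp->sp", w, Xc)
        grad = (Xc[:, 0, :] - xbar).sum(axis=0)
        D = Xc - xbar[:, None, :]
        H = np.einsum("sk,skp,skq->pq", w, D, D)       # observed information
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            ll_new = clogit_loglik(beta + t * step, Xc)
            if ll_new >= ll - 1e-14:
                break
            t *= 0.5
        beta = beta + t * step
        ll = ll_new
        if np.linalg.norm(grad) < tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    from .rsf import _wald_p

    return FitResult(
        model_id=f"ssf_{shape}",
        beta=dict(zip(names, beta.tolist())),
        se=dict(zip(names, se.tolist())),
        p_values=dict(zip(names, _wald_p(beta, se).tolist())),
        variance_components={}, loglik=ll, aic=-2 * ll + 2 * p,
        n_obs=strata.n_strata, converged=converged, singular=False,
        null_loglik=null_ll)


# ---------------------------------------------------------------------------
# Classification and switching


@dataclass
class SelectionClassification:
    category: str                 # max | min | intermediate | extreme | none
    top_shape: str                # linear | quadratic | none
    significant: bool
    peak_covariate: float | None = None
    p_linear: float | None = None
    p_quadratic: float | None = None


def _lrt_p(fit: FitResult, df: int) -> float:
    if fit.null_loglik is None:
        raise ValueError("fit lacks a null log-likelihood")
    stat = max(0.0, 2.0 * (fit.loglik - fit.null_loglik))
    return float(chi2.sf(stat, df))


def classify_selection(fit_linear: FitResult | None,
                       fit_quadratic: FitResult | None,
                       alpha: float = 0.05) -> SelectionClassification:
    """Gate on likelihood-ratio significance, pick the shape by AIC.

    The linear model is tested on 1 df, the quadratic jointly on 2 df.
    If neither is significant the category is "none"; otherwise the
    minimum-AIC significant model determines the category: linear slope
    sign gives max/min, quadratic curvature sign gives intermediate
    (downward parabola; peak at -b1/(2 b2)) or extreme (upward parabola).
    """
    candidates = []
    p_lin = p_quad = None
    if fit_linear is not None and fit_linear.converged:
        p_lin = _lrt_p(fit_linear, 1)
        if p_lin <= alpha:
            candidates.append(("linear", fit_linear))
    if fit_quadratic is not None and fit_quadratic.converged:
        p_quad = _lrt_p(fit_quadratic, 2)
        if p_quad <= alpha:
            candidates.append(("quadratic", fit_quadratic))
    if not candidates:
        return SelectionClassification("none", "none", False,
                                       p_linear=p_lin, p_quadratic=p_quad)
    top_shape, top = min(candidates, key=lambda c: c[1].aic)
    if top_shape == "quadratic":
        b1, b2 = top.beta["z"], top.beta["z2"]
        if b2 < 0:
            return SelectionClassification(
                "intermediate", "quadratic", True,
                peak_covariate=-b1 / (2.0 * b2), p_linear=p_lin, p_quadratic=p_quad)
        if b2 > 0:
            return SelectionClassification("extreme", "quadratic", True,
                                           p_linear=p_lin, p_quadratic=p_quad)
        logger.info("quadratic top model with exactly zero curvature; "
                    "treating as linear-shaped")
        b1_eff = b1
    else:
        b1_eff = top.beta["z"]
    return SelectionClassification("max" if b1_eff > 0 else "min",
                                   top_shape, True,
                                   p_linear=p_lin, p_quadratic=p_quad)


def switching_summary(classifications: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-individual strategy-switch flags across years.

    Input needs columns individual_id, year, category.  Individuals with
    at least two classified years are assessable; a switch is any change
    of category across years (including to or from "none").  Returns the
    per-individual table and the population switch fraction.
    """
    rows = []
    for ind, g in classifications.groupby("individual_id", sort=True):
        years = g["year"].nunique()
        if years < 2:
            continue
        rows.append({"individual_id": ind, "n_years": years,
                     "switched": g["category"].nunique() > 1})
    table = pd.DataFrame(rows, columns=["individual_id", "n_years", "switched"])
    fraction = float(table["switched"].mean()) if len(table) else float("nan")
    return table, fraction
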
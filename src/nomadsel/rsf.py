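"""Population-level resource selection functions.

The RSF contrasts used daily locations (response 1, weight 1) against
pseudo-absences (response 0, large weight, default 1000) in a weighted
logistic mixed model.  Two fixed-effect shapes encode the competing
hypotheses about selection: a linear term in the covariate z (selection
for the maximum or minimum available value) and a quadratic z + z^2
(selection for intermediate values — downward parabola — or for both
extremes — upward parabola).  Candidate random structure: intercept and
slope by individual, intercepts by year and by covariate scene.

Over-complex random structures routinely go singular on these designs; the
simplification ladder refits after removing the smallest singular variance
component until the fit is non-singular or only fixed effects remain.
Shapes are compared by AIC with Akaike weights.

Covariates enter on their natural scale (greenness in [-0.2, 1], snow
fraction in [0, 1]) so peak-selection formulas apply directly to the
reported coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .glmm import GLMMResult, RandomTerm, fit_glmm

logger = logging.getLogger(__name__)

RANDOM_TERMS = ("intercept_individual", "slope_individual",
                "intercept_year", "intercept_scene")


@dataclass
class ModelSpec:
    shape: str = "quadratic"  # "linear" | "quadratic"
    random_terms: tuple[str, ...] = RANDOM_TERMS
    weight_available: float = 1000.0

    def __post_init__(self) -> None:
        if self.shape not in ("linear", "quadratic"):
            raise ValueError(f"shape must be linear or quadratic, got {self.shape}")
        bad = set(self.random_terms) - set(RANDOM_TERMS)
        if bad:
            raise ValueError(f"unknown random terms: {sorted(bad)}")


@dataclass
class FitResult:
    """Coefficients and fit summary for RSF (GLMM) and SSF (clogit) models."""

    model_id: str
    beta: dict[str, float]
    se: dict[str, float]
    p_values: dict[str, float]
    variance_components: dict[str, float]  # per-term variances (SD^2)
    loglik: float
    aic: float
    n_obs: int
    converged: bool
    singular: bool
    singular_terms: list[str] = field(default_factory=list)
    marginal_r2: float | None = None
    conditional_r2: float | None = None
    null_loglik: float | None = None
    audit: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id, "beta": self.beta, "se": self.se,
            "p_values": self.p_values,
            "variance_components": self.variance_components,
            "loglik": self.loglik, "aic": self.aic, "n_obs": self.n_obs,
            "converged": self.converged, "singular": self.singular,
            "singular_terms": self.singular_terms,
            "marginal_r2": self.marginal_r2,
            "conditional_r2": self.conditional_r2,
            "null_loglik": self.null_loglik, "audit": self.audit,
        }


def _wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    return 2.0 * norm.sf(np.abs(z))


def _design(table: pd.DataFrame, spec: ModelSpec):
    z = table["covariate"].to_numpy(float)
    names = ["intercept", "z"]
    cols = [np.ones(len(z)), z]
    if spec.shape == "quadratic":
        names.append("z2")
        cols.append(z**2)
    X = np.column_stack(cols)
    terms = []
    for name in spec.random_terms:
        if name == "intercept_individual":
            terms.append(RandomTerm(name, table["individual_id"].to_numpy()))
        elif name == "slope_individual":
            terms.append(RandomTerm(name, table["individual_id"].to_numpy(), z))
        elif name == "intercept_year":
            terms.append(RandomTerm(name, table["year"].to_numpy()))
        elif name == "intercept_scene":
            terms.append(RandomTerm(name, table["scene_id"].to_numpy()))
    return X, names, terms, z


def fit_weighted_glmm(table: pd.DataFrame, spec: ModelSpec,
                      model_id: str = "rsf") -> FitResult:
    """Fit the weighted logistic (mixed) model for one season's table."""
    if table.empty:
        raise ValueError("empty use-availability table")
    X, names, terms, z = _design(table, spec)
    y = table["used"].to_numpy(float)
    w = np.where(y == 1, 1.0, spec.weight_available)
    res = fit_glmm(X, y, w, terms)
    if not res.converged:
        logger.warning("%s: fit did not converge", model_id)
    p = _wald_p(res.beta, res.se)
    # variance-partition R2: fixed vs fixed+random over total latent variance
    var_f = float(np.var(X @ res.beta))
    var_r = 0.0
    for t, s in zip(terms, res.sigma):
        scale = 1.0 if t.values is None else float(np.mean(np.asarray(t.values) ** 2))
        var_r += s**2 * scale
    total = var_f + var_r + np.pi**2 / 3.0
    return FitResult(
        model_id=model_id,
        beta=dict(zip(names, res.beta.tolist())),
        se=dict(zip(names, res.se.tolist())),
        p_values=dict(zip(names, p.tolist())),
        variance_components={t.name: float(s**2) for t, s in zip(terms, res.sigma)},
        loglik=res.loglik, aic=res.aic, n_obs=res.n_obs,
        converged=res.converged, singular=res.singular,
        singular_terms=list(res.singular_terms),
        marginal_r2=var_f / total, conditional_r2=(var_f + var_r) / total,
    )


def simplification_ladder(table: pd.DataFrame, spec: ModelSpec,
                          model_id: str = "rsf") -> FitResult:
    """Refit after dropping singular variance components until clean.

    At each rung the singular term with the smallest estimated variance is
    removed; the fixed-effects-only model is the floor.  The audit trail
    records every removal.
    """
    audit: list[str] = []
    current = spec
    while True:
        fit = fit_weighted_glmm(table, current, model_id)
        if not fit.singular or not current.random_terms:
            fit.audit = audit
            return fit
        drop = min(fit.singular_terms, key=lambda t: fit.variance_components[t])
        audit.append(
            f"removed {drop} (sd={np.sqrt(fit.variance_components[drop]):.2e})")
        logger.info("%s: singular fit; %s", model_id, audit[-1])
        current = replace(current,
                          random_terms=tuple(t for t in current.random_terms if t != drop))


def compare_shapes(fit_linear: FitResult, fit_quadratic: FitResult) -> pd.DataFrame:
    """AIC comparison of the two selection-shape hypotheses.

    Returns one row per model with df, AIC, ΔAIC and Akaike weight
    (exp(-Δ/2) normalized).  Fits must be on the identical row set.
    """
    if fit_linear.n_obs != fit_quadratic.n_obs:
        raise ValueError(
            f"fits are not comparable: n_obs {fit_linear.n_obs} vs {fit_quadratic.n_obs}")
    rows = []
    for name, fit in [("linear", fit_linear), ("quadratic", fit_quadratic)]:
        rows.append({"hypothesis": name, "model_id": fit.model_id,
                     "df": len(fit.beta) + len(fit.variance_components),
                     "aic": fit.aic})
    df = pd.DataFrame(rows)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    wraw = np.exp(-df["delta_aic"] / 2.0)
    df["weight"] = wraw / wraw.sum()
    return df.sort_values("delta_aic").reset_index(drop=True)


def multiplier_stability(
    table_builder: Callable[[int], pd.DataFrame],
    multipliers: Sequence[int],
    spec: ModelSpec,
) -> pd.DataFrame:
    """Coefficient trajectory across pseudo-absence multipliers.

    ``table_builder(m)`` must return the design table for multiplier m with
    identical used rows across calls.  The returned frame has one row per
    multiplier with the fitted coefficients; ``attrs['max_rel_delta']``
    holds the largest relative coefficient change between the two largest
    multipliers (NaN when only one multiplier is given).
    """
    multipliers = sorted(multipliers)
    rows = []
    for m in multipliers:
        fit = fit_weighted_glmm(table_builder(m), spec, model_id=f"m{m}")
        row = {"multiplier": m}
        row.update({k: v for k, v in fit.beta.items()})
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(multipliers) >= 2:
        # the intercept absorbs the used:available sampling ratio and moves
        # with the multiplier by construction; stability concerns the slopes
        drop = ["multiplier", "intercept"]
        a = out.iloc[-2].drop(drop).to_numpy(float)
        b = out.iloc[-1].drop(drop).to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(b - a) / np.maximum(np.abs(b), 1e-12)
        out.attrs["max_rel_delta"] = float(np.max(rel))
    else:
        out.attrs["max_rel_delta"] = float("nan")
    return out
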
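"""Relative selection strength (RSS) curves, peaks and report tables.

Under the exponential selection model w(x) = exp(b1 x + b2 x^2), the log
relative selection strength of covariate value x against a reference
x_ref is

    log RSS(x, x_ref) = b1 (x - x_ref) + b2 (x^2 - x_ref^2).

Changing the reference shifts every curve by a constant but never moves
the covariate value at which selection peaks, which is why reports focus
on the peak.  Curves are evaluated over the trimmed availability range —
the empirical 5th to 95th percentile of the pooled used + available
covariate values — and referenced to the mean of the values retained by
the trim.  For a downward parabola the peak is -b1/(2 b2) clamped to the
range; otherwise the peak sits on whichever boundary has the larger
selection weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .rsf import FitResult
from .ssf import SelectionClassification

CURVE_POINTS = 200


@dataclass
class RSSCurve:
    model_id: str
    covariate_grid: np.ndarray
    log_rss: np.ndarray
    reference_value: float
    peak_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"model_id": self.model_id,
                             "x": self.covariate_grid, "log_rss": self.log_rss})


def trimmed_range_and_mean(values: np.ndarray, trim: float = 0.05
                           ) -> tuple[float, float, float]:
    """5%/95% (by default) percentile range and the mean of retained values."""
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if len(v) < 20:
        raise ValueError(f"need >= 20 values to trim, got {len(v)}")
    low = float(np.quantile(v, trim))
    high = float(np.quantile(v, 1.0 - trim))
    kept = v[(v >= low) & (v <= high)]
    return low, high, float(kept.mean())


def log_rss(beta1: float, beta2: float | None, x, x_ref: float):
    """Log relative selection strength of x versus x_ref."""
    x = np.asarray(x, float)
    out = beta1 * (x - x_ref)
    if beta2 is not None:
        out = out + beta2 * (x**2 - x_ref**2)
    return float(out) if out.ndim == 0 else out


def peak_selection(beta1: float, beta2: float | None,
                   low: float, high: float) -> float:
    """Covariate value maximizing log RSS over [low, high]."""
    if low >= high:
        raise ValueError("low must be < high")
    if beta2 is not None and beta2 < 0:
        return float(np.clip(-beta1 / (2.0 * beta2), low, high))
    # linear or upward parabola: the maximum sits on a boundary
    return high if log_rss(beta1, beta2, high, low) >= 0 else low


def rss_curve(beta1: float, beta2: float | None, low: float, high: float,
              x_ref: float, model_id: str = "",
              n_points: int = CURVE_POINTS) -> RSSCurve:
    grid = np.linspace(low, high, n_points)
    return RSSCurve(model_id=model_id, covariate_grid=grid,
                    log_rss=log_rss(beta1, beta2, grid, x_ref),
                    reference_value=x_ref,
                    peak_value=peak_selection(beta1, beta2, low, high))


def _fit_betas(fit: FitResult) -> tuple[float, float | None]:
    return fit.beta["z"], fit.beta.get("z2")


def population_report(
    comparisons: Mapping[str, pd.DataFrame],
    top_fits: Mapping[str, FitResult],
    pooled_values: Mapping[str, np.ndarray],
    trim: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Season-level model comparison, coefficients, RSS curves and peaks.

    ``comparisons`` maps season -> the AIC table from
    :func:`nomadsel.rsf.compare_shapes`; ``top_fits`` maps season -> the
    AIC-best fit; ``pooled_values`` maps season -> pooled used + available
    covariate values for trimming and the reference mean.
    """
    model_rows, coef_rows, curve_frames, summary_rows = [], [], [], []
    for season, comp in comparisons.items():
        c = comp.copy()
        c.insert(0, "season", season)
        model_rows.append(c)
        fit = top_fits[season]
        for name in fit.beta:
            coef_rows.append({"season": season, "term": name,
                              "estimate": fit.beta[name], "se": fit.se[name],
                              "p": fit.p_values[name]})
        low, high, mean = trimmed_range_and_mean(pooled_values[season], trim)
        b1, b2 = _fit_betas(fit)
        curve = rss_curve(b1, b2, low, high, mean, model_id=f"{season}_pop")
        cf = curve.to_frame()
        cf.insert(0, "season", season)
        curve_frames.append(cf)
        summary_rows.append({"season": season, "trim_low": low, "trim_high": high,
                             "reference_mean": mean, "peak": curve.peak_value})
    return {
        "model_comparison": pd.concat(model_rows, ignore_index=True),
        "coefficients": pd.DataFrame(coef_rows),
        "curves": pd.concat(curve_frames, ignore_index=True),
        "summary": pd.DataFrame(summary_rows),
    }


CATEGORIES = ("max", "min", "intermediate", "extreme", "none")


def individual_report(
    classifications: pd.DataFrame,
    entity_values: Mapping[tuple, np.ndarray] | None = None,
    fits: Mapping[tuple, FitResult] | None = None,
    trim: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Category counts/percentages per season and lag, plus individual curves.

    ``classifications`` needs columns season, lag_days, individual_id,
    category (and year where applicable); the denominator per season-lag is
    the number of classified entities, i.e. those that passed the 20-step
    filter.  When per-entity pooled covariate values and top fits are
    supplied, significant entities get RSS curves over their own trimmed
    range (per-entity trims).
    """
    counts = []
    for (season, lag), g in classifications.groupby(["season", "lag_days"], sort=True):
        denom = len(g)
        row = {"season": season, "lag_days": lag, "n_entities": denom}
        for cat in CATEGORIES:
            n = int((g["category"] == cat).sum())
            row[f"n_{cat}"] = n
            row[f"pct_{cat}"] = 100.0 * n / denom if denom else float("nan")
        counts.append(row)
    out = {"category_table": pd.DataFrame(counts)}
    if entity_values is not None and fits is not None:
        frames = []
        for key, fit in fits.items():
            sub = classifications
            # key identifies the entity row; curves only for significant fits
            vals = entity_values.get(key)
            if vals is None or len(vals) < 20:
                continue
            low, high, mean = trimmed_range_and_mean(vals, trim)
            b1, b2 = _fit_betas(fit)
            curve = rss_curve(b1, b2, low, high, mean,
                              model_id="_".join(str(k) for k in key))
            frames.append(curve.to_frame())
        out["curves"] = (pd.concat(frames, ignore_index=True)
                         if frames else pd.DataFrame(columns=["model_id", "x", "log_rss"]))
    return out


def plot_rss_curve(curve: RSSCurve, ax=None):
    """Minimal RSS curve plot (no logic lives here)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.covariate_grid, curve.log_rss)
    ax.axvline(curve.reference_value, color="grey", lw=1)
    ax.plot([curve.peak_value],
            [log_rss_at_peak := float(np.interp(curve.peak_value,
                                                curve.covariate_grid, curve.log_rss))],
            "o")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("covariate")
    ax.set_ylabel("log RSS")
    ax.set_title(curve.model_id)
    return ax
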
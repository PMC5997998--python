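"""Photosynthetic efficiency and batch-culture growth parameters.

Fv/Fm — maximal PSII quantum yield — is (Fm - Fo)/Fm from
dark-acclimated fluorescence yields.  The specific growth rate mu
(day^-1) is the ordinary least-squares slope of ln(cell concentration)
vs time over the exponential phase.  Full growth curves are fitted on
the log scale with a Zwietering-type logistic that carries the three
features of a batch culture: carrying capacity K, maximum specific
growth rate mu, and lag duration,

    ln N(t) = ln n0 + A / (1 + exp(4 mu (lag - t) / A + 2)),
    A = ln(K / n0).

The fit minimizes squared error on ln(count), i.e. a multiplicative
noise model, consistent with how mu itself is defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .io import TimeSeriesTable


def compute_fvfm(fm, fo):
    """Fv/Fm = (Fm - Fo)/Fm, elementwise; bounded in [0, 1].

    Requires Fm > 0 and 0 <= Fo <= Fm.
    """
    fm_arr = np.asarray(fm, float)
    fo_arr = np.asarray(fo, float)
    if (fm_arr <= 0).any():
        raise ValueError("Fm must be > 0")
    if (fo_arr < 0).any() or (fo_arr > fm_arr).any():
        raise ValueError("Fo must satisfy 0 <= Fo <= Fm")
    out = (fm_arr - fo_arr) / fm_arr
    if np.isscalar(fm) and np.isscalar(fo):
        return float(out)
    return out


def log_logistic_lag(t, ln_n0: float, amplitude: float, mu: float, lag: float):
    """ln N(t) of the lag-logistic model; amplitude A = ln(K/n0)."""
    t = np.asarray(t, float)
    arg = np.clip(4.0 * mu * (lag - t) / amplitude + 2.0, -700.0, 700.0)
    return ln_n0 + amplitude / (1.0 + np.exp(arg))


@dataclass(frozen=True)
class GrowthRateResult:
    mu: float  # day^-1
    r_squared: float
    window: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class GrowthFit:
    """Fitted lag-logistic parameters for one cell-count series."""

    k: float  # carrying capacity, cells/mL
    mu: float  # day^-1
    lag: float  # days
    n0: float  # cells/mL
    residual_sd: float  # on ln(count)
    converged: bool
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "K": self.k,
            "mu": self.mu,
            "lag": self.lag,
            "n0": self.n0,
            "residual_sd": self.residual_sd,
            "converged": self.converged,
            "warnings": list(self.warnings),
        }


def _coerce_series(counts) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(counts, TimeSeriesTable):
        ids = counts.series_ids()
        if len(ids) != 1:
            raise ValueError(
                f"expected a single series, found {len(ids)}; "
                "fit each series separately"
            )
        frame = counts.frame
        return frame["time"].to_numpy(float), frame["value"].to_numpy(float)
    times, values = counts
    return np.asarray(times, float), np.asarray(values, float)


def _steepest_window(times: np.ndarray, log_counts: np.ndarray, width: int = 4):
    """Indices of the maximal-slope run of ``width`` consecutive points."""
    best_slope, best = -np.inf, (0, len(times))
    for start in range(0, len(times) - width + 1):
        sl = slice(start, start + width)
        fit = stats.linregress(times[sl], log_counts[sl])
        if fit.slope > best_slope:
            best_slope, best = fit.slope, (start, start + width)
    return best


def specific_growth_rate(
    counts,
    window: tuple[float, float] | str | None = None,
) -> GrowthRateResult:
    """mu from log-linear regression of ln(count) on time (days).

    ``window`` is a (t_min, t_max) interval, the string ``"auto"`` to
    use the maximal-slope 4-point run (a documented heuristic for the
    exponential phase), or None to use every point.
    """
    times, values = _coerce_series(counts)
    if (values <= 0).any():
        raise ValueError("cell counts must be > 0")
    log_counts = np.log(values)
    if window == "auto":
        if len(times) < 4:
            raise ValueError("auto window detection needs >= 4 points")
        start, stop = _steepest_window(times, log_counts)
        mask = np.zeros(len(times), bool)
        mask[start:stop] = True
    elif window is None:
        mask = np.ones(len(times), bool)
    else:
        t0, t1 = window
        mask = (times >= t0) & (times <= t1)
    if mask.sum() < 3:
        raise ValueError(f"need >= 3 points in window, got {int(mask.sum())}")
    fit = stats.linregress(times[mask], log_counts[mask])
    return GrowthRateResult(
        mu=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        window=(float(times[mask].min()), float(times[mask].max())),
        n_points=int(mask.sum()),
    )


def fit_logistic_with_lag(counts) -> GrowthFit:
    """Least-squares fit of the lag-logistic model on ln(count).

    Initial values are seeded from the data: n0 from the first count, K
    from the maximum, mu from the steepest 4-point log-linear segment,
    and lag from where that segment extrapolates back to ln n0.
    Non-convergence is flagged, never silent; a carrying capacity far
    above the observed range raises a warning flag (plateau not
    identified).
    """
    times, values = _coerce_series(counts)
    if len(times) < 6:
        raise ValueError("need >= 6 points spanning lag, exponential and plateau")
    if (values <= 0).any():
        raise ValueError("cell counts must be > 0")
    if values.max() <= values[0]:
        raise ValueError("observed maximum does not exceed the initial count")
    y = np.log(values)

    ln_n0_seed = y[0]
    amp_seed = max(y.max() - y[0], 0.1)
    start, stop = _steepest_window(times, y)
    seg = stats.linregress(times[start:stop], y[start:stop])
    mu_seed = max(seg.slope, 1e-3)
    lag_seed = (ln_n0_seed - seg.intercept) / seg.slope if seg.slope > 0 else 0.0
    lag_seed = float(np.clip(lag_seed, 0.0, times.max()))

    def residuals(p):
        return log_logistic_lag(times, p[0], p[1], p[2], p[3]) - y

    p0 = np.array([ln_n0_seed, amp_seed, mu_seed, lag_seed])
    lower = np.array([-np.inf, 1e-9, 1e-9, 0.0])
    upper = np.array([np.inf, np.inf, np.inf, float(times.max())])
    p0 = np.clip(p0, lower + 1e-9, None)
    result = optimize.least_squares(
        residuals, p0, bounds=(lower, upper), xtol=1e-15, ftol=1e-15, gtol=1e-15,
        max_nfev=20000,
    )
    ln_n0, amplitude, mu, lag = result.x
    n0 = float(np.exp(ln_n0))
    k = float(np.exp(ln_n0 + amplitude))
    resid = residuals(result.x)
    dof = max(len(times) - 4, 1)
    residual_sd = float(np.sqrt((resid**2).sum() / dof))
    warns = []
    final_fraction = values.max() / k
    if k > 5.0 * values.max() or final_fraction < 0.8:
        warns.append(
            "carrying capacity extrapolated beyond the observed data; "
            "plateau not identified"
        )
    return GrowthFit(
        k=k,
        mu=float(mu),
        lag=float(lag),
        n0=n0,
        residual_sd=residual_sd,
        converged=bool(result.success),
        warnings=tuple(warns),
    )
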
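"""Movement-speed coding of cholinergic activity across timescales.

Cholinergic ΔF/F is linearly related to the *logarithm* of movement speed.
This module provides the log2 transform (with a configurable speed floor), the
timescale-dependent Pearson correlation curve (smoothing windows 0.25–256 s),
the per-session speed→ΔF/F regression with its residual ("speed-adjusted
activity"), and exponential-decay fitting of the session-start recency signal
``A·exp(−t/τ) + offset``.

Frame-level series are strongly autocorrelated, so the regression reports both
the naive OLS standard error and an effective-sample-size-adjusted standard
error (inflated by ``sqrt(1 + 2·Σ ρ̂_k)``, the integrated autocorrelation time
of the residuals); see the package methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from cholinepipe.photometry import moving_average


@dataclass
class TimescaleCurve:
    windows: np.ndarray  # seconds, strictly increasing
    r: np.ndarray  # Pearson r per window (NaN where window > session)
    best_window: float  # argmax over valid windows

    def __post_init__(self) -> None:
        if np.any(np.diff(self.windows) <= 0):
            raise ValueError("windows must be strictly increasing")


@dataclass
class SpeedModel:
    """Per-session linear regression of z-scored ΔF/F on log2 speed."""

    slope: float
    intercept: float
    r: float
    se_slope: float  # naive OLS standard error
    se_slope_eff: float  # autocorrelation-adjusted standard error
    predicted: np.ndarray
    residual: np.ndarray


@dataclass
class DecayFit:
    """Nonlinear least-squares fit of A·exp(−t/τ) + offset."""

    A: float
    tau: float
    offset: float
    rss: float
    fit_window: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be nonnegative")


def log2_speed(speed: np.ndarray, floor: float = 1.0) -> np.ndarray:
    """``log2(max(speed, floor))``; zero at the floor, never −inf."""
    speed = np.asarray(speed, float)
    if np.any(speed < 0):
        raise ValueError("speed must be nonnegative")
    return np.log2(np.maximum(speed, floor))


def default_windows(lo_oct: float = -2.0, hi_oct: float = 8.0, step_oct: float = 0.5) -> np.ndarray:
    """Logarithmically spaced smoothing windows, 2^−2 … 2^8 s by fractional octaves."""
    return 2.0 ** np.arange(lo_oct, hi_oct + 1e-9, step_oct)


def timescale_correlation(
    dff: np.ndarray,
    log2speed: np.ndarray,
    rate: float,
    windows: np.ndarray | None = None,
) -> TimescaleCurve:
    """Pearson r between the two series after smoothing both at each window.

    Windows longer than the session are skipped (NaN); ``best_window``
    maximizes r over the valid entries.
    """
    dff = np.asarray(dff, float)
    log2speed = np.asarray(log2speed, float)
    if dff.size != log2speed.size:
        raise ValueError("series must be aligned and equal length")
    if windows is None:
        windows = default_windows()
    duration = dff.size / rate
    r = np.full(windows.size, np.nan)
    for i, w in enumerate(windows):
        if w > duration:
            continue
        a = moving_average(dff, w, rate)
        b = moving_average(log2speed, w, rate)
        if a.std() == 0 or b.std() == 0:
            continue
        r[i] = float(np.corrcoef(a, b)[0, 1])
    if np.all(np.isnan(r)):
        raise ValueError("no window fits within the session")
    best = float(windows[np.nanargmax(r)])
    return TimescaleCurve(windows=np.asarray(windows, float), r=r, best_window=best)


def _autocorr_inflation(resid: np.ndarray, rate: float, max_lag_s: float = 10.0) -> float:
    """sqrt(1 + 2·Σρ̂_k): SE inflation from the integrated autocorrelation time.

    The sum runs to the first nonpositive autocorrelation or ``max_lag_s``,
    whichever comes first (initial-positive-sequence rule).
    """
    resid = np.asarray(resid, float) - np.mean(resid)
    n = resid.size
    denom = float(resid @ resid)
    if denom <= 0 or n < 10:
        return 1.0
    max_lag = min(int(max_lag_s * rate), n - 2)
    s = 0.0
    for k in range(1, max_lag + 1):
        rho = float(resid[:-k] @ resid[k:]) / denom
        if rho <= 0:
            break
        s += rho
    return math.sqrt(1.0 + 2.0 * s)


def fit_speed_model(dff_z: np.ndarray, log2speed: np.ndarray, rate: float = 30.0) -> SpeedModel:
    """OLS of z-scored ΔF/F on log2 speed; residual is the speed-adjusted activity."""
    y = np.asarray(dff_z, float)
    x = np.asarray(log2speed, float)
    if x.size != y.size:
        raise ValueError("series must be equal length")
    xv = x - x.mean()
    var = float(xv @ xv)
    if var <= 0:
        raise ValueError("zero-variance regressor")
    slope = float(xv @ (y - y.mean())) / var
    intercept = float(y.mean() - slope * x.mean())
    predicted = slope * x + intercept
    residual = y - predicted
    n = y.size
    sigma2 = float(residual @ residual) / max(n - 2, 1)
    se = math.sqrt(sigma2 / var)
    r = float(np.corrcoef(x, y)[0, 1])
    infl = _autocorr_inflation(residual, rate)
    return SpeedModel(
        slope=slope,
        intercept=intercept,
        r=r,
        se_slope=se,
        se_slope_eff=se * infl,
        predicted=predicted,
        residual=residual,
    )


#: multi-start τ grid spanning tens-of-seconds decays an order of magnitude each way
TAU_GRID = (5.0, 15.0, 30.0, 60.0, 120.0)


def fit_exponential_decay(
    series: np.ndarray,
    t: np.ndarray,
    fit_window: float = 180.0,
    with_offset: bool = True,
    tau_grid: tuple = TAU_GRID,
) -> DecayFit:
    """Nonlinear least squares of ``A·exp(−t/τ) + offset`` over ``[0, fit_window]``.

    Multi-start over a τ grid; the best (lowest-RSS) converged fit wins. A
    near-flat input is flagged degenerate (A ≈ 0, τ unidentifiable) with the
    offset set to the mean.
    """
    series = np.asarray(series, float)
    t = np.asarray(t, float)
    sel = t <= fit_window
    y = series[sel]
    tt = t[sel]
    if tt.size < 10:
        raise ValueError("fit_window must cover at least 10 samples")
    span = float(y.max() - y.min())
    if span < 1e-12 * max(1.0, abs(float(y.mean()))) or span == 0.0:
        return DecayFit(A=0.0, tau=math.nan, offset=float(y.mean()), rss=0.0,
                        fit_window=fit_window, degenerate=True)

    tau_max = 10.0 * fit_window
    if with_offset:
        def model(tx, A, tau, off):
            return A * np.exp(-tx / tau) + off
        p0s = [(y[0] - y[-1], tau, float(y[-1])) for tau in tau_grid]
        bounds = ([-np.inf, 0.1, -np.inf], [np.inf, tau_max, np.inf])
    else:
        def model(tx, A, tau):
            return A * np.exp(-tx / tau)
        p0s = [(y[0], tau) for tau in tau_grid]
        bounds = ([-np.inf, 0.1], [np.inf, tau_max])

    best = None
    diagnostics = []
    for p0 in p0s:
        try:
            popt, _ = optimize.curve_fit(model, tt, y, p0=p0, bounds=bounds, maxfev=5000)
        except (RuntimeError, optimize.OptimizeWarning):
            diagnostics.append((p0, None))
            continue
        if popt[1] <= 0:
            diagnostics.append((p0, popt))
            continue
        resid = y - model(tt, *popt)
        rss = float(resid @ resid)
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise RuntimeError(f"exponential fit failed from all starts; diagnostics: {diagnostics}")
    popt, rss = best
    off = float(popt[2]) if with_offset else 0.0
    return DecayFit(A=float(popt[0]), tau=float(popt[1]), offset=off, rss=rss,
                    fit_window=fit_window)


@dataclass
class RecencyResult:
    observed: DecayFit
    predicted: DecayFit
    residual: DecayFit


def recency_analysis(
    observed: np.ndarray,
    model: SpeedModel,
    t: np.ndarray,
    fit_window: float = 180.0,
) -> RecencyResult:
    """Exponential decays of observed, speed-predicted and speed-adjusted activity.

    The three τ values quantify whether the session-start elevation of
    cholinergic activity outlives what movement speed alone predicts.
    """
    observed = np.asarray(observed, float)
    return RecencyResult(
        observed=fit_exponential_decay(observed, t, fit_window),
        predicted=fit_exponential_decay(model.predicted, t, fit_window),
        residual=fit_exponential_decay(model.residual, t, fit_window),
    )
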
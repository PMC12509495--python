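"""ΔF/F computation from dual-channel fiber photometry.

The correction removes photobleaching and motion artifacts shared between the
calcium-dependent signal ``s`` (465 nm) and the isosbestic control ``c``
(405 nm):

1. ``adjusted_control`` — fit a quadratic in time to ``s − c`` and add it back
   to ``c``, so the control tracks the slow bleaching difference between the
   channels.
2. ``fit_scale`` — scale the adjusted control onto the signal by minimizing
   ``Σ (s − (c·α + β))²``; this is a simple linear regression with a unique
   closed-form minimizer.
3. ``compute_dff`` — ``ΔF/F = (s − f) / f`` with ``f = c·α + β``.

Downstream transforms (Fourier resampling to the video clock, moving-average
smoothing, per-session z-scoring) are provided here as well; the applied order
is recorded in :attr:`DffSeries.stage_tags`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: canonical transform order enforced by :func:`preprocess`
STAGE_ORDER = ("corrected", "resampled", "smoothed", "zscored")


@dataclass
class SessionMeta:
    """Identity of one recording: animal, task phase, task repetition."""

    mouse_id: str = "m0"
    phase: str = "sample"  # "sample" or "test"
    oblom_id: int = 1
    session_id: str = "s0"

    def __post_init__(self) -> None:
        if self.phase not in ("sample", "test"):
            raise ValueError(f"phase must be 'sample' or 'test', got {self.phase!r}")


@dataclass
class PhotometrySession:
    """Raw demodulated two-channel photometry plus timestamps and metadata."""

    f465: np.ndarray
    f405: np.ndarray
    t: np.ndarray
    rate: float
    meta: SessionMeta = field(default_factory=SessionMeta)

    def __post_init__(self) -> None:
        self.f465 = np.asarray(self.f465, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if not (self.f465.shape == self.f405.shape == self.t.shape):
            raise ValueError("f465, f405 and t must have equal lengths")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")
            if abs(dt.mean() * self.rate - 1.0) > 1e-6:
                raise ValueError("rate inconsistent with timestamp spacing")

    @property
    def duration(self) -> float:
        return self.t.size / self.rate


@dataclass
class DffSeries:
    """ΔF/F (or z-scored ΔF/F) on a uniform clock, with its transform history."""

    values: np.ndarray
    t: np.ndarray
    rate: float
    stage_tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.values.shape != self.t.shape:
            raise ValueError("values and t must have equal lengths")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("DffSeries values must be finite")

    def with_stage(self, values: np.ndarray, tag: str, t=None, rate=None) -> "DffSeries":
        """Return a copy with new values and ``tag`` appended (append-only)."""
        return DffSeries(
            values=values,
            t=self.t if t is None else t,
            rate=self.rate if rate is None else rate,
            stage_tags=[*self.stage_tags, tag],
        )


@dataclass
class ControlFit:
    """Result of the adjusted-control scaling step."""

    alpha: float
    beta: float
    poly_coeffs: np.ndarray  # quadratic (c0, c1, c2) in centered time
    objective: float  # residual sum of squares of s on c*alpha+beta

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective (RSS) must be nonnegative")


def adjusted_control(s: np.ndarray, c: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Add the quadratic-in-time least-squares fit of ``s − c`` back onto ``c``.

    Time is centered at the session midpoint before fitting, for numerical
    conditioning; the fitted curve is affine-invariant to this choice.
    """
    s = np.asarray(s, float)
    c = np.asarray(c, float)
    t = np.asarray(t, float)
    if s.size < 3:
        raise ValueError("adjusted_control needs at least 3 samples for a quadratic fit")
    tc = t - 0.5 * (t[0] + t[-1])
    coeffs = npoly.polyfit(tc, s - c, deg=2)
    return c + npoly.polyval(tc, coeffs)


def _quadratic_coeffs(s: np.ndarray, c: np.ndarray, t: np.ndarray) -> np.ndarray:
    tc = t - 0.5 * (t[0] + t[-1])
    return npoly.polyfit(tc, np.asarray(s, float) - np.asarray(c, float), deg=2)


def fit_scale(s: np.ndarray, c_adj: np.ndarray) -> ControlFit:
    """Closed-form minimizer of ``Σ (s − (c_adj·α + β))²``.

    The objective is ordinary least squares of ``s`` on ``c_adj``:
    ``α = cov(c_adj, s) / var(c_adj)`` and ``β = mean(s) − α·mean(c_adj)``.
    """
    s = np.asarray(s, float)
    c_adj = np.asarray(c_adj, float)
    if s.size != c_adj.size or s.size < 2:
        raise ValueError("fit_scale needs two equal-length series of length >= 2")
    cm = c_adj.mean()
    var = float(np.mean((c_adj - cm) ** 2))
    if var <= 0:
        raise ValueError("c_adj has zero variance; alpha is undefined")
    alpha = float(np.mean((c_adj - cm) * (s - s.mean())) / var)
    beta = float(s.mean() - alpha * cm)
    resid = s - (c_adj * alpha + beta)
    return ControlFit(alpha=alpha, beta=beta, poly_coeffs=np.zeros(3), objective=float(resid @ resid))


def compute_dff(s: np.ndarray, fit_ctrl: np.ndarray) -> np.ndarray:
    """Element-wise ``(s − f) / f`` with ``f`` the fitted control ``c·α + β``."""
    s = np.asarray(s, float)
    f = np.asarray(fit_ctrl, float)
    bad = np.flatnonzero(f <= 0)
    if bad.size:
        raise ValueError(f"fitted control is nonpositive at index {bad[0]}")
    return (s - f) / f


def moving_average(x: np.ndarray, window: float, rate: float) -> np.ndarray:
    """Centered boxcar smoother with shrinking (truncated) edge windows.

    ``window`` is in seconds. A window shorter than one sample period returns
    the input unchanged (logged). Edge windows shrink rather than pad, which
    keeps the series length and avoids padding bias at the session start.
    """
    x = np.asarray(x, float)
    if window <= 0:
        raise ValueError("window must be positive")
    w = int(round(window * rate))
    if w <= 1:
        if window * rate < 1.0:
            logger.warning("moving_average window %.4g s < one sample period; identity", window)
        return x.copy()
    h_left = (w - 1) // 2
    h_right = w // 2  # asymmetric by one sample for even w
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - h_left, 0)
    hi = np.minimum(idx + h_right + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def resample(x: np.ndarray, rate: float, target_rate: float) -> np.ndarray:
    """Fourier-method resampling onto a uniform grid at ``target_rate``.

    Implemented as rational-factor polyphase resampling
    (:func:`scipy.signal.resample_poly`), which is bit-stable; linear padding
    limits edge transients. Identical rates return a copy.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    x = np.asarray(x, float)
    if target_rate == rate:
        return x.copy()
    frac = _as_fraction(target_rate / rate)
    y = sps.resample_poly(x, frac[0], frac[1], padtype="line", window=("kaiser", 8.0))
    n_target = int(round(x.size * target_rate / rate))
    if y.size > n_target:
        y = y[:n_target]
    elif y.size < n_target:
        y = np.concatenate([y, np.full(n_target - y.size, y[-1])])
    return y


def _as_fraction(ratio: float, max_den: int = 10000) -> tuple[int, int]:
    from fractions import Fraction

    fr = Fraction(ratio).limit_denominator(max_den)
    return fr.numerator, fr.denominator


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, SD 1 over the whole series (per session)."""
    x = np.asarray(x, float)
    sd = x.std()
    if sd <= 0:
        raise ValueError("zscore undefined for zero-variance input")
    return (x - x.mean()) / sd


def correct_session(session: PhotometrySession) -> tuple[DffSeries, ControlFit]:
    """Run the full adjusted-control correction on a raw session."""
    c_adj = adjusted_control(session.f465, session.f405, session.t)
    fit = fit_scale(session.f465, c_adj)
    fit = replace(fit, poly_coeffs=_quadratic_coeffs(session.f465, session.f405, session.t))
    dff = compute_dff(session.f465, c_adj * fit.alpha + fit.beta)
    series = DffSeries(values=dff, t=session.t.copy(), rate=session.rate, stage_tags=["corrected"])
    return series, fit


def preprocess(
    session: PhotometrySession,
    window: float = 0.5,
    target_rate: float = 30.0,
    smooth: bool = True,
    standardize: bool = True,
) -> DffSeries:
    """Correction → Fourier resample → 0.5 s moving average → per-session z-score.

    The order is fixed; each applied stage is appended to ``stage_tags`` so the
    provenance of any downstream series is auditable.
    """
    series, _ = correct_session(session)
    values = resample(series.values, session.rate, target_rate)
    t = session.t[0] + np.arange(values.size) / target_rate
    series = series.with_stage(values, f"resampled-{target_rate:g}", t=t, rate=target_rate)
    if smooth:
        series = series.with_stage(
            moving_average(series.values, window, target_rate), f"smoothed-{window:g}"
        )
    if standardize:
        series = series.with_stage(zscore(series.values), "zscored")
    return series


def check_stage_order(tags: list[str]) -> bool:
    """True if the applied stages appear in the canonical pipeline order."""
    ranks = []
    for tag in tags:
        base = tag.split("-")[0]
        if base in STAGE_ORDER:
            ranks.append(STAGE_ORDER.index(base))
    return ranks == sorted(ranks)
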
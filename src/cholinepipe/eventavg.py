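"""Event-triggered, linearly time-warped activity profiles around bouts.

Each behavioral bout contributes a row: 5 s of signal before onset at the
native 30 Hz rate, the within-bout samples linearly interpolated onto a
fixed-length relative-time grid (``n_core`` points), and 5 s after offset.
Averaging rows yields the temporal profile of cholinergic dynamics for that
behavior; the same bouts sliced from the speed-predicted signal give the
paired comparison series.

Rise/decay timing uses a threshold at baseline + 98% of the during-bout
elevation, searched 3 s before to 1 s after the onset (mirrored at the
offset); the median of all threshold crossings in that window, per bout, is
the bout's response time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from cholinepipe.behavior import Bout, BoutSet

logger = logging.getLogger(__name__)


@dataclass
class WarpedProfile:
    per_bout: np.ndarray  # (n_bouts, n_pre + n_core + n_post)
    mean: np.ndarray
    sem: np.ndarray
    n_pre: int
    n_core: int
    n_post: int
    rate: float
    included: list[Bout] = field(default_factory=list)
    mean_duration: float = 0.0

    @property
    def col_dt(self) -> np.ndarray:
        """Seconds represented by each column (core columns share the mean duration)."""
        dt = np.empty(self.n_pre + self.n_core + self.n_post)
        dt[: self.n_pre] = 1.0 / self.rate
        dt[self.n_pre : self.n_pre + self.n_core] = self.mean_duration / self.n_core
        dt[self.n_pre + self.n_core :] = 1.0 / self.rate
        return dt


@dataclass
class TimingEstimate:
    """Per-bout threshold-crossing times (s, relative to onset or offset)."""

    per_bout_crossing: np.ndarray  # NaN where no crossing in the search window
    median: float
    sd: float
    n_excluded_no_crossing: int
    side: str = "onset"


@dataclass
class PairedTiming:
    differences: np.ndarray  # observed − predicted, valid pairs only
    median_difference: float
    statistic: float
    p_value: float
    n_pairs: int
    low_n: bool


def _bout_indices(t: np.ndarray, rate: float, bout: Bout) -> tuple[int, int]:
    i_on = int(round((bout.onset_t - t[0]) * rate))
    i_off = int(round((bout.offset_t - t[0]) * rate))
    return i_on, i_off


def warp_bout(
    signal: np.ndarray,
    t: np.ndarray,
    rate: float,
    bout: Bout,
    pre: float = 5.0,
    post: float = 5.0,
    n_core: int = 100,
) -> np.ndarray:
    """One row of the warped matrix; raises if the bout ± margins leave the session."""
    signal = np.asarray(signal, float)
    n_pre = int(round(pre * rate))
    n_post = int(round(post * rate))
    i_on, i_off = _bout_indices(t, rate, bout)
    if i_off - i_on < 2:
        raise ValueError("bout shorter than 2 samples cannot be warped")
    if i_on - n_pre < 0 or i_off + n_post > signal.size:
        raise ValueError("bout margins extend beyond the session")
    core_src = signal[i_on:i_off]
    if n_core == core_src.size:
        core = core_src.copy()
    else:
        src_pos = np.linspace(0.0, 1.0, core_src.size)
        core = np.interp(np.linspace(0.0, 1.0, n_core), src_pos, core_src)
    return np.concatenate([signal[i_on - n_pre : i_on], core, signal[i_off : i_off + n_post]])


def build_profile(
    signal: np.ndarray,
    t: np.ndarray,
    rate: float,
    bouts: BoutSet | list[Bout],
    pre: float = 5.0,
    post: float = 5.0,
    n_core: int = 100,
) -> WarpedProfile:
    """Stack warped rows over bouts; mean ± SEM per aligned column.

    Bouts too close to the session edges are dropped (logged); at least two
    must survive.
    """
    bout_list = list(bouts)
    rows, included = [], []
    for bout in bout_list:
        try:
            rows.append(warp_bout(signal, t, rate, bout, pre, post, n_core))
            included.append(bout)
        except ValueError:
            logger.info("dropping bout at %.2f s: margins leave the session", bout.onset_t)
    if len(rows) < 2:
        raise ValueError("build_profile needs at least 2 usable bouts")
    per_bout = np.vstack(rows)
    mean = per_bout.mean(axis=0)
    sem = per_bout.std(axis=0, ddof=1) / math.sqrt(per_bout.shape[0])
    return WarpedProfile(
        per_bout=per_bout,
        mean=mean,
        sem=sem,
        n_pre=int(round(pre * rate)),
        n_core=n_core,
        n_post=int(round(post * rate)),
        rate=rate,
        included=included,
        mean_duration=float(np.mean([b.duration for b in included])),
    )


def threshold_crossing(
    signal: np.ndarray,
    t: np.ndarray,
    rate: float,
    bout: Bout,
    side: str = "onset",
    baseline_win: float = 5.0,
    frac: float = 0.98,
    search: tuple[float, float] | None = None,
) -> float | None:
    """Median threshold-crossing time near the bout onset (or offset), in seconds.

    Baseline is the mean over ``baseline_win`` seconds before the onset (after
    the offset for ``side='offset'``); the threshold is
    ``baseline + frac·(during − baseline)``. Crossings are located on the
    native grid with linear interpolation between straddling samples, in the
    direction of the during-vs-baseline change (toward it at onset, away from
    it at offset). Returns None (degenerate or no crossing) for exclusion.
    """
    signal = np.asarray(signal, float)
    i_on, i_off = _bout_indices(t, rate, bout)
    n_base = int(round(baseline_win * rate))
    during = float(signal[i_on:i_off].mean())
    if side == "onset":
        if i_on - n_base < 0:
            raise ValueError("baseline window extends before the session")
        baseline = float(signal[i_on - n_base : i_on].mean())
        ref_idx = i_on
        lo, hi = search if search is not None else (-3.0, 1.0)
        direction = math.copysign(1.0, during - baseline)
    elif side == "offset":
        if i_off + n_base > signal.size:
            raise ValueError("baseline window extends past the session")
        baseline = float(signal[i_off : i_off + n_base].mean())
        ref_idx = i_off
        lo, hi = search if search is not None else (-1.0, 3.0)
        direction = -math.copysign(1.0, during - baseline)
    else:
        raise ValueError("side must be 'onset' or 'offset'")
    if during == baseline:
        return None
    thr = baseline + frac * (during - baseline)
    j0 = max(ref_idx + int(math.floor(lo * rate)), 0)
    j1 = min(ref_idx + int(math.ceil(hi * rate)), signal.size - 1)
    seg = signal[j0 : j1 + 1] - thr
    crossings = []
    for j in range(seg.size - 1):
        a, b = seg[j], seg[j + 1]
        if a == 0.0:
            if direction * (b - a) > 0 or b == 0.0:
                crossings.append(j)
            continue
        if a * b < 0 and direction * (b - a) > 0:
            crossings.append(j + a / (a - b))
    if not crossings:
        return None
    times = (j0 + np.asarray(crossings, float) - ref_idx) / rate
    in_win = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    times = times[in_win]
    if times.size == 0:
        return None
    return float(np.median(times))


def estimate_timing(
    signal: np.ndarray,
    t: np.ndarray,
    rate: float,
    bouts: list[Bout] | BoutSet,
    side: str = "onset",
    **kwargs,
) -> TimingEstimate:
    """Per-bout crossing times; median/SD over bouts with at least one crossing."""
    per_bout = []
    for bout in bouts:
        try:
            per_bout.append(threshold_crossing(signal, t, rate, bout, side=side, **kwargs))
        except ValueError:
            per_bout.append(None)
    arr = np.array([math.nan if c is None else c for c in per_bout], float)
    valid = arr[~np.isnan(arr)]
    return TimingEstimate(
        per_bout_crossing=arr,
        median=float(np.median(valid)) if valid.size else math.nan,
        sd=float(np.std(valid, ddof=1)) if valid.size > 1 else math.nan,
        n_excluded_no_crossing=int(np.isnan(arr).sum()),
        side=side,
    )


def timing_comparison(observed_est: TimingEstimate, predicted_est: TimingEstimate) -> PairedTiming:
    """Paired observed-vs-predicted response times (Wilcoxon signed-rank).

    Pairs require a crossing in both series for the same bout; fewer than 5
    valid pairs flags the result as low-n.
    """
    a = observed_est.per_bout_crossing
    b = predicted_est.per_bout_crossing
    if a.size != b.size:
        raise ValueError("estimates must cover the same bouts")
    valid = ~np.isnan(a) & ~np.isnan(b)
    diffs = a[valid] - b[valid]
    n = int(diffs.size)
    low_n = n < 5
    if n == 0:
        return PairedTiming(diffs, math.nan, math.nan, math.nan, 0, True)
    if np.allclose(diffs, 0.0):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.wilcoxon(diffs)
    return PairedTiming(
        differences=diffs,
        median_difference=float(np.median(diffs)),
        statistic=float(stat),
        p_value=float(p),
        n_pairs=n,
        low_n=low_n,
    )
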
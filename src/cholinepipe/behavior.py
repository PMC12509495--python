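"""Behavioral measures: speed, object exploration, discrimination index, bouts.

Positions come from neck/nose tracking at the video frame rate; the ethogram is
a frame-by-frame binary labeling of locomotion, grooming, rearing, object
exploration and background. Object exploration is split into stationary vs
nonstationary object by the nose-to-object-center distance (10 cm radius).

Bouts are contiguous episodes of one behavior surviving a minimum-duration
filter (2 s) and a temporal-isolation filter (no same-behavior frame within
4 s before onset or after offset); they are the unit of event-triggered
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: behaviors that are mutually exclusive on a frame
EXCLUSIVE = ("locomotion", "grooming", "rearing")
#: full per-frame flag catalogue
BEHAVIORS = ("locomotion", "grooming", "rearing", "explore_stat", "explore_nonstat", "background")


@dataclass
class Trajectory:
    """Neck/nose positions (cm) on the video clock, with derived speed (cm/s)."""

    t: np.ndarray
    neck_xy: np.ndarray  # (n, 2)
    nose_xy: np.ndarray  # (n, 2)
    rate: float
    speed: np.ndarray | None = None
    state: np.ndarray | None = None  # latent behavior state (synthetic sessions only)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.neck_xy = np.asarray(self.neck_xy, float)
        self.nose_xy = np.asarray(self.nose_xy, float)
        n = self.t.size
        if self.neck_xy.shape != (n, 2) or self.nose_xy.shape != (n, 2):
            raise ValueError("neck_xy and nose_xy must be (n, 2) arrays matching t")

    @property
    def n_frames(self) -> int:
        return self.t.size


@dataclass
class Ethogram:
    """Binary behavior × frame matrix on the video clock.

    Invariants: ``explore_stat`` and ``explore_nonstat`` never co-occur;
    locomotion/grooming/rearing are mutually exclusive; ``background`` is set
    exactly on frames where every other flag is zero.
    """

    t: np.ndarray
    rate: float
    flags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        n = self.t.size
        for name in BEHAVIORS:
            if name not in self.flags:
                self.flags[name] = np.zeros(n, dtype=bool)
            self.flags[name] = np.asarray(self.flags[name]).astype(bool)
            if self.flags[name].size != n:
                raise ValueError(f"flag {name!r} length mismatch")
        self.refresh_background()
        self.validate()

    def refresh_background(self) -> None:
        others = [self.flags[b] for b in BEHAVIORS if b != "background"]
        self.flags["background"] = ~np.logical_or.reduce(others)

    def validate(self) -> None:
        excl = sum(self.flags[b].astype(int) for b in EXCLUSIVE)
        if np.any(excl > 1):
            raise ValueError("locomotion/grooming/rearing must be mutually exclusive")
        if np.any(self.flags["explore_stat"] & self.flags["explore_nonstat"]):
            raise ValueError("explore_stat and explore_nonstat must not co-occur")
        if np.any(self.flags["explore_stat"] & self.flags["grooming"]) or np.any(
            self.flags["explore_nonstat"] & self.flags["grooming"]
        ):
            raise ValueError("object exploration may co-occur only with rearing or locomotion")

    @property
    def n_frames(self) -> int:
        return self.t.size

    def explore_any(self) -> np.ndarray:
        return self.flags["explore_stat"] | self.flags["explore_nonstat"]


@dataclass
class Bout:
    """One filtered behavioral episode; times half-open ``[onset, offset)``."""

    behavior: str
    onset_t: float
    offset_t: float
    session_id: str = ""

    @property
    def duration(self) -> float:
        return self.offset_t - self.onset_t


@dataclass
class BoutSet:
    behavior: str
    bouts: list[Bout]
    min_dur: float = 2.0
    isolation: float = 4.0

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)


@dataclass
class DiResult:
    """Discrimination index: (t_nonstat − t_stat) / (t_nonstat + t_stat)."""

    di: float
    t_nonstat: float
    t_stat: float
    window: tuple[float, float]


def compute_speed(traj: Trajectory) -> np.ndarray:
    """Frame-to-frame Euclidean neck displacement × frame rate (cm/s).

    The first frame copies the second so the series keeps the trajectory
    length and stays aligned with ΔF/F at t = 0.
    """
    if traj.n_frames < 2:
        raise ValueError("compute_speed needs at least 2 frames")
    if not np.all(np.isfinite(traj.neck_xy)):
        bad = np.flatnonzero(~np.isfinite(traj.neck_xy).all(axis=1))
        raise ValueError(f"non-finite neck positions at frames {bad[:10].tolist()}")
    disp = np.linalg.norm(np.diff(traj.neck_xy, axis=0), axis=1)
    speed = np.empty(traj.n_frames)
    speed[1:] = disp * traj.rate
    speed[0] = speed[1]
    return speed


def classify_object_exploration(
    explore: np.ndarray,
    nose_xy: np.ndarray,
    objects: dict[str, tuple[float, float]],
    radius: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split generic exploration frames by nose distance to the object centers.

    Frames within ``radius`` of both centers go to the nearer one; exact ties
    break deterministically to the stationary object (logged). Exploration
    outside both radii is dropped (becomes background).
    """
    explore = np.asarray(explore).astype(bool)
    nose_xy = np.asarray(nose_xy, float)
    d_stat = np.linalg.norm(nose_xy - np.asarray(objects["stat"], float), axis=1)
    d_nonstat = np.linalg.norm(nose_xy - np.asarray(objects["nonstat"], float), axis=1)
    near_stat = d_stat <= radius
    near_nonstat = d_nonstat <= radius
    ties = explore & near_stat & near_nonstat & (d_stat == d_nonstat)
    if ties.any():
        logger.info("equidistant nose on %d frames; tie-break to stationary", int(ties.sum()))
    stat = explore & near_stat & (d_stat <= d_nonstat)
    nonstat = explore & near_nonstat & (d_nonstat < d_stat)
    return stat, nonstat


def discrimination_index(
    t_nonstat: float, t_stat: float, window: tuple[float, float] = (0.0, 0.0)
) -> DiResult:
    """DI = (t_nonstat − t_stat) / (t_nonstat + t_stat); undefined at zero total."""
    if t_nonstat < 0 or t_stat < 0:
        raise ValueError("exploration times must be nonnegative")
    total = t_nonstat + t_stat
    if total <= 0:
        raise ValueError("DI undefined: total exploration time is zero")
    return DiResult(di=(t_nonstat - t_stat) / total, t_nonstat=t_nonstat, t_stat=t_stat, window=window)


def sliding_di(
    etho: Ethogram, window: float = 180.0, step: float = 30.0
) -> list[DiResult | None]:
    """Per-window DI over sliding windows; zero-exploration windows yield None."""
    duration = etho.n_frames / etho.rate
    if window > duration:
        raise ValueError("window exceeds session length")
    t0 = etho.t[0]
    results: list[DiResult | None] = []
    start = t0
    dt = 1.0 / etho.rate
    while start + window <= t0 + duration + 1e-9:
        in_win = (etho.t >= start) & (etho.t < start + window)
        tn = float(etho.flags["explore_nonstat"][in_win].sum()) * dt
        ts = float(etho.flags["explore_stat"][in_win].sum()) * dt
        if tn + ts > 0:
            results.append(discrimination_index(tn, ts, window=(start, start + window)))
        else:
            results.append(None)
        start += step
    return results


def window_di(etho: Ethogram, start: float, end: float) -> DiResult:
    """DI over one absolute time window ``[start, end)``."""
    dt = 1.0 / etho.rate
    in_win = (etho.t >= start) & (etho.t < end)
    tn = float(etho.flags["explore_nonstat"][in_win].sum()) * dt
    ts = float(etho.flags["explore_stat"][in_win].sum()) * dt
    return discrimination_index(tn, ts, window=(start, end))


def extract_bouts(
    flags: np.ndarray,
    t: np.ndarray,
    behavior: str = "",
    min_dur: float = 2.0,
    isolation: float = 4.0,
    session_id: str = "",
) -> BoutSet:
    """Maximal runs of 1s, filtered by minimum duration and temporal isolation.

    A run shorter than ``min_dur`` is discarded. A surviving run is excluded if
    any same-behavior frame (including frames of discarded short runs) lies
    within ``isolation`` seconds before its onset or after its offset. Onsets
    and offsets are half-open ``[onset, offset)`` on the frame clock.
    """
    flags = np.asarray(flags).astype(bool)
    t = np.asarray(t, float)
    if flags.size == 0:
        return BoutSet(behavior, [], min_dur, isolation)
    rate = 1.0 / (t[1] - t[0]) if t.size > 1 else 1.0
    padded = np.concatenate(([False], flags, [False])).astype(int)
    d = np.diff(padded)
    onsets = np.flatnonzero(d == 1)
    offsets = np.flatnonzero(d == -1)
    t_end = t[0] + flags.size / rate
    times = np.concatenate([t, [t_end]])
    bouts = []
    for on, off in zip(onsets, offsets):
        onset_t, offset_t = times[on], times[off]
        if offset_t - onset_t < min_dur:
            continue
        pre = (t >= onset_t - isolation) & (t < onset_t)
        post = (t >= offset_t) & (t < offset_t + isolation)
        if flags[pre].any() or flags[post].any():
            continue
        bouts.append(Bout(behavior, float(onset_t), float(offset_t), session_id))
    return BoutSet(behavior, bouts, min_dur, isolation)


def proportion_of_total(per_behavior_profiles: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Percent share of each behavior at every aligned time point.

    Input: per-behavior mean occupancy profiles on a common event-relative grid
    (rows already averaged over bouts, values in [0, 1]; background included).
    Output percentages sum to 100 at every grid point.
    """
    names = list(per_behavior_profiles)
    stack = np.vstack([np.asarray(per_behavior_profiles[b], float) for b in names])
    total = stack.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("at least one behavior must occur at every aligned time point")
    pct = 100.0 * stack / total
    return {b: pct[i] for i, b in enumerate(names)}
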
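"""Seeded synthetic sessions with the statistical structure the analysis assumes.

Each session consists of a trajectory (neck/nose positions in a square arena),
an ethogram (semi-Markov behavior states with a position-gated object
exploration overlay), a latent cholinergic activity trace in z-units, and the
raw two-channel photometry rendered from that latent trace.

The latent activity is an additive composition

``z(t) = β_speed·log2(max(speed, v0)) + β_groom·I_groom + β_rear·I_rear
+ novelty_amp·I_novel_bout + A·exp(−t/τ) + OU-noise``

so every downstream estimator (speed regression, mixed model, event-triggered
profiles, exponential decay fits) has a known ground truth. The forward model
for the raw channels shares a slow multiplicative bleaching trend and additive
transient motion artifacts across the 465 nm signal and 405 nm control, so the
adjusted-control ΔF/F correction is identifiable:

``F465 = B(t)·(1 + g·z) + M(t) + ε₁``, ``F405 = c₀·B(t) + M(t) + ε₂``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from cholinepipe.behavior import Ethogram, Trajectory, classify_object_exploration, compute_speed
from cholinepipe.photometry import PhotometrySession, SessionMeta

# latent state codes
LOCOMOTION, GROOMING, REARING, BACKGROUND, OBJ_STAT, OBJ_NONSTAT = range(6)
_STATE_NAMES = ("locomotion", "grooming", "rearing", "background", "obj_stat", "obj_nonstat")

SCHEMA_VERSION = 1


@dataclass
class BleachParams:
    """Two-exponential multiplicative bleaching shared across channels."""

    base: float = 200.0  # a.u., F465 level at t = 0
    amp_fast: float = 0.05  # fraction decaying with tau_fast
    tau_fast: float = 60.0  # s
    amp_slow: float = 0.15
    tau_slow: float = 1000.0
    control_scale: float = 0.8  # c0: 405 nm channel brightness relative to 465 nm
    gain: float = 0.05  # g: fractional fluorescence change per z-unit


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-session generator (seeded, deterministic)."""

    seed: int = 0
    phase: str = "sample"  # "sample" or "test"
    session_duration: float = 900.0  # s
    photometry_rate: float = 610.0  # Hz
    video_rate: float = 30.0  # fps
    arena_size: float = 40.0  # cm
    object_centers: dict = field(default_factory=lambda: {
        # sample: two adjacent corners; test: one object moved to a novel corner
        "sample": {"stat": (10.0, 10.0), "nonstat": (30.0, 10.0)},
        "test": {"stat": (10.0, 10.0), "nonstat": (30.0, 30.0)},
    })
    object_radius: float = 10.0  # cm, exploration gating radius around a center
    # latent-activity composition (z-units)
    beta_speed: float = 0.25  # per log2(cm/s)
    beta_groom: float = -0.75
    beta_rear: float = 0.15
    novelty_amp: float = 0.3
    novelty_assignment: str = "phase_dependent"  # both objects in sample, nonstat in test
    recency_amp: float = 2.0  # A
    recency_tau: float = 28.0  # s
    noise_sd: float = 0.5
    ou_timescale: float = 2.0  # s, temporal smoothness of intrinsic activity
    speed_floor: float = 1.0  # cm/s, v0 of the log2 transform
    speed_lead: float = 0.0  # s; > 0 makes activity lead the speed signal
    # behavior dynamics
    dwell_params: dict = field(default_factory=lambda: {
        "locomotion": 8.0, "grooming": 6.0, "rearing": 4.0, "background": 6.0, "object": 6.0,
    })
    state_weights: dict = field(default_factory=lambda: {
        "locomotion": 0.30, "grooming": 0.12, "rearing": 0.16, "background": 0.25, "object": 0.17,
    })
    test_preference: float = 3.0  # nonstat-bout odds multiplier, first 3 min of test
    # speed process
    speed_medians: dict = field(default_factory=lambda: {
        "locomotion": 12.0, "grooming": 0.25, "rearing": 0.6, "background": 1.2,
    })
    approach_speed: float = 14.0  # cm/s toward an object outside its dwell zone
    speed_decay_amp: float = 1.0  # exploratory drive multiplier at t = 0
    speed_decay_tau: float = 45.0  # s
    # photometry forward model
    bleach_params: BleachParams = field(default_factory=BleachParams)
    motion_amp: float = 2.0  # a.u., shared additive artifact peak
    motion_rate: float = 0.05  # Hz, Poisson rate of artifact events
    channel_noise_sd: float = 0.0  # a.u., per-channel white measurement noise

    def __post_init__(self) -> None:
        if self.phase not in ("sample", "test"):
            raise ValueError("phase must be 'sample' or 'test'")
        for name in ("photometry_rate", "video_rate", "recency_tau", "ou_timescale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.session_duration < 60:
            raise ValueError("session_duration must be at least 60 s")
        for phase, objs in self.object_centers.items():
            for key, (x, y) in objs.items():
                if not (0 < x < self.arena_size and 0 < y < self.arena_size):
                    raise ValueError(f"object {phase}/{key} outside arena")
        for name, mean in self.dwell_params.items():
            if mean <= 2.0:
                raise ValueError(f"dwell mean for {name!r} must exceed 2 s")

    @property
    def objects(self) -> dict:
        return self.object_centers[self.phase]


@dataclass
class GroundTruth:
    """Latent activity at video rate plus its additive component breakdown."""

    t: np.ndarray
    rate: float
    z_true: np.ndarray
    components: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        total = sum(self.components.values())
        if not np.allclose(total, self.z_true, atol=1e-10):
            raise ValueError("GroundTruth components must sum to z_true")


@dataclass
class SyntheticSession:
    """Bundle of everything one generated session produces."""

    cfg: GeneratorConfig
    traj: Trajectory
    etho: Ethogram
    truth: GroundTruth
    photometry: PhotometrySession


def _rng(cfg: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _sample_states(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Semi-Markov state sequence at the video rate (exponential dwell times)."""
    names = ["locomotion", "grooming", "rearing", "background", "object"]
    weights = np.array([max(cfg.state_weights.get(n, 0.0), 0.0) for n in names])
    if weights.sum() <= 0:
        raise ValueError("at least one state weight must be positive")
    n = int(round(cfg.session_duration * cfg.video_rate))
    state = np.empty(n, dtype=np.int8)
    t = 0.0
    i = 0
    prev = -1
    while i < n:
        w = weights.copy()
        if prev in (LOCOMOTION, GROOMING, REARING, BACKGROUND):
            w[prev] = 0.0  # no self-transitions among the exclusive states
        if w.sum() <= 0:
            w = weights.copy()
        choice = rng.choice(5, p=w / w.sum())
        if choice == 4:  # object visit: pick which object
            p_nonstat = 0.5
            if cfg.phase == "test" and t < 180.0:
                p_nonstat = cfg.test_preference / (cfg.test_preference + 1.0)
            code = OBJ_NONSTAT if rng.random() < p_nonstat else OBJ_STAT
            mean = cfg.dwell_params["object"]
            dwell = max(2.5, rng.exponential(mean))
        else:
            code = choice
            mean = cfg.dwell_params[names[choice]]
            dwell = max(1.0, rng.exponential(mean))
        n_frames = max(1, int(round(dwell * cfg.video_rate)))
        state[i : i + n_frames] = code
        i += n_frames
        t = i / cfg.video_rate
        prev = code
    return state


def simulate_trajectory(cfg: GeneratorConfig) -> Trajectory:
    """Positions, speed, and the latent behavior-state sequence.

    The speed process relaxes toward a state-conditioned log-normal target with
    an OU timescale of ~1 s; an exploratory-drive multiplier
    ``1 + a·exp(−t/τ_speed)`` elevates early-session speed so the speed-decay /
    recency dissociation is reproducible. During object-visit states the animal
    steers toward the object center, then dwells near it at low speed.
    """
    rng = _rng(cfg, 0)
    state = _sample_states(cfg, rng)
    n = state.size
    dt = 1.0 / cfg.video_rate
    t = np.arange(n) * dt
    L = cfg.arena_size
    margin = 1.0
    objs = cfg.objects

    # per-episode log-normal target speeds for the non-object states
    medians = cfg.speed_medians
    target = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and state[j] == state[i]:
            j += 1
        code = state[i]
        if code in (OBJ_STAT, OBJ_NONSTAT):
            target[i:j] = np.nan  # decided geometrically in the loop
        else:
            med = medians[_STATE_NAMES[code]]
            target[i:j] = med * math.exp(0.35 * rng.standard_normal())
        i = j
    decay = 1.0 + cfg.speed_decay_amp * np.exp(-t / cfg.speed_decay_tau)

    eps_v = rng.standard_normal(n)
    eps_th = rng.standard_normal(n)
    tau_v = 1.0
    sqdt = math.sqrt(dt)
    neck = np.empty((n, 2))
    nose = np.empty((n, 2))
    x = float(rng.uniform(margin + 4, L - margin - 4))
    y = float(rng.uniform(margin + 4, L - margin - 4))
    theta = float(rng.uniform(-math.pi, math.pi))
    v = 2.0
    for i in range(n):
        code = state[i]
        if code >= OBJ_STAT:
            ox, oy = objs["nonstat"] if code == OBJ_NONSTAT else objs["stat"]
            dx, dy = ox - x, oy - y
            d = math.hypot(dx, dy)
            vt = cfg.approach_speed * decay[i] if d > 4.0 else 1.2
            theta = math.atan2(dy, dx) + 0.4 * eps_th[i] * sqdt
        else:
            vt = target[i] * decay[i]
            theta += 1.5 * eps_th[i] * sqdt
        sig = 0.2 * vt + 0.3
        v += (dt / tau_v) * (vt - v) + sig * sqdt * eps_v[i]
        if v < 0.0:
            v = 0.0
        x += v * dt * math.cos(theta)
        y += v * dt * math.sin(theta)
        if x < margin:
            x = 2 * margin - x
            theta = math.pi - theta
        elif x > L - margin:
            x = 2 * (L - margin) - x
            theta = math.pi - theta
        if y < margin:
            y = 2 * margin - y
            theta = -theta
        elif y > L - margin:
            y = 2 * (L - margin) - y
            theta = -theta
        neck[i, 0], neck[i, 1] = x, y
        nose[i, 0] = min(max(x + 3.0 * math.cos(theta), 0.0), L)
        nose[i, 1] = min(max(y + 3.0 * math.sin(theta), 0.0), L)
    traj = Trajectory(t=t, neck_xy=neck, nose_xy=nose, rate=cfg.video_rate, state=state)
    traj.speed = compute_speed(traj)
    return traj


def simulate_ethogram(cfg: GeneratorConfig, traj: Trajectory) -> Ethogram:
    """Frame-wise behavior flags from the latent states plus position gating.

    Object exploration is labeled only on object-visit frames where the nose
    is within ``object_radius`` of the visited object's center; it may co-occur
    with locomotion (fast approach frames) or rearing (object-supported rears),
    the only overlaps the behavior catalogue allows.
    """
    if traj.state is None:
        raise ValueError("trajectory lacks latent states; generate it with simulate_trajectory")
    rng = _rng(cfg, 1)
    state = traj.state
    speed = traj.speed if traj.speed is not None else compute_speed(traj)
    n = state.size
    objs = cfg.objects

    in_obj_state = state >= OBJ_STAT
    explore_raw = np.zeros(n, dtype=bool)
    for code, key in ((OBJ_STAT, "stat"), (OBJ_NONSTAT, "nonstat")):
        sel = state == code
        if sel.any():
            d = np.linalg.norm(traj.nose_xy[sel] - np.asarray(objs[key]), axis=1)
            explore_raw[sel] = d <= cfg.object_radius
    stat, nonstat = classify_object_exploration(
        explore_raw, traj.nose_xy, objs, radius=cfg.object_radius
    )

    locomotion = (state == LOCOMOTION) | (in_obj_state & (speed > 4.0))
    grooming = state == GROOMING
    rearing = (state == REARING) & ~locomotion
    # object-supported rearing: some slow within-radius stretches become rears
    explore_any = stat | nonstat
    slow_explore = explore_any & ~locomotion
    idx = np.flatnonzero(slow_explore)
    if idx.size:
        keep = rng.random(idx.size) < 0.25
        rearing = rearing.copy()
        rearing[idx[keep]] = True
    locomotion = locomotion & ~rearing

    return Ethogram(
        t=traj.t,
        rate=traj.rate,
        flags={
            "locomotion": locomotion,
            "grooming": grooming,
            "rearing": rearing,
            "explore_stat": stat,
            "explore_nonstat": nonstat,
        },
    )


def _novel_indicator(cfg: GeneratorConfig, etho: Ethogram) -> np.ndarray:
    mode = cfg.novelty_assignment
    if mode == "none":
        return np.zeros(etho.n_frames, dtype=bool)
    if mode == "both":
        return etho.explore_any()
    if mode == "phase_dependent":
        if cfg.phase == "sample":
            return etho.explore_any()
        return etho.flags["explore_nonstat"].copy()
    raise ValueError(f"unknown novelty_assignment {mode!r}")


def simulate_ground_truth(cfg: GeneratorConfig, traj: Trajectory, etho: Ethogram) -> GroundTruth:
    """Compose the latent activity from speed, behavior, novelty, recency, noise."""
    t = traj.t
    speed = traj.speed if traj.speed is not None else compute_speed(traj)
    if cfg.speed_lead != 0.0:
        speed = np.interp(t + cfg.speed_lead, t, speed)
    comp = {
        "speed": cfg.beta_speed * np.log2(np.maximum(speed, cfg.speed_floor)),
        "grooming": cfg.beta_groom * etho.flags["grooming"].astype(float),
        "rearing": cfg.beta_rear * etho.flags["rearing"].astype(float),
        "novelty": cfg.novelty_amp * _novel_indicator(cfg, etho).astype(float),
        "recency": cfg.recency_amp * np.exp(-t / cfg.recency_tau),
        "noise": _ou_noise(cfg, t.size),
    }
    z = sum(comp.values())
    return GroundTruth(t=t, rate=traj.rate, z_true=z, components=comp)


def _ou_noise(cfg: GeneratorConfig, n: int) -> np.ndarray:
    if cfg.noise_sd <= 0:
        return np.zeros(n)
    rng = _rng(cfg, 2)
    phi = math.exp(-1.0 / (cfg.video_rate * cfg.ou_timescale))
    innov = rng.standard_normal(n) * cfg.noise_sd * math.sqrt(1.0 - phi * phi)
    innov[0] = rng.standard_normal() * cfg.noise_sd
    from scipy.signal import lfilter

    return lfilter([1.0], [1.0, -phi], innov)


def render_photometry(cfg: GeneratorConfig, truth: GroundTruth, meta: SessionMeta | None = None) -> PhotometrySession:
    """Raw two-channel traces at the photometry rate from the latent activity.

    Bleaching is a shared two-exponential multiplicative trend; motion
    artifacts are Poisson-timed biexponential transients added identically to
    both channels, so the adjusted-control subtraction can remove them.
    """
    rng = _rng(cfg, 3)
    bp = cfg.bleach_params
    n_p = int(round(cfg.session_duration * cfg.photometry_rate))
    t_p = np.arange(n_p) / cfg.photometry_rate
    z_p = np.interp(t_p, truth.t, truth.z_true)
    floor = 1.0 - bp.amp_fast - bp.amp_slow
    bleach = bp.base * (
        floor
        + bp.amp_fast * np.exp(-t_p / bp.tau_fast)
        + bp.amp_slow * np.exp(-t_p / bp.tau_slow)
    )
    motion = _motion_artifacts(cfg, t_p, rng)
    f465 = bleach * (1.0 + bp.gain * z_p) + motion
    f405 = bp.control_scale * bleach + motion
    if cfg.channel_noise_sd > 0:
        f465 = f465 + rng.standard_normal(n_p) * cfg.channel_noise_sd
        f405 = f405 + rng.standard_normal(n_p) * cfg.channel_noise_sd
    if np.any(f465 <= 0):
        raise ValueError("gain drives F465 nonpositive; reduce bleach_params.gain or z amplitude")
    if meta is None:
        meta = SessionMeta(phase=cfg.phase, session_id=f"synth-{cfg.seed}")
    return PhotometrySession(f465=f465, f405=f405, t=t_p, rate=cfg.photometry_rate, meta=meta)


def _motion_artifacts(cfg: GeneratorConfig, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(t.size)
    if cfg.motion_amp <= 0 or cfg.motion_rate <= 0:
        return out
    n_events = rng.poisson(cfg.motion_rate * cfg.session_duration)
    tau_rise, tau_decay = 0.05, 0.5
    # normalize the biexponential kernel to unit peak
    t_pk = (tau_rise * tau_decay / (tau_decay - tau_rise)) * math.log(tau_decay / tau_rise)
    peak = math.exp(-t_pk / tau_decay) - math.exp(-t_pk / tau_rise)
    for t0 in rng.uniform(0, cfg.session_duration, n_events):
        rel = t - t0
        sel = rel >= 0
        kern = np.exp(-rel[sel] / tau_decay) - np.exp(-rel[sel] / tau_rise)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out[sel] += sign * cfg.motion_amp * kern / peak
    return out


def simulate_session(cfg: GeneratorConfig, meta: SessionMeta | None = None) -> SyntheticSession:
    """Full generation chain: trajectory → ethogram → latent activity → channels."""
    traj = simulate_trajectory(cfg)
    etho = simulate_ethogram(cfg, traj)
    truth = simulate_ground_truth(cfg, traj, etho)
    phot = render_photometry(cfg, truth, meta=meta)
    return SyntheticSession(cfg=cfg, traj=traj, etho=etho, truth=truth, photometry=phot)


def write_session(session: SyntheticSession, directory: str | Path) -> Path:
    """Persist one session in the on-disk session-directory format."""
    from cholinepipe import session_io

    return session_io.write_session(session, directory)
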
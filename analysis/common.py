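"""Shared paths and loaders for the numbered analysis scripts.

The demo experiment lives under ``scratch/demo_run`` (bulky per-session HDF5)
and its tables under ``results/`` (small CSV/JSON committed outputs). Scripts
are meant to be run in order from the repository root:

    python analysis/01_simulate_sessions.py
    python analysis/02_preprocess.py
    ...
"""

from pathlib import Path

import numpy as np

from cholinepipe import photometry, session_io, speedcode

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "demo_run"
SESSIONS_DIR = RUN_DIR / "sessions"
RESULTS = ROOT / "results"

#: demo experiment scale: 3 sample/test pairs of 10 min sessions
N_PAIRS = 3
DURATION = 600.0
SEED = 42


def session_dirs():
    if not SESSIONS_DIR.exists():
        raise SystemExit("no sessions found; run analysis/01_simulate_sessions.py first")
    return sorted(p for p in SESSIONS_DIR.iterdir() if p.is_dir())


def load_processed(directory):
    """Session bundle plus its processed ΔF/F and smoothed speed."""
    data = session_io.read_session(directory)
    dff_path = directory / "dff.h5"
    if not dff_path.exists():
        raise SystemExit(f"{directory} has no dff.h5; run analysis/02_preprocess.py first")
    dff = session_io.read_dff(dff_path)
    sp = photometry.moving_average(data.traj.speed, 0.5, data.traj.rate)
    n = min(dff.values.size, sp.size)
    l2s = speedcode.log2_speed(sp[:n])
    return data, dff, l2s, n


def speed_model(dff, l2s, n):
    return speedcode.fit_speed_model(dff.values[:n], l2s, rate=30.0)


def ensure_results():
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
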
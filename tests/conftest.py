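import numpy as np
import pytest

from cholinepipe import photometry, synth


@pytest.fixture(scope="session")
def default_session_300():
    """One default-config synthetic session (shortened to 300 s), reused read-only."""
    cfg = synth.GeneratorConfig(seed=3, session_duration=300.0)
    return synth.simulate_session(cfg)


@pytest.fixture(scope="session")
def dff_300(default_session_300):
    return photometry.preprocess(default_session_300.photometry)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_records(rep_seed, n_pairs=2, dur=300.0, **gen_overrides):
    """Small multi-session experiment as mixed-model input records."""
    records = []
    sessions = []
    for pair in range(n_pairs):
        for phase in ("sample", "test"):
            k = pair * 2 + (phase == "test")
            cfg = synth.GeneratorConfig(
                seed=rep_seed * 1000 + k, session_duration=dur, phase=phase, **gen_overrides
            )
            sess = synth.simulate_session(cfg)
            dff = photometry.preprocess(sess.photometry)
            meta = photometry.SessionMeta(
                mouse_id=f"m{pair % 2}",
                phase=phase,
                oblom_id=pair // 2 + 1,
                session_id=f"s{k}",
            )
            records.append(
                {"dff": dff, "speed": sess.traj.speed, "etho": sess.etho, "meta": meta}
            )
            sessions.append(sess)
    return records, sessions
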
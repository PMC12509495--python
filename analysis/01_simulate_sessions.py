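"""Generate the demo experiment: paired sample/test sessions with ground truth.

Writes one session directory per recording (raw two-channel photometry, pose,
ethogram, object map, latent activity) under scratch/demo_run/sessions.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import DURATION, N_PAIRS, SEED, SESSIONS_DIR

from cholinepipe import behavior, photometry, synth


def main():
    SESSIONS_DIR.mkdir(parents=True, exist_ok=True)
    k = 0
    for pair in range(N_PAIRS):
        for phase in ("sample", "test"):
            cfg = synth.GeneratorConfig(seed=SEED * 1000 + k, phase=phase,
                                        session_duration=DURATION)
            meta = photometry.SessionMeta(mouse_id=f"m{pair % 2}", phase=phase,
                                          oblom_id=pair // 2 + 1, session_id=f"s{k:02d}")
            sess = synth.simulate_session(cfg, meta=meta)
            synth.write_session(sess, SESSIONS_DIR / meta.session_id)
            n_bouts = {
                name: len(behavior.extract_bouts(sess.etho.flags[name], sess.etho.t, name))
                for name in ("locomotion", "grooming", "rearing")
            }
            print(f"{meta.session_id} ({phase}): mean speed "
                  f"{sess.traj.speed.mean():.1f} cm/s, filtered bouts {n_bouts}")
            k += 1
    print(f"\nwrote {k} sessions to {SESSIONS_DIR}")


if __name__ == "__main__":
    main()
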
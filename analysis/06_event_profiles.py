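"""Event-triggered, time-warped profiles and observed-vs-predicted tests.

Pools filtered bouts across sessions per behavior (object exploration split
by phase), warps each bout onto a 5 s / relative-core / 5 s grid, compares
observed to speed-predicted activity with the cluster permutation test
(1000 permutations), and estimates locomotion rise/decay timing via the
98%-threshold rule with a paired signed-rank comparison.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import ensure_results, load_processed, session_dirs, speed_model

from cholinepipe import behavior, clusterstat, eventavg

COMPARISONS = [("locomotion", None), ("grooming", None), ("rearing", None),
               ("explore_stat", "sample"), ("explore_nonstat", "sample"),
               ("explore_stat", "test"), ("explore_nonstat", "test")]


def main():
    results = ensure_results()
    sessions = []
    for directory in session_dirs():
        data, dff, l2s, n = load_processed(directory)
        sessions.append((data, dff, speed_model(dff, l2s, n), n))

    cluster_rows = []
    for name, phase in COMPARISONS:
        obs_rows, pred_rows, durs = [], [], []
        for data, dff, model, n in sessions:
            if phase is not None and data.photometry.meta.phase != phase:
                continue
            bouts = behavior.extract_bouts(data.etho.flags[name], data.etho.t, name)
            for b in bouts:
                try:
                    obs_rows.append(eventavg.warp_bout(dff.values[:n], dff.t[:n], 30.0, b))
                except ValueError:
                    continue
                pred_rows.append(eventavg.warp_bout(model.predicted, dff.t[:n], 30.0, b))
                durs.append(b.duration)
        key = name if phase is None else f"{name}:{phase}"
        if len(obs_rows) < 5:
            print(f"{key}: only {len(obs_rows)} bouts, skipped")
            continue
        dt = np.empty(400)
        dt[:150] = dt[250:] = 1 / 30
        dt[150:250] = np.mean(durs) / 100
        res = clusterstat.cluster_test(np.vstack(obs_rows), np.vstack(pred_rows),
                                       dt=dt, n_perm=1000, seed=7)
        cluster_rows.append({"comparison": key, "n_bouts": len(obs_rows),
                             "n_sig_clusters": len(res.sig_clusters),
                             "min_p": res.min_p,
                             "relative_length_pct": res.relative_length_pct})
        print(f"{key}: {len(obs_rows)} bouts, {len(res.sig_clusters)} significant "
              f"clusters, {res.relative_length_pct:.0f}% of the aligned span")
    pd.DataFrame(cluster_rows).to_csv(results / "event_clusters.csv", index=False)

    timing_rows = []
    for side in ("onset", "offset"):
        obs_t, pred_t = [], []
        for data, dff, model, n in sessions:
            bouts = behavior.extract_bouts(data.etho.flags["locomotion"], data.etho.t,
                                           "locomotion")
            if not len(bouts):
                continue
            o = eventavg.estimate_timing(dff.values[:n], dff.t[:n], 30.0, bouts, side=side)
            p = eventavg.estimate_timing(model.predicted, dff.t[:n], 30.0, bouts, side=side)
            obs_t.append(o.per_bout_crossing)
            pred_t.append(p.per_bout_crossing)
        a, b = np.concatenate(obs_t), np.concatenate(pred_t)
        cmpr = eventavg.timing_comparison(
            eventavg.TimingEstimate(a, float(np.nanmedian(a)), float(np.nanstd(a)),
                                    int(np.isnan(a).sum()), side),
            eventavg.TimingEstimate(b, float(np.nanmedian(b)), float(np.nanstd(b)),
                                    int(np.isnan(b).sum()), side),
        )
        timing_rows.append({"side": side, "median_diff_s": cmpr.median_difference,
                            "p": cmpr.p_value, "n_pairs": cmpr.n_pairs})
        print(f"locomotion {side}: observed-minus-predicted median "
              f"{cmpr.median_difference:+.2f} s (n={cmpr.n_pairs}, p={cmpr.p_value:.2g})")
    pd.DataFrame(timing_rows).to_csv(results / "timing.csv", index=False)


if __name__ == "__main__":
    main()
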
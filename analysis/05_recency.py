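"""Session-start recency signal: exponential decays and their dissociation.

Fits A·exp(−t/τ)+offset to the across-session averages of observed ΔF/F,
speed-predicted ΔF/F, and the speed-adjusted residual over the first 3 min,
then asks where observed exceeds predicted with a cluster-based permutation
test (sessions as paired events, 500 sign-flip permutations).
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from common import ensure_results, load_processed, session_dirs, speed_model

from cholinepipe import clusterstat, speedcode


def main():
    results = ensure_results()
    obs, pred, resid = [], [], []
    fit_window = 180.0
    n_fit = int(fit_window * 30)
    n_span = int(60 * 30)
    early_obs, early_pred = [], []
    for directory in session_dirs():
        data, dff, l2s, n = load_processed(directory)
        model = speed_model(dff, l2s, n)
        obs.append(dff.values[:n_fit])
        pred.append(model.predicted[:n_fit])
        resid.append(model.residual[:n_fit])
        early_obs.append(dff.values[:n_span])
        early_pred.append(model.predicted[:n_span])
    t = np.arange(n_fit) / 30.0
    fits = {
        name: speedcode.fit_exponential_decay(np.mean(series, axis=0), t, fit_window)
        for name, series in (("observed", obs), ("predicted", pred), ("residual", resid))
    }
    res = clusterstat.cluster_test(np.vstack(early_obs), np.vstack(early_pred),
                                   dt=1 / 30.0, n_perm=500, seed=7)
    doc = {name: {"A": f.A, "tau_s": f.tau, "offset": f.offset} for name, f in fits.items()}
    doc["cluster"] = [
        {"start_s": c.start_idx / 30.0, "length_s": c.length_s,
         "p_mass": c.p_mass, "p_length": c.p_length, "sign": c.sign}
        for c in res.sig_clusters
    ]
    with open(results / "recency.json", "w") as f:
        json.dump(doc, f, indent=1)
    for name, f in fits.items():
        print(f"{name:9s}: A={f.A:6.2f}  tau={f.tau:6.1f} s  offset={f.offset:6.2f}")
    if res.sig_clusters:
        c = min(res.sig_clusters, key=lambda c: c.start_idx)
        print(f"\nobserved > predicted from {c.start_idx / 30:.2f} s for "
              f"{c.length_s:.2f} s (p_mass={c.p_mass:.3g})")
    else:
        print("\nno significant observed-vs-predicted divergence cluster")


if __name__ == "__main__":
    main()
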
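"""Speed coding of cholinergic activity: linear vs log2, and its timescale.

Per session: Pearson r of ΔF/F with speed and with log2 speed (paired
comparison across sessions), the regression slope, and the correlation as a
function of smoothing-window size (0.25–256 s); the experiment-level best
timescale is the argmax of the session-averaged curve.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

sys.path.insert(0, str(Path(__file__).parent))
from common import ensure_results, load_processed, session_dirs, speed_model

from cholinepipe import photometry, speedcode


def main():
    results = ensure_results()
    rows, curves = [], []
    for directory in session_dirs():
        data, dff, l2s, n = load_processed(directory)
        sp = photometry.moving_average(data.traj.speed, 0.5, 30.0)[:n]
        model = speed_model(dff, l2s, n)
        curve = speedcode.timescale_correlation(dff.values[:n], l2s, 30.0)
        curves.append(curve.r)
        rows.append({
            "session_id": data.photometry.meta.session_id,
            "phase": data.photometry.meta.phase,
            "r_speed": np.corrcoef(dff.values[:n], sp)[0, 1],
            "r_log2speed": model.r,
            "slope": model.slope,
            "se_slope_eff": model.se_slope_eff,
            "best_window_s": curve.best_window,
        })
    df = pd.DataFrame(rows)
    df.to_csv(results / "speed_code.csv", index=False)
    mean_r = np.nanmean(np.vstack(curves), axis=0)
    pd.DataFrame({"window_s": curve.windows, "mean_r": mean_r}).to_csv(
        results / "timescale_curve.csv", index=False
    )
    tstat, p = stats.ttest_rel(df["r_log2speed"], df["r_speed"])
    print(df[["session_id", "r_speed", "r_log2speed", "slope"]].round(3).to_string(index=False))
    print(f"\nR(log2 speed) {df['r_log2speed'].mean():.3f} vs R(speed) "
          f"{df['r_speed'].mean():.3f}; paired t={tstat:.2f}, p={p:.2g}")
    print(f"best timescale of the mean curve: "
          f"{curve.windows[np.nanargmax(mean_r)]:.2f} s")


if __name__ == "__main__":
    main()
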
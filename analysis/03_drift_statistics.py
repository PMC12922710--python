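#!/usr/bin/env python
"""Fixational drift statistics of the synthetic cohort.

From the curated trials of script 02: mean drift velocity per observer,
growth of retinal slip with presentation duration (linearity check), and a
standalone Brownian-mode MSD calibration (ensemble slope vs 4D).  Writes
results/drift_stats.json.
"""

import json

import numpy as np
import pandas as pd

from common import RESULTS, SCRATCH_DIR
from conedrift import eye_motion as em
from conedrift import report as rp
from conedrift import synth

T_FRAME = 1000.0 / 27.0


def main() -> None:
    kept = pd.read_csv(SCRATCH_DIR / "kept_trials.csv")

    print("Mean drift velocity per observer (curated trials):")
    vel = kept.groupby("observer").velocity_arcmin_s.mean()
    for name, v in vel.items():
        print(f"  {name}: {v:.1f} arcmin/s")

    # slip grows linearly across the four longer durations
    longer = kept[kept.duration > 3]
    mean_slip = longer.groupby("duration").slip_arcmin.mean()
    slope, intercept, r2, p = rp.regress(mean_slip.index.to_numpy(float),
                                         mean_slip.to_numpy())
    print("\nMean retinal slip by duration (arcmin):")
    for d, s in mean_slip.items():
        print(f"  {d:>4} ms: {s:.2f}")
    print(f"Linear growth: slope {slope * 1000:.2f} arcmin/s of duration, "
          f"R^2 = {r2:.3f}")

    # Brownian-mode MSD calibration: ensemble slope vs 4D
    D = 2.5
    rng = np.random.default_rng(123)
    msds = []
    for _ in range(500):
        tr, fon = synth.gen_drift(600, 0.0, rng, diffusion=D,
                                  mean_reversion=0.0, start_spread=0.0,
                                  trace_jitter=0.0)
        ds = em.downsample(tr)
        msds.append(em.msd_curve(ds.xy_arcmin[fon[0]:], T_FRAME)[1])
    n = min(len(m) for m in msds)
    lags_s = np.arange(n) * T_FRAME / 1000.0
    slope_msd = np.polyfit(lags_s, np.mean([m[:n] for m in msds], axis=0), 1)[0]
    print(f"\nBrownian-mode MSD slope: {slope_msd:.2f} arcmin^2/s "
          f"(4D = {4 * D:.1f})")

    out = {
        "mean_velocity_arcmin_s": {k: round(v, 2) for k, v in vel.items()},
        "mean_slip_by_duration_arcmin": {str(d): round(s, 3)
                                         for d, s in mean_slip.items()},
        "slip_linearity_r2": round(r2, 4),
        "msd_slope_arcmin2_s": round(float(slope_msd), 3),
        "msd_expected_4d": 4 * D,
    }
    (RESULTS / "drift_stats.json").write_text(json.dumps(out, indent=2))
    print(f"Wrote {RESULTS / 'drift_stats.json'}")


if __name__ == "__main__":
    main()
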
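#!/usr/bin/env python
"""Reference-cohort arithmetic: Nyquist limits from printed densities,
cohort drift statistics, and the drift/fixation-offset regressions.

Everything here is computed from the embedded seven-observer reference
table; it establishes the anchor numbers the synthetic pipeline is judged
against.  Writes results/reference_cohort.json.
"""

import json
from pathlib import Path

import numpy as np

from conedrift import report as rp

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    t1 = rp.table1_fixture()
    nc = rp.nyquist_from_table_density(t1.density_cones_deg2)
    print("Closed-form lattice conversion density -> Nyquist limit (arcsec):")
    for p, d, printed, computed in zip(t1.participant, t1.density_cones_deg2,
                                       t1.nyquist_arcsec, nc):
        print(f"  {p}: {d:>6.0f} cones/deg^2 -> {computed:5.2f} "
              f"(printed {printed})")

    stats = rp.summarize_cohort(t1)
    drift = stats.loc["drift_length_600ms_arcmin"]
    vel = stats.loc["velocity_arcmin_s"]
    print(f"\nCohort: mean 600-ms drift length {drift['mean']:.2f} arcmin "
          f"(max/min ratio {drift['max_min_ratio']:.2f}); "
          f"mean drift velocity {vel['mean']:.1f} arcmin/s")

    sl, ic, r2_len, p_len = rp.regress(t1.isoa_cdc_offset_arcmin,
                                       t1.drift_length_600ms_arcmin)
    sv, iv, r2_vel, p_vel = rp.regress(t1.isoa_cdc_offset_arcmin,
                                       t1.velocity_arcmin_s)
    print(f"Drift length (600 ms) ~ ISOA-CDC offset: R^2={r2_len:.2f}, "
          f"p={p_len:.3f}")
    print(f"Drift velocity ~ ISOA-CDC offset:        R^2={r2_vel:.2f}, "
          f"p={p_vel:.3f}")

    OUT.mkdir(exist_ok=True)
    out = {
        "nyquist_from_density_arcsec": dict(zip(t1.participant,
                                                np.round(nc, 2))),
        "mean_drift_length_600ms_arcmin": round(float(drift["mean"]), 3),
        "drift_length_max_min_ratio": round(float(drift["max_min_ratio"]), 3),
        "mean_drift_velocity_arcmin_s": round(float(vel["mean"]), 3),
        "r2_drift_length_vs_offset": round(r2_len, 4),
        "p_drift_length_vs_offset": round(p_len, 4),
        "r2_velocity_vs_offset": round(r2_vel, 4),
        "p_velocity_vs_offset": round(p_vel, 4),
    }
    (OUT / "reference_cohort.json").write_text(json.dumps(out, indent=2,
                                                          default=float))
    print(f"\nWrote {OUT / 'reference_cohort.json'}")


if __name__ == "__main__":
    main()
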
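"""Study-level summaries: per-observer metrics, Nyquist-normalized
thresholds, cohort statistics, and simple regressions.

The module ships the published reference cohort table (seven observers:
cone density and Nyquist limit at the CDC, drift velocity, 600-ms drift
length and variance, seeing-cone area/count, and the ISOA-centroid-to-CDC
offset) as a fixture for cross-checks, and provides the trial-based
normalization of acuity thresholds: the per-condition Nyquist limit is
computed from the mean ICD of the seeing cones actually engaged in that
condition's trials, N_c = sqrt(3)/2 x mean ICD, and the normalized
threshold is threshold / N_c (unitless; 1.0 means acuity equal to the
local sampling limit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError
from .mosaic import SQRT3, icd_from_density, nyquist_limit


def table1_fixture() -> pd.DataFrame:
    """The reference cohort table (printed values, one row per observer)."""
    with resources.files("conedrift.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass
class ObserverSummary:
    """Per-observer metrics in the reference-table schema."""

    observer: str
    density_at_cdc: float
    nyquist_at_cdc: float
    mean_velocity_arcmin_s: float
    drift_length_600ms: float
    drift_variance_600ms: float
    seeing_area_deg2: float
    seeing_count: int
    isoa_cdc_offset_arcmin: float
    thresholds_arcsec: dict = field(default_factory=dict)      # duration -> arcsec
    thresholds_normalized: dict = field(default_factory=dict)  # duration -> x N_c

    def as_row(self) -> dict:
        row = {
            "observer": self.observer,
            "density_cones_deg2": self.density_at_cdc,
            "nyquist_arcsec": self.nyquist_at_cdc,
            "velocity_arcmin_s": self.mean_velocity_arcmin_s,
            "drift_length_600ms_arcmin": self.drift_length_600ms,
            "drift_variance_arcmin2": self.drift_variance_600ms,
            "seeing_area_deg2": self.seeing_area_deg2,
            "seeing_count": self.seeing_count,
            "isoa_cdc_offset_arcmin": self.isoa_cdc_offset_arcmin,
        }
        for d, t in self.thresholds_arcsec.items():
            row[f"threshold_{d}ms_arcsec"] = t
        for d, t in self.thresholds_normalized.items():
            row[f"threshold_{d}ms_nyquist"] = t
        return row


def trial_based_nyquist(seeing_icds: list) -> float:
    """Per-condition Nyquist limit from the ICDs (arcsec) of the seeing
    cones across that condition's trials: sqrt(3)/2 x mean ICD."""
    arrays = [np.atleast_1d(np.asarray(v, float)) for v in seeing_icds]
    arrays = [a for a in arrays if a.size]
    if not arrays:
        raise DegenerateInputError("no seeing-cone ICDs supplied")
    pooled = np.concatenate(arrays)
    return float(np.nanmean(pooled) * SQRT3 / 2.0)


def normalize_thresholds(thresholds: dict, seeing_icds_by_condition: dict,
                         cdc_nyquist: float | None = None) -> dict:
    """Threshold / trial-based N_c per condition.

    If a condition has no seeing cones, its N_c falls back to the CDC
    Nyquist limit with a warning.
    """
    out = {}
    for cond, thr in thresholds.items():
        icds = seeing_icds_by_condition.get(cond, [])
        try:
            nc = trial_based_nyquist(icds)
        except DegenerateInputError:
            if cdc_nyquist is None:
                raise
            warnings.warn(f"condition {cond}: empty seeing set, "
                          "falling back to CDC Nyquist limit")
            nc = cdc_nyquist
        out[cond] = float(thr / nc)
    return out


def nyquist_from_table_density(density_cones_deg2) -> np.ndarray:
    """Closed-form lattice conversion density -> ICD -> N_c (arcsec)."""
    return nyquist_limit(icd_from_density(density_cones_deg2))


def summarize_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD, min, max, and max/min ratio of every numeric column."""
    if len(df) < 2:
        raise DegenerateInputError("need >= 2 observers")
    num = df.select_dtypes(include=[np.number])
    out = pd.DataFrame({
        "mean": num.mean(),
        "sd": num.std(ddof=1),
        "min": num.min(),
        "max": num.max(),
    })
    out["max_min_ratio"] = out["max"] / out["min"]
    return out


def regress(x, y):
    """Ordinary least squares of y on x.

    Returns ``(slope, intercept, r2, p)``; R^2 is the squared Pearson
    correlation and p the two-sided slope t-test.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateInputError("need equal-length vectors, n >= 3")
    if np.allclose(x, x[0]):
        raise DegenerateInputError("zero-variance predictor")
    res = stats.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue**2), float(res.pvalue))
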
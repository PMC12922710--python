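"""End-to-end analysis orchestration.

``analyze_experiment`` runs the full chain on a dataset — curation (motion
and delivery flags), frame-resolved drift statistics, the seeing-cones
light-capture model, ISOA landing statistics, staircase pooling, Weibull
threshold fits, and Nyquist normalization — and returns a cohort table in
the reference schema plus per-observer detail.  ``RunConfig`` gathers every
analysis constant in one serializable place; a run is reproducible from its
archived config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import capture as cap
from . import eye_motion as em
from . import mosaic as mz
from . import optics as op
from . import psychophysics as psy
from . import report as rp
from .errors import (FitError, BinningError, DegenerateInputError,
                     OutOfDomainError)
from .synth import Experiment, ScenarioConfig, gen_experiment


@dataclass
class RunConfig:
    """All analysis switches and thresholds (single source of truth)."""

    k_density: int = 150               # cones averaged per density-map pixel
    density_pitch_arcsec: float = 12.0
    density_half_extent_deg: float = 0.25
    aperture_fraction: float = 0.48    # aperture diameter / local ICD
    aperture_convention: str = "fwhm"
    seeing_threshold: float = 0.01     # fraction of trial light
    v_max_arcmin_s: float = 30.0       # microsaccade criterion
    smooth_ms: float = 15.0
    delivery_threshold: float = 0.8
    isoa_mass: float = 0.68
    min_hits: int = 10                 # core seeing-cone criterion
    bin_width_range: tuple = (5.0, 11.0)
    min_bins: int = 7
    n_boot: int = 0                    # bootstrap resamples for threshold CIs
    t_ref_ms: float = 600.0
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "bin_width_range" in d:
            d["bin_width_range"] = tuple(d["bin_width_range"])
        return cls(**d)


@dataclass
class ObserverDetail:
    summary: rp.ObserverSummary
    kept: pd.DataFrame
    excluded: pd.DataFrame
    seeing_counts: np.ndarray
    core_fraction: float
    isoa: cap.IsoaSummary
    fits: dict                        # duration -> PsychometricFit (or None)
    nyquist_by_condition: dict        # duration -> trial-based N_c


def simulate_dataset(cfg: ScenarioConfig | None = None) -> Experiment:
    """Generate a synthetic dataset (thin wrapper over the generator)."""
    return gen_experiment(cfg)


def _flag_trials(trials: pd.DataFrame, traces: list, cfg: RunConfig):
    micro, blink = [], []
    for _, row in trials.iterrows():
        tr = traces[row.trace_index]
        micro.append(em.flag_microsaccade(tr, cfg.v_max_arcmin_s, cfg.smooth_ms))
        blink.append(em.flag_blink(tr))
    out = trials.copy()
    out["microsaccade"] = micro
    out["blink"] = blink
    return out


def analyze_observer(obs, trials: pd.DataFrame, traces: list,
                     frames_on: list, cfg: RunConfig,
                     raster: op.RasterSpec | None = None) -> ObserverDetail:
    """Run curation, drift statistics, light capture, and threshold fits
    for one observer."""
    raster = raster or op.RasterSpec()
    pitch = raster.pixel_pitch_arcsec
    psf = op.diffraction_psf(raster)
    rng = np.random.default_rng(cfg.seed)

    # --- density map and CDC (grid clamped to the square inscribed in the
    # mosaic so corners stay inside the convex hull)
    from scipy.spatial import ConvexHull
    hull = ConvexHull(obs.mosaic.positions)
    r_in = np.min(np.linalg.norm(
        obs.mosaic.positions[hull.vertices], axis=1))
    h = min(cfg.density_half_extent_deg, 0.95 * r_in / np.sqrt(2.0))
    dmap = mz.density_map(obs.mosaic, grid_spec=(-h, h, -h, h),
                          k=cfg.k_density,
                          pixel_pitch_arcsec=cfg.density_pitch_arcsec)
    cdc = mz.find_cdc(dmap)
    iy = np.argmin(np.abs(dmap.y - cdc[1]))
    ix = np.argmin(np.abs(dmap.x - cdc[0]))
    density_cdc = float(dmap.grid[iy, ix])
    nyq_cdc = rp.nyquist_from_table_density(density_cdc)

    # --- curation
    flagged = _flag_trials(trials, traces, cfg)
    kept, excluded = psy.curate(flagged)

    # --- per-trial drift + capture
    apertures = cap.build_apertures(obs.mosaic, cfg.aperture_fraction,
                                    cfg.aperture_convention)
    img_cache: dict = {}

    def activation_image(size, orientation):
        key = (round(size, 2), orientation)
        if key not in img_cache:
            img_cache[key] = op.trim_activation(op.retinal_image(
                op.make_tumbling_e(size, orientation, raster), psf))
        return img_cache[key]

    slip, vel, landing, seeing_sets, msd_curves = [], [], [], [], []
    seeing_icds_by_cond: dict = {int(d): [] for d in kept.duration.unique()}
    n_cones = obs.mosaic.n_cones
    for _, row in kept.iterrows():
        tr = traces[row.trace_index]
        fon = frames_on[row.trace_index]
        ds = em.downsample(tr)
        fxy = ds.xy_arcmin[fon]
        if len(fon) == 1:
            slip.append(0.0)       # single-frame: zero-slip assumption
            vel.append(np.nan)
        else:
            slip.append(em.slip_length(fxy))
            vel.append(em.mean_velocity(fxy, ds.frame_period_ms))
        after = ds.xy_arcmin[fon[0]:]
        msd_curves.append(em.msd_curve(after, ds.frame_period_ms))
        pos_deg = fxy[:1] / 60.0 if len(fon) == 1 else fxy / 60.0
        act = activation_image(row.size, row.orientation)
        amap = cap.capture_trial(act, pitch, apertures, pos_deg,
                                 seeing_threshold=cfg.seeing_threshold)
        seeing_sets.append(amap.seeing_indices)
        icds = obs.mosaic.icd[amap.seeing_indices]
        seeing_icds_by_cond[int(row.duration)].append(icds[np.isfinite(icds)])
        landing.append(fxy.mean(axis=0))

    kept = kept.assign(slip_arcmin=slip, velocity_arcmin_s=vel,
                       n_seeing=[len(s) for s in seeing_sets])
    counts = cap.seeing_heatmap(seeing_sets, n_cones)
    core = cap.core_fraction(counts, cfg.min_hits)
    try:
        iso = cap.isoa(np.array(landing), cfg.isoa_mass,
                       cdc=(cdc[0] * 60.0, cdc[1] * 60.0))
    except DegenerateInputError:   # too few landing points for a KDE region
        center = np.mean(landing, axis=0)
        off = float(np.hypot(center[0] - cdc[0] * 60.0,
                             center[1] - cdc[1] * 60.0))
        iso = cap.IsoaSummary(tuple(center), float("nan"), float("nan"),
                              float("nan"), off)

    # --- aggregate drift statistics
    vel_arr = kept.velocity_arcmin_s.to_numpy()
    mean_vel = float(np.nanmean(vel_arr)) if np.any(np.isfinite(vel_arr)) else np.nan
    longest = kept.duration.max()
    drift_len = float(kept.loc[kept.duration == longest, "slip_arcmin"].mean())
    try:
        dvar = em.drift_variance(msd_curves, cfg.t_ref_ms)
    except (DegenerateInputError, OutOfDomainError):
        dvar = float("nan")
    ever = counts > 0
    seeing_area = float(np.nansum(obs.mosaic.cell_areas[ever]))

    # --- thresholds per condition
    fits, thresholds, normalized, nyq_by_cond = {}, {}, {}, {}
    for d in sorted(int(x) for x in kept.duration.unique()):
        sub = kept[kept.duration == d]
        try:
            bins = psy.bin_trials(sub["size"].to_numpy(),
                                  sub["correct"].to_numpy(),
                                  cfg.bin_width_range, cfg.min_bins)
            fit = psy.fit_psychometric(bins, n_boot=cfg.n_boot, rng=rng,
                                       sizes=sub["size"].to_numpy(),
                                       correct=sub["correct"].to_numpy())
        except (FitError, BinningError):
            fits[d] = None
            continue
        fits[d] = fit
        thresholds[d] = fit.threshold
        nyq_by_cond[d] = rp.trial_based_nyquist(seeing_icds_by_cond[d])
    normalized = rp.normalize_thresholds(
        thresholds, {d: seeing_icds_by_cond[d] for d in thresholds},
        cdc_nyquist=nyq_cdc)

    summary = rp.ObserverSummary(
        observer=getattr(obs, "name", "obs"),
        density_at_cdc=density_cdc, nyquist_at_cdc=float(nyq_cdc),
        mean_velocity_arcmin_s=mean_vel, drift_length_600ms=drift_len,
        drift_variance_600ms=dvar, seeing_area_deg2=seeing_area,
        seeing_count=int(ever.sum()),
        isoa_cdc_offset_arcmin=float(iso.offset_to_cdc),
        thresholds_arcsec=thresholds, thresholds_normalized=normalized)
    return ObserverDetail(summary, kept, excluded, counts, core, iso,
                          fits, nyq_by_cond)


def analyze_experiment(exp: Experiment, cfg: RunConfig | None = None):
    """Analyze every observer; returns ``(cohort_df, details, exclusion_rate)``."""
    cfg = cfg or RunConfig()
    details, rows = {}, []
    n_total = n_excl = 0
    for obs in exp.observers:
        trials = exp.trials[exp.trials.observer == obs.name]
        det = analyze_observer(obs, trials, exp.traces[obs.name],
                               exp.frames_on[obs.name], cfg)
        details[obs.name] = det
        rows.append(det.summary.as_row())
        n_total += len(trials)
        n_excl += len(det.excluded)
    cohort = pd.DataFrame(rows)
    return cohort, details, n_excl / n_total if n_total else 0.0


def write_report(cohort: pd.DataFrame, details: dict, rate: float,
                 outdir) -> None:
    """Persist the cohort table (CSV) and a JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    rep = {"exclusion_rate": rate,
           "observers": {name: {
               "core_fraction": det.core_fraction,
               "isoa_area": det.isoa.area,
               "isoa_offset_to_cdc_arcmin": det.isoa.offset_to_cdc,
               "thresholds_arcsec": {str(k): v for k, v in
                                     det.summary.thresholds_arcsec.items()},
               "thresholds_normalized": {str(k): v for k, v in
                                         det.summary.thresholds_normalized.items()},
           } for name, det in details.items()}}
    (outdir / "report.json").write_text(json.dumps(rep, indent=2))
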
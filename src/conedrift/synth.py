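"""Synthetic AOSLO micro-psychophysics experiments.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage can be exercised without recorded data:

* quasi-hexagonal foveolar mosaics — jittered triangular lattices with a
  radial density falloff and peak densities in the ~11,700-18,000
  cones/deg^2 range,
* fixational drift — a random walk at the video-frame timescale with a
  fixed step length calibrated to the target mean velocity (10-17.5
  arcmin/s), i.i.d. step directions, and weak mean reversion toward a
  habitual fixation locus offset from the mosaic center; traces are
  linearly interpolated to the 864-Hz native rate and carry small
  registration jitter.  (A literal Brownian path has sampling-rate-
  dependent length, which would make a mean-velocity target ill-posed;
  the frame-scale walk keeps frame-resolved slip exactly calibrated while
  preserving linear MSD, D = v^2 T / 4.  Setting ``drift_diffusion``
  switches to Gaussian increments with that diffusion constant.)
* artifacts — microsaccade-like fast ramps and blink dropouts injected
  into a configurable fraction of trials (default 30%, matching typical
  curation losses),
* a simulated 4AFC observer whose percent correct follows a Weibull
  function of stimulus size with duration-dependent true thresholds
  expressed as multipliers of the trial-based cone Nyquist limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import capture as cap
from . import eye_motion as em
from . import mosaic as mz
from . import optics as op
from . import psychophysics as psy
from .errors import ConfigError

# canonical frame counts for the nominal durations (ms)
FRAMES_PER_DURATION = {3: 1, 80: 3, 220: 7, 370: 11, 600: 16}
DEFAULT_MULTIPLIERS = {3: 1.07, 80: 0.90, 220: 0.83, 370: 0.78, 600: 0.75}


@dataclass
class ScenarioConfig:
    """Study conditions for a synthetic experiment."""

    n_observers: int = 7
    density_peak_range: tuple = (11_700.0, 18_000.0)   # cones/deg^2
    density_falloff: float = 0.15      # fractional density decline per degree
    lattice_jitter: float = 0.08       # SD of positional jitter, x local spacing
    drift_velocity_range: tuple = (10.0, 17.5)         # arcmin/s
    drift_diffusion: float | None = None               # arcmin^2/s (optional)
    fixation_offset_range: tuple = (0.0, 7.0)          # arcmin, ISOA->CDC target
    start_spread_arcmin: float = 1.5
    mean_reversion: float = 0.03       # per frame, toward the fixation locus
    trace_jitter_arcmin: float = 0.02  # native-rate registration noise
    artifact_rate: float = 0.30
    durations: tuple = (3, 80, 220, 370, 600)          # ms
    true_normalized_thresholds: dict = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLIERS))
    beta_true: float = 3.0
    lapse_true: float = 0.01
    runs_per_condition: int = 5
    trials_per_run: int = 23
    mosaic_radius_deg: float = 0.42
    onset_frame: int = 8
    trace_len_ms: float = 1000.0
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_observers < 1:
            bad.append("n_observers")
        for name in ("density_peak_range", "drift_velocity_range",
                     "fixation_offset_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                bad.append(name)
        if not 0 <= self.artifact_rate <= 1:
            bad.append("artifact_rate")
        if tuple(sorted(self.durations)) != tuple(self.durations):
            bad.append("durations (must be ascending)")
        for d in self.durations:
            if d not in self.true_normalized_thresholds:
                bad.append(f"true_normalized_thresholds[{d}]")
        if any(m <= 0 for m in self.true_normalized_thresholds.values()):
            bad.append("true_normalized_thresholds (must be positive)")
        if self.runs_per_condition < 1 or self.trials_per_run < 1:
            bad.append("runs_per_condition/trials_per_run")
        if bad:
            raise ConfigError("invalid scenario fields: " + ", ".join(bad))


def frames_for_duration(duration_ms: float,
                        raster: op.RasterSpec | None = None) -> int:
    """Number of stimulus-on video frames for a nominal duration."""
    if duration_ms in FRAMES_PER_DURATION:
        return FRAMES_PER_DURATION[duration_ms]
    raster = raster or op.RasterSpec()
    return max(1, int(round(duration_ms / raster.frame_period_ms)))


def gen_mosaic(peak_density: float, rng: np.random.Generator, *,
               falloff: float = 0.15, jitter: float = 0.08,
               radius_deg: float = 0.42) -> mz.ConeMosaic:
    """Jittered triangular lattice with a radial density falloff.

    The lattice is generated at the peak spacing and radially remapped so
    local density declines by ``falloff`` per degree of eccentricity;
    positional jitter has SD ``jitter`` x local spacing per axis.
    """
    s0 = mz.icd_from_density(peak_density) / mz.DEG2ARCSEC
    pts = mz.triangular_lattice(s0, radius_deg)
    r = np.linalg.norm(pts, axis=1)
    scale = 1.0 + falloff * r / 3.0          # pushes density down by ~falloff/deg
    pts = pts * scale[:, None]
    if jitter > 0:
        s_local = s0 * (1.0 + falloff * r / 2.0)
        pts = pts + rng.normal(0.0, 1.0, pts.shape) * (jitter * s_local)[:, None]
    return mz.ConeMosaic(pts)


def gen_drift(duration_ms: float, velocity: float, rng: np.random.Generator, *,
              offset_arcmin=(0.0, 0.0), diffusion: float | None = None,
              mean_reversion: float = 0.03, start_spread: float = 1.5,
              trace_jitter: float = 0.02, artifact: str | None = None,
              raster: op.RasterSpec | None = None, onset_frame: int = 8,
              trace_len_ms: float = 1000.0,
              native_rate: float = 864.0) -> tuple[em.DriftTrace, np.ndarray]:
    """One native-rate trace plus the indices of the stimulus-on frames.

    Positions are drawn at frame centers (fixed step length v*T, random
    direction, weak mean reversion toward ``offset_arcmin``), then linearly
    interpolated to the native rate with added registration jitter.
    ``artifact`` in {None, 'microsaccade', 'blink'} injects a >30 arcmin/s
    ramp or a dropout overlapping the stimulus window.
    """
    raster = raster or op.RasterSpec()
    T = raster.frame_period_ms
    n_frames = int(np.floor(trace_len_ms / T))
    centers = (np.arange(n_frames) + 0.5) * T
    mu = np.asarray(offset_arcmin, float)

    pos = np.empty((n_frames, 2))
    pos[0] = mu + rng.normal(0.0, start_spread, 2)
    if diffusion is not None:
        sd = np.sqrt(2.0 * diffusion * T / 1000.0)
        steps = rng.normal(0.0, sd, (n_frames - 1, 2))
    else:
        L = velocity * T / 1000.0
        ang = rng.uniform(0, 2 * np.pi, n_frames - 1)
        steps = L * np.column_stack([np.cos(ang), np.sin(ang)])
    for k in range(n_frames - 1):
        pos[k + 1] = pos[k] + steps[k] + mean_reversion * (mu - pos[k])

    t = np.arange(0.0, trace_len_ms, 1000.0 / native_rate)
    x = np.interp(t, centers, pos[:, 0])
    y = np.interp(t, centers, pos[:, 1])
    if trace_jitter > 0:
        x = x + rng.normal(0, trace_jitter, len(t))
        y = y + rng.normal(0, trace_jitter, len(t))
    valid = np.ones(len(t), bool)

    n_on = frames_for_duration(duration_ms, raster)
    frames_on = np.arange(onset_frame, onset_frame + n_on)
    sweep = op.sweep_time(40, raster)  # ~3 ms for the largest optotype
    window = (onset_frame * T, onset_frame * T + (n_on - 1) * T + sweep)

    if artifact == "microsaccade":
        dur = 20.0
        t0 = rng.uniform(window[0] - dur / 2,
                         max(window[0] - dur / 2, window[1] - dur / 2))
        speed = rng.uniform(45.0, 90.0)
        ang = rng.uniform(0, 2 * np.pi)
        ramp = speed / 1000.0 * np.clip(t - t0, 0.0, dur)
        x = x + ramp * np.cos(ang)
        y = y + ramp * np.sin(ang)
    elif artifact == "blink":
        dur = 120.0
        t0 = rng.uniform(window[0] - dur + 10.0, window[1] - 10.0)
        valid &= ~((t >= t0) & (t <= t0 + dur))
    elif artifact is not None:
        raise ConfigError(f"unknown artifact type {artifact!r}")

    trace = em.DriftTrace(t, np.column_stack([x, y]), valid=valid,
                          rate_hz=native_rate, frame_rate_hz=raster.frame_rate_hz,
                          stimulus_window=window)
    return trace, frames_on


@dataclass
class SyntheticObserver:
    name: str
    peak_density: float
    velocity: float
    fixation_offset: np.ndarray       # arcmin
    mosaic: mz.ConeMosaic
    apertures: cap.ApertureMap


@dataclass
class Experiment:
    """A complete synthetic dataset."""

    config: ScenarioConfig
    observers: list
    trials: pd.DataFrame              # one row per trial
    traces: dict                      # observer name -> list of DriftTrace
    frames_on: dict                   # observer name -> list of index arrays
    manifest: dict


def _observer_params(cfg: ScenarioConfig, rng: np.random.Generator):
    n = cfg.n_observers
    lo, hi = cfg.density_peak_range
    dens = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2])
    vel = rng.uniform(*cfg.drift_velocity_range, n)
    off_mag = rng.uniform(*cfg.fixation_offset_range, n)
    off_ang = rng.uniform(0, 2 * np.pi, n)
    offsets = off_mag[:, None] * np.column_stack([np.cos(off_ang),
                                                  np.sin(off_ang)])
    return dens, vel, offsets


def gen_observer(cfg: ScenarioConfig, name: str, peak_density: float,
                 velocity: float, offset_arcmin,
                 rng: np.random.Generator) -> SyntheticObserver:
    mosaic = gen_mosaic(
        peak_density, rng, falloff=cfg.density_falloff,
        jitter=cfg.lattice_jitter, radius_deg=cfg.mosaic_radius_deg)
    tessellated = mz.tessellate(mosaic)
    apertures = cap.build_apertures(tessellated)
    return SyntheticObserver(name, peak_density, velocity,
                             np.asarray(offset_arcmin, float), tessellated,
                             apertures)


def gen_experiment(cfg: ScenarioConfig | None = None,
                   raster: op.RasterSpec | None = None) -> Experiment:
    """Generate mosaics, drift traces, staircase trial logs, and simulated
    responses for the whole scenario.

    The observer's true threshold on each trial is ``multiplier x N_c``
    where N_c is the trial-based Nyquist limit of the cones actually seeing
    that trial's stimulus, so mosaic density and acuity are linked.
    """
    cfg = cfg or ScenarioConfig()
    cfg.validate()
    raster = raster or op.RasterSpec()
    master = np.random.SeedSequence(cfg.seed)
    obs_seeds = master.spawn(cfg.n_observers)
    pitch = raster.pixel_pitch_arcsec
    psf = op.diffraction_psf(raster)

    dens, vel, offsets = _observer_params(
        cfg, np.random.default_rng(master.spawn(1)[0]))

    observers, rows = [], []
    traces: dict[str, list] = {}
    frames_on_all: dict[str, list] = {}
    img_cache: dict = {}

    def activation_image(size, orientation):
        key = (round(size, 2), orientation)
        if key not in img_cache:
            stim = op.make_tumbling_e(size, orientation, raster)
            img_cache[key] = op.trim_activation(op.retinal_image(stim, psf))
        return img_cache[key]

    u_crit = -np.log1p(-(psy.CRITERION - psy.GUESS_RATE)
                       / (1.0 - psy.GUESS_RATE - cfg.lapse_true))

    for i in range(cfg.n_observers):
        name = f"S{i + 1}"
        rng = np.random.default_rng(obs_seeds[i])
        obs = gen_observer(cfg, name, dens[i], vel[i], offsets[i], rng)
        observers.append(obs)
        traces[name] = []
        frames_on_all[name] = []
        median_icd = float(np.nanmedian(obs.mosaic.icd))

        for duration in cfg.durations:
            mult = cfg.true_normalized_thresholds[duration]
            for run in range(cfg.runs_per_condition):
                state = psy.StaircaseState()
                for j in range(cfg.trials_per_run):
                    size = state.next_size
                    orientation = op.ORIENTATIONS[rng.integers(0, 4)]
                    artifact = None
                    if rng.random() < cfg.artifact_rate:
                        artifact = ("microsaccade" if rng.random() < 0.7
                                    else "blink")
                    trace, frames_on = gen_drift(
                        duration, obs.velocity, rng,
                        offset_arcmin=obs.fixation_offset,
                        diffusion=cfg.drift_diffusion,
                        mean_reversion=cfg.mean_reversion,
                        start_spread=cfg.start_spread_arcmin,
                        trace_jitter=cfg.trace_jitter_arcmin,
                        artifact=artifact, raster=raster,
                        onset_frame=cfg.onset_frame,
                        trace_len_ms=cfg.trace_len_ms)
                    # truth: threshold = multiplier x trial-based Nyquist
                    ds = em.downsample(trace)
                    pos_deg = ds.xy_arcmin[frames_on] / 60.0
                    if duration == 3 or len(frames_on) == 1:
                        pos_deg = pos_deg[:1]  # zero-slip single placement
                    act = activation_image(size, orientation)
                    amap = cap.capture_trial(act, pitch, obs.apertures, pos_deg)
                    icds = obs.mosaic.icd[amap.seeing_indices]
                    icds = icds[np.isfinite(icds)]
                    nc = (float(np.mean(icds)) * mz.SQRT3 / 2.0
                          if icds.size else mz.nyquist_limit(median_icd))
                    thr_true = mult * nc
                    alpha_true = thr_true / u_crit ** (1.0 / cfg.beta_true)
                    correct, report = psy.simulate_observer(
                        size, alpha_true, cfg.beta_true, cfg.lapse_true, rng)
                    rows.append({
                        "observer": name, "duration": duration, "run": run,
                        "trial": j, "size": size, "orientation": orientation,
                        "response": report, "correct": correct,
                        "motivational": state.next_is_motivational,
                        "artifact": artifact or "",
                        "trace_index": len(traces[name]),
                        "true_threshold": thr_true,
                    })
                    traces[name].append(trace)
                    frames_on_all[name].append(frames_on)
                    state = psy.staircase_next(state, correct)

    trials = pd.DataFrame(rows)
    manifest = {
        "seed": cfg.seed,
        "n_observers": cfg.n_observers,
        "durations": list(cfg.durations),
        "runs_per_condition": cfg.runs_per_condition,
        "trials_per_run": cfg.trials_per_run,
        "n_trials": len(trials),
        "observer_params": [
            {"name": o.name, "peak_density": float(o.peak_density),
             "velocity": float(o.velocity),
             "fixation_offset_arcmin": o.fixation_offset.tolist()}
            for o in observers],
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
    }
    return Experiment(cfg, observers, trials, traces, frames_on_all, manifest)
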
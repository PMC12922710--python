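# Methods

This note documents the models, conventions, and numerical choices behind
`conedrift`, and what the synthetic-data generator does and does not
emulate.

## Coordinate and unit conventions

Retinal positions are degrees of visual angle, origin at the raster
center, x rightward, y upward; eye-motion traces are arcmin; cone-level
distances (ICD, Nyquist, stimulus sizes) are arcsec. The raster is
0.85° × 0.85°, 512 × 512 pixels at 27 Hz, giving a pixel pitch of
~5.98 arcsec and a frame period of ~37 ms; scanner timing divides the
frame period uniformly across lines (line flyback is ignored).

## Mosaic metrics

Cone centers are Voronoi-tessellated (scipy Qhull). A cell counts as
*bounded* only if it is finite and all its vertices lie inside the convex
hull of the centers; boundary cells are excluded from every area-based
statistic rather than extrapolated. The per-cone ICD is the mean distance
to Voronoi-adjacent cones.

Density at a map pixel is the reciprocal of the mean bounded-cell area of
the k = 150 nearest cones (reciprocal-of-mean, not 150/total-area; the two
coincide for equal cells, and reciprocal-of-mean follows directly from
"averaging the area of the k closest cones"). k is reduced with a warning
when fewer bounded cells exist. The default map pitch is 6 arcsec
(≈ one raster pixel); the pipeline clamps the map to the square inscribed
in the mosaic hull.

The CDC is the density-weighted centroid of the connected region at
≥ 80% of peak density (the component containing the peak). Density
weighting inside the region is an assumption — uniform weighting within
the contour would move the CDC by well under a map pixel on realistic
maps.

Triangular-lattice relations link density, spacing, and resolution: a
lattice of spacing s has one cone per (√3/2)s², so
ICD(d) = √(2/(√3 d)) and N_c = ICD·√3/2. These two closed forms are what
the reference-table checks rest on. One reference row (P3,
15,005 cones/deg², printed N_c 27.4) converts to 27.35 arcsec, i.e. the
printed density and printed Nyquist disagree by half a unit in the last
digit; the package therefore checks the conversion at the printed
precision (±0.1 arcsec) rather than by exact rounding.

## Eye motion

All drift statistics operate on the trace down-sampled to one position
per video frame (linear interpolation at frame centers), which suppresses
registration jitter in the 864-Hz native trace. Over the n stimulus-on
frames: slip is the sum of the n−1 displacement-vector norms; mean
velocity divides slip by the (n−1)-frame elapsed time; single-frame
(~3 ms) presentations are assigned exactly zero slip (at ~13 arcmin/s a
3-ms exposure moves the image < 2.4 arcsec, under a tenth of a cone).

MSD is the squared displacement from the stimulus-onset position as a
function of lag, per trial; *drift variance* is the across-trial sample
variance (n−1 denominator) of the MSD values at the 600-ms lag.

Microsaccade flagging differentiates the native trace after a 15-ms
moving-average smooth and fires when speed exceeds 30 arcmin/s inside the
stimulus window. The 15-ms window is an implementation choice: long
enough to suppress registration noise, short enough to resolve 20-ms
saccadic events. Blink flagging fires on any invalid (dropout) sample in
the window.

## Stimulus and optics

The Tumbling-E (5 × 5 stroke widths, gap = stroke) is drawn on a grid
oversampled 8× relative to raster pitch, blurred with a 5-pixel / σ = 1
pixel Gaussian at that nominal resolution for sub-pixel edge placement,
then block-averaged to raster pitch, zero-padded so blur never reaches
the border. OFF contrast is encoded as background 1000 / letter near 0,
and downstream computations use the activation (background − value) /
background. The 8× oversampling keeps sub-pixel edge placement error
below 1/16 pixel.

The PSF is the Airy intensity pattern for a 7-mm pupil at 788 nm (first
zero 28.3 arcsec), sampled at raster pitch with support out to 8
first-zero radii (truncated energy < 0.5%) and normalized to unit sum.
Retinal images are linear (zero-padded) convolutions; for capture the
image is cropped to the box holding 99.9% of its energy.

Delivery verification scores the normalized cross-correlation peak
between intended and delivered stimulus (mean-subtracted); the default
pass threshold 0.8 is configurable — no value is prescribed by the
procedure this mirrors.

## Seeing cones

Each cone receives a Gaussian aperture of diameter 0.48 × local ICD,
interpreted as the FWHM (the literature convention for cone apertures;
a 2σ interpretation is available behind a switch), so
σ = 0.48·ICD/2.355. Apertures integrate to one. Per stimulus-on frame,
the retinal image is placed at that frame's eye position and integrated
against each aperture; per-cone captures accumulate over frames, are
normalized by the trial's total captured light, and cones above the 1%
fraction are *seeing cones*. The 1% rule is applied to the
trial-cumulative fraction, not per frame. Temporal decay of the cone
response is deliberately excluded.

Numerically, each aperture is evaluated on a local pixel patch of radius
4σ (cones grouped by patch size so an outlier aperture does not inflate
every patch); the truncation error is ~1e-4 of a cone's capture and can
be driven below 1e-8 with `support_sigmas=8` where exactness matters.

The ISOA is computed with a Gaussian KDE (Silverman bandwidth): the
density level is the (1 − 0.68) quantile of the KDE evaluated at the
landing points, so the superlevel region contains 68% of points by
construction; area and density-weighted centroid are measured on a
200 × 200 grid. A trial's landing point is the mean stimulus-center
position over its stimulus-on frames.

## Psychophysics

Staircase: start 48 arcsec; ÷1.75 per correct until the first error;
thereafter ×0.82 after two consecutive correct (counter resets on each
step or error) and ×1.5 after any error. The first error itself takes the
×1.5 up-step. Every sixth trial is a 48-arcsec motivational stimulus; it
is answered and pooled into the psychometric data (it is a valid
response) but never advances the staircase or its counter. Note the
asymmetric 0.82/1.5 steps balance near 82% correct (≈ 1.14 α for β = 3),
slightly above the classic √0.5 point of a symmetric two-down/one-up.

Curated trials are pooled across runs and binned at the smallest width in
[5, 11] arcsec yielding ≥ 7 non-empty bins (bin center = mean member
size); if none qualifies the code falls back to quantile bins and flags
it. Binned counts are fit by binomial maximum likelihood with
Ψ(x) = γ + (1 − γ − λ)(1 − exp(−(x/α)^β)), γ fixed at 0.25, λ bounded in
[0, 0.05] (prevents threshold bias from rare finger errors), α and β
fitted in log space (L-BFGS-B). The threshold solves Ψ = 0.625 in closed
form, the criterion being γ + (1 − γ)/2 evaluated on the full fitted
curve including λ. CIs are percentile bootstrap over trials (500
resamples by default, re-binned on the original edges, warm-started).
Degenerate data (all correct, or never above chance) raise instead of
returning a meaningless fit.

Threshold normalization is *trial-based*: per condition,
N_c = √3/2 × mean ICD of the seeing cones pooled over that condition's
curated trials; the normalized threshold is threshold / N_c. Conditions
with empty seeing sets fall back to the CDC Nyquist limit with a warning.

## Synthetic-data generator

The generator reproduces the statistical structure the analysis assumes —
not the biology that produces it.

*Mosaics*: jittered triangular lattices (jitter SD 8% of local spacing)
radially remapped so density declines by a configurable fraction per
degree (default 0.15/deg); peak densities span 11,700–18,000 cones/deg²
across observers.

*Drift*: a literal Brownian path has sampling-rate-dependent length, so a
"mean drift velocity" target would be ill-posed at 864 Hz. Drift is
therefore generated as a random walk at the frame timescale: fixed step
length v·T with i.i.d. uniform directions and weak mean reversion
(0.03/frame) toward a habitual fixation locus offset 0–7 arcmin from the
mosaic center, then linearly interpolated to 864 Hz with 0.02-arcmin
registration jitter. This keeps frame-resolved slip and velocity exactly
calibrated while preserving linear MSD (D = v²T/4). Setting
`drift_diffusion` switches to Gaussian increments with that diffusion
constant (used for MSD-calibration checks). Trial start positions scatter
(SD 1.5 arcmin) around the fixation locus.

*Artifacts*: 30% of trials receive either a microsaccade-like ramp
(20 ms, 45–90 arcmin/s, always overlapping the stimulus window; 70% of
artifacts) or a 120-ms blink dropout (30%), which is what makes the
curation stage remove ≈ 30% of trials.

*Observer*: responses are Bernoulli draws from the Weibull Ψ with β = 3
and λ = 0.01; the true threshold on each trial is a duration-dependent
multiplier times that trial's seeing-cone Nyquist limit, linking acuity
to the mosaic actually sampled. The default multiplier schedule
(1.07, 0.90, 0.83, 0.78, 0.75 at 3/80/220/370/600 ms) interpolates the
group means the design targets; it is a scenario *input* — the package
does not model why slip improves acuity.

What the generator does **not** emulate: image-registration artifacts
beyond white jitter, ocular torsion, saccade main-sequence realism,
structured (non-random-walk) drift, cone temporal dynamics, and
ON/OFF-pathway asymmetries. Passing tests therefore validate the
analysis machinery under the stated statistical assumptions, not the
physiology of real recordings.

## Problem sizes and determinism

All randomness flows from explicit seeds (`numpy` `SeedSequence`
spawning per observer); identical config + seed reproduces datasets
bit-identically. The shipped analyses use a three-observer cohort with
the full five-duration design; the recovery checks in the test suite use
two observers × three durations (3/80/600 ms) × five runs of 23 trials
across 20 seeds, and the psychometric-recovery check uses 100 replicates
of the five-runs-of-23 budget with 500 bootstrap resamples. Mosaics are
generated to 0.35–0.42° radius (7–10 k cones), large enough that drift
plus fixation offsets never leave the tessellated region.

## Known limitations

- The density map evaluates only inside the convex hull; montage-edge
  behavior is not modeled.
- The binned ML fit ignores lapse-rate uncertainty beyond the [0, 0.05]
  bound; very small pools (< ~60 trials) give wide, occasionally
  bound-hitting fits, which the pipeline reports as missing conditions
  rather than guessing.
- The delivery-verification stage is exercised with synthetic
  degradations only; the generator injects no delivery artifacts by
  default.
- ISOA area depends on the KDE bandwidth (Silverman); only the contained
  point fraction, not the area, is calibration-checked.
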
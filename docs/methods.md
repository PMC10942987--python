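# Methods

This note documents the models and procedures implemented in
`vasomotion`, the parameters that matter, the numerical conventions,
and what the synthetic-data tests do and do not demonstrate about real
imaging data.

## Vessel width from intensity profiles

A dye-filled vessel lumen appears as a bright band. Per frame, the
intensity profile along a line orthogonal to the vessel is (optionally)
smoothed with a moving average (`smooth_px`, default 3 samples), and
the width is the distance between the two half-height crossings around
the global peak.

Conventions, chosen where the underlying workflow relied on visual
judgement:

- **Half height** is `(max + min)/2` of the smoothed profile, i.e.
  relative to the local background, because in vivo background
  fluorescence is nonzero. This makes the measurement invariant to
  affine intensity rescaling.
- **Peak** is the global maximum; ties break toward the profile centre.
- **Crossings**: from the peak, walk outward to the first sample
  *strictly below* half height and interpolate linearly between the
  bracketing samples. Taking the first (not outermost) crossing is
  robust to bright structures beyond the vessel.
- **Radius** uses a caller-supplied fixed midline as one boundary
  (default: intensity centroid of the time-averaged profile) and the
  half-height crossing on one chosen side as the other, so one-sided
  wall motion is measured even when the two walls move heterogeneously.
- Frames whose profile is flat or unbounded at the edge are flagged and
  linearly interpolated from neighbours; a trace with more than 20 %
  failed frames is rejected outright.

Coordinates are 0-based with continuous sub-pixel positions; widths are
reported in µm via the stack's pixel size (0.994 µm/px for standard
frame scans). On noiseless synthetic movies the tracking error is
< 0.05 px; the closed-form checks (top-hat support, Gaussian
FWHM = 2√(2 ln 2)·σ) hold to 0.02 px with smoothing disabled. Note the
default 3-px smoothing widens a σ = 4 px Gaussian by ~0.2 px (box
variance (k²−1)/12 adds in quadrature); disable it when profiles are
already clean.

## The oscillation index

For a uniformly sampled trace *X*, the baseline smooth *X₀* is the
**6th smallest value in a trailing 20-sample window** (startup samples
reuse the first full window's statistic; the trailing alignment is the
causal reading of a running baseline). The noise scale σ is the sample
SD (n−1) of *X − X₀* over the whole record; events are maximal runs of
samples strictly above *X₀ + kσ* with *k* = 2, with the run maximum as
the peak (earliest index on ties). The index is

- frequency = events / record duration (Hz),
- amplitude = mean over events of (peak − X₀(peak))/X₀(peak) × 100 %,
- peak-interval SD = sample SD of successive peak-time differences,
  reported as undefined (not 0) below three events.

Two properties of this statistic matter for interpretation:

1. **The amplitude is an envelope excursion, not a half-amplitude.**
   X₀ sits near the 27.5th percentile of the signal distribution
   (order 6 of 20). For a sinusoid of fractional amplitude *a* that is
   ≈ 0.63·A below the midline, so the measured ΔX/X₀ converges to
   ≈ 1.63·a (a 3 % sinusoid reads ≈ 4.9 %). Amplitudes produced by this
   index are internally consistent and comparable across conditions,
   but they are not estimates of the sinusoidal modulation depth, and
   recovery tests against the generator's `amplitude_frac` fail by this
   factor by construction.
2. **Event counting is noise-sensitive at the stated SNR.** With noise
   SD one fifth of the peak deviation, the threshold *X₀ + 2σ* sits
   close to the cycle peaks (σ is dominated by the oscillation itself,
   not the noise). Noise then splits long supra-threshold runs at slow
   frequencies (≈ +27 % median frequency error at 0.05 Hz) and pushes
   marginal peaks under threshold at 0.15 Hz (≈ −18 %); 0.10 Hz
   recovers within ~6 %. Noiseless recovery is exact at all
   frequencies, which is what the oracle tests pin down. There is no
   run-merging gap or refractory period — that is the literal event
   definition being reproduced — so users needing rate estimates at low
   SNR should corroborate with the spectral peak, which stays on the
   true frequency bin throughout.

The alternative readings of "double SD of the baseline" (SD of the raw
trace — nearly identical because the baseline is almost flat; SD of the
baseline series itself — an order of magnitude smaller and badly
overcounting) were considered and rejected.

## Spectral analysis

The default is a plain periodogram: rectangular window, mean detrend,
one-sided, density-normalised so that Σ PSD·Δf equals the variance of
the detrended signal exactly (machine precision; `scipy.signal.periodogram`
stands behind this). A Hann taper and linear detrend are available for
leakage and drift control but are not the default, since typical traces
(200–500 samples) are analysed as a single segment. Band power over
0–0.3 Hz is a trapezoidal integral with PSD interpolated at the band
edges, so adjacent bands add exactly; the in-band peak is the maximum
PSD bin (earliest on ties). Absolute PSD units depend on acquisition
settings; only relative comparisons (e.g. pre vs post AUC) are
meaningful across datasets.

## Cooperation index

Radius traces are extracted at 29 sites, ±35 µm from a core position in
2.5 µm steps. The profile is the Pearson r of each site against the
core (r(0) ≡ 1); sites with failed extraction or zero variance are
missing, not zero. The **extent** scans outward from the core and
reports the largest distance d such that *every* defined site with
0 < |offset| ≤ d has r ≥ 0.3 on *both* sides; a missing value breaks
contiguity (conservative), and a failing first neighbour gives extent
0. The all-pairs matrix uses the same estimator and agrees with the
profile on the core row exactly. Averaging across vessels is an
unweighted mean of r per offset.

The core position is user-supplied (the field workflow picks it
arbitrarily); the synthetic coupled generator mixes a shared sinusoid
with independent noise at weight exp(−|offset|/L), so the expected
r equals the weight and the expected extent is ≈ L·ln(1/0.3) ≈ 1.2·L,
capped at 35 µm — the basis of the rank-correlation test.

## Velocimetry, flux, stalls

**Manual velocimetry** converts annotated streak endpoints to velocity:
v = Δpixel·pixel_size / (Δline·line_period), mean over streaks, in
mm/s. The sign convention is explicit: the baseline (pre-occlusion)
flow direction is positive, so flow reversal is a sign flip, and
mirroring the kymograph mirrors the velocity.

**Automatic velocimetry** scores candidate streak angles by the
variance of the shear projection (each line shifted so streaks at that
angle become vertical, then averaged): the true angle maximises the
projection contrast. The angle grid is 1° over (−89°, 89°), excluding
exactly horizontal; for slopes steeper than 1 px/line the projection is
evaluated on the transposed block so the shear stays inside the field.
Because 1° is a ~9 % velocity step at shallow angles, the grid maximum
is refined by a bounded continuous search within ±1°; recovery on
noiseless synthetic kymographs is then within ~1 % across
0.2–13 mm/s. Blocks whose best score is below `variance_floor` (2×)
times the median score across angles carry no dominant orientation and
are skipped; if all blocks are skipped the result is "no flow"
(velocity undefined, not 0). The per-vessel velocity is the median over
blocks (manual mode uses the mean over streaks; the original workflow
does not state its reduction).

**Flux** is streak count / total scan time (cells/s).

**Stall classification** needs a per-frame flowing indicator. Real
records were judged by eye; the deterministic surrogate is windowed
dispersion: the sample SD over 3-frame windows, with a frame counted as
non-flowing when *some* window containing it is quiet. The
exists-window rule makes an n-frame stall map to exactly n non-flowing
frames in the noiseless limit (a centred window would erode 2 frames
per edge and break the 10-frame boundary case); its price is a possible
dilation of up to window−1 frames per side under noise. The quiet
threshold is `k_sigma` (2) times a sensor-noise estimate built in two
stages: a floor from the mean of the lowest 4 % of windowed SDs (4 % ≈
the window fraction a minimal 10-frame stall contributes to a 200-frame
record; a 10 % quantile would mix flowing windows into the estimate),
then a refinement pooling the frame values under provisionally quiet
windows (SD below half the median level) into a within-run SD, which is
unbiased where 3-sample SDs are not. Records with no quiet cluster —
median windowed SD below 3× the floor — are reported all-flowing, and a
perfectly constant record is all non-flowing.

A capillary is **stalled** iff some run of ≥ 10 consecutive non-flowing
frames exists in the 200-frame record (~10.8 s of 216 s; runs are never
merged across intervening flowing frames), and the stall rate is the
percentage of stalled capillaries in the field.

## Synthetic data: what it emulates, and what it does not

All generators draw from one explicit seed per spec (no global state;
identical spec + seed is bit-identical) and attach their parameters as
ground truth.

- **Radius traces**: base·(1 + a·sin(2πft + φ)) + drift·t + N(0, σ²),
  at frame intervals restricted by default to the 0.625–0.926 Hz
  frame-scan range (configurable).
- **Calcium traces**: baseline plus half-sine transients (3-sample rise
  and fall — the simplest shape with a well-defined peak) arriving as a
  thinned Poisson process at the spec'd mean rate, peaking at
  `amplitude_frac`·F₀.
- **Vessel movies**: a horizontal band whose half-width follows the
  radius trace, with erf-smoothed edges (softness 1 px default). The
  erf edge keeps the half-height crossings exactly at the nominal walls,
  so FWHM recovery is a calibration closure, not a fit.
- **Line scans**: Poisson-arriving streaks of fixed slope
  v·line_period/pixel_size with Gaussian cross-section (σ 0.8 px) on a
  bright background (2 µm/px, 2 ms lines by default).
- **Capillary records**: 200 frames at 1.0841 s (≈ 216.8 s). While
  flowing, the ROI intensity carries a sign-alternating random-depth
  modulation with SD `transit_signal_sd` (default 10, vs sensor noise
  2): at ~1 s frame intervals successive frames sample uncorrelated
  blood-cell occupancy, and the bounded-below alternating waveform
  guarantees every flowing window is dispersive. An i.i.d. Gaussian
  modulation was rejected: it produces chance-quiet flowing windows at
  rates (tens of percent near SNR 3) that make exact stall recovery
  impossible for any windowed-dispersion detector, which would say more
  about the noise model than about the classifier.

Not emulated: photobleaching, motion artefacts, heartbeat/respiratory
pulsation, curved vessels, hemodynamic coupling between radius and
flow, and realistic noise magnitudes (the source workflow reports
none). Passing recovery tests therefore demonstrate correctness of the
measurement chain under the stated signal models — not robustness to
every artefact of in vivo data; the failed-frame flagging and the
no-flow/contrast guards are the designed degradation paths.

## Classification and normalization

Inert: frequency strictly below 0.0249 Hz (the venular reference; the
figure-legend variant 0.026 Hz is available via the cutoff argument).
Aberrant: amplitude strictly above 5 % or strictly below 1 %; boundary
values are normal/active. Change rates are 100·post/pre (pre > 0
required); paired tables keep only keys present in both the pre and
post mappings and report the excluded keys. Inferential statistics are
deliberately out of scope — the package emits tidy tables for standard
tools.

## Problem sizes in the test suite

Simulations in the tests and acceptance script are sized for a desk
run: 300 s traces at 0.926 Hz sampling (~277 samples), 50 seeds per
recovery sweep, 100-seed nulls, 256-line kymographs, a 23-capillary
stall field, and exhaustive boolean enumeration up to length 20 for the
stall-rule oracle. These match the acquisition regime of the imaging
workflow while keeping the whole suite under half a minute.
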
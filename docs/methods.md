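# Methods

This note documents the models, conventions and numerical choices behind
`calwave`, in the order data flows through the pipeline.

## Synthetic recordings

The generator (`calwave.simulate`) emulates a two-photon movie of an evoked
calcium wave in dye-loaded cortical-plate tissue. It is the package's
validation substrate: every analysis stage is tested by recovering its
ground truth.

**Scene.** Somata are a thinned Poisson point process (uniform positions,
optional hard-core minimum separation, default 10 µm for touching 5-µm-radius
disks) over the dye-loaded region. Each cell is a uniform disk (radius 5 µm,
overlap resolved by maximum) with log-free baseline brightness
(mean 600 a.u., CV 0.15) over diffuse background (100 a.u.). A dark margin
(28 px at ~5 a.u.) along one edge stands in for unloaded tissue; the
dye-area mask needs genuinely dark pixels to estimate the background from,
and densities (simulated and recovered) are defined per loaded area.

**Wave model.** A cell at distance `d ≤ max_extent` from the stimulus
centre is recruited with probability `p` and activates at
`t_stim + d / v(θ) + jitter` (Gaussian jitter, default SD 0.15 s; `v` may be
a function of angle for anisotropic waves). Cells under the stimulus spot
activate at the stimulus itself — they are directly irradiated, not
recruited. Activated cells follow
`F(t) = baseline · (1 + A · k(t − onset))` with the transient kernel
`k(t) ∝ (1 − e^(−t/τ_r)) e^(−t/τ_d)` normalized to peak 1
(τ_r = 0.5 s, τ_d = 2 s; the published traces show fast-rise/slow-decay
transients without parameterizing them, so the kernel shape is a modelling
choice).

**Acquisition.** Defaults mirror the experimental design: 1/1.2 s frame
interval, 512×512 px, five baseline frames, stimulus spot 25 µm (within the
20–30 µm used experimentally) rendered as a saturating disk for the ~3 s
irradiation (the bleaching-routine artifact), 1 µm/px calibration (the field
then spans ~512 µm, consistent with the 400 µm analysis range; the
publication gives magnification but no calibration). Optical blur is a
Gaussian PSF (σ = 1 µm); noise is Gaussian with SD 5 % of background
(Poisson shot noise available); drift is a rigid per-frame translation.

**Condition presets.** `condition_preset` carries, per condition,
truncated-at-zero normal distributions of the per-recording metrics with the
published means/SDs: density 470 ± 220 (control), 56 ± 51 (suramin),
1190 ± 370 (caffeine) cells/mm²; distance 273 ± 68 vs 88 ± 44 µm; speed
119 ± 80 vs 194 ± 163 µm/s. Two quantities the publication does not state
are free parameters chosen once: suramin's speed distribution reuses
control's (no speed change is reported under suramin), and the control peak
amplitude is 0.8 ΔF/F (a typical evoked Fluo-4 response), with suramin at
−58 ± 29 % and caffeine at +55 ± 40 % relative to it.
`simulate_recording` realizes a drawn density target through the recruitment
probability `p = target / (realized soma density × extent coverage)`, where
the coverage factor accounts for the part of the loaded region the
(possibly frame-clipped) extent circle does not reach; the distance target
sets `max_extent`, the speed target sets `v`, and the amplitude target sets
`A`. Recording length adapts to the wave (`extent/speed + 10 s`, 30–120
frames) so slow waves are fully captured.

**What the generator does not emulate.** Non-rigid (heartbeat) deformation,
depth attenuation, neuropil ΔF/F signal (only somata carry the transient),
photobleaching, and mechanistic ATP/IP₃ dynamics — the wave is purely
phenomenological. Passing recovery tests therefore demonstrates estimator
correctness under the stated geometry and noise, not robustness to every
property of in vivo data.

## Registration

Per-frame translation against a reference frame (default frame 0) via FFT
cross-correlation of mean-subtracted, Hann-windowed images; windowing
suppresses the non-periodic boundary energy that otherwise biases the peak
by ~0.1 px. The integer peak is refined to subpixel by separable parabolic
interpolation, on log-correlation where the neighbourhood allows it (the
peak of band-limited image correlation is near-Gaussian, making the
log-parabola nearly unbiased). Ties break toward zero shift; constant images
return (0, 0) with a warning. Shift estimation runs on intensity-clamped
copies (99.5th percentile of the reference) so the saturating irradiation
artifact and large transients cannot capture the correlation. Frames are
resampled bilinearly with the negated shift (edge fill: frame median);
estimated shifts below 0.1 px are treated as zero, because resampling a
static frame for a noise-driven subpixel estimate blurs it relative to
unresampled frames and imprints edge artifacts on ΔF/F. Rotation is omitted:
over the ≤ 60 frames of an evoked recording, rigid translation is the
dominant motion.

A residual limitation: with genuinely fractional drift, the ~0.1 px
registration error times the PSF-limited intensity gradient leaves ΔF/F
residuals up to ~0.2–0.4 *at soma borders* (measured with both bilinear and
cubic resampling). Low-gradient pixels are noise-limited. Cell-level traces
average over whole ROIs and are far less affected.

## Temporal Kalman filter

Each pixel runs a scalar predict/correct recursion with the previous
estimate as prediction: `est_t = pred + K_t (obs − pred)`,
`K_t = max(P/(P+R), 1 − gain)`, `P ← P(1 − K_t)`, with `P` and `R` seeded by
`initial_variance` (default 0.05). `gain` (default 0.8) is the maximum
fraction of the previous estimate retained — the stack-filter plugin
convention — so the observation weight starts at 0.5 and settles at
`1 − gain`; `gain = 1` disables the filter entirely. The filter reduces the
temporal variance of static white noise by ~9× at defaults, at the cost of
a group delay of a few frames.

Because of that delay, the pipeline applies the filter only on the raster
branch (polar ROI traces, where per-pixel denoising matters for
visualization and event robustness); cell-level metrics use ΔF/F of the
registered, unfiltered stack. Soma traces average tens of pixels, so their
SNR does not need the filter, while a lagged onset would bias `t_half` and
hence every speed estimate downward.

## ΔF/F and the dye-area mask

`ΔF/F(t) = (F(t) − F₀)/F₀` with `F₀` the per-pixel mean of the first five
frames (the estimator — mean vs median — is a choice; the frame count is the
experimental design). Pixels with `F₀ ≤ 0` are masked and excluded
downstream rather than producing infinities. The visible dye-loaded area is
`baseline ≥ 2 × background`, with background estimated robustly as the
median of the lowest-decile baseline pixels ("visible area" has no published
operational definition; this is ours). Active-cell densities are normalized
to this area in mm².

## Cell detection and wave metrics

Somata are detected on the baseline image: difference-of-Gaussians band-pass
tuned to the expected radius band (2.5–10 µm), Otsu threshold of the
in-mask band-pass response, local maxima as seeds, watershed-grown regions,
and a radius-band filter. Detection is deterministic. Each ROI's trace is
the mean ΔF/F over its valid pixels.

A cell is **active** when its post-stimulus ΔF/F reaches 5 % — the
wave-border criterion — with the boundary counting as active. Cells
overlapping the stimulus spot (centroid within spot radius + cell radius)
are flagged and excluded from density, distance and amplitude statistics.

Cell **onset** is the first post-stimulus frame at which the trace reaches
the same 5 % threshold. (The half-maximum rule is reserved for polar ROI
events: applied to single-cell transients with a ~0.5 s rise, half-maximum
crossings would add a constant ~0.5 s latency to every onset and bias all
speeds downward; the threshold crossing keeps onset latency well below one
frame.)

The wavefront radius `r(t)` is the largest stimulus distance among recruited
cells with onset ≤ t (centroid-based, so extent and recruitment share one
substrate). The propagation distance `D` is the final radius. `t_half` is
the first frame time, relative to the stimulus, with `r(t) ≥ D/2` —
first-frame-at-or-above, no interpolation — and the speed is
`(D/2)/t_half`. Speeds are therefore quantized by the frame grid: at
1.2 fps a wave reaching its half site between frames is attributed the next
frame time; for noiseless linear waves whose `D/2` falls on a frame
boundary the estimator is exact. Failed waves (`D = 0`) report missing
speed and are excluded pairwise from group statistics. The amplitude at the
half-propagation site is the mean per-cell peak ΔF/F over active cells in
the annulus `D/2 ± 20 µm` (width 40 µm, widened once to 80 µm if empty,
then missing).

## Polar analysis

The ΔF/F movie is resampled into (radius, angle) about the stimulus centre
by bilinear interpolation; samples outside the frame are invalid. The
default angular count makes the arc length at the 400 µm analysis limit
equal the radial step (2π·400 ≈ 2513 samples at 1 µm steps), so the
transformed image is approximately area-faithful at the limit. ROIs are
70 µm squares *of the transformed grid* — their physical arc span grows
with radius, mirroring the published construction — tiled from the
stimulus-spot edge out to 400 µm (block count = ⌊(limit − offset)/side⌋);
ROIs with under 50 % valid pixels are dropped. Each ROI's half-maximum event
time is the first post-baseline frame at or above
`baseline + (peak − baseline)/2`, gated by the same 5 % minimum excursion
(stated experimentally for cells; reused for ROIs for consistency). Event
times are affine-invariant given detection; the gate is intentionally
absolute.

Rasters are binary ROI × frame matrices ordered block-major, angle-minor.
Within each block, events at or before the block median form the **leading
front** and later events the **lagging front** (the published split is
qualitative; the median is our formalization). The **anisotropy index** is
the coefficient of variation of per-angle mean event delay across angular
tracks — 0 for a perfectly isotropic wave — and the per-angle apparent
speed is the least-squares slope of ROI radius versus event time along that
angle. Both are this package's formalizations of "some tracks are faster
than others" and are flagged as such in reports. The index is only
comparable between geometries where all angles sample the same blocks
(e.g. a centred stimulus); frame-time quantization and discrete soma
sampling keep it near ~0.03–0.05 even for perfectly isotropic simulated
waves at the production ROI geometry.

## Statistics

Two-sided Mann–Whitney U from midrank sums. The p-value is exact (full
enumeration, via `scipy.stats.mannwhitneyu(method="exact")`) when
`max(n1, n2) ≤ 8` and the pooled sample is tie-free, else the normal
approximation with tie-corrected variance and continuity correction. Both
routes agree within 0.02 for tie-free samples with 5 ≤ n ≤ 8 (verified
exhaustively), and the asymptotic route is calibrated at the study group
sizes (null rejection 0.047 at α = 0.05 over 10⁴ simulations). Condition
summaries report mean ± sample SD (n−1); missing values are excluded
pairwise with counts; no multiple-testing correction is applied (each panel
is reported individually). Sidedness is two-sided by convention.

## Problem sizes in the test suite

The suite validates at deliberately scaled sizes chosen to exercise every
code path with comfortable statistical margins: full-frame 512×512 stacks
for velocity recovery (3 stacks, 40 frames) and for the 100-seed
leading-front ordering check (32 frames, 240 angular samples — the angular
count is a free parameter of the check, not of the claim); 256–360 px
fields for registration, recovery and directionality unit tests; and
Monte-Carlo twins of the condition comparisons at the study group sizes
(13/16/14) with 100 replicates.

## Known limitations

- Translation-only registration; non-rigid (heartbeat) motion is out of
  scope.
- Speeds inherit one-frame quantization from the first-frame-at-or-above
  `t_half` convention; at 1.2 fps this systematically underestimates fast
  waves (documented, matches the event-detection convention).
- The anisotropy index is descriptive and geometry-dependent (see above);
  no statistical test of directionality is provided.
- The simulator's somata-only signal understates neuropil contributions;
  polar ROI means on sparse recruitment (suramin-like waves) can fall below
  the 5 % event gate even where individual cells are active — which is also
  the physically expected behaviour of a weak wave.
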
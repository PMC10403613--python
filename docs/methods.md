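# Methods

`vsdpop` analyzes mesoscale voltage-sensitive dye imaging (VSDI) recordings
of cortical population responses evoked by optogenetic stimulation (ChR2)
and by intracortical microstimulation (ICMS), and ships a synthetic session
generator with known ground truth so the entire pipeline is testable
without in-vivo data. This note documents the signal model, the analysis
conventions, the numerical choices, and what the synthetic data does and
does not establish.

## Recording model

A session is a set of stimulated and blank (no-stimulation) trials, each a
stack of fluorescence frames: 100 × 100 pixels covering 5 × 5 mm of cortex
(50 µm/pixel) at 100 Hz (10 ms frames). Frame timestamps are relative to
stimulation onset (t = 0 ms); a frame "at t = 20 ms" is the single frame
with that timestamp — there is no temporal binning. The default recording
is 40 frames with 10 pre-onset baseline frames (t = −100 … 290 ms), long
enough for the slowest decays analyzed here to cross the 30% threshold.

## Preprocessing

1. **Frame-zero division.** Per trial and pixel, fluorescence is divided by
   the mean pre-onset fluorescence. We subtract 1 so that Δf/f sits at 0
   during the baseline; blank subtraction re-centers the signal regardless,
   so this offset convention is cosmetic but makes intermediate stages
   interpretable.
2. **Blank subtraction.** The frame-wise mean over blank trials is
   subtracted from every stimulated trial, removing heartbeat and slow
   photobleaching components shared between the two trial types.
3. **Trial averaging.** Per-trial corrected stacks are retained alongside
   the average so ROI SEMs over trials remain computable downstream.
4. **Artifact masking (optostimulation only).** The frames at t = 0 and
   t = 10 ms contain the laser light artifact and are invalidated. Pixels
   within 500 µm of the fiber tip whose trial-averaged Δf/f drops below
   −0.002 in the 10–40 ms window (immediately after laser offset) are
   invalidated as dye-bleached. These parameters are qualitative rules in
   the source protocol; the defaults are exposed in `PipelineConfig`.
   Bleach detection runs on the trial average (not per trial): the average
   has the better SNR for a per-pixel rule, and the spot is static.

Invalid frames/pixels carry NaN plus boolean masks; every downstream mean
is mask-aware. Poisoning masked entries with extreme values leaves all
results unchanged (tested).

## Time-course analysis

The response ROI is a circle of radius 5 pixels centered at the argmax of
the 3 × 3-boxcar-smoothed map at t = 20 ms — the first frame after the
laser artifact, which is also where all conditions peak. Argmax ties break
to the smallest (row, col). Within a multi-pulse session, the ROI is
located on the strongest (10 ms) condition and reused for the 2 and 5 ms
conditions, whose SNR is too low for reliable standalone localization.

Three normalizations serve different comparisons:

- **To the 10 ms condition** (per session, at t = 20 ms): removes
  across-session amplitude variance (staining quality, expression level).
  The 10 ms condition's grand-average peak is exactly 1 with SEM 0 — an
  identity forced by the definition, used as a pipeline self-check.
- **To each condition's own peak** (t = 20 ms by default; the global
  valid-frame maximum is selectable and coincides on well-behaved data):
  compares decay dynamics across conditions of unequal amplitude.
- **Raw**: for absolute amplitude comparisons.

SEM is over trials within a session, and over sessions in grand averages;
the two live in distinct fields.

## Ring (space–time) analysis

Forty concentric annuli of 50 µm width tile the disk of radius 2 mm around
the ROI center: ring k holds pixels with center distance d in
((k−1)·50, k·50] µm. The half-open intervals on pixel-center distances
guarantee disjointness and exactly 40 rings; exact multiples of the step
are kept on the inner ring despite floating-point square roots (an epsilon
guards the boundary). The "center" activation is the mean of the ring means
of rings 1–5 (a minimal-pixel-count rule); a 150 µm-disk alternative is
selectable (`ring_center_mode='r150'`), since the two definitions appear
interchangeably in the source material and we do not guess which produced
the printed numbers. Summed activation adds the ring means over rings with
outer edge ≤ 2 mm and valid frames with 20 ≤ t ≤ 100 ms inclusive (9 frames
at 10 ms sampling); ring means rather than pixel sums, i.e. rings are not
area-weighted. Reporting bands: ring1 = 150–350 µm, ring2 = 700–900 µm,
ring3 = 1250–1450 µm (elementary rings 4–7, 15–18, 26–29).

## Decay-time-to-threshold maps

Per pixel, the peak reference is the value at t = 20 ms (the true maximum
is hidden by the artifact) and the decay time is the first time t ≥ 20 ms
at which the signal falls strictly below 70% (fast phase) or 30% (slow
phase) of that peak, interpolated linearly between the last frame at or
above and the first frame below threshold. First crossing wins; transient
re-crossings are ignored ("descending transient"). With the per-pixel peak
reference a pixel is never below threshold at 20 ms; when an external peak
reference is supplied, such pixels get exactly 20 ms. The analysis window
ends at the last acquired frame; pixels that never cross are missing — not
right-censored values — and are excluded from medians, with their count
reported. Pixels with non-positive peak are missing. Distributions pool
per-pixel decay times across sessions within the central (ring1) and
distal (ring3) bands and are summarized as median ± MAD (unscaled).
Outlier-session exclusion is supported only via an explicit config list;
no automatic rule is applied because no criterion is defined for one.

## YFP expression quantification

Each animal's in-vivo YFP image is min–max normalized to [0, 1] within the
imaging-chamber mask (a 1st–99th percentile-clipped variant is available
for robustness); the expressing area is the count of pixels strictly above
mean + 2·STD of the chamber pixels (population STD; strict inequality is
immaterial for continuous data and deterministic for ties). The group
difference (long vs short expression) is compared with a label-shuffle
null: all distinct label assignments when at most `n_perm` exist, else
`n_perm` seeded random permutations; reported as observed difference,
null mean ± STD, and a z-like score.

## Statistics

Two-sided Wilcoxon rank-sum for independent samples and signed-rank for
paired samples, with mid-rank tie handling. For combined n ≤ 20 (rank-sum)
or n ≤ 15 (signed-rank) the exact null distribution is computed by dynamic
programming over doubled-midrank subset sums — valid under ties, where
textbook exact tables are not — with the two-sided p defined symmetrically
as P(|W − µ| ≥ |w − µ|). Larger samples use the tie-corrected normal
approximation (scipy). Zero paired differences are dropped; an all-zero
difference vector leaves the signed-rank test undefined and raises.
Bonferroni correction is per reported panel (family size 3 for the
three-condition comparisons). Summaries are mean ± SEM (SD/√n) or
median ± MAD. The electrode-integrity check compares first-trial vs
last-trial peak (t = 20 ms) values and slow-phase amplitudes across ICMS
sessions by rank-sum; the slow phase is defined as t ∈ [60, 100] ms
(after the fast phase), exposed in config since no window is specified in
the source protocol.

## Synthetic data generator

Raw fluorescence per trial is
`F = F0 · (1 + drift + heartbeat + R + A) + ε`, with `R = 0` on blank
trials, camera noise ε ~ N(0, noise_sd) on raw counts (that is where
camera noise physically lives, not on Δf/f), and F0 ≈ 1000 units with mild
radial vignetting (only ratios matter downstream). The response field is

    R(x, y, t) = amplitude · T(t) · exp(−d² / (2 σ(t)²)),
    σ(t) = σ0 + v · max(t − 20 ms, 0),

with T rising as the square stimulus pulse convolved with the ChR2(H134R)
opening/closing kinetics (τ_open ≈ 1.92 ms, τ_close ≈ 17.9 ms; closed-form
convolution), normalized and clipped so the maximum T = 1 falls at the
20 ms anchor, then decaying bi-exponentially
(w_fast·e^(−Δt/τ_fast) + w_slow·e^(−Δt/τ_slow)). The rise shape before
20 ms is unconstrained by any analysis here (hidden by the artifact frames
for opto) and is deliberately simple. Drift (linear) and heartbeat
(6 Hz sinusoid — the urethane-anesthetized rat range; no rate is stated in
the source) are deterministic waveforms identical in stimulated and blank
trials and re-centered to zero mean over the baseline window, so blank
subtraction removes them exactly; on noise-free input the pipeline
recovers R to machine precision (≤ 1e−10 asserted). The laser artifact is
a large frame-wide additive offset during the pulse frames — its shape is
irrelevant because those frames are dropped — and the bleach spot is a
−0.005 Δf/f offset within 150 µm of the fiber tip after laser offset,
deep enough for the −0.002 detection rule under all conditions. ICMS
sessions have neither.

### Study-condition presets

Peak amplitudes are the printed per-pulse grand means of the source study
(in Δf/f): short expression 0.5/1.03/1.4 × 10⁻³ for 2/5/10 ms, long
expression 2.3/3.05/3.6 × 10⁻³, ICMS 5.1 × 10⁻³. Because `amplitude` is
defined as the exact peak (T is unit-peak per pulse), the growth of the
response with pulse duration is carried by these tables rather than by the
kinetics convolution — the convolution alone would understate the short
pulses relative to the measured ratios. Spatial and decay parameters were
chosen once, by matching analytic estimates of ring sums and
threshold-crossing times to the printed summed activations and decay
medians: σ0 = 300/550/700 µm and spread speed 1/4/5 µm/ms for
short/long/ICMS; decay (w_fast, τ_fast, τ_slow) = (1.0, 8 ms, –),
(0.55, 9 ms, 75 ms), (0.45, 9 ms, 110 ms). These give low-threshold
central decay medians near 30/50/80 ms and preserve every ordering the
study reports. Default scale: 12 stimulated + 10 blank trials per
condition, 6 sessions per condition; across-session variability enters as
a lognormal session gain (SD 0.2) shared by all conditions of a session —
exactly the variance the 10 ms normalization is designed to cancel — plus
per-condition lognormal jitter (SD 0.08). YFP images are top-hat patches
of extent 430 µm (short) vs 590 µm (long) with per-animal extent jitter,
3 animals per group, sized to the printed pixel counts (~232 vs ~438).

### What the synthetic data does not emulate

Radially symmetric spread (no barrel-map anisotropy, no columnar
structure); separable space–time response (no traveling-wave phase lags);
stationary noise without spatial correlations; no motion, no hemodynamic
contamination, no trial-to-trial adaptation. Passing tests therefore
establish the correctness of the analysis operations and the internal
consistency of the study's orderings under its stated conditions — not
that real cortex behaves this way. Distal decay-time distributions are one
visible divergence: in real recordings distal pixels are noise-dominated
and their medians floor near 20 ms, while the noiseless synthetic far
field keeps the temporal shape of the center; the central-band medians,
which carry the scientific contrast, match well.

## Numerical choices

- Missing data: NaN plus boolean masks; all reductions mask-aware.
- Ring boundary epsilon 1e−9 on d/step before the ceiling.
- Bi-exponential recovery fits (used for generator validation) identify
  the fast/slow components by bounding τ_fast ∈ [1, 40] ms and
  τ_slow ∈ [40, 1000] ms, initialized at (0.5, 10, 80).
- Exact-test DP works on doubled midranks so all sums are integers; the
  exact/approximate switch is at combined n = 20 (rank-sum) and n = 15
  (signed-rank).
- All randomness flows from one integer seed through
  `numpy.random.SeedSequence`; identical configs give byte-identical
  output tables.

## Problem sizes used in the shipped analyses

The numbered drivers and the acceptance script use 6 sessions per
condition with 12 stimulated / 10 blank trials at the full 100 × 100 × 40
geometry, 10,000 null simulations for test calibration, and exhaustive
permutation for the 6-animal YFP shuffle — the study's own scale, which
runs in well under a minute per stage on a single core.
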
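# Methods

This note documents the models, estimators and numerical choices in
`fearcalc`, and what the synthetic generators do and do not emulate.

## Stimuli and schedules

Pips are placed at exact multiples of the pip period (1/0.9 s) starting at
t = 0; the repetition phase is not otherwise constrained, and a fixed phase
makes waveforms reproducible. Pip count is ⌊rate × train duration⌋ (27 for
the standard 30 s cue). WGN pips are independent standard-normal draws per
pip, low-pass filtered with a zero-phase 257-tap FIR (Hamming window,
cutoff 20 kHz; > 40 dB stopband per pass, doubled by forward–backward
filtering). Pips are unit-RMS normalised; the nominal 80 dB SPL is metadata
only, since no calibration path exists in software.

Schedules strictly alternate CS+ (each abutted by a 1 s US at its offset)
and CS−, with inter-stimulus gaps drawn uniformly from 10–60 s. Only the
gaps are random; the alternation order is fixed, which is one concrete
realisation of an interleaved presentation order. A no-CS− control variant
omits the CS− epochs. A 30 s baseline epoch precedes the first CS+.

## cVm change

Vm is averaged in bins of one pip period (the stimulus clock; the 30 s
stimulation then spans exactly 27 bins and the sustained-step closed form
27·s holds without partial-bin corrections). An OLS line is fit to the
per-bin mean Vm over the baseline (which must end at stimulation onset and
span ≥ 3 bins), subtracted from all bins, and the residuals cumulated.

Detrending the per-bin Vm — rather than fitting the line to the cumulative
curve itself — is deliberate: for a stationary baseline the two coincide in
expectation (the cumulative of a constant is a line), but detrending first
also cancels a linear instrumental drift in Vm *exactly*, whereas a line
extrapolated from the cumulative of a drifting baseline diverges
quadratically outside the baseline window. The statistic is therefore
invariant to any affine trend a + b·t and homogeneous under scaling of Vm
deviations. The regression abscissa is the mean sample time of each bin
(bin edges are rounded to whole samples; nominal centres would leave a
small drift residual).

Spikes are removed first: samples above −20 mV (configurable) are bridged
by linear interpolation between flanking subthreshold samples, clamping at
trace edges, so the statistic reflects subthreshold depolarisation only.
t₂ is fixed at t₁ + 30 s; traces too short for t₂ report it as missing
rather than extrapolating. Curves report values in mV (per-bin mean Vm
summed over bins).

The NMDAR component is the difference of control and blocked cVm at t₁;
supralinearity compares an observed paired response against the arithmetic
sum of the component responses. Both operations require matching
stimulation windows and bin widths.

## Transient detection

ΔF/F uses the causal lower-half baseline: F₀(t) is the mean of the smallest
⌈n/2⌉ of the n frames in (t − 3 s, t]. Frames whose window is incomplete
are flagged as warm-up and never host detections. This baseline sits
~0.8 noise SD below the true background, leaving ΔF/F with a small positive
offset; the detector therefore centres ΔF/F on its robust (median)
background level before thresholding.

Templates are unit-peak double-exponential kernels on a grid of rise
{0.05, 0.1, 0.2} s × decay {0.4, 0.8, 1.5} s, sampled at the recording
frame period; a parametric grid is reproducible where a hand-curated
transient library would not be. Every window of the trace is scored by
Pearson correlation against each template; frames covered by any window
with r ≥ 0.6 (configurable) form candidate regions.

The event amplitude at a frame is the least-squares template amplitude (the
best-correlating template scaled to the data over its window), which is
unbiased for a transient matching a library shape and substantially less
noisy than the raw single-frame maximum. A peak is accepted iff this
amplitude reaches k = 3 × the background SD — 1.4826 × the median absolute
deviation of non-candidate ΔF/F samples, robust to event contamination —
and a frame adjacent to the peak stays above one background SD (a real
transient outlives one frame; single-frame shot-noise excursions do not).
Peaks closer than 1 s merge into the larger one — roughly one fast-indicator
rise-plus-decay, below which two detections on axonal data are almost
always one transient split by noise. Designed to this operating point, the
detector achieves ≤ 5% of 60 s pure-noise runs with any detection, and
recall and precision above 0.9 for 6×SD events at 0.1 Hz; 60 s is the scale
of a per-CS analysis window with margin, the unit at which detection
quality matters here.

Frame QC computes the 2D correlation of every frame against the session
mean image (after a first pass that excludes obvious outliers from the
reference) and discards frames below 0.7. A constant movie has undefined
correlations; all frames are kept with a warning.

## Spatial spread

At the frame where the across-ROI mean ΔF/F is maximal (searched within
±1 s of the event peak), the ΔF/F-vs-position profile over the 2×2-pixel
ROI tiles is max-normalised and fit with a Gaussian (free amplitude,
centre, σ, and baseline offset) by nonlinear least squares;
FWHM = 2√(2 ln 2)·σ. A non-convergent fit, a non-positive profile, or
σ exceeding the dendrite length is reported as FWHM = dendrite length and
flagged, which forces the global label. FWHM is computed in µm — the 50 µm
local/global boundary is a physical length — and also reported as % of
dendrite length for comparability with spread conventions that normalise by
branch length. Classification is a pure threshold: global iff FWHM ≥ 50 µm.

## Behavioural metrics

Freezing % is the summed overlap of freezing bouts with the evaluated
epochs over total epoch duration. The learning index multiplies freezing %
by the discrimination index (f₊ − f₋)/(f₊ + f₋); when both are zero the
discrimination is undefined and the index is reported as 0. Learner
classification uses the recall CS+ index with a strict > 20% rule (an index
of exactly 20 is a non-learner), and negative discrimination yields a
negative index without clipping.

Events are assigned to epochs by peak time with half-open [onset, offset)
intervals. Cumulative ΔF/F per CS is the bouton-averaged sum of peak
amplitudes of events inside that CS ("amplitude" = event peak ΔF/F, the
attribute the detector reports, not area); Δcumulative is the mean over
CS− minus the mean over CS+. Bouton averaging keeps the statistic
comparable across animals with different bouton counts. The cohort
learning correlation is an OLS fit of recall freezing % on Δcumulative;
r² is the squared Pearson correlation.

## Synthetic generators

All generators are pure functions of (truth, seed) and emit ground-truth
sidecars, so every downstream stage is tested closed-loop.

**Vm.** A two-state telegraph process (up −63.5 mV / down −68.5 mV, mean
dwells 0.15/0.25 s — a light-anaesthesia slow oscillation whose histogram is
clearly bimodal at the 0.8 mV noise level) plus Gaussian noise, 2 ms
triangular spikes to +30 mV at 0.3 Hz (so spike removal is exercised), and
a sustained evoked step added from stimulation onset to the end of the
trace (persisting ≥ 30 s beyond offset). A 10 s burn-in puts the telegraph
in its stationary regime; without it the first dwell biases the baseline
fit. A blocker simulation scales the step by (1 − NMDAR fraction). The
default 1 mV step corresponds to an evoked cVm of 27 mV — the scale of the
noise-evoked somatic response — and the state parameters give a per-trial
cVm spread (SD ≈ 11 mV) comparable to the cell-to-cell spread of real
recordings while letting a 100-seed mean recover the step within 10%. The
generator holds the evoked step constant rather than letting it decay after
stimulation, so t₂ values grow linearly with the post-stimulus window
rather than saturating as real responses do.

**Dendrites.** A dendrite is a 2-pixel-wide strip (0.5 µm/pixel, 31 Hz
frames); each event contributes a Gaussian spatial footprint
(σ = FWHM/2√(2 ln 2)) times a slow-indicator double-exponential time course
(rise 0.18 s, decay 1.2 s — conventional slow-variant kinetics, since the
indicators' kinetics are not part of the analysis contract), on a baseline
of 100 fluorescence units with Gaussian noise scaling as √F
(shot-noise-like). The default noise (12 units at baseline brightness)
puts a 0.8 ΔF/F event at peak SNR ≈ 5 at the ROI level — detection and
fitting are non-trivial but achievable, and injected FWHM values between
10 and 81 µm are recovered within a few % in the mean.

**Boutons.** Inhomogeneous Poisson event trains per bouton (20 boutons by
default) with per-epoch rates taken from the measured per-CS transient
counts of conditioned animals, converted to Hz: the learner profile keeps
the first, footshock-free CS+ near baseline (1.03 events/30 s) and raises
paired CS+ (1.97) and CS− (2.07); the non-learner profile is flat
(0.74/0.68/0.77); baseline 0.02 Hz. Amplitudes are lognormal with median
0.3 ΔF/F (a conventional axonal transient size; no amplitude distribution
is part of the contract), fast-indicator kinetics (rise 0.05 s, decay
0.4 s), frame period 0.256 s, additive ΔF/F noise SD 0.05. These defaults
yield detected Δcumulative ≈ 0.07–0.09 for learners and ≈ 0.0–0.03 for
non-learners, with per-animal spread similar to real cohorts.

**Cohort.** Recall freezing = 500 × Δcumulative + 15% + Gaussian noise,
clipped to [0, 100], with Δcumulative uniform on [0, 0.12]. The 6% noise SD
is the value at which the cohort relation has r² ≈ 0.89 over that range,
matching the strength of the reported behavioural correlation; slope and
intercept map the Δcumulative range onto recall freezing between ~15% and
~75%.

What the generators do *not* emulate: biophysical NMDA-spike or network
dynamics, optical point-spread functions and motion artifacts (QC is
exercised with synthetic outlier frames, not realistic motion), indicator
saturation and bleaching, bout-level freezing microstructure, and any
correlation structure between boutons. Passing tests therefore demonstrate
correctness of the estimators under the stated noise models, not robustness
to every artifact of real recordings.

## End-to-end pipeline

`run_pipeline` simulates a cohort (half learner, half non-learner profiles,
protocols alternating), detects bouton transients, computes per-CS
statistics, generates recall freezing from each animal's *measured*
Δcumulative through the cohort relation, scores learning indices, and fits
the cohort OLS. All outputs are reproducible byte-for-byte from (config,
seed); a manifest records the package version and every parameter.
Per-animal seeds are derived arithmetically from the run seed and kept
below 2³¹.

## Problem sizes

Default simulation scales — 150 s Vm traces at 1 kHz, 60 s detector traces
at 3.9 Hz, 12 s single-event dendrite movies, 10-animal cohorts with
20 boutons each, and 50–100 seeds per Monte-Carlo estimate — were chosen so
each stage's sampling error is well inside the tolerances being tested
while a full test-plus-acceptance run stays in the minutes range on one
core.
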
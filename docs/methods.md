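# Methods

`mapkdyn` quantifies live-imaging experiments in which an epithelial
monolayer carries a kinase translocation reporter (KTR) for ERK together
with nuclear labels, and a subpopulation of "inducible" cells can be
switched into an oncogene-expressing state. The package has two halves: a
seeded synthetic-data generator that emulates each input modality with
known ground truth, and the analysis pipeline that recovers biology-level
quantities from those inputs. All spatial units are µm, time is minutes,
angles are degrees, and z increases apically (0 = coverslip).

## ERK activity traces

ERK activity is read per cell and per frame as the cytoplasm/nucleus
intensity ratio of the KTR channel: active ERK phosphorylates the reporter
and exports it from the nucleus, so a higher ratio means more activity.
The ratio is used ordinally throughout; no attempt is made to calibrate it
to kinase activity units. The localization channel (a fluorescently tagged
ERK) is summarized as a nucleus/cytoplasm ratio; sustained activity drives
nuclear accumulation, which the per-cell *localization fold change* (mean
over the final hour ÷ mean over the first hour) captures.

Trace cleaning follows three rules: a trace is dropped if its track jumped
between objects (detected here as any frame-to-frame displacement above 20
µm), if any frame carried a nonpositive intensity (segmentation failure),
or if it covers less than two thirds of the time course. The coverage
threshold is a parameter because fast-moving conditions shorten tracks and
need a relaxed cut. Cleaning is idempotent and every exclusion is logged
with a reason.

### Synthetic traces

Pulsatile traces are sums of symmetric Gaussian bumps on a flat baseline.
Bump times follow a homogeneous Poisson process (`mean_rate`, events/hour)
thinned by a refractory period (default 30 min) and constrained to lie one
pulse width away from either end of the recording, so that every
ground-truth event is a whole, in-window extremum (a truncated half-bump
has no defined in-window peak and would make "true count" ambiguous).
Sustained traces rise logistically from baseline to plateau, with the
10–90% rise spanning `rise_time_min`. Gaussian noise is added per frame;
with `noise_sd = 0` every trace equals its closed-form template exactly.

Defaults — 6 h at 5-min frames, baseline ratio 0.5, pulse amplitude 0.5,
pulse FWHM 20 min, refractory 30 min, noise sd 0.05, sustained plateau 1.5
with onset 60 min — are the package's study conditions. Pulse
amplitude/width statistics for this cell system are not established
quantities; these values were chosen once as realistic for 20–30 min ERK
pulses sampled every 5 min and are free parameters of the generator, not
calibrated claims.

### Peak calling

The caller mirrors a findPeaks-style scheme specialized to these traces:

1. *Candidates.* The trace is smoothed with a centered 3-frame moving mean
   (minimal denoising that preserves 20–30 min pulses) and plateau-aware
   local maxima/minima are located; a plateau is represented by its
   earliest frame.
2. *Refinement.* Each extremum is refined by a least-squares fit of
   `amplitude·exp(−(t−µ)²/2σ²) + offset` (inverted for minima) over ±2
   frames **of the raw trace** — smoothing is only for candidate
   detection, so it cannot attenuate measured amplitudes. The fit is
   solved as constrained least squares on a (µ, σ) grid with closed-form
   amplitude/offset: µ within one frame of the candidate, σ between one
   frame interval and the window span. The lower σ bound is an
   identifiability constraint — on a 5-point window an unconstrained
   4-parameter fit lets σ collapse below the sampling interval, at which
   point the "fitted" extremum value simply interpolates one noisy sample
   and false-peak amplitudes inflate several-fold. The refined value is
   additionally clamped to the window's observed range. Degenerate
   (constant) windows keep the raw frame value.
3. *Decision.* A candidate maximum is a peak iff (i) the rise from the
   preceding refined minimum ≥ `min_amplitude`, (ii) the rise rate
   (Δvalue/Δtime between that minimum and the maximum) ≥ `min_slope`, and
   (iii) a subsequent fall of at least `fall_fraction` × rise occurs
   before the trace ends. Rule (iii) is what makes a sustained plateau
   yield zero peaks.

Thresholds are exposed in `PeakConfig` and were calibrated on the
synthetic ensembles: `min_amplitude = 0.2` sits above the false-rise tail
of extremum-selection noise at the default noise level while staying below
the smallest genuine rise (the second pulse of a refractory-limited pair
rises only ≈ 0.58 × amplitude out of the inter-pulse valley);
`fall_fraction = 0.4` — the fall after the *first* pulse of an adjacent
pair is likewise ≈ 0.58 × amplitude, so demanding half of its full-height
rise leaves under one noise-sigma of margin and discards genuine opening
pulses of close pairs, while 0.4 leaves ≈ 1.8σ and still rejects every
plateau (whose fall is ~0); `min_slope = 0.001` ratio/min rejects hour-scale
drifts but never a genuine pulse — note that for the first pulse after a
long quiescent baseline the preceding minimum can be hours away, so any
larger slope threshold silently discards opening pulses. A brute-force
scan (`scan_peaks_reference`, no smoothing or fitting) implements the same
amplitude/fall/slope definition directly on raw samples and serves as the
independent oracle on noiseless traces.

Known limitation: at noise sd ≳ 0.1 (4× the default) a flat trace starts
to produce occasional false rises above 0.2, because candidate extrema are
selected *as* extremes of the noise; any threshold low enough to resolve
refractory-limited pulse pairs admits some of that tail. Within the
package's study conditions (noise 0.05–0.1 for pulse-bearing traces) the
caller is ≥ 95% exact; applications at substantially worse SNR should
raise `min_amplitude` or widen the smoothing window.

### Dynamics classification

A trace is *sustained* if its duty cycle — the fraction of frames above an
adaptive activity level (10th-percentile baseline estimate + 0.2 ratio
units) — is ≥ 0.8; otherwise *pulsatile* if ≥ 2 peaks were called;
otherwise *quiescent*. The call is a pure function of (duty cycle, peak
count). The percentile baseline estimate assumes ≥ 10% of frames are
pre-onset or inter-pulse; a sustained trace whose onset precedes ~10% of
the recording is the degenerate case (its "baseline" is then the plateau
itself, and with zero noise the duty cycle collapses to 0). Accuracy
checks use a pulsatile archetype at noise 0.1 (amplitude 5× noise), a
sustained archetype at noise 0.2 (step 5× noise), and a quiescent
archetype at the default imaging noise 0.05 — a flat trace has no
amplitude, so "amplitude/noise" does not pin its noise level.

## Directed migration

For one position, the inducible-group center is the centroid of inducible
nuclei at the epoch-start frame (computed once per epoch, not per frame —
the groups are near-stationary on the 4–6 h scale). Neighbors are the
non-inducible cells inside the axis-aligned 200 µm × 200 µm window around
that center at the same frame. Each neighbor contributes displacement
vectors over consecutive non-overlapping 20-min intervals (overlapping
windows would pseudo-replicate autocorrelated motion); an interval whose
endpoint frame is missing is skipped, and zero displacements are dropped
as angle-undefined. The migration angle is the unsigned angle between the
displacement and the unit vector toward the center, folded to [0°, 180°]
(0 = directly toward, 180 = directly away); the toward/away statistic is
symmetric about the center axis, so the fold loses nothing. Radial
histograms use equal-width bins over [0°, 180°], right-open except the
last.

Significance between two angle distributions uses the subsampling
procedure: `n_iter` iterations each draw `min(n_sub, sample size)` angles
without replacement independently from each sample and run a two-sample
Kolmogorov–Smirnov test; the summary is the **median** p over iterations,
star-coded ns/*/**/*** at 0.05/0.01/0.001. Iteration RNGs derive from one
seed, so the median p is reproducible; with `n_iter = 1` and `n_sub` at
least both sample sizes the procedure reduces to the classical test.

Calibration note: with large samples the procedure is deliberately — and
strongly — conservative under the null. Subsampling m = 1000 from n =
5000 and taking the median across iterations removes the subsampling
variability, leaving only the between-base-sample discrepancy, which at
n = 5000 is ≈ √(1000/5000) ≈ 0.45× the KS null scale the m = 1000 test
expects. Monte Carlo (200 replicates): the null rejection fraction at
α = 0.05 is 0.00 and the smallest median p observed is ≈ 0.31. Its power
against real concentration differences is nevertheless excellent (von
Mises κ = 1 vs uniform at 1000 angles/group: median p ≪ 0.001 in every
replicate). The procedure should be read as a guard against the
vanishing-p pathology of enormous pooled samples, not as an exact test.

### Synthetic trajectories

Inducible cells are planted as a compact Gaussian cluster (sd 15 µm)
around the field center; neighbors are uniform over the field. Cells take
fixed-length steps whose headings are uniform, except neighbors under bias
draw headings from a von Mises distribution about the direction to the
group center with concentration κ (the standard single-parameter circular
bias model; κ = 0 recovers an isotropic random walk). Bias can start at a
configurable time to create before/after epochs, and step length can be
rescaled from a set time to emulate induced migration speed-ups. The
optional paracrine wave is purely kinematic: a neighbor at distance d
receives one activity pulse at `trigger + d / wave_speed`. No diffusion,
receptor, or mechanical model is implied — the generator reproduces the
*geometry* of outward-propagating activation, which is all the angle
statistics consume.

## Apical extrusion (ΔZ)

Each imaging position yields a two-channel z-stack (channel "inducible":
inducible nuclei only; channel "all": every nucleus). Per channel, the
per-plane total pixel intensity is computed after subtracting a per-stack
background (median of the lowest-decile pixels, a scheme robust to the
sparse bright foreground) and clipping at zero. This intensity-vs-z
profile is the intensity-weighted nuclear-height density up to
normalization, and is fit with a single Gaussian plus offset by
least squares, initialized at moment estimates (weighted centroid and sd);
non-convergence falls back to the moments with a flag, and flagged
positions are excluded from condition statistics. ΔZ = fitted mean of the
inducible channel − fitted mean of the all-cell channel; positive values
mean the inducible nuclei sit apical to the monolayer. A single Gaussian
is used even though the inducible channel is transiently bimodal
mid-extrusion; mixture modeling is out of scope and the single-Gaussian
mean remains a monotone summary of apical displacement.

Because the all-cell channel contains the (displaced) inducible nuclei
too, ΔZ slightly under-reports the true offset — at 10% inducible
fraction the recovered-vs-true regression slope is ≈ 0.96 rather than 1.

Condition values are normalized by subtracting the mean ΔZ of a reference
(parental) condition, whose normalized mean is then exactly 0. Subtraction
rather than division: parental ΔZ fluctuates around 0, so a ratio would be
unstable and sign-ambiguous. Outliers are flagged by the robust rule
|value − median| > 3 × (1.4826 × MAD) when at least 4 observations are
available; flagged values remain in the output but leave means and tests.
Conditions are compared with Welch's two-sided two-sample t-test,
star-coded as above.

Synthetic stacks render each nucleus as a 3-D Gaussian blob (lateral sd
3.5 µm, axial sd 2.5 µm) on a 128 × 128 × 26 grid (0.65 µm pixels, 1 µm
z-step over 25 µm). Monolayer nuclear heights are N(8, 1.5²) µm; inducible
nuclei are shifted apically by the true offset. 100 nuclei per field
approximate a confluent monolayer (~70 µm²/nucleus); 10% are inducible,
matching the coculture proportions the extrusion assays use.

## Population statistics

S-phase fractions are EdU-positive counts over nuclei counts. The
proliferation fold change is fraction(+Dox)/fraction(−Dox) per position,
divided by the mean fold of the parental condition so that parental
normalizes to exactly 1. The proportion–response relation reports, per
position, the percent of inducible nuclei (from the −Dox composition) and
the neighbor fold change. EdU counts are simulated binomially per
position/population/Dox state.

Shed-protein tables carry four conditions (WT/KO × ±Dox) in triplicate;
designated hits gain a programmed log-fold-change in WT+Dox only
(sheddase-dependent, induction-dependent release). Per protein, ln fold
changes are differences of mean log-abundance (+Dox vs −Dox within WT;
WT vs KO within +Dox) with unpaired t-tests across triplicates (the
simplest test consistent with triplicate designs; no multiplicity
correction, matching the raw p < 0.05 filter downstream). The filter
retains proteins with both p-values < 0.05 and marks them "in box" when
both |ln FC| > ln 1.5; it is monotone in both thresholds.

## Pipeline, formats, determinism

Tables are CSV with fixed headers; stacks are multi-page TIFF
(channel-major pages) with a YAML sidecar carrying channel count and z
scale; ground truth is JSON. Readers validate schemas, reject malformed
rows with line-numbered log entries, and raise before any computation when
a requested stage's config block is missing. The pipeline runner chains
simulate → analyze → report, stamps every CSV with a config hash (the hash
excludes the output directory), and writes a manifest with per-stage
output checksums, row counts and wall times. Every stage is deterministic
given the master seed: re-running a config reproduces byte-identical
outputs, which the manifest checksums make checkable.

## Problem sizes used in the test suite and acceptance script

Trace ensembles use 100–200 cells of 72 frames; KS calibration uses 200
null replicates and 100 power replicates at the procedure's native scale
(1000 iterations × 1000 subsampled angles); ΔZ recovery uses 10 stacks per
true offset over offsets {0, 2, 4, 6, 8} µm; EdU and shed tables use 16
positions × 1000 nuclei and 200 proteins × triplicates. These sizes give
the derived statistics standard errors comfortably inside the asserted
bands while keeping a full run of the suite and the acceptance script in
the minutes range on a single core.
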
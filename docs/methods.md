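# Methods

This note documents the models and numerical choices behind `sleepcoord`: the
detectors, the coordination statistics, and the synthetic generator used to
validate them. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal primitives

All filtering is zero-phase by default: the order-4 Butterworth band-pass is
applied forward and backward (`sosfiltfilt`), which squares the magnitude
response and removes group delay. Edges are handled by reflection padding of
roughly three filter time constants. Smoothing kernels (the 300 ms/40 ms
Gaussian of the envelope-threshold spindle detector, the 400 ms and 600 ms
Tukey moving averages of the candidate-epoch detector) are normalized to unit
sum, so constants pass through unchanged; the Tukey taper fraction defaults to
0.5. Envelopes are Hilbert analytic amplitudes.

The event-locked spectrogram is a Hann short-time FFT (0.5 s segments, 25 ms
hops), averaged over epochs, converted to dB and baseline-corrected by the
epoch-wide mean per frequency. Significance is assessed per cell against 200
surrogate averages computed at circularly shifted event times, two-sided and
uncorrected at the requested level. It is a functional diagnostic, not a
bit-match for any particular plotting toolbox.

## Downstate detection

Half-waves of the 0.1–4 Hz signal are delimited by consecutive zero crossings
0.25–3 s apart (strict variant 0.25–1 s); the extremum between the crossings
is the wave peak. Per channel, the most extreme 40% of peaks of each sign are
retained (strict: 20%), with floor counts and ties broken toward the earlier
peak. Percentiles pool over the whole analysed (N2/N3, exclusion-free)
record.

Which sign is the DS is decided from 60–100 Hz amplitude. Cortex: the sign
whose mean gamma in ±250 ms around the peak falls below the ±3 s epoch
baseline, with a Welch t-test between signs gating significance (no
significant asymmetry, or no actual decrease, raises
`PolarityUndeterminedError` and the channel is excluded, not silently
labelled). Thalamus: baseline gamma is minimal, so the DS sign is the one with
a gamma *increase* in the 100–500 ms down-to-upstate transition window; the
assignment is then validated by splitting the putative DSs into the top and
bottom 10% of post-peak (0–500 ms) spindle-band amplitude and requiring a
significant transition gamma increase in *both* strata — this guards against
mistaking spindle-band leakage for the transition signature.

Artifact rejection removes any event whose ±3 s epoch (−2/+4 s for spindles)
contains a first difference above a per-channel threshold or an absolute value
above 7 SD of the rectified signal pooled over all epochs. The per-channel
visual diff thresholds of clinical practice are not recoverable in code; the
automated surrogate is 3× the 99.99th percentile of the absolute first
difference, which sits above physiological fast activity (spindle and gamma
cycles) but far below step or spike artifacts. Run manifests flag the
surrogate.

## Spindle detection

**Envelope-threshold ("previous") method.** Detection threshold mean + 3 SD
(cortex) or mean + 1.5 SD (thalamus) on the Gaussian-smoothed spindle-band
envelope; boundaries at mean + 1 SD; durations restricted to 0.3–2 s.

**Candidate-epoch + classifier ("current") method.** The edge envelope is the
rectified 10–16 Hz signal under a 400 ms Tukey average; a further 600 ms
average gives the amplitude envelope. The per-channel candidate threshold is
the smallest amplitude-envelope peak inside any manually marked spindle.
Candidates are located at supra-threshold amplitude-envelope peaks, bounded
where the edge envelope is ≥ 0.45 × its matched peak, with epochs under
300 ms discarded and overlapping epochs merged. Note that the 300 ms floor
applies to *epochs*: after the 400 ms smoothing even a quarter-second burst
usually produces a longer epoch, so the floor binds mainly when a small local
edge peak is matched against a larger neighbour.

Fifteen metrics are computed per epoch (amplitude-envelope peak, duration,
FFT amplitudes in 10–16 and 5–8 Hz and their ratio, spindle peak frequency,
10–16 / 4–8 / 18–25 Hz band-envelope maxima, sleep stage coded N3 = 1, number
of band-passed peaks, peak rate, inter-peak interval mean and SD, and a flag
for peak rate in 10–16 /s). FFTs use the mean-removed raw epoch zero-padded
to 4 s (≥ 0.25 Hz resolution); peaks are counted with prominence ≥ 10% of the
segment's envelope peak.

Model selection: zero-variance columns are dropped, then the predictor with
the largest variance inflation factor is removed iteratively while it exceeds
10 (ties, including jointly infinite VIFs, remove the larger column index
first). Bidirectional stepwise selection minimizes AIC from the full
surviving set and is deterministic given the data; a bootstrap (rows resampled
with replacement, single-class resamples redrawn) reports per-feature
selection frequencies. The probability cutoff scans a 0.5% grid over
leave-one-out predicted probabilities and minimizes |FPR − FNR| with ties
toward the lower threshold. The printed rate definitions are used verbatim —
FPR = FP/(FP + FN), FNR = FN/(TP + FN) — with the textbook FP/(FP + TN)
available via `fpr_convention="standard"`; the printed convention is unusual
but is applied as stated rather than silently corrected.

Logistic fits use a Newton/IRLS solver with internal feature standardization;
on (quasi-)complete separation or non-convergence the fit falls back to a
small ridge penalty (α = 1 on z-scored predictors) with a warning, which keeps
leave-one-out probabilities away from exact 0/1. The solver is cross-checked
against statsmodels' `Logit` in the test suite.

Training labels: candidates overlapping a manual mark by any amount are class
1; candidates inside the exhaustively marked periods matching no mark are
class 0; everything else is unlabelled and only scored. Detection applies the
cutoff, then removes events outside N2/N3 or touching exclusion intervals,
then runs artifact rejection on −2/+4 s epochs. Spindles are classed slow
(> 10, ≤ 12 Hz) or fast (> 12, < 16 Hz) by FFT peak frequency.

## Coordination statistics

Peri-event histograms count every (reference, target) pair within the window
in 50 ms bins with edges at bin multiples. The binomial order test counts
target events in (−500, 0) versus (0, +500) ms of each reference (all pairs by
default, nearest-only as an option; exact zero lags are excluded) and is
two-sided exact at probability ½; Bonferroni adjustment is α/n over tested
pairs. The conditional-probability matrix reports P(thalamic DS within 500 ms
after a channel-i DS) on the diagonal and the same probability additionally
conditioned on a channel-j DS off the diagonal. The χ² test compares the
joint condition against the *disjoint* complement (channel-i DSs without a
channel-j DS): the joint events are a subset of the single-channel events, so
testing against the diagonal itself is miscalibrated; the disjoint contrast
tests the same hypothesis and is calibrated (checked by simulation in the
acceptance suite). Calibration of the χ² holds in the regime where
conditioning windows do not overlap — DSs cannot recur within 500 ms — and
cell counts support the asymptotics.

The cortico-thalamic DS delay averages the 0.1–4 Hz cortical signal locked to
thalamic DS peaks preceded by a cortical DS within 500 ms, and takes the time
of the minimum in [−0.5, 0] s per pair, then the mean over pairs. DS onset is
the real root of the second derivative of a degree-20 polynomial (fitted on a
time axis normalized to [−1, 1] for conditioning) closest to the supplied
guess; on waveforms whose onset is a curvature kink rather than a sign-change
inflection (for example an ideal half-sine) this localizes the onset only to
about a tenth of a second, while smooth sigmoid-like onsets are recovered to
milliseconds.

The trough-locked gamma delay spline-interpolates (cubic, 8× upsampled) the
55–100 Hz analytic amplitude of each structure and, for each thalamic spindle
trough, finds the nearest envelope peak within ±35 ms per structure. A peak
must have prominence ≥ 2× the median envelope — without this floor,
micro-maxima of the noise envelope sit closer to the trough than the true
gamma burst and shrink the estimated lag toward zero; troughs lacking a
qualifying peak in either structure are excluded and counted. The delay is
the mean of (cortical − thalamic) peak times; consecutive non-overlapping
trough subsets give per-subset mean latencies compared by a paired two-tailed
t-test (the subset construction is one reading of an ambiguous published
procedure and is flagged as such).

Enrichment factor: (bins-per-minute × tallest 50 ms bin count within ±500 ms
of DS peaks) / n_DS, divided by the channel's overall spindle density.
Coupling windows for the normalized proportion are [0, +750] ms (cortex) and
[−500, +250] ms (thalamus) around DS peaks, normalized by the channel's DS
count over the subject maximum. Overlap between channels counts any temporal
intersection, boundary touching included.

## Detector scoring

Detections match truth intervals greedily by largest overlap, one-to-one —
in contrast to the any-overlap counting of the between-channel overlap
statistic, so each manual mark is credited at most once. d′ and C come from
normal quantiles of hit and false-alarm rates with the log-linear (+0.5 per
cell) correction at 0/1 rates. The true-negative count, which the published
rates never define, is taken as the number of unmatched non-spindle candidate
epochs — the natural "non-spindle unit" of this pipeline — and is a
convention, not a reproduced fact.

## The synthetic generator

The generator's defaults encode the study conditions: cortical DS density
16.3/min and thalamic 11.5/min, spindle densities 5/min (cortex) and 7.1/min
(thalamus), cortical→thalamic DS lag Normal(218, 66) ms, thalamic spindle
onset at the thalamic DS peak, thalamo-cortical spindle lag 15 ms (so cortical
spindle onsets land ≈ 233 ms after the cortical DS peak, in the 200–250 ms
histogram bin), spindle durations 0.4–1.6 s at 10–16 Hz, recording at 256 Hz
with four cortical and two thalamic channels.

Scheduling: cluster seeds follow a gamma-renewal process (shape 2, rate
30/min); each cortical channel joins a cluster with probability q unless it is
inside a 1.25 s slow-oscillation refractory period; a thalamic DS follows a
cluster of size k with probability {1: 0.20, 2: 0.38, 3: 0.53, 4: 0.64} and
the configured lag; a thalamic spindle follows a thalamic DS with the
probability implied by the spindle density, and projects back to each
participating cortical channel with the probability implied by the cortical
spindle density. Because refractory and edge thinning remove a predictable
fraction of nominal events, the derived probabilities include a fixed
schedule-loss factor (0.74) so realized densities land on the configured
values.

Rendering: the DS is a 500 ms negative half-sine with an area-balanced
upstate rebound (0.6 amplitude, 1.5× width — zero net area, so the
acquisition-high-passed event train does not bias the baseline); spindles are
Tukey-windowed sinusoids (taper 0.25, so the detector's 45%-crossing onset
sits within ~25 ms of the scheduled onset); high gamma is band-limited noise
whose amplitude is suppressed 80% during cortical DS troughs, raised on
cortical upstates, boosted strongly on thalamic down-to-upstate transitions
(thalamic baseline gamma is set low, as in thalamic recordings), and bursts
phase-locked to individual spindle troughs. Short (0.15–0.28 s) in-band
"distractor" transients at 6/min supply the non-spindle candidate epochs a
classifier must learn to reject; a perfectly clean simulation would otherwise
contain no class-0 training epochs at all.

Background noise is 1/f^a Gaussian noise shaped by a 0.16 Hz acquisition
high-pass (clinical amplifiers band-pass at acquisition) plus a ~1.1 Hz delta
bump emulating ongoing sub-threshold slow-wave activity. The slopes (cortex
1/f^0.8 with bump gain 4, thalamus 1/f^2.8 with gain 2) and amplitudes
(events: DS 200/90 µV, spindles 40/30 µV for cortex/thalamus; background RMS
15/7 µV) were fixed once, by a calibration experiment, so that the background
produces qualifying 0.25–3 s half-waves at about 2.5× the scheduled DS rate —
the regime the fixed-fraction (40%) retention rule presupposes: retaining 40%
of too few waves discards true DSs, of too many admits background waves. The
published analyses operated on real N2/N3 sleep, where this ratio holds by
construction of the 40% choice. Amplitude draws are clipped (DS factor
0.6–1.4, spindle lognormal factor 0.45–2.2) so no physiological event crosses
its own channel's 7 SD artifact threshold.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: volume conduction (bipolar derivations justify
independent channel noise), non-stationary sleep architecture (stages
alternate in fixed 5-minute blocks), spindle frequency drift within events,
uncoupled ("isolated") thalamic spindles (every scheduled thalamic spindle
descends from a thalamic DS, so synthetic coupling proportions and enrichment
factors are far higher than any real recording's), epileptiform activity
beyond the simple step/spike injections used by the artifact-rejection tests,
and real inter-subject variability of amplitudes and spectra. Detector
performance on this synthetic benchmark is an upper bound, not a clinical
validation.

## Problem sizes and determinism

The test suite and the acceptance script use a 30-minute, six-channel
simulation (plus smaller purpose-built fixtures); statistical-calibration
checks use 600–1000 replicates of independent event trains. All randomness is
seeded: the generator consumes a single config seed, bootstrap and classifier
training take explicit seeds, and `scripts/acceptance.py` derives everything
from its `--seed` argument. Hypothesis-based property tests run
derandomized.
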
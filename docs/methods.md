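# Methods

This note documents the models and procedures behind `sleeplfp`, the
reasoning for each default, and what the synthetic validation does and does
not establish.

## Signal model and time base

A recording is a channels × samples array in µV at a single sampling rate
(≥ 200 Hz; typical rodent polygraphy is digitized at 1 kHz). Sample `i` maps
to time `start_time_s + i/fs`; all intervals are half-open `[onset, offset)`
with 0-based indices. Vigilance states are per-4 s-epoch labels
(WAKE/NREMS/REMS/ARTIFACT); an epoch has exactly one state, and state
changes are resolved only at epoch granularity. Analyses run on
*consolidated* NREMS bouts — maximal runs of NREMS epochs strictly longer
than 20 s ("> 20 s" taken literally, so a 20 s run is excluded). Artifact
and transition epochs break bouts and are never bridged.

## Spectral estimation

Non-overlapping rectangular 4 s windows are tiled inside each bout
(remainder samples dropped; windows never span bouts). Each window is
mean-subtracted and transformed with a squared-magnitude FFT; window spectra
are averaged with equal weight. No taper or overlap is used — the estimate
is deliberately the plainest consistent choice, and the 4 s window fixes a
0.25 Hz grid. The one-sided density is scaled so its sum equals the
mean-square of the windowed signal (Parseval-consistent), which makes the
subsequent normalization — density ÷ (0–35 Hz sum) × 100, the 35.00 Hz bin
included — exactly scale-free.

Band powers are bin sums over half-open intervals `(lo, hi]`: a bin lying
exactly on a shared border (1.5 Hz between SO and delta) counts for the
lower band only, so SO (0.5–1.5 Hz), delta (1.5–4 Hz) and sigma (10–15 Hz)
partition their stretch of the axis and never double-count.

Open choice: whether per-animal spectra should weight recording days
equally or by NREMS amount is under-determined; all windows are averaged
equally here, and per-segment weighting can be composed by the caller from
per-segment spectra.

## Spindle detection

1. Zero-phase FIR band-pass 9–16 Hz (Hamming design, ~53 dB stop band,
   transition ≈ 2 Hz, applied forward–backward).
2. Point-wise squaring, then a **100 ms moving average**. The raw squared
   signal oscillates at twice the spindle frequency and would fragment
   every event into half-cycle islands; 100 ms exceeds one oscillation
   period (≈ 80 ms at 12.5 Hz) while staying much shorter than a spindle.
   The length is exposed (`smooth_ms`) because it is an interpolation of
   the method, not part of it.
3. Threshold = mean + 1.5 × SD of the envelope over all NREMS samples of
   the recording (one threshold per signal, not per bout; population SD —
   at these sample counts the sample/population distinction is far below
   any other uncertainty).
4. Supra-threshold runs must contain ≥ 3 full cycles of the band-passed
   signal, counted as zero crossings within the run (k crossings bound
   (k−1)/2 cycles). The criterion is applied to the supra-threshold core,
   the stricter of the two possible readings; a fixed-duration alternative
   (`min_duration_s`) is available.
5. Accepted runs are extended to the nearest band-pass zero crossing before
   the onset and after the offset; extended events that overlap or are
   separated by < 10 ms are fused transitively (fusion is final — the cycle
   criterion is not re-applied); events touching the first or last sample
   of their bout are discarded. Fusion precedes the edge rule.

Event amplitude is the arithmetic mean of the envelope over
`[onset, offset)` (µV²; no per-animal normalization). Intra-spindle
frequency is the peak of the magnitude FFT of the mean-removed, band-passed
event segment, zero-padded to a 0.25 Hz grid, restricted to 9–16 Hz. The
peak counts as *distinguishable* only if it is a local maximum with
magnitude ≥ 2 × the median in-band magnitude — a concrete operationalization
of an otherwise qualitative notion; both the ratio and a raw-trace mode are
exposed.

The detector is amplitude-scale covariant: scaling the trace by k scales
envelope and threshold by k² and leaves event times unchanged.

## Slow-oscillation detection

The trace is low-passed at 2 Hz (zero-phase FIR, transition ≈ 1 Hz). Zero
crossings delimit half-waves; each negative-then-positive half-wave pair
gives a candidate with trough (x1, y1) and peak (x2, y2). Candidates never
span bout boundaries. With Y1/Y2 the candidate means over the whole
recording's NREMS (a single per-recording statistic), a candidate is
selected when

1. 0.5 s ≤ x2 − x1 ≤ 2 s (bounds inclusive),
2. y1 < ⅔·Y1 (both negative; "lower" = more negative),
3. y2 − y1 ≥ ⅔·(Y2 − Y1).

All three criteria are time- or ratio-based, so selection is invariant under
trace rescaling. Peak-then-trough pairs are not candidates. The **SO
period** used downstream runs from the zero crossing before the trough to
the zero crossing after the peak — one full cycle; this concrete definition
of the event extent is a package choice, exposed through the event fields.

## Spindle–SO coupling

The Hilbert transform is taken over whole low-passed NREMS bouts (edge
distortion confined to bout margins, which the event rules exclude), never
per SO period. Phase convention: 0° at the SO positive peak, ±180° at the
trough, so the rising trough→peak segment (−180°, 0°) is the cortical
active state (AS) and [0°, 180°] the silent state (SS); boundary phases 0°
and 180° are assigned to SS (half-open convention). LFP polarity depends on
referencing; `invert_polarity` flips the mapping.

A spindle enters the analysis when ≥ 95 % of its duration is covered by the
**union** of SO periods, and is paired with the single maximal-overlap SO
event (ties → earlier). Consecutive selected SO cycles produce abutting
periods, so a spindle straddling a cycle boundary is still "inside the SO";
testing coverage per single event instead would exclude onsets just before
each falling zero crossing — a phase-selective censoring that distorts the
AS/SS fractions the analysis exists to estimate.

Occurrence histograms use 30° bins tiling (−180°, 180°] (bin width
configurable; the choice is conventional).

## Synthetic LFP generator

NREMS segments are the sum of: an SO cosine (default 0.8 Hz, 75 µV, phase
0° at bout start), band-limited Gaussian delta activity (1.5–4 Hz, RMS
25 µV), 1/f background noise (RMS 15 µV, slope 1), and injected spindles.
WAKE/REMS segments carry background noise only. Spindles are carriers of
9.5–15.5 Hz (normal, mean 11 Hz, SD 1 Hz — the intra-frequency distribution
peaks near 10–12 Hz) under a raised-cosine (Tukey) envelope with a 30 %
taper and ≥ 4 full cycles (normal duration 0.6 ± 0.12 s), amplitude 60 µV
in the spindle-rich preset. The carrier bounds sit inside the 9–16 Hz
detection band because the FIR response is −6 dB exactly at the band edges,
and the cycle floor keeps every injected event on the detectable side of
the detector's own 3-cycle rule: ground truth should test recovery, not
encode events the method rejects by definition. The Tukey taper
(`taper_fraction=1` gives a full Hann bell) reflects that spindles sustain
supra-threshold sigma power through the event; a pure bell makes the
mean+1.5 SD threshold crossing lag the true onset by > 100 ms for *any*
detector implementing these rules.

Spindle counts per bout are Poisson at the configured rate. Each event's
onset phase on the SO cycle is drawn first — von Mises around
`phase_pref_deg` with concentration `phase_kappa`, or uniform at κ = 0 —
and only then is a concrete SO cycle chosen uniformly among the
collision-free placements, so the realized phase distribution is exactly
the drawn one. Events with no feasible placement are skipped and counted
(`n_skipped`); at default densities this thinning is negligible.
`kappa_for_as_fraction` inverts the von Mises half-circle mass so an
active-state preference (e.g. 0.70) can be dialled directly. All draws flow
from one `numpy` generator stream: identical seeds give bit-identical
recordings.

**What the generator does not emulate:** amplitude-nonstationary SO trains
(fixed frequency and amplitude per bout), spindle amplitude–SO phase
coupling beyond onset preference, state-transition artifacts, EMG, inter-
channel correlation, and the across-animal variability of real data sets.
Passing recovery tests therefore demonstrates correctness of the *analysis
under the stated signal model*, not detector performance on arbitrary
recordings.

## Statistics stage

Normality is screened per group with Shapiro–Wilk at α = 0.05 (the screen's
α is conventional; groups smaller than 3 fall back to rank tests). Unpaired
comparisons use Student's t (both groups normal) or Mann–Whitney U; paired
designs use paired t or Wilcoxon signed-rank. When more than two
comparisons share one data set, the reported significance threshold is
α/m — e.g. 0.05/3 ≈ 0.017 for the three frequency bands.

## Numerical choices and degenerate inputs

- FIR tap counts follow the Hamming rule `numtaps ≈ 3.3·fs/transition`;
  `filtfilt` padding is capped at signal length − 1 so short traces remain
  filterable (their edges are less accurate, and excluded by event rules).
- Zero crossings treat exact zeros as positive; crossing index is the first
  sample on the new side.
- Quantile binning distributes remainder epochs to the earliest bins.
- Degenerate inputs raise rather than default silently: missing sampling
  rate metadata, non-contiguous hypnogram epochs, zero-power spectra,
  empty NREMS envelopes, inverted band edges, sub-3-cycle waveform
  requests. Empty *detector output* is valid (no events is a result).
- Unknown hypnogram state strings degrade to ARTIFACT with a logged
  warning; unknown config keys are errors.

## Validation problem sizes

The test and acceptance runs use synthetic recordings of 3–25 min at
500–1000 Hz: 10 min of NREMS with ~60 injected spindles for detector
recovery; four ~6 min bouts (~250 included spindles) for phase-preference
recovery; 20 seed-matched recording pairs for the preset band-power
contrast; deterministic constructions (pure sines, hand-built candidate
sets, step/ramp series) for the rule-level oracles.

## Known limitations

- The 3-cycle rule interacts with the self-referential threshold: in
  spindle-dense signal the threshold rises, shortening supra-threshold
  cores; very short or band-edge events are rejected by design.
- Trough-to-peak timing (criterion 1 of SO selection) rejects genuinely
  oscillatory cycles whose extrema are jittered across the 0.5 s bound by
  slow noise; with a 0.8 Hz SO this affects ~10 % of cycles at the default
  noise levels.
- Hilbert phase at spindle onsets carries ±~10° of jitter from sub-2 Hz
  noise leakage, adding (unbiased) misclassification near the AS/SS
  boundaries.
- EDF support is read-only and assumes equal sampling rates across
  channels.
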
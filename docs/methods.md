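# Methods

## Estimators

For a signal vector `x` of length N the package computes

- Activity `= Var(x)`,
- first difference `d_i = x_{i+1} − x_i` (N − 1 entries),
- Mobility `= sqrt(Var(d) / Var(x))`,
- Complexity `= Mobility(d) / Mobility(x)`.

**Variance convention.** Both variances use the population denominator
(mean squared deviation over the entries actually present: N for `x`,
N − 1 for `d`, N − 2 for `dd`). Textbook presentations sometimes mix
`1/N` for the signal with `1/(N−1)` for the differences; a mixed
convention breaks exact scale equivariance (`Activity(c·x) = c²·Activity(x)`)
and the exact agreement with a direct transcription of the definitions,
which the tests assert to 1e-12. The difference between conventions is
an O(1/N) factor, negligible at the 125–500-sample windows used here.

**Units.** The first difference is a raw per-sample difference — no
multiplication by the sampling rate — so Mobility is dimensionless
(per-sample) and Complexity is a pure ratio. For a sampled sinusoid at
frequency f, Mobility is exactly `2·sin(π·f/fs)`; converting a mobility
value to an equivalent frequency in Hz is left to the caller.

**Degenerate signals.** A zero-variance signal has undefined Mobility,
and a zero-variance first difference (a linear ramp) has undefined
Complexity. Scalar calls raise `DegenerateSignalError`; bulk/windowed
extraction substitutes NaN (Activity is still reported, e.g. 0 for a
constant window), logs a warning, and downstream analyses exclude those
rows (listwise) with the exclusion count logged. Listwise rather than
pairwise exclusion keeps the correlation matrix a true correlation
matrix of one common row set (always symmetric positive semidefinite)
and keeps correlation and clustering operating on the same rows.

**Bounds and their fine print.** Under the difference-operator spectrum
(weight `w(ω) = 4 sin²(ω/2)`, maximal at the Nyquist frequency),
Mobility² is a spectral mean of `w` — hence Mobility ≤ 2 — and
Cauchy–Schwarz gives Complexity ≥ 1. These identities are exact for
circular differences; the linear (non-circular) differences used here
add O(1/N) edge terms, so finite narrowband samples can undershoot the
Complexity bound slightly (measured: 0.93 for a non-integer-period
sinusoid at N = 500; 0.999 for narrow band-limited noise at N = 125)
and very short vectors can overshoot the Mobility bound (2.12 at
N = 3). The property tests therefore assert both bounds on broadband
stationary fixtures at window-scale lengths (Gaussian noise,
N ∈ [64, 512]), where the spectral argument applies and the bounds hold
with a wide empirical margin; scale/shift equivariance is asserted on
arbitrary fixtures because it holds identically.

## Windowing

`windowed_hjorth` slides a window of `window_length` samples with step
`hop`, keeping only full windows (starts 0, hop, 2·hop, …). The default
analysis windowing is 125 samples (1 s) with a 25-sample (0.2 s) hop —
fine enough to show within-trial feature dynamics, long enough that the
variance estimates are stable. Full-trial mode (one window spanning the
trial) is the default for `build_feature_table` and is what the
clustering evaluation uses, since task labels live at trial level. Both
modes are exposed because per-recording feature series and per-trial
feature points are both standard presentations.

## Synthetic generator

Each channel is zero-mean Gaussian noise band-limited to the 5–50 Hz
acquisition band (zero-phase forward–backward Butterworth of order 4,
chosen to mimic an acquisition bandpass without phase distortion),
rescaled so its sample SD equals the electrode's `noise_sd` exactly,
plus — where `burst_sd > 0` — an independent band-limited component in
a narrower task band. Hjorth parameters depend only on second-order
structure, so this is the minimal model that gives the generator full
control over the features the analysis consumes.

Default parameters (µV), fixed by spectral-moment arithmetic:

| task | noise_sd | burst_sd | burst band |
|---|---|---|---|
| Rest | 8 (14 on electrodes 14–15) | 0 | — |
| BEO | 8 | 5 | 8–13 Hz |
| movement (CLH, CRH, DLF, PLF, DRF, PRF) | 8 | 12 (18 on a task-specific electrode pair) | 8–30 Hz |

Consequences: every movement electrode's variance (8² + 12² = 208 µV²)
exceeds the largest Rest variance (14² = 196 µV²), so movement Activity
dominates Rest on all electrodes; the Rest state carries the elevated
electrodes 14–15 as its own signature; the 8–30 Hz burst lowers the
spectral centroid, separating movement from Rest in Mobility and
Complexity as well; and the per-task emphasis pairs give the eight
tasks distinct spatial signatures. Windowed movement features land in
realistic EEG ranges (activity up to a few hundred µV², mobility
roughly 0.3–1.4, complexity between 1.1 and 3).

Sessions follow a documented default schedule of 62 (task, Rest) pairs
= 124 trials, the seven non-Rest tasks cycling in protocol order with a
Rest trial after every task; the schedule is an explicit argument, not
an inferred protocol. Per-trial random substreams are keyed by
`(seed, CRC-32(subject), task ordinal, trial index)`, so any trial can
be regenerated in isolation, bit-identically, regardless of generation
order.

What the generator does **not** emulate: 1/f background, ocular/muscle
artifacts, nonstationarity within a trial, inter-subject variability,
volume conduction between electrodes. Passing recovery tests therefore
show the pipeline is correct and sensitive under controlled
second-order structure — not that real recordings separate this
cleanly.

## Analysis choices

- **Correlation**: Pearson over complete rows, recorded in the result's
  method label; Spearman is a parameter away. Electrode–electrode
  correlation of a single feature is exposed as an optional view.
- **Clustering**: features are standardized per column (z-score) before
  k-means, because Activity's µV² scale would otherwise dominate the
  Euclidean metric; k-means runs 10 restarts with a fixed seed, and
  rows are first sorted into a canonical key order so results are
  bitwise reproducible and invariant to input row order. Agreement with
  task labels uses the adjusted Rand index (chance-corrected; 1 =
  perfect). A permutation helper rebuilds the null ARI distribution by
  label shuffling for significance context.
- **Task contrasts** are descriptive only: per-electrode mean
  differences, ratio of mean activities, and Cohen's d (NaN, not an
  error, when a group has fewer than two observations). No hypothesis
  tests are performed.

## Problem sizes and determinism

The shipped evaluation sizes — 30 trials per task for two-task
recovery, 6 per task for eight-task clustering, 124-trial sessions,
100 000-sample noise oracles, 100-seed periodogram averages — run the
full suite in about a minute on one CPU while leaving the Monte-Carlo
margins far from the asserted thresholds. All randomness flows from
explicit integer seeds; pipeline outputs (trial CSVs, feature tables,
reports) contain no timestamps and are byte-identical across reruns
with the same configuration.

## Known limitations

- The CSV dialect is the package's own (comma-separated, header
  `E1..E16`); adapting a real dataset's naming scheme is a
  manifest-construction concern left to the caller, and files with
  extra columns (timestamps, annotations) are rejected rather than
  guessed at.
- Mobility/Complexity are reported per sample; cross-dataset
  comparisons at different sampling rates need the caller to account
  for fs.
- No supervised classification is implemented; clustering agreement is
  the only label-recovery evaluation.
- Frequency-domain (spectral-moment) estimation of the parameters is
  out of scope; only the time-domain difference estimators are
  provided.
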
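# Methods

## The analysis in one paragraph

Subjects are represented by feature vectors computed from their ECG alone,
clustered with k-means at k = 2, 4, 8, and the clusters are cross-tabulated
against medical-record condition flags (obesity, smoker, hypertension,
diabetes). Two statistics summarize cluster/condition association: the
**ratio** (fraction of a cluster positive for a condition, with > 50% read as
a significant association) and the **concentricity** (the largest
single-cluster share of all positives for a condition, which stays
informative when a condition is too rare for any within-cluster majority).
Because real clinical recordings and their private preprocessing parameters
are not distributed with this package, all quantitative claims are made on a
synthetic cohort whose generating process is part of the package and fully
seeded.

## Synthetic cohort model

Each beat is a sum of five Gaussian bumps. A wave is (amplitude mV, center ms
relative to the R apex, sigma ms); the default morphology is a textbook
limb-lead beat:

| wave | amplitude (mV) | center (ms) | sigma (ms) |
|------|---------------|-------------|------------|
| P    |  0.15         | −160        | 22         |
| Q    | −0.10         |  −28        |  9         |
| R    |  1.00         |    0        | 11         |
| S    | −0.18         |   28        |  9         |
| T    |  0.30         |  260        | 45         |

R-R intervals are drawn i.i.d. from Normal(60000/hr, rr_sd) ms, clipped
positive; the first apex sits half an interval into the record. The
sum-of-Gaussians idealization (as in ECGSYN) was chosen over spliced
templates because every fiducial point is analytically known, making
delineation and QRS-detection tests exact.

Per subject, base morphology is jittered multiplicatively (default 8%,
normal, clipped at ±2.5σ; R's center stays at 0), heart rate is drawn from
Normal(72, 8) bpm clipped to [40, 160], and condition flags are independent
Bernoulli draws at the configured prevalence (defaults are the PTB diagnostic
cohort counts over 290 subjects: obesity 20, smoker 73, hypertension 63,
diabetes 29). Flagged subjects then receive configurable effect deltas.
Shipped defaults — plausibility values motivated by the clinical literature
on these conditions, **not** measured effect sizes:

* diabetes: QRS widening ×1.4 (Q/R/S sigmas and the Q and S center offsets)
  and T amplitude ×0.7;
* hypertension: R amplitude ×1.3;
* smoker: heart rate +15 bpm;
* obesity: all wave amplitudes ×0.8.

Scaling the Q and S *centers* along with the widths matters: widening the
Gaussians alone would leave the Q-to-S span, and hence the measured QRS
duration, nearly unchanged.

Noise is additive with five seeded, independent streams: baseline wander
(five sinusoids at random frequencies in 0.05–2.00 Hz), a power-line tone
(50 Hz default), EMG (white noise FIR-shaped into 20–150 Hz, unit-variance
normalized then scaled), sparse electrode-motion transients (Poisson events,
60 ms Gaussian bumps of random sign), and white noise. A zero-amplitude spec
is the identity; zeroing one class does not change the realization of the
others.

Seeding: one master seed; subject i's clean-signal and noise seeds are
`(master·1000003 + 2i) mod 2³¹` and that value +1, and profile sampling uses
a separate fixed offset — so any subject can be regenerated in isolation,
bit for bit.

**What the generator does not emulate**: multi-lead geometry (one synthetic
lead), pathological beat classes (ectopy, infarction, bundle-branch block),
heart-rate-dependent morphology (QT adaptation), non-stationary noise
bursts, and realistic covariance between conditions (flags are independent).
Passing tests therefore demonstrate that the pipeline recovers structure a
condition imposes on beat morphology; they do not certify performance on
clinical recordings.

Default record parameters: 1000 Hz sampling (the PTB digitization rate) and
10 s duration — long enough for ~12 beats, i.e. ~10 complete cycles, which
supports two four-segment wavelet groups and a stable per-beat median, while
keeping 200-subject cohort runs to seconds.

## Preprocessing

**Denoising** is a linear-phase FIR band-pass (firwin, Hamming), default
0.5–40 Hz, applied forward and then backward by FFT convolution so the net
phase is zero (the magnitude response is squared; in-band ripple is
negligible, hence in-band idempotence to < 1%). The nominal tap count
4·fs/low is capped at a third of the record length so short records stay
well conditioned. An IIR notch and wavelet soft-threshold shrinkage
(universal threshold, σ from the MAD of the finest detail band) are optional
and off by default — the synthetic data controls its own power-line content.

**QRS detection** takes the positive-to-negative zero crossings of the
first-order derivative of a 5–25 Hz band-limited copy (local maxima of the
QRS-band signal; the band-limiting suppresses P/T waves and baseline so a
plain amplitude floor is meaningful). Two non-linear suppressions follow: a
candidate must reach 0.3× the running median of the last eight accepted peak
amplitudes (bootstrap: the 95th percentile of candidate amplitudes), and
candidates within a 200 ms refractory window of the last accepted peak are
discarded. Accepted peaks are finally refined to the raw-signal maximum
within ±40 ms. The refractory constant and the floor fraction are standard
ECG practice, not derived values, and both are configurable.

**Beat segmentation** yields one beat per interior R peak, windowed from the
previous to the next R (open at the next), so windows tile the detected span
exactly; the two edge peaks have no complete cycle and are dropped.

## Feature extractors

**RBP** — implemented exactly as defined (ties are decreases; sliding
stride-1 windows; first bit most significant; frequencies over all 2^m
bins). Word length m is not fixed by the method's description; the default
is m = 8 (256 bins), in line with the symbolic-dynamics lineage the feature
comes from, configurable 1–16. The feature is computed on the denoised full
record without segmentation and is invariant to positive affine rescaling of
the signal by construction. Bit order is arbitrary but fixed: any consistent
order permutes histogram bins, and clustering is permutation-invariant.

**Wavelet** — each R-R cycle's first 169 and last 85 samples are
concatenated. 169 + 85 = 254, not 256; the stated segment length is honored
by repeating the final value twice (edge replication adds no spurious
discontinuity), and a `strict_254` mode skips the padding. Cycles shorter
than 254 samples are skipped and counted. Segments are grouped four at a
time (a trailing partial group is dropped), each segment gets an n-level DWT
(default db4 — orthogonal, so energy checks are exact; level 6), and the
four coefficient vectors are concatenated per group. Boundary handling is
periodization, which keeps exactly 256 coefficients per segment at any level
and permits all 8 levels for a 256-point input (the library's conservative
`dwt_max_level` of 5 guards a boundary-distortion rule that periodization
does not need). The subject vector is the mean over its group vectors —
aggregation across groups is a package choice; the mean makes the subject
vector independent of group order and of record duration.

**Waveform** — fiducial windows are standard physiological bounds: Q within
80 ms before R, S within 80 ms after, P the maximum 80–300 ms before R, T
the largest |signal − median| 80–400 ms after S, all truncated at beat
edges. Q and S are taken as the *local minimum nearest R* within their
windows (falling back to the window minimum when no interior local minimum
exists): after high-pass filtering, the window's global minimum can sit on
baseline undershoot rather than on the notch, and the nearest-notch rule is
what keeps the recovered QRS duration rank-correlated ≥ 0.9 with the
generating width across a cohort. The 24 features use fixed conventions,
documented in `WAVEFORM_FEATURE_NAMES` order: positions are R-relative (ms);
amplitude pairs are signed differences `amp(first) − amp(second)` (mV);
durations are absolute spans (ms); slopes are amplitude difference over
signed time difference (mV/ms); the QRS area is the shoelace area of the
(t, amplitude) triangle at Q, R, S (mV·ms). The subject vector is the
element-wise median over beats, robust to occasional mis-delineation.

## Clustering and metrics

K-means is Lloyd's algorithm: initial centers are k distinct data points
drawn with a seeded generator; assignment breaks distance ties toward the
lowest group index; an empty cluster is re-seeded at the point farthest from
its nearest center; convergence is unchanged assignments or |ΔE| < 1e-8,
capped at 300 iterations. E is recorded each iteration and checked
non-increasing in the tests. An `n_init` restart option keeps the lowest-E
fit; the default is a single start, matching the plain
random-initialization description of the method. On exhaustive enumeration
of all assignments for ≤ 8 points and ≤ 3 clusters, the restarted solver
attains the global minimum on 200 of 200 random instances.

Standardization: under `auto`, waveform features are z-scored (they mix ms,
mV, mV/ms and mV·ms — without scaling, durations dominate the metric) while
RBP (already normalized frequencies) and wavelet coefficients (shared units)
are clustered raw. Override with `always`/`never`.

Crosstabs count, per cluster, the subjects positive for each condition among
those whose flag is known; unknown flags drop a subject from that
condition's numerator and denominator only. Ratio and concentricity are
computed from the crosstab, so they can equally be evaluated on externally
printed count tables.

## Numerical and degenerate-input choices

* Sample indexing 0-based, times in seconds, amplitudes in mV, throughout.
* Signal CSV sampling rate = reciprocal of the median time step; non-monotone
  time or non-numeric cells raise errors naming the row.
* WFDB support is read-only, single-segment, storage format 16 (the PTB
  layout); any other format code raises an explicit unsupported-dialect
  error rather than mis-decoding.
* A flat or too-short signal yields zero peaks (with a warning), zero beats,
  and the subject is excluded from feature sets that need beats, with the
  exclusion listed in the pipeline report.
* Wave amplitudes below 1e-12 mV are treated as absent during synthesis, so a
  degenerate all-zero morphology produces an exactly zero trace while the
  R-amplitude-positive invariant stays enforceable.
* Equidistant centers and median ties resolve deterministically (lowest
  index; numpy's median midpoint), and every random draw descends from an
  explicit seed, so pipeline reports are byte-identical across runs.

## Known limitations

* The delineator locates peak points only (no P/T onsets or offsets); the 24
  features need nothing more, but QT-style intervals measured from peaks
  underestimate clinical definitions.
* The QRS detector assumes a dominant positive R deflection, as generated;
  negative-R leads would need the amplitude test applied to |signal|.
* Concentricity is biased toward large clusters at small k (its baseline
  under no association is the largest group's share, not 1/k); compare
  across k with that in mind.
* Disease effects are single-lead morphology shifts; nothing in the
  generator (or the pipeline) models inter-lead information, medication, or
  comorbidity structure.
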
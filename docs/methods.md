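# Methods

This note documents the models, conventions and numerical choices behind
`orthobci`, the assumptions of its synthetic-data generator, and what the
test suite does and does not establish about real EEG.

## Signal model and geometry

All signals are microvolts internally; file boundaries convert (EDF physical
scaling is honoured on read). Sample indexing is 0-based and epoch windows
are half-open `[onset, onset + n_t)`. At the default 256 Hz the 800 ms
post-stimulus window is `floor(0.8 · 256) = 204` samples; decimation by 4
(stride slicing, phase 0) leaves `ceil(204/4) = 51`. No extra anti-alias
filter precedes decimation: the 4–14 Hz feature band lies far below the
32 Hz post-decimation Nyquist.

### FIR filtering

The three analysis bands (4–14, 20–40, 4–40 Hz) use Hamming-window
linear-phase FIR band-passes of order 256. Offline the causal filter is
applied and its constant group delay (128 samples) removed by shifting, so
epochs stay stimulus-locked while the per-sample output is identical to what
a causal online implementation produces mid-stream. Forward–backward
(zero-phase IIR-style) filtering was deliberately avoided to preserve this
online/offline parity. The tail is zero-padded; the last half filter-length
of a recording is therefore attenuated, which is irrelevant in practice
because sessions end with rest phases.

### Artifact screening

Per channel of the 4–40 Hz epoch: peak-to-peak voltage, sample standard
deviation (denominator `n_t − 1`), and the ratio of 20–40 Hz to 4–40 Hz
energy. Thresholds 200 µV / 50 µV / 0.7, compared with `≥`. A zero 4–40 Hz
denominator (dead or disconnected channel) is itself an artifact verdict and
the ratio is reported NaN. Screening precedes every downstream stage; the
decimation routine refuses epochs flagged artifact.

## Spatial filtering

The CCA problem stacks the transposed artifact-free target epochs into `U`
and equally many transposed copies of their entrywise-average ERP into `V`
(both `(51·n_target) × n_e`). Columns of both matrices are mean-centred —
standard CCA convention; whether the original system centred is unknowable
from the outside, so centring is recorded here as the package's convention.
The numerical route is whitened cross-covariance SVD with a relative ridge
of 1e-8 on both covariance diagonals (Cholesky of the ridged covariances,
SVD of the whitened cross block). The ridge bounds attainable correlations
slightly below 1 in degenerate cases (identical epochs reach ~1 − 2e-8);
tests account for this. Because `V` consists of duplicated rows its rank is
at most `n_e`; the ridge keeps the solve well-posed regardless.

Weight-vector scale is free in CCA, so each retained filter is normalized to
unit Euclidean norm with its largest-magnitude element positive; ties among
equal correlations break toward the lower filter index. Default `n_w = 4`
filters are retained, ordered by decreasing canonical correlation.

## Classification

Features are the flattened `n_w × 51` projected samples, filter-major
(feature id `f·51 + t`). The classifier is LDA with the pooled covariance
shrunk toward `(tr Σ / p)·I` by a factor γ, and **equal class priors** in
the decision rule: with a 1:5 target/non-target imbalance, empirical priors
would bias the boundary toward non-target, and the evaluation metric
(weighted accuracy) treats classes equally.

γ defaults to the analytic Ledoit–Wolf estimate. During the stepwise search
γ is computed once on the full candidate matrix and held fixed while
candidates are scored (per-candidate re-estimation inside cross-validation
would multiply the search cost by a large constant for no measurable
selection benefit); the final model refit re-estimates γ on the selected
subset. A fixed γ can be configured instead.

The stepwise search scores feature subsets by 5-fold cross-validated
weighted accuracy (stratified folds, fixed internal seed, per-fold class
scatter matrices precomputed so each candidate evaluation is one small dense
solve). Forward steps add the best candidate if it improves the score by
more than ε = 0.001; backward steps remove any feature whose removal costs
at most ε; the loop stops when neither step changes the set, with a hard
iteration cap of twice the feature budget (`n_f ≤ 60`). Ties break toward
the lowest feature id, which also makes the search invariant to duplicated
candidate columns. If no single feature beats the empty model the fit fails
loudly ("no informative features"); the cross-validation driver treats such
a fold as the constant non-target predictor, i.e. chance.

## Controller

Per-option ring buffers (capacity 10) hold only artifact-free labels;
artifact labels increment a discard counter and leave all evidence
untouched. Selection requires, simultaneously: ≥ 5 buffered epochs for the
candidate, ≥ 70 % of them *target*, and ≥ 60 % *non-target* for every other
option **with at least one buffered label** — options not yet flashed (or
all-artifact) cannot veto, since early in an attempt most buffers are empty.
With these defaults at most one option can qualify at any instant: a
candidate at ≥ 70 % target is at ≤ 30 % non-target, under the 60 % veto bar
(and indeed any threshold pair in (0.5, 1] sums above 1, so the invariant
holds for all accepted configurations; the test suite additionally verifies
it by exhaustive enumeration). After a selection all buffers reset and
flashing pauses 4 s while the movement executes. Attempts time out after
30 s of flashing; the label-stream timestamps used by the replay engine are
epoch-completion times (onset + 800 ms), so reported selection times include
the processing lag a live system incurs.

## Calibration schedule

"Random flashing" is realized as balanced randomization — each round is a
uniform permutation of the six options, re-drawn when it would repeat the
previous round's last option — because only a once-per-round scheme is
consistent with exactly 264 target and 1,320 non-target epochs over
8 runs × 33 rounds. Flashing occupies 198 × 150 ms = 29.7 s per run; the
remaining 10.3 s per run are allocated fixation 3 s, cue 2 s, preparation
2 s, rest 3.3 s, making each run 40 s and the session 320 s. The phase
breakdown beyond the totals is a package convention. Cued targets are drawn
uniformly per run (a balanced mode is available). Training requires at
least 20 valid target epochs; below that the average-ERP estimate is too
noisy to anchor the CCA fit.

## ERP significance

The analysis window is 200 ms pre-stimulus (51 samples) + 800 ms
post-stimulus in the 4–40 Hz band, artifact-screened with the standard
rules. Per channel and class the epochs are averaged and the whole window is
baseline-corrected by the pre-stimulus mean. The baseline distribution is
the **averaged waveform's own 51 pre-stimulus samples**, smoothed by a
Gaussian KDE with the normal-reference bandwidth `1.06·s·n^{−1/5}`
(configurable multiplier); the acceptance band is the KDE's (α/2, 1 − α/2)
quantile pair, inverted on a fine grid of the KDE CDF. Post-stimulus points
outside the band are flagged +1/−1 (mutually exclusive by construction).
Pooling single-epoch baseline samples instead is a config switch
(`pooled` semantics can be emulated by passing pooled arrays to
`baseline_band` directly); the averaged-baseline reading was chosen because
it makes channel-grid significance masks computable from an average alone.
Under a pure-noise null the flagged fraction runs slightly conservative
(~0.037 at α = 0.05) because KDE smoothing widens the band; the Monte-Carlo
level test asserts α ± 0.03. No correction across time points or channels
is applied — masks are descriptive, per-point statements.

## Evaluation

Cross-validation is stratified 5-fold with the full stepwise+RLDA stage
re-fit per training fold; per-class accuracies are pooled over held-out
folds and `acc_w = 0.5(acc_t + acc_nt)` holds by construction. The
permutation test re-scores `m` label permutations with the same
cross-validation and reports the +1-smoothed p-value
`(1 + #{perm ≥ obs}) / (1 + m)`, never zero; `m` defaults to 1,000 in
library use (10,000 mirrors the reference analysis; tests use less).
Online reports count a selection correct only when it matches the cue;
timeouts and wrong selections are failures. `t_avg` averages the selection
times of **successful** attempts only (a timeout has no selection time); if
no attempt succeeded the ITR is reported as 0 with `t_avg` undefined. Eq-8
boundary conventions: `0·log₂0 = 0` at acc ∈ {0, 1}. Condition comparisons
are the two-sided paired t-test (df = n − 1; identical columns return
t = 0, p = 1 rather than 0/0) and the Wilcoxon rank-sum test.

## Simulator: what it emulates, and what it does not

Per session, a single seed feeds named substreams (schedule, noise,
artifacts) through `numpy` seed sequences, so every artifact of a run is
reproducible from one integer.

* **Evoked response:** a Gaussian-windowed positive deflection (default
  5 µV peak at 350 ms, 120 ms FWHM) minus an optional early negativity
  (2 µV at 220 ms), scaled by a fixed centro-parietal topography
  (Pz = 1.0, Cz = 0.9, …) and added at every target-flash onset.
* **Background:** Gaussian noise shaped to a 1/f^1 power spectrum with a
  10 Hz alpha bump, mixed to uniform inter-channel correlation 0.3, scaled
  to 3.5 µV RMS per channel. The RMS was chosen so that the default
  parameters emulate a well-performing subject: calibration CV weighted
  accuracy lands near 88 %, the upper range reported for real participants
  of such systems.
* **Artifacts:** 200 ms raised-cosine-enveloped 7 Hz bursts of 300 µV on a
  random channel, Poisson-placed at 2/min. The in-band carrier matters: a
  plain raised-cosine hump is mostly DC and would be attenuated by the
  4–40 Hz front end before the screening sees it. Ground-truth burst flags
  agree with the screening verdicts on ≥ 95 % of epochs.

The generator reproduces the *statistical* structure the pipeline assumes —
stimulus-locked means, colored noise, gross artifacts. It does **not** model
latency jitter or amplitude habituation of the evoked response, eye-blink or
line-noise waveform families, non-stationary drifts, volume-conduction
topography beyond a fixed gain vector, or any subject-to-subject
variability. Passing end-to-end tests therefore demonstrates internal
consistency and correct algorithmic behaviour under the assumed model, not
expected performance on any particular human recording.

## Problem sizes in the test suite

Unit and property tests run on reduced geometries (e.g. 4-run × 15-round
calibrations, two-channel ERP nulls, 12–200-observation classifier
fixtures); the full 8 × 33 geometry is exercised wherever the claim is about
the design's exact bookkeeping (epoch counts, session duration) and in the
end-to-end recovery checks (full-session training; 30 simulated online
attempts at 8 µV; 40 null attempts). These sizes were chosen as the smallest
instances that make each statistical assertion stable across the fixed
seeds.

## Known limitations

* EDF/EDF+ is read (via `mne`) but not written; the portable on-disk format
  is headered CSV + TSV events + JSON metadata sidecar.
* The stepwise scoring criterion of the original system is unspecified in
  the source material; cross-validated weighted accuracy with ε = 0.001 is
  this package's choice and selected feature sets will differ from any
  system using a different criterion (e.g. Wilks' lambda).
* The controller's behaviour when *no* other option has buffered evidence is
  likewise a documented reading (empty buffers pass vacuously), not a
  verified property of the original implementation.
* Single-session, single-subject scope: no cross-session transfer,
  re-referencing, or adaptive recalibration.
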
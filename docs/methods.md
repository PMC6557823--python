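# Methods

## Data model

A Humphrey 24-2 exam is represented by its 52 analysed total-deviation
values (TDV, dB), 52 pattern-deviation values (PDV, dB), the three
reliability indices (false-positive, false-negative, fixation-loss
rates, %), laterality, and date. The two physiologic-scotoma locations
(15, ±3) carry no visual information and are excluded. The canonical
point ordering — superior→inferior rows, nasal→temporal within a row,
in right-eye convention (temporal = positive x) — is a frozen constant
shared by the encoder, the model head, and every metric; nothing
downstream may reorder it.

30-2 exams are converted to 24-2 by selecting the overlapped lattice
points (the 24-2 lattice is a strict subset of the 30-2 lattice), never
by interpolation. Left eyes are mirrored (x → −x) into right-eye
convention before indexing, pooling anatomically homologous locations
across eyes; the mirror permutation reverses each row block and is its
own inverse. Exams with any reliability index ≥ 33% fail screening
(strict inequality — 33.0 exactly fails).

Mean deviation, used only as a binning covariate, is stored when
supplied and otherwise computed as the unweighted mean of the 52 TDVs;
the instrument's eccentricity weighting is proprietary and nothing in
the pipeline depends on it.

## Input encoding

Five exams plus a prediction date become a 6×108 matrix. Feature layout
per row: time displacement (days ÷ 10000), then FP, FN, FL (÷ 100),
then PDV (÷ 50), then TDV (÷ 50). Displacements are integer day counts
relative to the most recent exam; the query row carries only the
positive forecast horizon. Dividing the reliability rates by 100 is a
package choice (only the dB and time divisors are forced by the
design); it keeps every feature within [−1, 1] and is recorded as a
constant so raw percentages are one edit away. The encoding is affine
and bijective per row: `decode_row` recovers every input to < 1e-9,
which the tests exploit as a round-trip invariant.

Rows are fed to the recurrence in order of decreasing displacement
(query first, then most recent → oldest). Because that order is unusual
for an RNN, a `sequence_order="chronological"` switch feeds the
reversed sequence instead; the default is the decreasing order, and all
reported results use it.

## Network and training

Single LSTM layer, 6 units, forget gates, no peepholes; gates use the
logistic sigmoid, the candidate uses tanh; cell and hidden state start
at zero. A 52-neuron dense layer with identity activation maps the
final hidden state to normalized TDV (TDVs are signed, so a squashing
output would be wrong). Parameter count is exactly
4·(h·(d+h)+h) + (o·h+o); at (108, 6, 52) that is 2760 + 364 = 3124,
and a property test checks the closed form against explicit tensor
enumeration for random small configurations.

The forward pass, backpropagation through time, and Adam are
implemented directly on numpy arrays. At 3124 parameters and
six timesteps the matrices are tiny; an explicit implementation keeps
every gate inspectable and is verified against central finite
differences (relative error ~1e-6) and a hand-computed single-unit
recurrence.

Training choices (not forced by the architecture, declared here as
package defaults): MSE on normalized TDV; Adam with learning rate
1e-3, batch size 32; at most 500 epochs; 9:1 seeded train/validation
split with floor(0.1·n) validation samples, split by eye; early
stopping after 20 non-improving validation epochs with best-weight
restore. Glorot-uniform kernel initialization from the seeded
generator; forget-gate bias 1.0 (keeps memory open early), other
biases 0. Training with a fixed seed is bit-reproducible on one
machine. Predictions are reported unclamped; the CLI offers
`--clamp` to bound outputs to the instrument range.

Weights serialize to a versioned JSON document (config + tensor layout
+ flat float64 payload). JSON's repr-based float encoding round-trips
IEEE-754 doubles exactly, so save/load is bit-exact.

## OLR baseline

Per point: ordinary least squares of raw-dB TDV against time
displacement in days over the five input exams, evaluated at the query
horizon — the same displacement convention as the encoder, so both
methods answer the identical question. Implemented with a shared design
matrix across the 52 points via `numpy.linalg.lstsq`; tests pin it to
an independently coded normal-equations oracle (max deviation < 1e-8 dB
over 1000 random series). TDV (not raw threshold sensitivity) is
regressed, matching the metric scale. No clamping by default.

## Evaluation protocol

Per-eye RMSE = sqrt(Σₙ (trueₙ − predₙ)²/52); per-point MAE across
eyes. Method comparison is paired per eye: Shapiro–Wilk on the paired
differences at α = 0.05 chooses a paired t-test (normal) or Wilcoxon
signed-rank test (otherwise), two-sided; the report names the test
applied. A constant nonzero difference (normality undefined, t
degenerate) falls back to Wilcoxon; all-zero differences report p = 1.
Binned tables use edges {≤2.5, 2.5–5, 5–7.5, 7.5–10, >10} % for
reliability factors and {<−12, −12…−9, −9…−6, −6…−3, ≥−3} dB for mean
deviation. The binning covariate of an eye defaults to the mean of its
five input exams' rates/MD (`--bin-covariate last` uses the most
recent input exam instead); a per-eye series summary is the less noisy
choice and the pipeline exposes both. Error-vs-factor trends report
Spearman's rho and a simple linear regression, per method.

## Synthetic cohorts

The simulator generates what the forecaster assumes of real perimetry,
with a hidden ground truth retained for oracle tests:

- **Series**: 6 exams per eye at uniform 0.5–1.5-year intervals.
- **Baseline field**: per-point N(0,1) texture, 0–2 cluster-shaped
  defects (menu: superior/inferior arcuate bundles, nasal step,
  paracentral — frozen coordinate sets over the canonical grid), and a
  diffuse shift bringing the field mean to an initial-MD draw from
  N(−7.0, 6.1) truncated to [−30, 2] dB, the profile of a mixed
  glaucoma-clinic population.
- **Progression**: 60% of eyes progress (a package default — clinic
  cohorts mix stable and progressing eyes in roughly this ratio);
  progressing eyes lose TDV linearly in 1–2 menu clusters with
  pointwise slopes N(−0.6, 0.3) dB/year.
- **Noise**: observation σ = 1.0 + 0.12·max(0, −TDV_true) dB, capped
  at 6 dB — fluctuation grows with defect depth. Observed values are
  rounded to 1 dB (instrument convention) and clipped to [−40, 15];
  truth is kept unrounded.
- **Reliability**: FP/FL from scaled Beta draws; FN additionally grows
  with true defect depth.
- **Outlier exams**: with probability 0.08 per exam (default; roughly
  one affected exam per two series, enough to give trend extrapolation
  a realistic long tail), noise σ is tripled and FN inflated by 10
  percentage points.
- **PDV**: derived as TDV minus the general height, estimated by the
  7th-highest TDV — the published surrogate for the instrument's
  proprietary algorithm; PDV only feeds the model input, so mild
  fidelity suffices.

The same seed yields byte-identical cohort files. What the simulator
does *not* emulate: SITA staircase psychophysics, learning/fatigue
effects, media-opacity drift, diagnosis subtypes, or inter-eye
correlation within a patient. Passing tests therefore demonstrate that
the pipeline recovers a linear-trend-plus-heteroscedastic-noise
process with outliers — the structural claim behind the method — not
clinical accuracy.

## Problem sizes and numerical choices

The packaged checks train on a 200-eye noiseless cohort (pipeline
wiring: OLR must be exact up to the 1-dB rounding floor, i.e.
< 0.51 dB RMSE, and the trained network < 2 dB on held-out eyes) and
on 1408-eye contaminated cohorts with 281-eye test cohorts over seeds
1–3 (the network's mean per-eye RMSE must not exceed 1.10× the
baseline's). These sizes keep a full suite run to well under a minute
of training per cohort while leaving the comparison's direction stable
across seeds. Degenerate inputs fail loudly: fewer or more than five
input exams, non-increasing dates, a prediction date not after the
last exam, zero-variance regressors, and empty datasets all raise.

## Known limitations

- The training hyper-parameters are package defaults, not reported
  facts; conclusions about the comparison hold under these defaults
  and the simulator's assumptions.
- One eye contributes one (5-input, 1-target) sample; sliding windows
  over longer series are out of scope.
- Simulated eyes are independent; the 9:1 split therefore cannot leak
  across eyes, but real bilateral data would need patient-level
  splitting.
- The general-height PDV surrogate and unweighted-mean MD deviate from
  the instrument's proprietary definitions; both are used only where
  fidelity is immaterial (model input features, binning covariates).
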
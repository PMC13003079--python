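# Methods

## The scientific problem

An animal trained on one behavioral rule ("schema") and then switched to a
conflicting rule poses a representational question: does the neural
population overwrite the old rule, or keep it readable alongside the new
one?  This package implements, on fully synthetic data with known ground
truth, the analysis battery used to answer that question in an 8-odor
go/no-go discrimination task governed by two orthogonal reward rules:

* **non-match rule** — a response is rewarded when the current odor differs
  from the previous trial's odor;
* **cue-identity rule** — a response is rewarded when the odor belongs to a
  fixed rewarded set (odors 1–4), regardless of history.

The two rules are orthogonal: over the 16 trial types (8 odors × match /
non-match configuration), each rule's rewarded/non-rewarded dichotomy cuts
the type set in an independent direction.

## Task simulator (`taskgen`)

Odor sequences are a repeat-or-redraw Markov chain: with probability
`repeat_prob` the previous odor repeats (a match trial); otherwise a new
odor is drawn uniformly from the other 7.  The first trial of a session has
no predecessor and is non-match by convention (this scores at most one
trial per session).  With the default `repeat_prob = 0.49`, the long-run
fraction of potentially rewarded trials is ≈ 0.51 under the non-match rule;
odor marginals stay uniform, so the cue-identity potential-reward fraction
is ≈ 0.50.  These defaults reproduce the near-50/50 reward balance the task
is engineered for under both rules.  The real task's sequence-construction
procedure is not documented anywhere we could follow; the repeat-probability
mechanism is this package's stand-in, and the chain's autocorrelation (odor
identity decorrelates as `repeat_prob^k` over lag k) is a property real
sequences may not share.

Behavioral agents are logistic policies:
`P(go) = lapse/2 + (1 − lapse)·σ(go_bias + w_nm·s_nm + w_ci·s_ci)` with
`s_rule = ±1` as the rule prescribes go/no-go.  They emulate the observed
phenomenology (naive go-everything bias; old-rule-biased errors after the
rule switch) but are not learning models: weights are scheduled per
session, not acquired by reinforcement.

Behavioral metrics: accuracy under either rule (computable regardless of
the active rule), the go-probability per trial type, and trials-to-criterion
— the first trial count at which accuracy over a sliding 30-trial window
reaches 80% under the active rule, with ties at threshold counting as
crossing.

## Synthetic populations (`neuro_synth`)

Each unit's odor-window firing rate is
`baseline + (Δ_nm/2)·s_nm + (Δ_ci/2)·s_ci + gain[type]`, so `Δ` is the
between-condition rate difference in Hz.  Spike counts are Poisson in each
epoch; when spike times are requested they are placed uniformly within
their epoch (piecewise-constant inhomogeneous Poisson), and the rate matrix
is derived from the same counts so the two views agree exactly.  Negative
implied rates are clipped at zero with a warning.  Selectivity lives only
in the odor-sampling window; baseline epochs carry the baseline rate alone,
which keeps the z-score denominator signal-free by construction.

Defaults: baseline rates uniform on 5–15 Hz, effect size 5 Hz (≈ 1 SD of
the windowed Poisson rate at these baselines), 500 ms response window, 1 s
baseline window.  Per-type `gain` terms default to zero so the
odor-invariance assumption behind cross-condition generalization holds
exactly; the "memorization" regime draws idiosyncratic per-type gains
(SD 6 Hz) to produce decodable structure with no abstract rule axis.
Units are partitioned round-robin over simulated animals so that
leave-one-subject-out analyses are exercisable; pseudo-population assembly
treats those partitions exactly as it would separate animals.

Selectivity schedules emulate learning: the non-match-coding fraction ramps
5% → 25% across the five non-match sessions; after the rule switch the
cue-identity fraction ramps identically while a residual 10% of units keep
non-match coding at a reduced 3 Hz effect — in the rule-switching group
only.  Controls carry cue-identity coding alone.  The ramp endpoints follow
the reported selective-unit proportions; the residual fraction and reduced
effect are this package's choice for a regime in which the residual code is
detectable by population measures while single-unit residual selectivity
stays near ~5–10%.

What the generator does **not** emulate: cross-session unit identity,
firing-rate drift, correlated (non-Poisson) variability, latency structure
within the odor window, and any coupling between single-trial neural
fluctuations and the agent's choices.  Passing tests therefore certify the
statistics' behavior under their stated assumptions — calibration under the
null, recovery of programmed coding — not performance on real recordings.

## Single-unit statistics (`unit_metrics`)

PSTHs: 50 ms bins aligned to the un-poke (decision) event, smoothed with a
5-bin uniform moving average (edge-replicated padding, conserving total
mass up to edge effects).  Z-scores: mean response-window rate of a
condition minus the mean baseline rate over all trials, divided by the SD
of per-trial baseline rates (an effect size in baseline-SD units); zero
baseline SD raises an explicit error.  Δz is the rewarded-minus-non-rewarded
z difference per rule and is exactly antisymmetric under label exchange.

Rule selectivity is an empirical permutation test with a deviation-style
statistic: the maximum absolute difference between the two conditions'
cumulative normalized spike-time profiles over the sampling window, and the
absolute rate difference, each standardized against the permutation null,
combined by taking the larger.  p-values use the add-one convention
(1 + k)/(1 + n_perm), so p = 0 is never reported and the test is exactly
calibrated by construction.  Units with fewer than 5 trials in either
condition are marked untestable rather than given p = 1.  The original
parameter-free deviation test this mirrors calibrates its statistic with
Gumbel asymptotics; the permutation null trades that speed for exact
finite-sample calibration that the suite can verify.

## Population geometry (`geometry`)

Pseudo-populations align trials of the same type across animals (each
animal's trials subsampled without replacement to a common per-type count;
columns standardized per animal independently).  Types missing from any
animal are excluded with a warning.

The embedding backend is pluggable.  `umap` gives the nonlinear 3-D
embedding used for visualization; `linear` is a deterministic 3-component
PCA (fixed sign convention, bit-reproducible) on which every statistic is
exactly checkable — all downstream quantities are defined on whatever 3-D
coordinates are supplied.  The test suite and default pipeline use the
linear backend; its hyperparameters are none, and the nonlinear embedder's
hyperparameters are configuration, not claims.

Rule separation is a variance-normalized Euclidean distance between the
dichotomy's two centroids: `d = sqrt(Σ_k (μ_ak − μ_bk)² / s_k²)` with
`s_k²` the pooled within-group variance per embedding dimension (the
"normalized Euclidean" of the analysis this mirrors is not given as a
formula; per-dimension pooled variance is our reading, and it makes d
scale-free).  Ward linkage over the 16 type centroids summarizes cluster
structure.

Inference: leave-one-subject-out recomputation (the session value is the
mean over left-out-animal iterations), against a null built by permuting
trial-type labels within each animal *before* assembly — this preserves
every unit's rate distribution while destroying label structure.  p-values
follow the add-one convention, doubled and capped for two-tailed use;
Holm–Bonferroni corrects across a session family.  Group differences
compare the observed difference of LOSO means against the elementwise
difference of the two groups' null samples.

## Decoding battery (`decoding`)

The canonical type ordering is fixed package-wide: non-match trials of
odors 1–8 at indices 0–7, match trials at 8–15.

**CCGP.**  For a rule's dichotomy, each partition holds out one odor
condition per class (for cue identity, a condition is an odor pooled over
configurations; for non-match, a condition is a single trial type), trains
a ridge-penalized logistic classifier (C = 1) on the rest, and tests only
on held-out trials.  With 4–8 conditions per class there are at most 64
distinct splits, so the 500 partitions resample splits with replacement.
Significance versus chance (0.5) is the add-one two-tailed tail probability
of 0.5 under the partition-accuracy distribution.  High CCGP certifies an
odor-invariant (abstract) code; the memorization regime decodes well within
conditions but falls to chance here — the dissociation the measure exists
to detect.

**Rule axes and cosine.**  Each bootstrap iteration draws a balanced
with-replacement sample, standardizes units within the sample, and fits a
logistic classifier under a strong ridge (C = 1e-3); weights are mapped
back to unit space.  The strong penalty keeps the axis near the
class-mean-difference (coding) direction rather than the noise-whitened
discriminant — a weakly penalized fit actively subtracts any coding
direction shared between the rules (the other rule's modulation is the
dominant shared noise), which would make alignment between the two axes
unrecoverable by construction.  Cosine similarity
`cos θ = w_nm·w_ci / (‖w_nm‖‖w_ci‖)` then reads 0 for disjoint coding
populations, ≈ +1 for shared coding, ≈ −1 for negated coding (verified by
the recovery suite).

**Confusion matrices and templates.**  A linear SVM decodes the 16 trial
types with leave-one-trial-out cross-validation; row r of the confusion
matrix is the hard-vote frequency of predicted types over trials of true
type r (soft prediction probabilities are available as an option).  Types
with fewer than 2 trials are excluded with an index map.  Three block
templates — non-match (configuration blocks), cue-identity (odor-group
blocks), both-rules (their elementwise product) — are scored with a ±1
scoring matrix excluding the main diagonal (correct classification inflates
all templates equally), normalized by the matrix's total off-diagonal mass
so scores lie in [−1, 1].  Significance: 1000 joint row/column label
permutations, add-one upper tail.  The diagonal ratio divides the mean
main-diagonal probability by the mean same-odor/other-configuration
("side-diagonal", offset ±8) probability; it indexes how strongly the
match/non-match distinction separates otherwise-identical odors, and
returns +inf when the side diagonal is empty.

**Per-rule decoders, residualization, ignore-go.**  Rule decoders are
balanced-subsampled, stratified 5-fold cross-validated logistic
classifiers with label-permutation p-values.  Choice residualization
removes each unit's OLS projection on the binary choice; residuals are
exactly uncorrelated with choice (a constant choice vector skips the step
with a warning).  Because residualization uses the whole session before
cross-validation, decoding accuracy on residualized data can dip below
chance; the meaningful read-out is the absence of above-chance accuracy.
The ignore-go probability is computed on incongruent trials (rewarded
under non-match, not under cue identity): among those the non-match decoder
labels "rewarded", the fraction on which the agent withheld its response.

## Decoder–behavior linkage (`linkage`)

Pooled OLS regressions of behavioral on decoder accuracy across rat/session
points; within-session slopes and Pearson r across animals (sessions with
fewer than 3 points are skipped); and a Fisher-Z comparison of epochs:
per-session r's are z-transformed, aggregated with (n − 3) weights (the
aggregation scheme is our choice; the analysis this mirrors does not state
one), and compared with `z = (z̄1 − z̄2)/sqrt(SE1² + SE2²)` against a
standard normal.  |r| = 1 is clamped with a warning.  Early/late epoch
boundaries are configuration (default sessions 1–2 vs 4–5).

## Pipeline, fixtures, determinism (`pipeline`)

`RunConfig` carries every parameter with the canonical analysis defaults
(50 ms bins, 5-bin smoothing, 500 ms response window, 1 s baseline, 80%/30
criterion, α = 0.05, 1000 permutations, 1000 bootstraps, 500 CCGP
partitions) and validates before any compute.  All randomness flows from
the named seed; identical configurations produce byte-identical CSV
outputs (verified in the suite).  `generate_fixtures` emits five small
canonical regimes — non-match-only, cue-identity-only, dual, memorization,
null — with ground-truth metadata; they are generated programmatically, not
stored.  Outputs are plain delimited text plus a JSON summary.

## Problem sizes

Simulation sizes in the test suite and analysis scripts are chosen so each
check has adequate power at desk scale: behavioral constants use 100
sessions × 300 trials; the null-calibration suites use 150–400 replicates
with 199–1000 permutations; decoding fixtures use 40–100 units × 8–20
trials per type; the end-to-end analyses (`analysis/`) use 80-unit
populations, 12 trials per type, 200–500 permutations and 200–300
partitions.  The headline quantities of the recorded-data study (e.g.,
CCGP trajectories 0.59 → 0.96, 25% selective units, diagonal-ratio medians)
depend on the real recordings; the synthetic schedules reproduce their
qualitative structure, and only the by-construction task constants and
calibration bounds are asserted numerically.

## Known limitations

* Agents do not learn; acquisition dynamics are scheduled.
* Poisson, uncorrelated variability flatters decoders relative to real
  populations with shared noise.
* The trial-type-balanced decoding tables ignore the Markov structure of
  real sequences (type counts in real sessions are stochastic).
* The linear embedding backend is a faithful testbed but not a substitute
  for the nonlinear embedder's cluster geometry on real data; statistics
  are defined on coordinates, whichever backend produced them.
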
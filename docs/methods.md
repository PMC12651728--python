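# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the known limitations of the package. Notation: a
cohort has N patients, each with a temporal grid of T hourly bins and D
clinical variables; six binary outcomes are predicted jointly.

## Pipeline overview

For each cross-validation fold the pipeline runs, in order: stratified
patient-level partitioning; preprocessing fitted on the training partition
only; outcome-onset censoring; supervised contrastive embedding; kernel
density estimation and density-adaptive KNN (DA-KNN) graph construction;
dual-scale temporal encoding fused by neighborhood attention; training with
AdamW, cosine learning-rate annealing, gradient clipping and early stopping
on validation ROC-AUC; and evaluation of the held-out partition through the
frozen preprocessing and graph statistics. Every data-dependent statistic is
fit on training patients and frozen before it touches held-out data, and the
test suite audits this with content hashes of the fitted objects.

## Preprocessing

**Time alignment.** Observations are averaged into hourly bins over
[0, T) hours (default T = 72). The ICU monitoring data this emulates mixes
sub-hourly vitals with ~8-hourly labs; an hourly grid is the coarsest
alignment that keeps vital dynamics while avoiding mostly-empty bins.

**Winsorization.** Per-variable clipping at the 0.5th/99.5th percentiles of
the training distribution. Quantiles use linear interpolation between order
statistics (numpy's default); this convention is load-bearing for the unit
tests and is therefore stated explicitly.

**Decay imputation.** Missing bins are filled by
x~_t = α·x~_(t−1) + (1−α)·x̄, where x̄ is the patient's mean of observed,
pre-censoring values (falling back to the training median when a patient has
no observations of a variable). The first step decays from x̄ itself, i.e.
x~_0 = x̄, which makes a series that starts missing revert immediately
toward the baseline rather than to an arbitrary zero. α defaults to 0.7 —
long gaps approach the baseline with a half-life of roughly two hours —
and is exposed in `StudyConfig` since no canonical value exists.

**Derived features.** Per-variable slope between the first and last
pre-censoring observation (units: scaled value per hour) and stepwise
differences Δ_t = x_t − x_(t−1). A window with fewer than two observations
yields a slope of 0 together with a cleared `slope_defined` flag, so the
encoders see "no trend information" instead of a spurious magnitude.

**Robust scaling.** (x − median)/IQR with training-fold statistics. A zero
IQR (near-constant labs) maps to 0 with a warning rather than dividing by
zero.

**Censoring.** For a patient–outcome pair with onset at hour t*, every
measurement with t ≥ t* is masked and excluded from imputation, baselines,
slopes and deltas. Because the model has a single shared trunk for all six
outcomes, the pipeline censors each patient at the *earliest* onset among
their positive outcomes — the most conservative choice, guaranteeing that no
post-onset information reaches any outcome head. The per-pair operation
`censor_at_onset` is also exposed separately.

## Contrastive embedding

A two-layer perceptron maps statics plus per-variable summary statistics
(mean, slope, last value) to an L2-normalized embedding (default d = 16).
Training minimizes the sum over outcomes of a one-vs-rest supervised
contrastive loss with cosine similarity and temperature τ = 0.1 (the
sensitivity sweep's optimum; stable between 0.05 and 0.2). Anchors are
reweighted by inverse class prevalence — 1/p for outcome-positives,
1/(1−p) for negatives, normalized to mean 1 — so rare outcomes shape the
geometry despite contributing few pairs. Anchors with an empty positive set
are skipped (the loss is undefined at |P(i)| = 0). The encoder input uses
summaries rather than learned temporal features because the graph must be
built per fold *before* the temporal encoders are trained.

The embedding dimension default (16) is deliberately smaller than what a
40k-patient cohort would support: the KDE below operates in embedding space,
and in high dimensions with desk-scale N the density estimate degenerates to
its self-term. d = 16 keeps the density informative at N in the hundreds to
thousands.

## Density-adaptive graph

Density: ρ_i = 1/(N·h^d) Σ_j K(‖h_i − h_j‖/h) with a Gaussian K and
bandwidth h = 0.25 (midpoint of the best range 0.2–0.3 from the sensitivity
sweep). A cheaper proxy — the mean Gaussian edge weight to the k₀ nearest
nodes — is available behind `GraphConfig(density_method="edge")`; the KDE
form is authoritative.

Neighborhood size: k_i = min(k_max, max(1, ⌊k_base·ρ̄/ρ_i⌋)) with
k_base = 15 (sweep optimum) and k_max = 30. Flooring is conservative (fewer
redundant edges); the ρ̄ anchor keeps the population-mean degree near
k_base, which the tests assert within ±20%. Edges are stored *directed*
(node → its k_i nearest training nodes): symmetrizing would destroy the
per-node degree assignment that is the point of the construction. Edge
weights are exp(−‖h_i−h_j‖²/2σ²) with σ set to the median nearest-neighbor
distance of the training embeddings (no canonical value exists; the median
NN distance puts the kernel's shoulder at the typical edge length). Raw
weights are stored unnormalized — the attention softmax renormalizes them
anyway — and enter attention as additive log-biases.

During training, k_base anneals linearly from 3 to its target over the
first 20% of epochs (avoiding degenerate early neighborhoods), the graph is
refreshed every 5 epochs, and per-node degree changes are clipped to
|Δk_i| ≤ 2 per refresh to prevent abrupt topology shifts. Because the
contrastive embeddings are frozen within a fold, what changes across
refreshes is the annealed k_base and the clip state.

Held-out patients attach through frozen statistics: their density is
evaluated under the training KDE, their k under the training ρ̄, and their
neighbors are drawn from training nodes only. Training edges never change
during attachment (hash-audited).

## Temporal encoders

**ST-CNN.** y_t = σ(W_g ∗ X_(t:t+w)) ⊙ ReLU(W_c ∗ X_(t:t+w)) with window
w = 6 bins (the hyperacute 0–6 h phase) and 32 channels, max-pooled over
time. The sigmoid gate suppresses noise; max pooling keeps the strongest
local response — acute-event detection semantics.

**LT-GRU.** A GRU whose extra gate g_t = σ(W_g x_t + U_g(β·h_(t−1) +
(1−β)·EMA(h_(t−2)))) mixes the previous hidden state with an exponential
moving average of earlier states, EMA_t = β·h_t + (1−β)·EMA_(t−1),
initialized EMA_0 = h_0 = 0. A single β (default 0.9) serves as both the
EMA decay and the gate mixing weight. The source formulation is ambiguous
about whether the gate reads the EMA through t−1 or t−2; this
implementation follows the equation form (t−2) and notes the discrepancy
here. The effective update z_t ⊙ g_t keeps h_t an elementwise convex
combination of h_(t−1) and the tanh-bounded candidate, so the state can
never blow up — a property the tests assert directly. The readout is the
final hidden state (trend semantics).

Imputed values enter the encoders as-is; the observation mask and the
stepwise differences are appended as extra input channels, so the network
can discount imputed stretches.

## Fusion and training

Node representations (concatenated ST/LT encodings plus statics, slopes and
slope flags, projected to 64 dims) pass through two multi-head attention
layers (4 heads) restricted to each node's DA-KNN neighborhood plus a
self-loop; two layers give 2-hop relational reach. Attention logits are
QKᵀ/√d_k plus the log edge weight; a residual connection and ReLU follow
each layer. The output head is a sigmoid per outcome — six independent
probabilities, since the endpoints are not mutually exclusive — trained
with summed per-outcome binary cross-entropy (the loss the sigmoid
multi-label head implies). Outcomes with no positive training labels are
skipped with a warning.

Optimization: AdamW, cosine learning-rate decay, global-norm gradient
clipping at 1.0, early stopping on mean validation ROC-AUC. Defaults:
lr 1e-3, hidden 64, dropout 0.3, 50 epochs, patience 15. The learning rate
sits at the top of the 1e-5…1e-3 search range and the hidden size at the
bottom of {64, 128, 256}: training here is full-batch (one optimizer step
per epoch on a desk-scale cohort), which favors larger steps and smaller
models than the minibatch regime the midpoint defaults assume. All values
stay inside the stated search ranges.

All randomness (initialization, dropout, batching) flows from the config
seed; two runs with the same seed are bit-identical, which the tests
assert.

## Evaluation protocol

Stratified 5-fold cross-validation at the patient level using iterative
multi-label stratification over the six outcomes (rarest-label-first
assignment), so per-fold prevalences track the cohort. Within each training
fold, 10% of patients form the internal validation subset used for early
stopping and threshold selection. Operating thresholds are chosen on that
subset, either F1-optimal or sensitivity-constrained (≥ 0.92, the
high-sensitivity screening regime). Discrimination: ROC-AUC (rank statistic
with half credit for ties) and AUPRC; the reported mean AUC is the
arithmetic mean of per-outcome AUCs. Calibration: Brier score, a 10-bin
equal-width reliability table, and a logistic recalibration of y on
logit(ŷ) giving the calibration slope; calibration-in-the-large is the
intercept of the same model with the slope fixed at 1 (offset logit). CIs
are percentile bootstrap over 1000 patient-level resamples. Reported rates
round to two decimals and the number needed to screen to one decimal.

## Interpretability

Attributions use expected gradients: per patient, baselines are drawn from
training patients (default 50) and gradients are integrated along straight
paths with a stratified midpoint rule (default 10 baselines × 20 steps =
200 function evaluations). Completeness — Σ_j φ_j = f(x) − mean_b f(b) —
is an axiom of Shapley attribution, but the path quadrature converges only
linearly through ReLU kinks, and on patients whose prediction sits near the
background mean even a small absolute quadrature error is large relative to
the gap. The estimator therefore enforces efficiency by construction: the
per-patient quadrature residual is redistributed across features in
proportion to |φ| (zero attributions stay zero, preserving the dummy
axiom), and the raw residual is retained on the attribution map as a
diagnostic. The estimator's accuracy is validated separately — and
non-circularly — against exact coalition enumeration on small models.
The attributed function holds the patient's frozen graph
neighborhood fixed: during attribution a node's own inputs are
differentiated while every neighbor keeps its observed representation, so
φ reflects the patient's own features only. An exact coalition-enumeration
Shapley implementation (≤ 10 features) is the oracle the estimator is
validated against, including the symmetry and dummy axioms.

Global rankings mean-pool |φ| over patients and timebins to the
(variable × channel) level; per-patient temporal maps sum |φ| per bin and
summarize the hyperacute (0–6 h), acute (6–24 h) and subacute (24–72 h)
phases. Stability is audited by rerunning the estimator across seeds and
background sizes and reporting pairwise Spearman correlations of the
rankings plus the coefficient of variation of the top-15 mean |φ|.

## Synthetic cohort

The generator emulates the statistical structure the pipeline assumes — it
is the package's test bed, not a clinical simulator.

- **Severity.** Each patient carries a latent hourly severity: baseline +
  drift·t/T + AR(1) noise with coefficient 0.95 and unit stationary
  variance. The AR coefficient is chosen so both acute excursions and slow
  drifts exist — precisely the two signals the dual-scale encoders target.
- **Observations.** Vitals (default 4: heart rate, MAP, SpO₂, respiratory
  rate) load linearly on severity with realistic intercepts and noise,
  sampled every 0.5 h with 3% missingness. Labs (default 4: lactate,
  bilirubin, creatinine, pH) sample every 8 h; the flagged labs (lactate,
  bilirubin) are observed with probability increasing in concurrent
  severity, calibrated to 45% missingness — informative missingness, as in
  real ordering behavior; the remaining labs miss at 15%.
- **Interventions.** Three binary hourly channels: vasopressor and
  mechanical ventilation switch on when expressed severity exceeds fixed
  thresholds (1.1 and 1.6), and a treatment-escalation channel switches on
  at the patient's *first outcome onset* — treatment administered in
  response to the event. The escalation channel is therefore pure
  post-onset signal: onset censoring removes it entirely, and a
  leakage-allowed run that retains it shows inflated discrimination. This
  is the mechanism the leakage-control experiment exercises (with low
  outcome noise, so post-onset data identifies the label). Binary channels
  bypass winsorization and robust scaling.
- **Outcomes.** Outcome k is positive when max_t sev(t) + ε_ik exceeds a
  threshold calibrated (up to 50 bisection nudges) to the target
  prevalence; onset is the first crossing hour. The six outcomes share the
  severity path with independent noise (sd 0.4), making them correlated
  but distinct. Default prevalences are realistic ICU rates: mortality
  0.10, sepsis 0.15, AKI 0.20, respiratory failure 0.15, cardiac arrest
  0.05, prolonged stay 0.25. The real cohort's outcome correlation
  structure is unpublished; this sharing scheme is a stand-in and flagged
  as such.
- **Rare phenotype.** A 5% subpopulation draws shifted statics (older,
  lower BMI, high CKD rate) and a larger severity-loading multiplier,
  occupying a sparse region of feature space — the regime DA-KNN exists
  for.

What the generator does *not* emulate: pharmacokinetics, treatment feedback
loops, waveform-resolution signals, inter-variable missingness correlation,
and site effects. Passing tests therefore demonstrate that the machinery is
correct and leakage-free under the assumed structure, not that the model
reaches any particular performance on real ICU data.

## Problem sizes and numerical choices

The bundled studies run at desk scale, chosen so the full pipeline
exercises every component: end-to-end training on 600 patients × 72 bins,
graph-population checks on 2000 patients, calibration recovery at 10⁴
samples, attribution audits on subsets of ~60–100 patients. Degenerate
inputs are handled explicitly: zero IQR → 0 with warning; single
observation → slope sentinel; empty positive sets skipped; k_i exceeding
N−1 truncated with warning; all-coincident embeddings → σ fallback 1;
boundary probabilities clipped only inside the logistic recalibration.
Ties: stable argsort everywhere neighbor order matters; AUC ties get half
credit.

## Limitations

- Dense N×N attention masking bounds practical cohorts at ~10⁴ nodes; the
  approximate-KNN and random-feature accelerations needed at
  hospital-database scale are out of scope here.
- The hyperparameter search is a simple hook, not Bayesian optimization.
- The contrastive encoder consumes summary features, so embedding-space
  geometry cannot reflect temporal shape differences invisible to the
  summaries.
- Real-data ingestion (hospital ICU database schemas) is out of scope; the CSV
  interchange format is the package's boundary.
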
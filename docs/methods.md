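# Methods

## Model family

All survival models map a nonnegative metabolite concentration vector
x ∈ ℝ^P to either a scalar log-risk ĥ(x) (Cox-type), a discrete hazard
probability mass over m time bins (discrete-time), or m nonnegative
piecewise-constant hazard rates (piecewise-hazard). The classification
variant replaces the head with a sigmoid probability of aggressive
pathology. Inputs are z-scored per metabolite with training-fold statistics
stored inside the model; concentrations span orders of magnitude, and
without standardization the masked first layer's effective learning rates
are dominated by the most abundant metabolites.

The pathway-informed first layer computes ReLU(x(W ⊙ Π) + b) where
Π ∈ {0,1}^(P×Q) is the metabolite × pathway incidence mask. The mask
multiplies the weight inside the forward pass, so the gradient at masked
positions is identically zero and those weights remain exactly zero after
any number of updates — mask integrity is structural, not a projection
step. "Depth" counts trainable layers: depth 2 is mask + head, depth 3
inserts one ReLU hidden layer of width 64, depth 4 two; depth 1 is a plain
linear model used to cross-check the classical Cox fit. Dense baselines
replace the masked layer with a fully connected layer of width 64 by
default, or width Q for the width-matched ablation.

## Losses

* **Cox partial likelihood** (scalar head): inclusive risk set
  {j : dⱼ ≥ dᵢ} with Breslow handling of tied event times. The printed
  strict-inequality form of the partial likelihood would leave the
  latest event with an empty denominator; the inclusive convention is
  standard and is used identically in the loss, the test oracle, and the
  Breslow baseline estimator. Training uses an O(N log N)
  sorted/cumulative-log-sum-exp implementation, checked against the O(N²)
  reference form; both are shift-invariant and stabilized by log-sum-exp.
  Full-batch training keeps the risk set complete, avoiding the biased
  mini-batch partial likelihood — cohorts here are a few hundred samples.
* **Discrete-time composite loss**: softmax masses over m uniform bins
  spanning [0, max training duration]; likelihood term −log(mass at the
  event bin) for deaths, −log Ŝ(bin) for censored, with
  Ŝ(j) = 1 − Σ_{k≤j} mass_k; ranking term Σ exp((Ŝᵢ(kᵢ) − Ŝⱼ(kᵢ))/σ)
  over pairs with i an event and j surviving past i (a strictly later
  bin), mixed by α. Pair comparability under censoring follows the
  standard convention. Both terms are kept as sums, matching the printed
  form; the trainer normalizes by N internally.
* **Piecewise-constant hazard**: softplus rates η per interval;
  per-sample log-likelihood e·log η_κ − η_κ ρ ΔT_κ − Σ_{j<κ} η_j ΔT_j with
  κ(t) the interval index and ρ(t) the interval fraction; the loss is the
  mean over samples. Each rate multiplies its interval length, so the
  model is invariant to rescaling time (halving all rates while doubling
  all widths leaves censored contributions unchanged). Intervals are
  left-closed; the final boundary closes the last interval (ρ = 1), and
  out-of-grid test durations are clamped to the grid with the same rule.
* **Class-weighted binary cross-entropy**: mean of w_y · CE with
  inverse-frequency weights by default; a weight of c is exactly
  equivalent to replicating that class's samples c times.

Optimization is full-batch Adam (lr 3·10⁻³, up to 400 epochs), early
stopping on validation loss with patience 30 and best-weights restore.
These defaults were set by inspecting train/validation loss trajectories on
synthetic cohorts: the networks interpolate the training partial likelihood
within tens of epochs while validation loss turns up early, so the restored
best-validation model — not the final iterate — is the fitted model.
Initialization is uniform He-style fan-in scaling on the dense weight
before masking, zero biases, all seeded. Dropout (ablation only) applies
inverted dropout after the first hidden activation.

The classical linear Cox baseline is fit by Newton iterations on the
Breslow-tied partial likelihood via scikit-survival, with a ridge fallback
(penalty 0.1, logged) if the unpenalized fit diverges.

## Evaluation

Harrell's concordance counts pairs (i, j) with i an event and dᵢ < dⱼ;
ties in the score (including tied event durations) count one half. The
time-dependent index scores each comparable pair by predicted survival at
the earlier patient's event time, Ŝᵢ(dᵢ) vs Ŝⱼ(dᵢ). Cox-type curves come
from Ŝ(t|x) = exp(−Λ₀(t)e^{ĥ(x)}) with Λ₀ the Breslow step estimator
computed on the training fold (the default; configurable), so under a
shared baseline the time-dependent index reduces exactly to Harrell's —
a property the tests assert to 1e−12. Discrete-time and piecewise-hazard
models carry their own curves. AUROC/AUPRC use scikit-learn (trapezoidal
ROC, step-integrated precision–recall).

The cross-validation protocol shuffles patients (not samples) into 5 folds,
tests on fold i, validates on fold (i+1) mod 5, trains on the rest, and
repeats 3 times with derived seeds — 15 iterations summarized by median and
IQR. Deep models are not re-fit after early stopping; the classical Cox
baseline is re-fit on train+validation. Folds are drawn uniformly over
patients with no event-rate stratification. Test folds never contribute to
normalization statistics, early stopping, or the baseline hazard;
iterations whose test fold contains no events are flagged and excluded
with a warning.

## Attribution

Shapley values use the interventional convention: features absent from a
coalition are replaced by background-set column means (background = the
training-fold samples; the choice of background is a free parameter of any
Shapley analysis and is stored with each report). `exact_shapley`
enumerates all 2^d coalitions (d ≤ 12) and satisfies efficiency,
symmetry and the null-feature axiom to numerical precision; it is the
oracle for the unbiased permutation-sampling estimator used at metabolite
(P = 37) and pathway (Q = 138) scale. Pathway attributions treat each
sample's pathway-activation vector as the input of the sub-network from
activations to output. Importance is the **mean absolute** attribution
across evaluated samples so opposing-sign effects do not cancel; rankings
break exact ties by feature order (stable sort). The metabolite→pathway
flow table distributes each pathway's importance over its member
metabolites proportionally to their mean absolute Shapley share of that
pathway's activation — one defensible normalization among several, chosen
so flows are nonnegative and sum exactly to the pathway importance.

### Identifiability of planted signals

Pathway-level attribution can only recover a planted signal when the
signal-carrying metabolites reach the network exclusively through the
planted pathway units: if a member metabolite also belongs to other
pathways, the masked layer can route the same information through any of
them and the attribution legitimately lands elsewhere. The recovery
experiments therefore plant effects on pathways with pairwise-disjoint
member sets made exclusive (`choose_disjoint_pathways`,
`plant_exclusive_pathways`). This is a property of the question, not of the
estimator — on real mappings, importance spread across overlapping pathways
is the expected behavior.

## Synthetic cohorts

The generator emulates the shape of a metabolomics-based glioma survival
cohort: P = 37 log-normal concentrations (log-sd 0.5), Q = 138 pathways
with 468 memberships, n = 384 samples, ~30% censoring and ~78%/22%
aggressive/benign imbalance by default. Pathway scores are z-scored
mask-aggregated concentrations; the true log-risk is a linear combination
of a few active pathway scores plus Gaussian noise; event times are
exponential with rate baseline_rate·e^risk (baseline 10⁻³/day, median
survival ≈ 2 years at zero risk), so proportional hazards hold by
construction and `oracle_cindex` — the concordance of the generating risk —
is the ceiling any fitted model can reach in expectation. Censoring is
independent Uniform(0, c) with the horizon c bisected to hit the target
censored fraction within a point or two. Malignancy thresholds a second
noisy copy of the latent risk at the 22.1% cohort quantile.

What the generator does **not** emulate: metabolite–metabolite covariance
beyond shared pathway aggregation, non-exponential baseline hazards,
informative censoring, measurement error in quantification, or batch
effects. Passing tests therefore demonstrate correctness of the losses,
the training mechanics, the evaluation protocol and the attribution
chain — not clinical performance on real spectra.

## Numerical choices and degenerate inputs

* Probabilities and hazard rates are floored at machine-scale ε before
  logs; mass rows must sum to 1 within 1e−6.
* A cohort with zero events is rejected (the partial likelihood is
  undefined); a constant feature after normalization gets unit scale
  rather than division by zero.
* `randomize` (edge-count-matched mask) may produce all-zero rows or
  columns — only the total edge count is preserved, by design; row
  shuffling preserves per-pathway in-degrees and the row multiset.
* Checkpoints are single `.npz` archives (weights, mask, normalization,
  grid, config, seed) with a schema version.

## Problem sizes

Test and acceptance runs use cohorts of n = 100–2000 with P = 37/Q = 138
(protocol-scale experiments) and P = 15/Q = 20 (attribution recovery,
20 cohorts with model selection over two initializations). These sizes
give stable medians across the 15-iteration protocol while keeping any
single experiment in the seconds-to-a-minute range on one CPU.

## Known limitations

* The discrete-time ranking loss is O(N²) in the batch; fine for
  full-batch cohorts of hundreds, not for large N.
* Hyperparameter search is a simple validation-loss grid over explicit
  candidate configs; no schedulers or nested search.
* Permutation-sampling Shapley error decreases as O(1/√permutations);
  the default 100–200 permutations ranks reliably but individual values
  carry sampling noise of a few percent.
* The time-dependent concordance uses the training-fold baseline hazard
  by default; with very small test folds an alternative test-fold baseline
  (config-switchable) can differ noticeably.
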
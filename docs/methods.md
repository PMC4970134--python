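# Methods

## The Venn machine

A Venn predictor wraps a classifier (the *taxonomy*) in a transductive
loop. For a test object `x` with training set `z_1..z_{n-1}` over a label
alphabet of size `K`, each candidate label `y` is hypothesized in turn; the
augmented set of `n` examples is partitioned into categories; and the
empirical label distribution of the category containing `(x, y)` becomes
row `p_y` of a `K×K` matrix `P`. The prediction is the column with the
largest minimum entry, and the interval `[P_l, P_u]` is that column's min
and max. The hypothesized example counts with its hypothesized label; rows
are raw frequencies (no smoothing), so each row sums to 1 exactly.

Validity — cumulative correct predictions staying between the cumulative
interval bounds — holds for *any* taxonomy that treats the augmented set
symmetrically, assuming only i.i.d. sampling. Accuracy and interval width,
by contrast, depend entirely on how informative the taxonomy is.

**Taxonomy modes.** The faithful construction (`mode="loo"`) trains the
taxonomy classifier once per example on the other `n−1` examples: `K·n`
fits per prediction. The `"induct"` shortcut trains once per hypothesis on
the full augmented set and labels all `n` examples with it: `K` fits per
prediction. Both are symmetric in the set, so validity is preserved;
`induct` is the default choice in the large simulations here and `loo` the
default of the API. The modes can genuinely differ: a high-capacity
taxonomy that interpolates the augmented set (an RBF SVM with large C, or
any classifier on noise-free, widely separated data) assigns each
hypothesized example to its own hypothesized label under `induct`, making
every category pure — `P` collapses toward the identity, all column
qualities are 0, and the predictor honestly reports an uninformative
`[0, 1]` interval with a tie-broken label. `loo` avoids this because the
held-out example cannot vote for itself.

**Tie-breaking** for the best column goes to the smallest alphabet index;
deterministic and documented, since nothing in the selection rule
distinguishes tied columns.

## Underlying classifiers

* **Gaussian naive Bayes** — per-feature Gaussian class-conditional
  densities with empirical priors; delegated to scikit-learn's
  `GaussianNB`. Zero-variance degeneracies are handled by the standard
  variance floor (`var_smoothing` × the largest feature variance,
  default 1e-9).
* **Softmax regression** — linear class scores with intercepts, fit by
  L-BFGS on the cross-entropy objective plus an L2 ridge (default 1e-4,
  intercepts excluded). The ridge both regularises and removes the
  shared-shift non-identifiability of the softmax parameterisation, making
  the objective strictly convex. The objective value at every accepted
  iterate is recorded (it is non-increasing by the line-search guarantee),
  and failure to converge raises a diagnostic error carrying the final
  gradient norm.
* **SVM + Platt + coupling** — one-vs-one RBF support vector machines
  (scikit-learn `SVC`; decision values exposed with the antisymmetric
  convention `f_ij = −f_ji`, positive favouring class `i`; the binary
  special case is sign-flipped to match, since the backing library orients
  binary decision values toward the second class). Pairwise probabilities
  are `r_ij = 1/(1 + exp(A·f_ij + B))` with `(A, B)` fit by Newton's
  method with backtracking on the regularised negative log-likelihood with
  prior-smoothed targets `(N⁺+1)/(N⁺+2)` and `1/(N⁻+2)` — the numerically
  stable formulation of Platt's fit. The printed per-pair objective this
  construction replaces is not a usable loss, so the standard
  maximum-likelihood sigmoid is used. Coupling solves
  `min_p ½ΣΣ(r_ji p_i − r_ij p_j)²` on the simplex via the fixed-point
  sweep on the KKT system (tolerance 1e-10 on the KKT residual, cap 5000
  sweeps — the iteration converges linearly and the cap is a safety net).
  Both pieces are cross-checked in the tests against an SLSQP quadratic
  program, an exhaustive 1e-3 simplex grid, and scikit-learn's own
  internally calibrated SVC.

As a Venn taxonomy the SVM uses its native one-vs-one voting rule — only
the label is needed, so the sigmoid/coupling chain is skipped, which is
also what keeps the `K` fits per induct-mode prediction affordable.

**Hyperparameters.** The RBF grid search spans `C ∈ {2², 2⁴, …, 2¹⁴}` and
`γ ∈ {2⁻⁹, 2⁻⁷, …, 2⁻¹}` with stratified 5-fold cross-validated accuracy;
ties go to the smallest `C`, then the smallest `γ`. In the offline
protocol tuning runs once on the full set and is frozen across folds
(nested re-tuning is configurable but off by default for cost); online it
re-runs every 25 steps once every class has at least 5 members. Tuning is
off by default (`C = 10`, `γ = "scale"`), which suits the synthetic
experiments here.

## Validity criteria

Log loss `−ln p` / `−ln(1−p)` and square loss `(p−q)²` are computed on the
probability assigned to the *predicted* label. Interval predictions are
first collapsed to the loss-matched minimax point — `p = P_u/(1−P_l+P_u)`
for log loss, `p = P_u + P_l²/2 − P_u²/2` for square loss; both provably
lie inside `[P_l, P_u]` and are monotone in each bound. `d_ln` is the mean
log loss (`+∞` propagates: a confident wrong claim is not clipped away —
an epsilon-clip exists for plotting only), `d_sq` the root of the mean
square loss, and `d1` the endpoint discrepancy `|CN/N − ΣP/N|`, taken as
`max` over the two bounds for interval predictors. Each minimax conversion
feeds only its own criterion.

## Protocols

*Offline*: leave-one-out over the dataset; the min-max feature scaler is
refit inside every fold on the training portion only (the source protocol
is silent here; refitting is the leakage-free reading). *Online*: a seeded
random initial set of 3 samples per class, then the remaining samples in a
seeded random order, each predicted, revealed, added, and the model refit.
The test order is a single seeded shuffle, recorded in the run manifest.
Per-class sensitivity is `C_kk / Σ_j C_kj` and specificity
`1 − (Σ_{i≠k} C_ik) / (Σ_{i≠k} Σ_j C_ij)`; a class with no true samples
reports NaN rather than a silent zero.

## Synthetic data

The recording generator emulates a headspace measurement cycle: flat
baseline (default 20 s), saturating-exponential rise during a 180 s
response phase, exponential recovery, 340 s total at 2 Hz, over a
16-sensor, 9-class, 35-samples-per-class campaign by default. Class
identity is a per-class × per-sensor pattern of amplitudes (0.5–4 V) and
rise/decay time constants (5–35 s / 20–80 s) drawn once per campaign;
within-class variation comes from white read noise (0.02 V) and a
per-sample lognormal gain jitter (σ = 0.05) shared across sensors,
mimicking variation in the volatile load. The sampling rate always comes
from recording metadata, never a constant, so campaigns recorded at other
rates are handled identically. What the simulator does *not* model:
sensor drift between measurements, humidity/temperature covariates,
cross-correlated noise, and chamber flow dynamics — so passing results
show the machinery is correct under i.i.d. conditions, not that real
ginseng-scale campaigns would reach the same accuracy.

The Gaussian-mixture feature generator draws spherical class-conditional
Gaussians with controllable mean separation (default experiments use 4-D
features, unit variance, one-hot means scaled by 1.9 — about 85–90 %
Bayes-attainable accuracy, comparable to a realistic discrimination task).
Its i.i.d.-by-construction sampling is exactly the hypothesis of the Venn
validity theorem, which is what makes it the right substrate for the
validity experiments. The misspecification experiment duplicates a 2-D
signal four times with 0.05-σ jitter: naive Bayes multiplies the four
nearly identical likelihoods and becomes overconfident, while the data
remain i.i.d., separating "model wrong" from "sampling assumption wrong".

## Problem sizes and numerical choices

The validity experiments run online streams of ~500 samples (3 classes,
5 seeds, all three taxonomies, induct mode) and check the cumulative
correct count against the cumulative bounds with a `3√N` allowance at
every step — a ≥6-standard-deviation band for the binomial fluctuations,
so violations indicate a broken implementation rather than bad luck.
Oracle-equivalence checks run 50 random problems at `n ≤ 15, K ≤ 3`
against an explicit-loop reimplementation, exactly. Calibration checks use
n ≈ 1000 (well-specified) and n = 300 (misspecified). Brute-force coupling
verification enumerates the 2-simplex at step 1e-3. Floats in CSV output
carry 17 significant digits and are parsed in round-trip mode, so
write-then-read is exact.

## Known limitations

* Venn prediction is transductive and therefore expensive: `K·n` (loo) or
  `K` (induct) classifier fits per test point, and another factor `n` in
  leave-one-out evaluation. No incremental refitting is attempted.
* The induct shortcut can be uninformative (wide intervals) with
  interpolating taxonomies; see above.
* Platt sigmoids are fit on training-set decision values, not on
  cross-validated ones; on small, separable training sets they are
  correspondingly optimistic. The Venn construction is unaffected (it uses
  only predicted labels).
* `select_from_matrix` validates row sums at 1e-9, so externally supplied
  matrices must be proper distributions per row.
* Model persistence covers NB/softmax/Platt parameters as JSON; SVC state
  belongs to its backing library's own serialisation.
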
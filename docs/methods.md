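# Methods

## Model

Each identified spectrum *i* carries a latent status *T_i* (1 = the
matched peptide is correct, 0 = incorrect) and a summarized score *S_i*.
Scores are treated as i.i.d. draws from the two-group mixture

S ~ π₀ f₀(S) + (1 − π₀) f₁(S),

fit independently per precursor charge because the discriminant that
produces *S* is charge-specific. The positive component f₁ is
Normal(μ, σ). The negative component f₀ is, by default, a three-parameter
shifted Gamma with shape α > 0, **rate** β > 0 and shift γ (density zero
below γ; mean γ + α/β); a Gumbel (max-extreme-value) with location μ_G
and scale β_G is selectable instead (variance β_G²·π²/6, mean
μ_G + β_G·γ_E with γ_E the Euler–Mascheroni constant).

Auxiliary discrete features — number of tryptic termini (NTT ∈ {0,1,2}),
number of missed cleavages (NMC ≥ 0), and the precursor-mass error ΔM
discretized into 1-Da bins centered on integers — are modeled as
per-component multinomials, conditionally independent of the score given
the component. The joint density of a record is then the score density
times the product of its feature-level probabilities under that
component.

## Fitting

EM with closed-form updates:

* **E-step** — PEP_i = π₀ f₀(s_i) g₀(i) / (π₀ f₀(s_i) g₀(i) +
  (1 − π₀) f₁(s_i) g₁(i)), where g_c(i) is the product of the discrete
  factor probabilities (1 for absent features).
* **M-step** — π₀ is the mean PEP. The Normal uses the weighted MLE with
  weights (1 − PEP_i) and the *biased* variance form (same denominator as
  the mean). The shifted Gamma sets γ to the minimum observed score and
  then applies weighted method of moments on the shifted scores
  (α = m₁²/m₂, β = m₁/m₂ with PEP weights); the Gumbel uses weighted
  method of moments (scale = √(6·variance)/π). Discrete tables are
  PEP-weighted (respectively (1 − PEP)-weighted) level frequencies.

Because the Gamma/Gumbel updates are moment estimators rather than exact
maximizers, the observed-data log-likelihood is not guaranteed to ascend
at every iteration; in practice it increases monotonically up to a
relative ripple below ~2·10⁻⁵ near convergence, and the tests assert
exactly that.

**Initialization** (the fitting literature leaves this open): π₀ starts
at 0.9 — incorrect matches dominate typical searches — the Normal is
initialized from the top decile of scores, the negative family from the
bottom half by moments. **Convergence**: the fit stops when no parameter
moves by more than ε (default 10⁻⁴, a conventional choice for this
model family) or after `max_iterations` (default 1000). Charges with
fewer than `min_records` (default 100) scored records are skipped with a
warning: EM on fewer spectra is unstable, which is precisely what the
bootstrap diagnostics expose. PEPs are clamped to [10⁻¹², 1 − 10⁻¹²]
inside the loop to avoid division by zero; reported PEPs are the raw
E-step values at the converged parameters.

**Semisupervised (target-decoy) mode.** Decoy matches are known to be
incorrect, so their PEP is pinned to 1 on every iteration. They
contribute to the negative component's updates (including the global
minimum that sets the Gamma shift, and the incorrect-side discrete
tables) but are excluded from π₀, the Normal update, and the
correct-side tables, so π₀ remains the incorrect proportion *of the
target population*. On simulations where the two components overlap
heavily, anchoring the negative component this way reduces the error of
its fitted moments relative to the unsupervised fit in essentially every
replicate (the acceptance checks require a majority of 20).

## Semiparametric variant

When the parametric shapes visibly misfit (a skewed or multimodal
correct-score distribution is the common case), both components can be
estimated by weighted Gaussian-kernel densities:
p(s) = (1/(W·h)) Σ w_i K((s − s_i)/h), W = Σ w_i, which reduces to the
classical 1/(n₀h) form for unit weights. The negative KDE is built once
from decoy scores (unit weights) and held fixed; the positive KDE is
rebuilt each iteration from target scores; π₀ is re-estimated as the
mean target PEP; iteration stops when no PEP moves by more than ε.

**Positive-component weights.** The natural choice — weighting every
target by its current (1 − PEP) — has a biased fixpoint: the summed
(1 − PEP) mass of the many confidently incorrect targets leaks into the
positive density estimate and drags π₀ down (≈0.63 where the parametric
fit and the truth sit at 0.70 in our well-specified validation). The
package therefore zeroes the weight of any target whose PEP is at or
above `positive_weight_cutoff` (default 0.9); the first iteration, which
starts from a flat PEP, falls back to the untruncated weights. Validated
on two scenarios: a well-specified Normal/Gamma simulation (π₀ 0.7075
with truncation vs 0.7046 parametric) and a strongly bimodal positive
component (mean |PEP − true posterior| 0.012 vs 0.202 for the
misspecified parametric fit).

**Bandwidth.** Silverman's rule by default,
h = 0.9·min(sd, IQR/1.34)·n_eff^(−1/5), with weighted sd/IQR and
effective sample size n_eff = (Σw)²/Σw²; leave-one-out likelihood
cross-validation over a log-spaced grid is available (`method="cv"`) and
picks smaller bandwidths on multimodal data, at quadratic cost. As a
guardrail against overfitting small samples the fit refuses to run on
fewer than 500 targets unless forced; kernel components are only
worthwhile under strong, visible deviation from the parametric shapes.

## Adaptive discriminant

Fixed discriminant coefficients trained on unconstrained searches can
separate poorly on constrained ones. The adaptive loop re-learns them
from the experiment: score the current best candidates; fit the mixture;
take records with PEP ≥ `pep_high` (default 0.9) as negatives and
PEP ≤ `pep_low` (default 0.05) as positives; draw I (default 10) random
subsamples of 70% of the positives, train a Fisher linear discriminant
per subsample against the full negative set, and average the I
coefficient vectors; rescore every spectrum's top-K (default 5)
candidates with the averaged coefficients and promote the highest scorer
(ties to the lowest original rank); repeat until max |Δβ| < ε (default
10⁻⁴) or `max_rounds` (default 20).

Design choices the procedure leaves open, as resolved here:

* the I discriminants are trained against the **full** negative set —
  negatives are plentiful and their covariance estimate benefits from
  all of them; only the positive set is subsampled;
* **training-set floor** (`min_training`, default 50): when the PEP
  thresholds select fewer records (heavy early overlap), the selection
  is padded with the most confident records by PEP rank — a handful of
  training points produces an LDA that oscillates from round to round;
* the subsample generator is re-derived from the master seed at the
  start of every round, so once the training selection stops changing
  the subsamples (hence the averaged coefficients) repeat exactly and
  the ε-stop is a true fixed point rather than a noise floor;
* the LDA intercept places the decision value 0 at the midpoint of the
  projected class means, matching the convention that correct matches
  score above 0.

On simulations with equal-covariance Gaussian classes (where the Bayes
combiner is exactly linear with direction Σ⁻¹(μ₁ − μ₀)) the loop started
from weak uninformative coefficients recovers the true direction with
cosine ≥ 0.98 and accepts at least as many targets at a 5% decoy-ratio
FDR as the weak coefficients in 10/10 validation replicates.

## Confidence measures

* PEP: the E-step posterior at the record's score and feature levels.
* p-value / FPR: P(S > s | T = 0) from the negative component's survival
  function (closed form for Gamma/Gumbel, exact Gaussian-CDF sums for
  kernels). The two are the same tail; the package exposes both names
  and the tests assert the identity exactly.
* FDR at cutoff t: model-based tail ratio; mean of PEPs over records
  with score ≥ t; or the decoy/target count ratio above t. Tail
  comparisons use strict `> t`, the mean-PEP set uses `≥ t`, exactly as
  each formula is written — at a tied cutoff they can differ by the tie
  group. A conditional model-based FDR multiplies each component tail by
  that component's probability of the conditioned discrete level(s).
* q-values: cumulative minimum of the chosen FDR estimator over the
  observed scores of the charge, lowest cutoff upward; a dense-grid mode
  (`q_values_grid`) reproduces fixed-increment cutoff scans. q-values are
  monotone in the score even where the raw FDR curve is not.

## Synthetic data

`psmix.synth` draws exactly the structure the model assumes: per charge,
each target is incorrect with probability π₀ (score from the negative
component, discrete levels from the incorrect-side tables) and correct
otherwise; decoys are extra negative-component draws flagged `is_decoy`;
every record carries `true_label`, enabling `true_fdr` (label-based
FDR). `raw_features` mode instead emits class-conditional
multivariate-normal engine features with shared covariance — making the
Bayes-optimal combiner linear and giving the adaptive module a
recoverable ground truth — and `simulate_candidate_sets` wraps this into
per-spectrum top-K candidate lists in which a correct spectrum hides its
correct candidate at rank 1 with probability 0.8, else at a uniform
lower rank.

What the generator deliberately does **not** emulate: target/decoy
competition within a concatenated search (decoy counts are independent
of target counts), score dependence between candidates of the same
spectrum, and any spectrum-level physics (fragmentation, noise peaks,
retention time). Passing tests therefore demonstrate correctness of the
estimators under the model's own assumptions — calibration on real
searches additionally depends on how well those assumptions hold, which
is exactly what the bootstrap and quantile-quantile diagnostics are for.

## Diagnostics

Bootstrap resampling (B with-replacement resamples, default 100,
recommended range 100–500) refits the model per resample, stratified by
charge so per-charge record counts are preserved. Per parameter:
bias = mean(resampled) − original, variance = sample variance (ddof 1),
MSE = variance + bias². Resamples whose refit degenerates are excluded
with a warning (more than 20% failures aborts) — degeneration frequency
is itself a diagnostic of an unstable fit. `qq_pairs` returns matched
empirical quantiles (linear interpolation between order statistics) for
visual comparison of two score samples.

## Problem sizes and numerical choices

Validation and acceptance runs use simulations of 3,000–10,000 targets
per fit, 20 replicates for the semisupervised/unsupervised contrast and
10 for the adaptive/fixed contrast; these sizes give sampling noise well
inside the asserted tolerances while keeping a full run in the minutes
range on one core. The semisupervised/unsupervised comparison scores the
negative component by the squared errors of its distribution mean and
standard deviation rather than the raw (α, β, γ) triple: shape and rate
are strongly anti-correlated, so raw parameter errors are dominated by a
ridge direction that says little about where the fitted density actually
sits. Degenerate inputs fail loudly: identical scores, zero component
weights, empty rejection regions and missing charge models all raise
typed errors rather than returning NaN.

## Known limitations

* The shift of the Gamma is the sample minimum — simple and as the
  estimator is defined, but it converges slowly (n^(−1/4) for shape ≈ 4)
  and biases α slightly low at moderate n; the bootstrap quantifies the
  resulting spread.
* Kernel fits need hundreds of decoys and targets; below that the
  parametric (or semisupervised parametric) path is the right tool, and
  the code enforces this unless forced.
* π₀ comes from the mixture fit only; no p-value-based π₀ estimator is
  provided.
* pepXML/mzIdentML are out of scope; the native format is delimited
  text.
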
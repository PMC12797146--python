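# Methods

## Model

The generative model is a conditional variational autoencoder over a vector
of standardised brain measures `Y` (F features) given covariates `X`
(7 columns, fixed order: age, sex, ICV, diabetes, hypercholesterolaemia,
obesity, smoking; age and ICV z-scored on the training cohort, binaries
passed through as 0/1).

- Encoder: `[Y, X] → ReLU hidden → (μ_z, log σ_z²)`, defining
  `q(z | Y, X) = N(μ_z, diag σ_z²)` over an L-dimensional latent space.
- Decoder: `[z, X] → ReLU hidden → (μ_Y, log σ_Y²)`, defining a diagonal
  Gaussian observation model per feature.
- Training minimises the negative evidence lower bound
  `mean_batch[ KL(q ‖ N(0, I)) + NLL(Y; μ_Y, σ_Y²) ]` with the KL summed
  over latent dimensions and the Gaussian negative log-likelihood summed
  over features. This reduction keeps the two terms on a common per-subject
  scale; losses are therefore comparable across runs only at fixed F.
- Reparameterisation `z = μ_z + σ_z ⊙ ε`, `ε ~ N(0, I)`, makes the
  stochastic layer differentiable. All gradients are derived analytically
  (plain NumPy) and checked against central finite differences at 1e-4
  relative tolerance in the test suite.

Both log-variance heads are clamped to [−10, 10] for numerical stability;
gradients are masked outside the clamp. Optimisation uses Adam
(lr 1e-3, batch 256 by default); a seeded 10% validation split is held out,
standardisation is fitted on the remaining 90% only, and early stopping
monitors the validation loss with patience 20 (the parameters from the best
epoch are restored). A non-finite loss at any point aborts training with the
epoch index. A seeded random-search tuner with k-fold cross-validation is
provided for architecture/learning-rate selection.

### Inference

Prior-sampling prediction draws K latent vectors per subject from
`N(0, I)` (K = 1000 by default — comfortably above the ~400 draws needed for
a stable 95% interval), decodes each with the subject's covariates, and
combines the K Gaussian components by the law of total variance:
`μ* = mean_k μ^(k)`, `σ*² = mean_k σ²^(k) + mean_k (μ^(k) − μ*)²`. The
within/between components are stored and the identity `σ*² = within +
between` holds exactly. Because latents come from the prior, both components
mix aleatoric and epistemic uncertainty; no explicit disentanglement is
attempted. Posterior-sampling prediction is identical except latents come
from `q(z | Y, X)`.

Draw randomness is organised as one stream per subject, keyed by
`(master seed, subject key)`, so predictions are invariant to batching and
subject order; subject keys default to position and may be supplied.

Deviation scores `z = (Y − μ*)/σ*` are computed on the standardised scale —
the scale the model was trained on; for log-transformed WMH features this
means deviations are in log-volume SD units. Predicted means can be mapped
back to raw units via the inverse transform, but a raw-scale σ* for log
features is deliberately not defined. The extreme-deviation threshold is
±2.58 (two-sided 99% of N(0,1)), configurable.

## Standardisation

WMH volumes are `log(x + offset)`-transformed before z-scoring; the offset
defaults to 1 mm³, which maps a zero lesion load to zero log-volume,
preserves monotonicity and keeps the transform finite for all non-negative
volumes. The offset is configurable since no canonical value exists for
zero handling. All SDs use the sample (n−1) convention. Standardise /
destandardise are exact inverses; the loader rejects missing values,
misaligned subject ids and negative WMH volumes rather than imputing.

## Synthetic cohorts

The generator emulates a population imaging cohort of 45–84-year-olds:

- age: truncated normal, realised mean 60.76 y, scale 7.20 y, range
  [45, 84] (the pre-truncation location is solved so the *realised* mean
  matches the target despite the asymmetric truncation);
- male fraction 30.8%; diabetes 1.8%, hypercholesterolaemia 7.4%, obesity
  8.5%, smoking history 33.8% (Bernoulli);
- ICV: normal, 1.55e6 ± 1.4e5 mm³;
- blood pressure: bivariate normal (SBP 135 ± 18, DBP 82 ± 10, r = 0.7),
  chosen so all four hypertension grades occur in realistic proportions;
  grading follows the standard thresholds (0: SBP<130 and DBP<85;
  1: SBP 130–139 or DBP 85–89; 2: SBP 140–159 or DBP 90–99;
  3: SBP≥160 or DBP≥100, higher grade winning).

Features follow a linear model on the standardised covariates on a
*transformed* scale — identity for morphometric measures, log for WMH —
plus independent Gaussian noise (optional age-linked heteroscedasticity).
Effect sizes are expressed in multiples of each feature's noise SD, with
deterministic per-feature jitter so features within a category are distinct;
defaults follow well-replicated directions (ageing thins cortex and grows
WMH load; male sex and larger ICV mean larger volumes; vascular risk factors
add small detriments) with total covariate effects reaching ~0.5 SD.
Hypertension pathology enters as additive per-level shifts on the
transformed scale (e.g. WMH: 0 / +0.15 / +0.35 / +0.80 SD for levels 0–3;
small negative shifts for morphometry). WMH features are exponentiated back
to mm³ and clipped at zero, producing the heavy right skew and exact zeros
of real lesion maps. Every subject's true conditional mean and SD are
recorded, so the generator doubles as an oracle for parameter-recovery and
calibration tests.

What the generator does **not** emulate: correlated residuals between
features (beyond what shared covariate effects induce), non-linear covariate
response, longitudinal structure, and site effects. Two consequences matter
when reading test results. First, the WMH zero-clip makes the observed
log scale deviate from the generating Gaussian below zero, so oracle
calibration checks are run against data the oracle itself generates, and
exactness checks exclude clipped WMH features. Second, with conditionally
independent residuals a posterior-sampling encoder can only partially absorb
an out-of-distribution pathology shift: posterior deviations show clearly
attenuated z elevation and extreme-deviation rates relative to prior
sampling, but not the full rank-correlation collapse seen on real data,
where strong cross-feature residual structure lets the encoder reconstruct
observations almost exactly. Passing tests therefore demonstrate the
direction and mechanism of the prior/posterior asymmetry, not its real-data
magnitude.

## Evaluation battery

- Accuracy per feature: median absolute error, RMSE, Spearman's ρ (Pearson
  on midranks under ties; undefined for constant vectors, returned as
  missing with a warning), explained variance `1 − SS_res/SS_tot`.
- Model comparison: median-based permutation test — pool the two per-feature
  score vectors, re-partition into the original sizes n_perm times
  (default 10,000), p = proportion of shuffled |median differences| ≥ the
  observed one, floored at 1/n_perm so p is never 0. Cliff's delta
  (computed by sorting rather than O(n²) pairing) is the effect size;
  Benjamini–Hochberg FDR is applied within each analysis table.
- Calibration: ECE over central Gaussian intervals at confidence levels
  0.05–0.95 in steps of 0.1 (10 levels): mean absolute gap between nominal
  and observed coverage.
- Covariate sensitivity: add one training-SD to age for every hold-out
  subject, re-predict in both modes with matched per-subject draw seeds,
  summarise per-feature median shifts and test the paired per-(subject,
  feature) absolute effects with the Wilcoxon signed-rank test. The effect
  size is the matched-pairs rank-biserial correlation of
  (posterior − prior) effects — negative when posterior sampling is less
  responsive. Pairing at (subject, feature) granularity is a design choice;
  a zero perturbation is reported as degenerate rather than tested.
- Covariate independence: Spearman for continuous covariates, point-biserial
  for binaries, FDR over the whole table. Clinical association: Spearman of
  z against hypertension level (0–3) per feature with FDR; requires at
  least two levels.

## Scaled study conditions

The test suite and `scripts/acceptance.py` run a 20-feature configuration
(5 per category): training n = 2000 normotensive-only, hold-out n = 1000,
evaluation n = 6000 mixed; cVAE latent 32 / hidden 256, up to 600 epochs
with patience 30; K = 300–500 draws. The package defaults (latent 64,
hidden 512, K = 1000) remain those appropriate for a ~200-feature problem.
Under the scaled conditions the prior-sampling model recovers ground-truth
conditional means at r > 0.9 per feature with predictive SDs within 25% of
the generating noise SD, and the prior-vs-baseline comparison is
non-significant, while the posterior mode wins reconstruction accuracy —
the expected behaviour of a covariate-only norm versus a dual-input
autoencoder.

## Known limitations

- Diagonal Gaussian observation model: no cross-feature covariance in the
  predictive distribution; deviations are scored marginally per feature.
- Gaussian z-scores are a poor fit for heavily zero-inflated WMH regions
  even after the log transform; percentile/CDF-based scores would handle
  such features without parametric assumptions but are not implemented.
- The tuner is a random search, adequate for the small discrete spaces used
  here, not a substitute for a full Bayesian optimisation study.
- Checkpoints store raw weight tensors plus JSON config/state in a single
  zip archive with a format version field; cross-version compatibility is
  best-effort.
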
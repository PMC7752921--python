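# Methods

## Distributional transformation

DT maps a vector of out-of-sample predictions onto the empirical distribution
of the training-set target values. With predictions `y^_1..y^_m` and a
reference sample `y_1..y_n` (the training targets), each prediction is
replaced by

    y~_i = F_ref^{-1}( F_pred(y^_i) ),

where `F_pred(t) = #{j : y^_j <= t} / m` is the right-continuous empirical
CDF of the predictions and `F_ref^{-1}(q) = min{ y in sample : F_ref(y) >= q }`
is the generalized-inverse (left-continuous, non-interpolating) empirical
quantile function of the reference. The composition is evaluated in integer
arithmetic — the index of the selected reference order statistic is
`ceil(k * n / m) - 1` for a prediction of rank `k` — so two exact properties
hold with no floating-point caveats:

- **Rank preservation.** Ranks of the output equal ranks of the input, so
  Spearman correlation with any third variable is invariant under DT.
- **Equal-n permutation.** When `m = n` and predictions are distinct, the
  output is exactly a permutation of the reference sample: its empirical CDF
  *is* the reference CDF, and the two-sample KS statistic against the
  reference is exactly 0.

Consequences: transformed values always lie inside the observed reference
range, and the transform is idempotent for a fixed reference.

**Assumptions.** DT is justified when training and validation sets are
independent and identically distributed samples of the target variable — in
particular when the target's distribution was matched (e.g. controlled for
mean age) while splitting. If the validation distribution genuinely differs
from the training distribution, DT imposes the wrong distribution by design.

**Ties and alternatives.** Tied predictions share an ECDF level and map to
identical outputs; an optional seeded jitter (`jitter=True`) breaks ties with
infinitesimal noise, off by default because determinism is preferred. An
interpolating quantile variant (`interpolate=True`) trades the exact equal-n
permutation property for smoother outputs when `m != n`. No plotting-position
correction is applied to the prediction ECDF: the largest prediction maps to
level 1, i.e. to the reference maximum.

## Decoders

**OLS.** `beta = (X'X)^{-1} X'y` via a symmetric eigendecomposition of the
Gram matrix; a reciprocal condition number below 1e-10 raises an error naming
the columns loading on the near-null eigenvector. No intercept column is
added anywhere: the acquisition-site indicator block spans the constant, so
the model is estimable and the design keeps `p = 2R + S + 1` columns. The fit
retains `(X'X)^{-1}`, `sigma2 = RSS/(n-p)` and `df = n-p` for inference.

**SVR.** Epsilon-insensitive regression, linear kernel, internal feature
standardization; defaults `epsilon = C = IQR(y)/13.49` (IQR/1.349 is a robust
SD estimate; dividing by a further 10 keeps the insensitivity tube at a tenth
of the target spread). A constant training target short-circuits to
predicting that constant. The quadratic-programming solve is delegated to a
standard SVM library behind this surface.

**Neural network.** Implemented directly in numpy with explicit
backpropagation; gradients are validated against central finite differences
in the test suite (agreement ~1e-10). Default architecture: the p features
enter as a univariate sequence (one feature per step) into an LSTM with 125
hidden units; the last hidden state passes through a fully connected layer
(50 units), dropout (p = 0.5), and a fully connected scalar output, with no
nonlinearity between the fully connected layers. Training: MSE loss, Adam
(lr 0.01, beta1 0.9, beta2 0.999), 100 epochs, mini-batch 20, gradient
clipping by global L2 norm at 1, forget-gate bias initialised to 1, Glorot
weight initialisation. Because the sequence layout makes predictions depend
on feature order, the column order is fixed to [GM | WM | site | gender]. An
order-free MLP variant (p → 125 → 50 → 1, ReLU, dropout 0.5) is available via
`architecture="mlp"`; it reaches high out-of-sample accuracy within tens of
epochs, whereas the sequence architecture needs several hundred optimizer
epochs at small n before the output scale is reached — the test suite and the
acceptance script therefore exercise the LSTM at reduced layer sizes and use
the MLP for accuracy smoke checks. All randomness derives from one seed;
training is deterministic under single-threaded execution.

**Z-scoring.** Non-indicator columns are mean-subtracted and divided by the
sample SD (ddof = 1); indicator columns pass through bit-identically. By
default each design matrix (training and validation) is scaled by its *own*
statistics; scaling the validation matrix by training statistics is available
by fitting the scorer once and reusing it (`scale_with_train` in the
pipeline).

## Evaluation statistics

- R², adjusted R² (with `p_model` = number of design columns for every
  decoder, a documented simplification since SVR and the network have no
  clean parameter count), Pearson r, Spearman r, MAE, RMSE, and the rank
  correlation of the error `y - y^` with `y` ("objective 2": small magnitude
  = age-independent errors). Correlations whose defining variance vanishes
  are reported as NaN, never silently as 0.
- **Wilcoxon signed-rank** on paired absolute errors: zero differences
  dropped, average ranks for ties, z from the normal approximation with tie
  and continuity corrections, signed so that z < 0 when the first method has
  smaller absolute errors. For n <= 25 without ties the p-value comes from
  exact enumeration instead; the continuity correction keeps the
  approximation within 0.05 of the exact p down to n ≈ 8.
- **Empirical KL divergence** on histograms over shared bins (default 1-year
  bins aligned to integer multiples of the width, spanning the union range),
  natural log. Epsilon smoothing (`eps = 1/(10(n_p+n_q))` added to all
  predicted bins, renormalised) is applied only when a bin has actual mass
  but zero predicted mass; identical samples therefore give exactly 0, and
  disjoint supports give a large finite value that grows as 1/eps.
- **Two-sample KS**: D = sup |F_a - F_b| with the asymptotic Kolmogorov
  p-value (library-backed, oracle-checked).
- **Coefficient inference**: `SE(beta_j) = sqrt(sigma2 * [(X'X)^{-1}]_jj)`,
  CI `beta_j ± z_{1-alpha/2} SE` with the standard-normal quantile (1.645 at
  the default 90% level; a Student-t option exists behind `use_t`), and
  significance tiers p < 0.05, p < 0.001, and Bonferroni p < 0.05/p. Note
  that with fewer than 50 design columns the Bonferroni tier is *less*
  stringent than p < 0.001; tiers are assigned by the smallest threshold the
  p-value clears.

## Synthetic population generator

The generator emulates a multi-site structural-imaging age study:

- **Ages**: truncated two-component normal mixture, default means 30 and 70
  years, SDs 10, weights 0.55/0.45 on [17, 90] — a bimodal adult distribution
  with few middle-aged subjects, the regime in which range-shrinking decoders
  interact most visibly with DT. The true age histogram of any given study is
  never exactly this; the mixture is fully configurable.
- **Features**: 2R region means (default R = 116), each
  `intercept_r + slope_r * age + site_offset + noise`. Slopes are
  region-specific and signed, magnitudes uniform in [0.3, 1] × `effect_scale`
  (default 0.003 density units/year, i.e. roughly a 0.2 change over the adult
  range); intercepts sit in plausible tissue-density ranges (GM 0.45-0.65,
  WM 0.35-0.55); noise SD defaults to 0.02 and per-site offsets to SD 0.005 —
  mild site effects, with every site sampling the whole age range
  (round-robin site assignment after shuffling).
- **Covariates**: balanced ±1 gender, S = 17 one-hot site columns.
- **Split**: 4:1 by default; `match_age` stratifies on age deciles so the
  split age distributions are matched (two-sample KS D < 0.05 at n = 10⁴).

What this world does *not* contain: nonlinear age effects, heteroscedastic
noise, feature correlations beyond the shared age signal, site-by-age
interactions, or any cortical geometry — passing tests here show the
machinery is correct and that DT behaves as predicted in a controlled linear
world, not that any particular accuracy will be reached on real data. The
toy NIfTI fixtures (slab-partitioned label volume, constant or random tissue
values, identity 1 mm RAS affine) exist solely to make reslicing and region
averaging exactly checkable.

**Distortion scenarios** stand in for decoder pathologies when studying DT in
isolation: shrinkage towards the mean (factor 0.6 with mild 2-year noise is
the standard "range under-coverage" scenario), truncation, and additive
noise. The identity scenario (factor 1, no noise) returns the input exactly;
applying DT to it measures the pure quantile-matching discrepancy between two
matched samples, about 0.3 years MAE (≈0.6% of the mean age) at the default
study size — the "no benefit, no harm" regime where predictions already share
the reference distribution.

## Feature extraction

The atlas is resliced onto the data grid by nearest-neighbour lookup through
the two affines (half-coordinates round away from zero, deterministically;
out-of-volume positions become background), then each subject's GM and WM
volumes are averaged within every atlas region in ascending label order. No
density threshold is applied before averaging. Empty regions yield NaN plus a
warning rather than a silent drop. Reslicing never invents labels, and an
identity reslice is voxel-identical.

## Numerical choices

- DT quantile indices in exact integer arithmetic; the float path for
  arbitrary quantile levels backs off by 1e-9 before `ceil` to guard against
  `k/n * n` rounding up.
- Gram singularity threshold: reciprocal condition 1e-10; the Gram inverse is
  symmetrized after the eigendecomposition.
- Wilcoxon variance with the tie term `sum(t³ - t)/48`; zero variance (all
  differences equal in magnitude after dropping zeros, n = 1) returns
  (z = 0, p = 1).
- KL bin edges at integer multiples of the bin width; a degenerate range
  (single point) is widened to one bin.
- The acceptance script and tests run the heavy pieces at reduced sizes
  (network at 600 subjects / 20 regions; Monte-Carlo coverage at 1000-2000
  replicates), chosen as the package's own default desk-scale settings.

## Known limitations

- The sequence-input network is faithful to its specification but is a slow
  learner in this implementation and at desk scales; the MLP variant is the
  practical choice.
- Adjusted R² with `p_model = p` is a convention, not a principled effective
  degrees of freedom, for SVR and the network.
- `coefficient_inference` uses normal quantiles by default (matching the
  z = 1.645 convention) even at small n; pass `use_t=True` for exact
  small-sample intervals.
- The CLI `predict` subcommand reloads only the JSON-serialized linear model;
  SVR/network workflows run end-to-end through `dtdecode run` instead.
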
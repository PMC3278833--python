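# Methods

## Model

`grnstab` treats a gene-expression time course as a realization of a
first-order multivariate vector autoregression: with `y^t` the row vector of
`I` gene expressions at time `t`,

    y^t = y^{t-1} β + ε^t,      ε^t ~ N(0, Σ) i.i.d.

The I×I coefficient matrix `β` encodes the network: `β_ij ≠ 0` means gene
*i*'s expression at time `t−1` linearly influences gene *j*'s at `t`.
Stacking the `T−1` lagged pairs gives the regression `Y = Zβ + E` with
`(T−1)` rows, which decomposes into `I` independent univariate regressions,
one per target gene.  The model is linear, first-order (one lag), and
assumes equally spaced time points and Gaussian innovations; it does not
model measurement error separately from biological innovation noise, and a
detected edge is a lag-1 linear (Granger-style) dependence, not a verified
physical interaction.

## Estimation and tuning

With `T` typically below `I`, ordinary least squares is unavailable or
unstable, so columns of `β` are estimated by penalized least squares

    (1/2n)‖y_j − Zb‖² + λ(α‖b‖₁ + (1−α)/2‖b‖₂²),   n = T−1.

Ridge (`α=0`) is solved in closed form; lasso (`α=1`) and elastic net
(`α∈(0,1)`) by warm-started cyclic coordinate descent over a descending
penalty path, implemented on the Gram statistics `(Z'Z, Z'y, y'y)` so that
leave-one-out folds are rank-1 downdates rather than refits from raw data.

Tuning deliberately reproduces the conventions of the reference
coordinate-descent software (glmnet) and of MATLAB's `ridge`, because the
measurable behavior of the penalized fits — in particular the number of
spurious edges — depends on these conventions as much as on the objective:

* **Standardization and intercept.**  Predictors are centered and scaled to
  unit population variance, and an intercept is fitted via centering,
  *within each training fold*.  Coefficients are reported on the original
  data scale.  Both can be disabled (`standardize`, `fit_intercept`).
* **Response scaling.**  For lasso/enet the response is internally scaled
  to unit variance and the penalty divided by `sd(y)` (the reference
  software's gaussian normalization).  This leaves the L1 term invariant
  but weights the L2 term inversely to the response scale — a subtle but
  consequential convention for the elastic net.
* **Penalty grid.**  100 log-spaced values from `λ_max` (smallest penalty
  with an all-zero solution) down to `λ_max·1e-4` (`1e-2` when the design
  has at least as many columns as rows), truncated where the fraction of
  deviance explained saturates (increment below 1e-5 of itself, or above
  0.999).  Truncation keeps the cross-validation minimum out of the
  overfitting tail of the path.
* **Selection rule.**  Leave-one-out cross-validation per target gene.
  Lasso/enet select the largest penalty whose CV error is within one
  standard error of the minimum (the 1-SE rule); the elastic-net mixing
  weight `α` is chosen from {0.1, …, 0.9} by the minimum CV error over each
  curve before the 1-SE rule is applied within the winning curve.  Ridge
  searches the fixed grid {0.001, 0.1, 1, 10, 100} with the plain CV
  minimum, and its penalty enters the standardized normal equations
  unscaled (`Z'Z + λI`) — the classical parameterization on which that
  grid is expressed.  Ties break toward the smaller penalty (then smaller
  `α`).
* **Convergence.**  A coordinate-descent sweep terminates the iteration
  when the largest variance-weighted squared coefficient update falls below
  `1e-7` times the response variance (the reference software's criterion);
  `fit_penalized` exposes the tolerance for high-precision use.

These conventions were fixed by matching per-replicate outputs against
R glmnet on identical data, not by tuning toward any benchmark value.

## Edge calling

Synthetic benchmarks call an edge wherever `|β̂_ij| > ε` with `ε = 1e-4`;
all `I²` directed entries including self-loops are candidates.  Real-data
workflows instead use an approximate significance test: the sampling
variance of a penalized coefficient is approximated by the ridge-type
sandwich `(Z'Z + λW⁻)⁻¹ Z'Z (Z'Z + λW⁻)⁻¹` with `W = diag|β̂|` (its
pseudo-inverse reciprocates the nonzero entries), the statistic
`β̂_k/√(σ̂²w_k)` is referred to a *t* distribution whose degrees of freedom
equal the number of nonzero coefficients in that target's regression, and
all `I²` p-values of a model are corrected together by Benjamini–Hochberg
at level `q` (default 0.05; zero coefficients get p = 1).  The residual
variance is `RSS/(n − d)` with `d` capped at `n−1`.  This test is a
closed-form approximation, conservative under the null in our simulations,
and intended for screening rather than exact inference.

## Stability

For `B` networks from replicate or perturbed data: pairwise stability
`ρ = 1 − d_H/(|s_a| + |s_b|)` (Hamming distance normalized by total edge
count; 1 for two empty networks; symmetric; 1 iff identical), overall
stability `ρ̄` (mean over unordered pairs), and per-edge occurrence
frequencies `e_ij` whose strict `> 0.5` exceedances form the stable
consensus network.  A strict-Hamming alternative normalizing by `I²` is
available (`normalization="entries"`) but saturates near 1 for sparse
networks and does not reproduce the benchmark's stability levels.

## Synthetic data

The generator emulates a short time-course experiment on a known network:

* **Topology** — directed Barabási–Albert growth from a single node; each
  new node attaches to an existing node with probability ∝
  `in_degree^γ + b` (γ = 1.2, b = 1, one edge per node), the edge pointing
  from the new node to the chosen one.  An `I`-gene network therefore has
  exactly `I−1` edges, hubs accumulate in-degree, and the graph is acyclic,
  so the coefficient matrix is nilpotent and trajectories cannot diverge.
* **Coefficients** — magnitudes uniform on [0.8, 1] on the edges, zero
  elsewhere, positive/negative counts differing by at most one.
* **Trajectories** — initial expressions uniform on [10, 15]; innovations
  `N(0, I)` by default.  The initial transient decays within a few steps
  (nilpotency), after which the series is innovation-driven.
* **Perturbation** — i.i.d. `N(0, (σ+δ)²)` added to every entry, with `δ`
  solving `Var(signal)/(σ+δ)² = SNR` for a target signal-to-noise ratio
  (`Var(signal)` is the overall sample variance of the input matrix and σ
  the residual standard deviation of the unperturbed fit), so larger SNR
  means milder perturbation.

What the generator does *not* emulate: correlated gene programs,
measurement-platform noise, missing values, uneven sampling, feedback
loops, or nonlinearity.  Passing benchmarks therefore demonstrate correct
behavior of estimator and metrics under the stated linear model — not
performance on real expression data, where correlated regressors notably
favor the elastic net over the lasso.

A consequence of the acyclic design worth knowing: with innovation noise
switched off entirely, trajectories are exactly zero after the graph depth,
so noise-free data from generated topologies cannot identify the
coefficients.  Noise-free identifiability checks in the test suite use a
persistent cyclic (ring) truth instead.

## Experiments

The synthetic benchmark fixes one topology and coefficient matrix per
network size, simulates `B` replicate series per (size, length) cell that
differ only in initial state and innovations (default B = 100), fits each
method on the shared replicates, scores accuracy against the truth over
all `I²` entries, and computes overall stability across the `B` detected
networks.  The perturbation study fits a reference network on the input
data via the significance test, then for each SNR fits `B` perturbed copies
and reports stability, the stable network, and mean F-measure against the
reference (taken as truth).  Seeding is hierarchical
(master seed → cell → replicate via `numpy.random.SeedSequence`), so any
replicate is re-runnable in isolation and a fixed master seed yields
bit-identical tables.

`scripts/acceptance.py` runs the headline cells at their study sizes
(B = 100 for the 10-gene cells; the 50-gene cell at B = 25, a size chosen
to keep a laptop run in minutes while leaving the replicate-mean recall
stable to well under a percent).  Because each run draws a single
ground-truth topology, ratio metrics such as F and stability vary by a few
hundredths from seed to seed; the test suite averages its benchmark checks
over three topology seeds to keep that draw from dominating the comparison.

## Known limitations

* First-order dynamics only; no group penalties, priors, or time-varying
  coefficients.
* The coefficient significance test is approximate (ridge-type sandwich +
  nonzero-count degrees of freedom); p-values are screening quantities.
* Per-target penalty selection; a single shared penalty across targets was
  evaluated and performs substantially worse on the benchmark.
* LOOCV with the 1-SE rule is conservative; on noise-free (degenerate) CV
  curves selection is driven by numerical ties and exact support recovery
  is not guaranteed.
* Coordinate-descent solutions for undersampled designs can carry slightly
  more than `n` active coefficients when the lasso solution is non-unique.
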
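# Methods

## Generative model

Community dynamics follow the stochastic discrete-time Lotka-Volterra
(Ricker) map

    x_i(t+1) = x_i(t) · exp( Σ_j c_ij (x_j(t) − x̄_j) + η_i(t) ),   η_i ~ N(0, σ_p²)

with timestep fixed to 1 (time measured in sampling intervals). The
equilibrium `x̄` is a fixed point of the noiseless map by construction.
Writing `u = x − x̄` and linearizing gives the first-order vector
autoregression `u(t+1) = J u(t) + ξ` with Jacobian `J = I + diag(x̄) C` and
`ξ_i = x̄_i η_i`; its stationary covariance solves the discrete Lyapunov
equation `Σ = J Σ Jᵀ + Σ_ξ`, computed in `network_eval.linearized_covariance`
through the Kronecker-product vectorization identity. Note the linearized
noise covariance is `diag((x̄_i σ_p)²)`, not `σ_p² I`: the log-scale noise is
scaled by the local abundance. `process_noise_covariance` builds this
matrix; `linearized_covariance` deliberately takes the noise covariance as
an explicit argument rather than defaulting to `σ² I`, which is only correct
at unit equilibria.

Relative abundances `y_i = x_i / N` follow approximately the same map with
coefficients rescaled by the mean total population size, provided total
abundance fluctuations are small (reasonable for communities of ~10 or more
species). Inference on relative data therefore returns coefficients known
only up to one global multiplicative constant; `recovery_r2` reports the
best-fit scale alongside R².

Measurement error (sequencing noise, OTU mis-assignment) is modelled as
i.i.d. multiplicative log-normal corruption of each observed value; for
relative data the corrupted columns are renormalized to sum to 1, since
read counts are compositional by construction. Corrupting the absolute
abundances and then closing the composition is algebraically the same
operation.

## The inference algorithm

Each row `c_i` of the interaction matrix is estimated independently.

1. Estimate `x̄` as the per-species median over all timepoints and
   replicates (robust to transients and skewed noise). The estimate is
   computed once from the full timeseries and shared across bootstraps.
2. Build the regression: one candidate row per consecutive timepoint pair
   within each replicate (never across replicate boundaries), design
   `(x_1(t) − x̄_1, …, x_M(t) − x̄_M)`, response `log(x_i(t+1)/x_i(t))`
   (natural log). Transitions where the *focal* species is zero at either
   end are dropped (the log is undefined); zero abundances of other species
   are legal covariates.
3. Forward stepwise selection on a random half/half train/test split of the
   rows (training takes the extra row when the count is odd): start from the
   active set `{i}`; at each iteration fit every single-candidate extension
   on the training rows by least squares, score it by test-set MSE, take the
   best candidate (ties broken by lowest species index), and accept iff
   `(E_old − E_new)/E_old > threshold`, else stop.
4. Repeat step 3 for `n_bootstrap` independent partitions and aggregate the
   sparse coefficient rows entrywise by the **median**. A coefficient is
   nonzero in the output only if it was selected in more than half the
   partitions, so sparsity survives aggregation (a mean would destroy it).

All least-squares fits are minimum-norm pseudo-inverse solutions, so
rank-deficient sub-designs (duplicated or collinear columns, possible with
compositional input) cannot fail. Internally the stepwise loop works on
precomputed train/test Gram matrices (`XᵀX`, `Xᵀy`, `yᵀy`), which makes a
candidate evaluation O(k³) in the active-set size instead of O(K·k²) in the
row count; `pinv(XᵀX)Xᵀy = pinv(X)y`, so the result is identical to the
direct SVD fit, which the tests assert.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `threshold` | 0.05 (CLI `infer`: 0.03) | relative held-out-MSE improvement required to accept a covariate; larger ⇒ sparser network |
| `n_bootstrap` | 100 | train/test repartitions aggregated by the median; odd counts avoid the even-median averaging of the two central values |
| `sigma_process` | 0.05 | log-scale std of environmental noise per step |
| `sigma_measurement` | 0.0 | log-scale std of observation noise |
| equilibria | log-normal, median 1, log-sd 0.5 | order-unity abundances with ~3× spread |
| `c_ii` | Uniform(−1.5, −0.5)/x̄_i | guarantees each isolated single-species map is stable (\|1 + c_ii x̄_i\| < 1) |
| off-diagonals | Uniform(−0.5, 0.5)/x̄_j, 2M of them | sparse regime the stepwise estimator targets; each kept only if the system stays stable |
| initial conditions | x̄ · exp(Uniform(−0.5, 0.5)) | distinct but bounded starting points per replicate |

Stability means spectral radius of the discrete-map Jacobian strictly
below 1; the marginal case (radius exactly 1, e.g. an all-zero coefficient
matrix) counts as unstable. The generator places off-diagonal couplings one
at a time by rejection and raises after `100 × n_offdiag` failed draws
rather than silently returning fewer edges.

## Numerical choices

- Test MSE is evaluated through the Gram quadratic form and clamped at 0
  against round-off.
- A held-out MSE below `1e−12 × mean(y²)` on the test split is treated as an
  exact fit and stops the stepwise loop: relative improvements at round-off
  scale are meaningless and would otherwise admit spurious covariates on
  noiseless data.
- Candidate ties are broken by lowest species index; combined with seeded
  partitioning this makes every fit bit-reproducible.
- Species with fewer than two usable transitions get an all-zero row and a
  logged warning, not an exception; fewer than `5M` usable rows logs a
  sample-size warning.
- "Unbagged" fits (the benchmark contrast) run a single stepwise pass with
  train = test = all usable rows — selection on in-sample error with no
  partition, the literal no-bagging limit. In-sample MSE decreases
  monotonically as covariates are added, so the acceptance threshold is the
  only brake on model growth.
- Edge-list and abundance TSVs are written with shortest round-trip float
  repr and read with pandas' `round_trip` parser, so I/O is bit-exact.

## What the synthetic benchmarks do and do not show

The simulator generates exactly the model the estimator assumes, plus the
two noise sources above. Passing benchmarks therefore demonstrates the
statistical machinery (identifiability from compositional data, robustness
of topology recovery to errors-in-variables, the variance reduction from
median bagging) — not robustness to model misspecification. Real sequencing
data additionally feature sampling gaps, day-to-day environmental
covariates, non-stationary equilibria, and count noise at low abundance,
none of which are emulated. The benchmark problem sizes (10 species,
10 × 500 timepoints, 10–20 replicate matrices, 50 bootstraps) were chosen
as the package's standard desk-scale configuration; all are arguments.

Under these default conditions the per-edge signal in the regression —
`c_ij · sd(u_j)`, roughly 0.015 for typical generated couplings at
σ_p = 0.05 — is a few percent of the response variance once 10%
measurement noise is added. Sensitivity at high measurement noise is
accordingly modest (edges are *missed*, not invented: specificity stays
near 1), and the bagged-vs-unbagged specificity contrast is muted because
neither variant accepts many covariates in that regime. With stronger
environmental forcing (larger σ_p) or stronger couplings the sensitivity
under noise rises steeply; the defaults were kept at the declared values
rather than tuned per benchmark.

## Limitations

- Coefficients from relative data carry an unidentified global scale; only
  ratios, signs and topology are directly interpretable.
- Errors-in-variables bias on coefficient *values* is not corrected (no
  instrumental variables); topology is the robust output under noise.
- Interactions are assumed constant in time and across environments.
- No L1/lasso-style regularization: sparsity comes from stepwise selection
  only, by design.
- The TSV reader treats adjacent columns as consecutive samples; gap
  handling in irregularly sampled data is the caller's responsibility.
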
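# Methods

## Model

For clusters `i = 1, …, n` with `n_i` observations each (`N = Σ n_i`):

```
y_ij = β0 + x_ij' β + z_ij' γ_i + ε_ij
γ_i ~ N_q(0, Q)     independent across clusters
ε_ij ~ N(0, σ²)     independent of γ
```

`x_ij ∈ R^p` holds the candidate fixed-effect covariates and
`z_ij ∈ R^q` the random-effect design (a leading 1 for a random
intercept, plus any covariates declared as random slopes). Stacked over
clusters this is `y = β0·1 + Xβ + Zγ + ε` with block-diagonal `Z`.

Estimation maximizes the penalized log-likelihood

```
ℓ_pen(β0, β, γ, σ², Q) = log φ(y | β0·1 + Xβ + Zγ, σ²I) − ½ Σ_i γ_i' Q⁻¹ γ_i ,
```

i.e. the conditional Gaussian log-likelihood with a ridge penalty on the
random effects at their generating covariance. Model comparison uses the
marginal Gaussian log-likelihood with per-cluster covariance
`V_i = Z_i Q Z_i' + σ² I` (see "Information criteria" below).

## Why a correction step

A covariate that is constant within every cluster lives in the span of
the random-intercept design: any fixed effect `β_r x_r` with
cluster-constant `x_r` can be reproduced exactly by shifting the `γ_i`.
In a greedy, slowly-updating procedure such as boosting, the random
effects (which are updated every iteration) win this competition and the
covariate is never selected. The algorithm therefore constrains the
random-effect updates to be orthogonal to the directions that
fixed effects should explain.

For each random-effect coordinate `s` define a correction space over the
`n` clusters:

- random intercept: the constant vector together with all
  cluster-constant covariates (one representative value per cluster),
- random slope on covariate `x_s`: the constant vector (so that the
  average slope is carried by the fixed effect `β_s`).

Let `C_s` be the orthogonal projector (hat matrix) onto the `s`-th
correction space. Arranging the random effects effect-wise via the
permutation `P` (all first coordinates, then all second coordinates, …),
the correction operator is

```
C = P⁻¹ (I_nq − diag(C_1, …, C_q)) P ,
```

applied to every random-effect update. After each corrected step,
`X_cs' γ̃_s = 0` holds exactly for every correction space `X_cs`: the
random effects carry no component that a fixed effect could explain.

## The algorithm

Initialize `β0 = ȳ`, `β = 0`, `γ = 0`, `σ² = Var(y)`, `Q = 0.1 I_q`.
For `m = 1, …, m_stop`:

1. **Component-wise fixed-effect step.** For each candidate `r`, with
   `X̃_r = [1, x_r]` and current residual `u = y − η̂`, the penalized-score
   Fisher update of `(β0, β_r)` is `(X̃_r'X̃_r)⁻¹ X̃_r'u` — `σ²` cancels,
   so it equals the least-squares fit of the residual on `(1, x_r)`.
   Evaluate the information criterion of each hypothetical damped update
   and apply only the best one: `β0 += ν·u0`, `β_r* += ν·u_r*`. All other
   coordinates remain untouched, so at iteration `m` at most `m`
   coordinates of `β` are nonzero.
2. **Corrected random-effect step.** A damped Fisher step for all random
   effects, `γ += ν · C · F⁻¹ s`, where `F = blockdiag(F_i)` with
   `F_i = σ⁻² Z_i'Z_i + Q⁻¹` and `s_i = σ⁻² Z_i'(y_i − η̂_i) − Q⁻¹ γ_i`,
   then corrected by `C` as above.
3. **Variance components.** Approximate EM update
   `Q̂ = n⁻¹ Σ_i (F_i⁻¹ + γ_i γ_i')`, projected to the symmetric
   positive-semidefinite cone; `σ̂² = Var(y − η̂)` (unbiased sample
   variance of the residuals).

The path is always run to `m_stop`; the reported model is the iteration
`m*` with the smallest information criterion along the path. If the
criterion is still decreasing at `m_stop`, a warning suggests raising it.

## Information criteria

`IC = −2 ℓ + pen(df)` with `pen = 2·df` (AIC) or `log(n)·df` (BIC, the
default, with `n` the number of clusters). Degrees of freedom
`df = #variance parameters + #{β_r ≠ 0}`, where
`#variance parameters = 1 + q(q+1)/2` (σ² plus the unique entries of Q);
nonzero-ness is exact, since boosting only ever touches selected
coordinates.

By default `ℓ` is the **marginal** log-likelihood, which accounts for the
random-effect structure when comparing candidates and stopping points and
is well defined without reference to the penalty. Setting
`BoostConfig(ic_likelihood="conditional")` uses the conditional
log-likelihood instead. The candidate comparison in step 1 scores the
fixed-effect update alone (steps 2–3 are not hypothetically replayed per
candidate).

## Default parameters

| parameter | default | rationale |
| --- | --- | --- |
| `nu` (step length) | 0.1 | standard weak-learner damping; small enough that selection order, not step size, drives the path |
| `m_stop` | 1500 | large enough that the IC minimum is interior for the problem sizes studied here |
| `criterion` | BIC | sparser selection than AIC; penalty `log(n)` uses the number of clusters, the effective sample size for cluster-level structure |
| initial `Q` | `0.1 I` | weakly informative; the EM step adapts it within a few iterations |
| `start_mode` | `"simple"` (`β0 = ȳ`) | `"premodel"` instead initializes `σ²`, `Q` from an intercept-only mixed model fitted by EM |
| `center_intercept` | `True` | include the constant vector in the intercept correction space, keeping the mean level in `β0` |

## Numerical choices

- Per-cluster operations are batched by grouping clusters of equal size,
  and the marginal likelihood reuses one Cholesky factorization of the
  `V_i` blocks per iteration; candidate scoring expands the marginal
  quadratic form so all `p` candidates are scored with a single
  multi-right-hand-side solve.
- `Q⁻¹` falls back to a ridge-regularized inverse
  (`Q + ε·tr(Q)/q·I`, `ε = 1e−10`) when `Q` is ill-conditioned
  (condition number above `1e12`).
- The EM update of `Q` is symmetrized and its eigenvalues clipped at
  zero; a warning is emitted if a meaningfully negative eigenvalue
  (below `−1e−8`) had to be clipped.
- Correction-space bases are orthonormalized by SVD; rank-deficient
  spaces (e.g. collinear cluster-constant covariates) are handled by
  dropping null directions, with a warning.
- A candidate whose column is collinear with the intercept (a constant
  covariate) is skipped with a warning rather than producing an unstable
  update.
- Exact ties in the candidate criterion are broken toward the lowest
  covariate index, for determinism; ties are measure-zero on continuous
  data.
- All randomness flows through explicit seeds; refitting with the same
  data and configuration replays the path bit-for-bit.

## Simulation designs

`SimScenario` generates two designs, both with standard-normal
covariates, `β0 = 1`, `β = (2, 4, 3, 5, 0, …, 0)`, covariates 1–2
cluster-constant and the rest cluster-varying, and `σ = 0.4`; defaults
`n = 50` clusters of size `n_i = 5`:

- `design="intercepts"`: a random intercept with SD `τ`.
- `design="slopes"`: correlated random intercept plus random slopes on
  `x2` (cluster-constant) and `x4` (cluster-varying), `q = 3`, with
  `Q` having `τ²` on the diagonal and correlation 0.6 off-diagonal.

`run_study` fits fresh draws and summarizes: squared-error metrics
(`mse_β` over the full coefficient vector including the intercept;
`mse_σ`, `mse_τ` on the standard-deviation scale; `mse_Q` as squared
Frobenius norm) by median and IQR, and selection rates (TP, FP, FDR,
computed from exactly-nonzero coefficients against the four informative
covariates) by mean. Per-replication seeds derive from the scenario seed
by a counter-based scheme, so any subset of replications is
independently reproducible.

`scripts/acceptance.py` runs 20 replications per cell. This is this
package's own default for a fast, single-CPU reproduction; medians and
selection rates are stable at that size for these designs, but
tail-sensitive quantities (IQRs, rare false positives) would need more
replications.

## Scope and limitations

- Gaussian responses only; no generalized (non-identity link) models.
- The random-effect structure is shared by all clusters; crossed random
  effects are not supported.
- The correction uses exact within-cluster constancy to classify
  covariates; numeric covariates intended as cluster-constant must be
  stored exactly constant.
- The EM step for `Q` is approximate (it conditions on the current
  penalized-mode `γ`), and `σ²` is estimated from marginal residuals;
  for very small clusters both can be biased downward relative to REML.
- Inference (standard errors, tests) is out of scope; the output is a
  selected model with point estimates along a regularization path.
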
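# Methods

## Model and likelihood

The CAR regression model on `n` sites is `Y = Xβ + ε`,
`ε ~ N(0, σ²Vₙ)` with `Vₙ = (I − ρW*)⁻¹D`, where `W` is the binary
symmetric contiguity matrix, `W*` its row-standardized form, and
`D = diag(1/wᵢ₊)`.  We keep σ² out of `Vₙ` so that the profile equations
are internally consistent: σ² cancels in the GLS step and appears only
through the profiled variance.  The profiled variance carries the `1/n`
MLE divisor, matching the `(n/2)·log(RSS_V/n)` term of the profile
log-likelihood.

Two identities make the fit cheap and numerically benign:

- `Vₙ⁻¹ = D⁻¹(I − ρW*) = diag(wᵢ₊) − ρW` — symmetric and *linear in ρ*.
  After one pass of cross-products of `(X, Y)` against `diag(wᵢ₊)` and
  `W`, every profile evaluation costs `O(p²)`.
- `log|Vₙ| = −Σ log wᵢ₊ − Σ log(1 − ρλᵢ)`, where `λᵢ` are the (real)
  eigenvalues of `W*`, obtained once per weights object from the similar
  symmetric matrix `D^{1/2}WD^{1/2}`.

The admissible ρ interval is `(1/λ_min, 1/λ_max)` (open); `λ_max = 1`
for row-standardized weights.  ρ̂ is located by a 41-point grid across
the interval followed by bounded scalar refinement in the bracketing
cell (absolute tolerance 1e-8); this guards against local maxima of the
profile curve.  A ρ̂ within 1e-6 of an endpoint raises a boundary flag
in the convergence record rather than failing.  All matrix inverses are
realized as Cholesky solves; covariance factors are symmetrized as
`(V + V′)/2` before factorization.

## Estimators

With `β = (β₁, β₂)` (`p₁` main, `p₂` nuisance) and
`A₂ = V⁻¹ − V⁻¹X₂(X₂′V⁻¹X₂)⁻¹X₂′V⁻¹` the weighted annihilator, the
information blocks are computed as Schur complements of `X′V̂⁻¹X`
(`X₁′A₂X₁` and `X₂′A₁X₂` are never formed through the n×n projector in
the fitting path).  The estimator set:

- LU  = `F(X₁′A₂X₁, d) β̂₁` — full-model Liu;
- LUS = `F(X₁′V̂⁻¹X₁, d_s) β̂₁ˢᴹ` — sub-model Liu, using the sub-model's
  own profile fit (its own ρ̂; a `share_rho` switch reuses the full-model
  ρ̂ instead);
- PTL = LU if `Lₙ > χ²_{p₂,α}`, else LUS;
- SL  = LUS + (LU − LUS)(1 − (p₂−2)/Lₙ), `p₂ ≥ 2`;
- PSL = LUS + (LU − LUS)(1 − (p₂−2)/Lₙ)⁺.

`Lₙ = β̂₂′(X₂′A₁X₂)β̂₂ / S²` with
`S² = (Y − Xβ̂ᴸᵁ)′V̂⁻¹(Y − Xβ̂ᴸᵁ)/(n − p)`, where `β̂ᴸᵁ` is the
full-vector Liu fit (an `s2_residuals="mle"` switch uses plain MLE
residuals for sensitivity analysis).  The critical value is the central
chi-square quantile with `p₂` degrees of freedom, with no small-sample
correction.

Degenerate partitions: `p₂ = 0` collapses all five estimators to the
(single-block) Liu estimate; `p₂ = 1` disables SL/PSL (the Stein weight
needs `p₂ ≥ 2`) but keeps the pretest; `p₂ = 2` makes the shrink factor
one (SL = PSL = LU) and is flagged.  `Lₙ` below 1e-12 is treated as an
exact zero and SL/PSL return LUS, the positive-part limit.

The data-driven biasing parameter is `d_opt = 1 − 2pσ²/(pσ² + β′β)`,
clipped into `[1e-6, 1 − 1e-6]`; in `d_mode="optimal"` it is evaluated on
the full fit for `d` and on the sub fit (with `p₁`, σ̂²_sub, β̂ˢᴹ) for
`d_s`.  The choice of the same rule for `d_s` is a package convention;
no other prescription exists for the sub-model parameter.

### Small-sample calibration of the pretest

With ρ known, `Lₙ` is exactly distributed as `p₂·F(p₂, n−p)` under `H₀`
(Gaussian errors), so referring it to the central χ²_{p₂} quantile
over-rejects in small samples: at `n = 49`, `p = 15`, `α = 0.05` the
exact rate is `P(χ²₁₀/(χ²₃₄/34) > 18.31) ≈ 0.092`, and plugging in the
profile-likelihood ρ̂ raises the measured rate to ≈ 0.14–0.17.  The
package implements the chi-square reference as specified (it is the
correct asymptotic calibration and what the SRE study uses); users
working at small `n` should expect the pretest to behave like a more
liberal test, and the acceptance script reports the honestly measured
rate.

## Asymptotic bias and risk

Under local alternatives `β₂ = ξ/√n` the scaled errors
`θ₁ = √n(LU − β₁)`, `θ₂ = √n(LUS − β₁)`, `θ₃ = θ₁ − θ₂` are jointly
Gaussian and `θ₂ ⊥ θ₃` (the sub-model coefficient estimate is exactly
uncorrelated with the full-model nuisance estimate — a finite-sample
identity, `X₁′A₁ = 0`).  PTL/SL/PSL are functions of `(θ₂, θ₃, Lₙ)` with
`Lₙ → χ²_{p₂}(Δ)`, so their bias and risk follow from the classical
normal-chi-square mixing identities
`E[z·φ(L)] = μ·E[φ(χ²_{q+2}(Δ))]`,
`E[zz′φ(L)] = Σ·E[φ(χ²_{q+2}(Δ))] + μμ′·E[φ(χ²_{q+4}(Δ))]`.

Two evaluation modes are exposed:

- **plugin** (default): the means and covariances of `(θ₁, θ₂)` are
  computed *exactly at finite n* from `X`, `V(ρ)`, σ² and `(d, d_s)` —
  e.g. `Var θ₁ = nσ²F₁M_f⁻¹F₁′` with `M_f = X₁′A₂X₁` and
  `F₁ = (M_f+I)⁻¹(M_f+dI)` — and combined with the mixing identities.
  The noncentrality is the exact parameter of the quadratic form,
  `Δ = ξ′C₂₂.₁ξ/σ²` with `C = X′V⁻¹X/n`.  At `d = 1` this reduces to
  the classical MLE-based pretest/shrinkage risk expressions.  The
  chi-square mixing step treats the (O(1/√n)) deterministic Liu-bias
  component of θ₃ with the same `q+2` weight as the ξ-shift; this is the
  only approximation beyond the Gaussian/chi-square limits themselves,
  and the Monte Carlo comparisons in the test-suite bound its effect at
  the percent level for n ≥ 100.
- **printed**: the classical limit display evaluated verbatim from
  `C`, `G_d = (C+I)⁻¹(C+dI)`, `λ = −(1−d)(C+I)⁻¹β`, `B = G_d C⁻¹ G_d′`
  and blocks.  Several displayed pieces are typographically damaged
  (documented in the code): the marginal covariances written as
  `σ²B₁₁.₂⁻¹` and `σ²B₁₁⁻¹` do not reduce to the MLE covariances at
  `d = 1`; the shift vector π is displayed with incompatible dimensions
  and is read as `G_d11 C₁₂ ξ` from the accompanying derivation; γ
  carries a sign inconsistency resolved in favor of the derivation
  (`γ = λ₁₁.₂ − π`); and the positive-part risk display needs trace
  operators restored to be well-typed.  The printed mode exists to
  quantify these deviations against the plugin/Monte-Carlo results, not
  to be patched silently.

The quadratic bias is `AQ = AB′B₁₁.₂AB` in both modes (a common scalar
weight); the printed expansions of AQ for LU/LUS/PTL/SL are exact
algebraic expansions of this definition and are verified as such.

Noncentral chi-square machinery: the CDF is the Poisson-mixture series
truncated when the remaining mixture mass falls below 1e-12 (validated
against `scipy.stats.ncx2`); inverse moments `E[(χ²)⁻¹]`, `E[(χ²)⁻²]`
use the mixture of central closed forms; truncated inverse moments use
adaptive quadrature of the scipy density (relative tolerance 1e-10),
with the complementarity `E[·1{>c}] + E[·1{≤c}] = E[·]` checked to 1e-9.

## Synthetic-data generator

The generator reproduces the canonical study conditions and is
first-class, tested code:

- design: rows i.i.d. `N(0, Σ)` with AR(1) structure
  `Σ_{jk} = ρₓ^{|j−k|}` (ρₓ ∈ {0.3, 0.6, 0.9} in the study menus);
  a fresh design is drawn per replicate — the generator averages over
  designs rather than conditioning on one;
- coefficients: `β = (1_{p₁}, Δ, 0_{p₂−1})` so `Δ = ‖β − β₀‖` indexes
  the violation of `H₀`; Δ ranges over [0, 2] (default grid
  {0, .1, .2, .4, .6, .8, 1, 1.5, 2});
- errors: `ε ~ N(0, σ²(I − ρW*)⁻¹D)` via Cholesky of the symmetrized
  covariance, σ² = 1, ρ ∈ {−0.9, −0.5, 0, 0.5, 0.9}, queen contiguity on
  N×N lattices (N = 7, 10), no wraparound — corner/edge/interior sites
  keep their natural 3/5/8 neighbor counts;
- default replicate count 2000, α = 0.05; per-replicate RNG streams are
  derived from the master seed via `SeedSequence(seed, spawn_key=(Δ-index,
  rep))`, so results are independent of execution order or worker count.

What the generator does **not** emulate: irregular polygon contiguity,
covariate distributions with heavy tails or measurement error,
non-Gaussian responses, and model misspecification of the neighborhood
(the fitted `W` is always the generating `W`).  Passing tests therefore
certify internal consistency of the method under its own assumptions,
not robustness on real areal data.

The SRE report is `MSE(baseline)/MSE(estimator)` per Δ, with the MSE of
an estimator the replicate mean of `Σᵢ(β₁ᵢ* − β₁ᵢ)²` and the baseline
the full-model MLE β̂₁ (the natural reference; a `baseline="LU"` switch
reproduces the alternative normalization under which SRE(LU) ≡ 1).
Ratio uncertainties use the paired delta method on the per-replicate
losses.  Replicates failing to fit are dropped from *all* estimators
(paired comparison preserved) and counted.

## Residual bootstrap

Steps, per the standard recolored-residual scheme: fit the full model;
estimate `d` (and `d_s`) once from the original fits, using the
unweighted variance `(Y−Xβ̂)′(Y−Xβ̂)/(n−p)` inside `d_opt` (the
convention attached to this procedure; everywhere else the profiled,
`V⁻¹`-weighted variance is used); Cholesky `V̂ₙ = AA′`; whiten, center,
resample with replacement, recolor; refit full and sub models per
sample with `(d, d_s)` held fixed; predict with the one-pass plug-in
conditional mean `ŷ*ᵢ = x₁ᵢ′β₁* + ρ̂*Σⱼ W*ᵢⱼ(y*ⱼ − x₁ⱼ′β₁*)` (iterating
the correction is available but contracts to the bare trend, so one
pass is the default); root-MSPE per sample compares predictions to the
*original* `y` (a `compare_to="bootstrap"` switch targets `y*` instead,
since either reading of the error definition is defensible); REMSPE is
`mean-rMSPE(LU)/mean-rMSPE(estimator)`.  More than 5% failed refits is a
hard error; fewer are dropped and reported.

## Problem sizes used in the checked experiments

The test-suite exercises the pipeline at the study's own scales: the
null-calibration and SRE experiments on the 7×7 queen lattice (2000 and
500 replicates respectively), the risk-formula/Monte-Carlo comparison on
a 30×30 lattice (n = 900, 2000 replicates per Δ ∈ {0, 1, 4}, d = 0.5),
and the bootstrap ordering check with K = 600 resamples at n = 49.
Estimator-recovery unit tests use 40–80 replicates on 7×7 and 10×10
lattices, sized to keep Monte Carlo error well inside the asserted
tolerances.

## Known limitations

- The chi-square pretest calibration is asymptotic; see the small-sample
  note above.  An exact-F option would change the printed procedure and
  is deliberately not substituted.
- ρ̂ from the profile likelihood is noticeably downward-biased and
  variable at n ≈ 49; the estimator comparisons are unaffected (all
  estimators share the fitted V̂ₙ), but V̂ₙ itself should not be
  over-interpreted on small lattices.
- The plugin risk evaluation conditions on the design `X` and the true
  ρ; it describes risk for the design at hand, not an average over
  designs.
- Only binary contiguity weights are supported (no distance-band or
  k-nearest-neighbor schemes), and sub-model selection is an input, not
  a feature.
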
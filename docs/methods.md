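# Methods

## Setting

A finite population of `N` units carries a study variable `y` and an
auxiliary variable `x` whose population mean `μx` is known. A sample of
size `n` is drawn by simple random sampling without replacement (SRSWOR)
and the goal is to estimate `μy`. All first-order theory is written in the
relative sampling errors

```
e0 = (ȳ − μy)/μy,   e1 = (x̄ − μx)/μx,
```

whose design moments under SRSWOR are `E[e0] = E[e1] = 0`,
`E[e0²] = λC_y²`, `E[e1²] = λC_x²`, `E[e0e1] = λC_yx`, with
`λ = (1 − n/N)/n` the finite-population-correction factor,
`C = S/μ` the coefficients of variation (variances with the `N−1`
divisor) and `C_yx = S_yx/(μy μx) = ρ C_y C_x`.

## Estimator family

`T0` is the sample mean; `T1`/`T2` the classical ratio and product
estimators; `T3` the exponential-ratio form
`ȳ exp((μx − x̄)/(μx + x̄))`; `T4` the regression estimator
`ȳ + φ̂₁(μx − x̄)` with the sample slope `φ̂₁ = s_yx/s_x²` (a theoretical
mode substitutes `β₁ = S_yx/S_x²`); `T5`–`T8` log-transformed-auxiliary
estimators. The two log-ratio-type estimators with free constants are

```
TP1 = (k1 ȳ + k2) · μx ln(x̄/μx)/(x̄ − μx)
TP2 = (k3 ȳ + k4) · ln(x̄/μx) · exp((x̄ − μx)/(x̄ + μx))
```

The TP1 adjustment factor `ln(1+e1)/e1` is extended continuously to 1 at
`x̄ = μx` (evaluated as `log1p(u)/u`, which is stable arbitrarily close to
the removable singularity). TP2 vanishes identically at `x̄ = μx`; a
Monte-Carlo replicate landing there returns 0 with a degeneracy flag
rather than raising, and flags are counted in the results table.

Two published forms required a decision:

* **T5** as published contains the unknown `μy`; the default "standard"
  variant is `ȳ ln(μx)/ln(x̄)`, the unique form whose first-order error
  reproduces the associated published MSE with `k = 1/ln(μx)`. The
  published form remains available as `variant="paper-literal"` for
  diagnostics (it needs a `PopulationSummary`).
* **T8** is implemented exactly as published: a function of `x` alone,
  `K1·log[(μx+Md)/(x̄+Md)] + K2·log[(x̄+Md)/(μx+Md)]` with `Md` the
  population median of `x`. It carries no usable closed-form MSE, so its
  constants come only from user input or empirical tuning, and the
  printed-theory path reports it as unsupported.

## Dual-path first-order theory

The theory module deliberately ships two parallel derivations.

**Series path (default).** Each estimator is rewritten with
`ȳ = μy(1+e0)`, `x̄ = μx(1+e1)` and expanded to total degree 2 in
`(e0, e1)` inside a truncated polynomial ring. Expansions are built only
by composing primitive scalar series — `log(1+u)`, `1/(1+u)`, `exp(u)`,
`log(1+u)/u` — with ring operations; there are no estimator-specific hand
rules, so every coefficient is mechanically derived (and cross-checked
against a sympy bivariate Taylor expansion in the test suite). Bias is
`E[T − μy]`; MSE is the expectation of the degree-2 truncation of
`(T − μy)²`, which retains the squared-linear and constant×quadratic
cross terms consistently.

**Printed path.** Literal transcriptions of the published closed forms:
the per-estimator MSEs, the TP1/TP2 MSE surfaces in the auxiliary
constants `A1..E1` / `A2..E2`, the published optimal constants and the
published minimum-MSE expressions. The published algebra is internally
inconsistent in documented ways, and the transcription preserves the
inconsistencies rather than silently repairing them:

* the published optimal `k1` carries `−D1E1` where Cramer's rule applied
  to the published normal equations gives `+D1E1` (the `k2` component
  agrees);
* the published minimum-MSE expressions equal neither the published MSE
  surfaces at the published optima nor at the literal Cramer solutions;
* the published regression-estimator MSE omits the `μy²` scale that its
  log-difference analogue includes;
* the published TP2 expansion has no constant term, so its first-order
  bias is ≈ `−μy`, contradicting the published bias expression;
* one published ratio-MSE uses `D = μx/μy` where the dimensionally
  consistent classical constant is `R = μy/μx`.

Each discrepancy is pinned by a regression test so any silent "fix"
breaks the suite. User-facing efficiency tables default to the series
path; `variant="paper-literal"` selects the published `D` convention
where the two differ (applied uniformly to the three formulas carrying
`D`), and the undefined constant `D2` in the second normal-equation
system is set to `C2`, the only assignment consistent with the linear
`k4` term of the published surface.

## Optimal constants

The series-mode MSE is an exact quadratic in the free constants; its
Hessian and gradient are recovered from six exact evaluations. When the
Hessian is positive definite the closed-form minimizer is returned (one
Newton refinement keeps the gradient at numerical zero), status `ok`.
For TP2 the first-order surface is *degenerate*: along
`k4 = −k3μy` the objective is unbounded below, so the solver reports
status `degenerate` and falls back to a bounded L-BFGS-B search over
`[−100, 100]²`. This is a structural property of the estimator's
first-order linearization (its leading error term is proportional to
`e1` only), not a numerical artifact; consequently TP2's "theoretically
tuned" constants sit on the search box and the resulting estimator is
poor, which the simulation results report honestly.

Efficiency comparisons use `PRE = 100·Var(T0)/MSE(T)`. Dominance of the
tuned TP1 over a competitor is condition-dependent: the adjustment factor
contributes a fixed `−e1/2` error term per unit of scale, so the
first-order minimum is approximately `λμy²C_x²(1−ρ²)/4`, which beats the
sample mean's `λμy²C_y²` iff `C_x√(1−ρ²)/2 < C_y`. With matched
coefficients of variation the condition holds for every ρ, and that is
the regime the property tests assert.

## Synthetic populations

`generate_population` emulates the study conditions: `N = 1000` units,
mean vector `(40, 50)`, and a target study–auxiliary Pearson correlation
in `{0.92, 0.71, 0.38}`. Three marginal families span light-tailed,
positively skewed and heavy-tailed regimes:

| family    | marginals                                   | default dispersion |
|-----------|---------------------------------------------|--------------------|
| normal    | `N(40, σ_y²)`, `N(50, σ_x²)`                | `σ_y = σ_x = 1` (unit variances) |
| gamma     | shape `a`, scale `mean/a`                   | `a = 4` (CV = 0.5) |
| lognormal | log-scale `σ`, mean-matched                 | `σ = 0.5`          |

Dependence is a Gaussian copula: one latent standard-normal pair is drawn
per population, and the latent correlation is calibrated by secant
iteration *on the realized Pearson correlation of the generated N-point
population*, so the realized ρ matches the target to ~1e−4 by
construction (a `CalibrationError` is raised if it cannot be brought
within 0.05). For the normal family the transform is affine, so the
result is still an exact bivariate normal draw. What this generator does
not emulate: measurement error, outlier contamination, nonresponse, or
nonlinear mean relationships beyond what the copula induces — so passing
tests certify the sampling theory under the stated families, not
robustness to those real-data features.

## Monte-Carlo evaluation

For each sample size, free constants are resolved once from the
finite-population characteristics (`theoretical` mode, the default:
TP1/TP2 by series-MSE minimization; T7/T8 by empirical least squares,
having no usable closed form) or per-scenario by empirical tuning. `R`
SRSWOR replicates are drawn (library default `R = 10,000`; tests and the
acceptance script use 2,000–5,000 with 3-standard-error tolerances);
empirical MSE is accumulated about the true `μy`, so the reference
"variance" of `T0` is its MSE about `μy`, exactly as the evaluation
framework defines it. Aggregate PRE is the ratio of mean squared errors;
per-replicate PREs `100·(T0−μy)²/(T−μy)²` are additionally summarized by
their mean, Monte-Carlo standard error `sd/√R`, a normal 95% interval and
a nonparametric 95% percentile interval (2.5%/97.5% quantiles, inclusive
linear-interpolation rule, recorded in output metadata). The
per-replicate PRE distribution is heavy-tailed — its denominator can be
arbitrarily close to zero — so those summaries can be enormous or tiny;
the aggregate PRE is the stable headline number.

Empirical tuning exploits that every tunable estimator is *linear* in its
constants: the empirical-MSE objective over a fixed pre-drawn replicate
set is an exact least-squares problem, solved by bounded least squares
within `[−100, 100]` per constant. Near-collinear designs (TP2, T8) pin
the solution to the box; the `on_boundary` flag reports this.

All randomness flows through explicit `numpy` generators spawned from a
single scenario seed; identical seeds give bit-identical result tables.

## Numerical choices

* Normal-equation systems with `|Δ| < 1e−12 × scale(A·B)` are treated as
  degenerate (census `λ = 0` collapses all constants to 1 and `Δ` to 0).
* The published TP1 surface subtracts order-1 constants
  (`A1 − 2C1 + 1 = λ(C_y² + C_x²/4)` at unit constants), so float
  agreement with the series path is asserted at the surface's natural
  `μy²` scale; the series path itself is cancellation-free and is held to
  1e−12 relative against closed forms.
* Estimator failures inside a Monte-Carlo run (e.g. a nonpositive `x̄`
  under an aggressive marginal) are tolerated up to a configurable
  fraction (default 1%) and then abort with diagnostics.

## Known limitations

First-order theory only; higher-order corrections, stratified and
two-phase designs, and uncertainty in `μx` are out of scope. The
theoretical tuning of TP1/TP2 uses population characteristics (including
`μy` through the intercept constant), mirroring the evaluation framework
it implements; in applications those constants must be estimated, and the
reported efficiencies are upper bounds on what plug-in tuning achieves.
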
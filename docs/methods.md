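# Methods

## Observation model

Track counts are NB2: `y ~ NegBin(μ, α)` with `Var = μ + μ²/α`, `α > 0` the
overdispersion (Poisson as `α → ∞`). The log mean is the transect-length
offset plus a linear predictor plus a latent field value. The NB2
log-likelihood is strictly concave in `η = log μ`, which the inner Newton
optimisation relies on.

Covariate scaling: each numeric covariate is centred and divided by twice
its standard deviation (computed on the analysis rows, after the
census-validity and complete-case filters), so a one-unit change is
comparable to switching the binary triangle-type indicator
(wildlife/forest = 1, field/farmland = 0, left unscaled). The sign
convention makes a negative type weight mean "higher density in farmland
mosaic transects". Coordinate covariates (x, y, x·y), when included, are
scaled like any other numeric column.

Lag structure: the census of winter year *y* is explained by the cone crop
of autumn *y − 1* (interpolated), nest occupancy of summer *y − 1* and
earlier (inside the kernel), marten density of the same winter, and
previous-day weather. A lag-1 marten column can be assembled
(`include_marten_lag`) but is excluded from the default covariate set.

## Latent field

The field lives on the full site × year grid with separable covariance
`σ² · M(d; range) ⊗ R_t`: Matérn with smoothness ν = 1 in space
(`M(d) = (κd)K₁(κd)`, `κ = √8/range`, so correlation ≈ 0.14 at `d = range`)
and a unit-variance stationary AR1 in time (`R_t = ρ^|Δt|`). ν is fixed at 1
— the conventional default for this model family, making "range"
well-defined and testable. The RW1 alternative replaces the AR1 precision
with the first-difference (path-Laplacian) precision plus a 1e-5 diagonal
ridge; the ridge acts as a diffuse prior on the level, standing in for an
explicit sum-to-zero constraint that would break the banded solver.
Space–time interaction beyond separability is out of scope.

## Estimation

Empirical-Bayes Laplace approximation:

1. **Inner problem.** At fixed hyperparameters `θ = (range, σ, ρ, α)` the
   joint mode of (weights β, field u) is found by Newton iteration with
   step halving; β carries a N(0, 10²) prior per coordinate (weak on the
   2-SD-scaled design). In time-major ordering the prior precision
   `(1/σ²) Q_t ⊗ M⁻¹` is banded with bandwidth `2S − 1` (S sites) because
   the AR1/RW1 precision is tridiagonal; the likelihood curvature is
   diagonal, so each Newton step costs one banded Cholesky, `O(T·S³)`
   rather than `O((ST)³)`. The small dense β block is handled by a Schur
   complement. Convergence: gradient sup-norm below 1e-6 (relative), at
   most 60 steps, else a convergence error with the iteration trace.
2. **Outer problem.** The Laplace log marginal likelihood (joint log
   density at the mode plus prior and Hessian determinant terms, the
   latter from the banded factor) is maximised over transformed
   hyperparameters (log range, log σ, Fisher-z ρ, log α) by Nelder–Mead
   with an explicit starting simplex and warm-started inner modes.
   Starting values come from data moments (median pairwise distance for
   the range; the spread of log empirical rates for σ).
3. **Hyperparameter penalty.** The marginal likelihood carries a fixed
   weakly-informative penalised-complexity prior: on the range,
   `π(r) ∝ r⁻² exp(−λ/r)` with λ set by `P(range < 10 km) = 0.05` (10 km =
   the kernel cutoff / transect scale); on σ, an exponential tail with
   `P(σ > 3) = 0.05`. Without it the profile likelihood for the range is
   flat over a wide right tail whenever the true range approaches the
   domain diameter — a standard weak-identifiability pathology of Matérn
   range estimation under fixed-domain conditions — and single-replicate
   estimates occasionally diverge. The penalty parameters are fixed by
   unit/geometry rules, not fitted. With it the estimator is the MAP of
   the hyperparameter posterior, matching what the latent-Gaussian
   software this emulates does by default.
4. **Summaries.** The latent posterior is Gaussian at the joint mode:
   coefficient means/SDs come from the Schur-complement covariance,
   quantiles and the (coincident) mode from 4,000 seeded draws.
   Hyperparameter SDs come from a central-difference Hessian of the
   penalised marginal likelihood (step 0.05 on the transformed scale) with
   delta-method transforms (`sd(range) = range · sd(log range)`, etc.).
   Posterior draws of the per-observation linear predictor — used for
   WAIC, fitted counts ± SD, and predictive surfaces — are exact draws
   from the Gaussian approximation via the banded Cholesky factor
   (default 400).

WAIC is `−2(lppd − p_waic)` with `lppd = Σᵢ log meanₘ p(yᵢ|ηᵢ⁽ᵐ⁾, α̂)` and
`p_waic = Σᵢ varₘ log p(yᵢ|ηᵢ⁽ᵐ⁾, α̂)`; α̂ is held at its point estimate
(empirical Bayes), so hyperparameter uncertainty is not propagated into
WAIC. Ranking ties break toward fewer covariates.

Baselines: `spatial_process="none"` drops the field entirely and reproduces
an independent NB regression (verified against a direct ML fit to 1e-4);
`covariates=()` with the field is the smoothing-only model.

Kriged density surfaces use the spatial conditional mean
`k₀' M⁻¹ u_t` of the fitted field for the requested year, combined with the
intercept only (covariates are centred, so this is the density at average
covariate values, in tracks/km); grid nodes farther than 50 km from every
transect are flagged as extrapolated.

## Predation kernel

Height `1` within the plateau radius, `exp(−(d − flat_top)²/(2·sd²))`
beyond it, `0` past the 10-km cutoff. Temporal discount `0.9^(lag−1)` for
lags 1…15 (full weight for the summer preceding the census — the decay
exponent convention is forced by that maximum), zero otherwise; same-year
and future nests are ignored by default (`symmetric_window` enables the
bidirectional reading). Overlapping nests combine by `max` by default —
keeping the index in [0, 1] and reading as "pressure from the most
influential nest" — with the complement-product (independent-risks) rule as
an option. Shape selection fits, for each of the 20 grid candidates, an
independent NB regression of counts on the candidate kernel covariate with
the length offset, and takes the lowest AIC. The independent regression
(not the full spatiotemporal model) is used deliberately: the covariate is
a deterministic function of shape, a 20-way spatiotemporal grid search
would be disproportionate, and the selection predates the field fit.

## Cone surface

Thin-plate-spline regression of cones-per-tree on planar coordinates, per
autumn; missing observations excluded; negative predictions clamped to 0.
The smoothing parameter is chosen by GCV over a log-spaced grid, with the
influence-matrix trace computed exactly by fitting the spline to the
identity matrix; `smoothing="exact"` gives the interpolating spline (used
by the exactness tests: constants and affine surfaces are reproduced to
machine precision). Missing southern observations in the listed failure
years are imputed as zeros *before* fitting — in those years a missing
southern census effectively means "no cones to count".

## Synthetic data

The generator emulates: (i) transect geometry — 12-km wildlife triangles
uniform over a rectangular planar region (km coordinates; all model
distances are metric, so no geodesy), 6-km field triangles 85% south of the
region's southern cut and skewed westward; (ii) Bernoulli censusing of each
transect each winter (default 0.29, ≈ 550 of 1,900); (iii) the exact count
model above, with defaults at the published posterior means (Table-2-style
weights, 655-km range, ρ = 0.99) so parameter-recovery experiments have
known truth; (iv) masting cones — lognormal shared year effect (SD 1.0 on
the log scale) × smooth static spatial surface (Matérn, 300 km, SD 0.5) ×
small site noise, zeroed at southern sites in failure years with half of
those zeros recorded as missing; (v) nest territories — Poisson point
pattern at 3/100 km² with year-to-year occupancy persistence 0.9
(abandonment permanent); (vi) previous-day weather on a 10×10-km lattice
(northward temperature decline, shared year effects, day-level cell noise;
lognormal precipitation); (vii) marten counts as an independent log-Gaussian
Poisson intensity sharing a habitat-quality surface with nothing but the
marten covariate itself — so a positive squirrel–marten association can
arise from shared habitat without any direct interaction. The AR1 is
initialised at stationarity, making marginal-variance tests exact.

What it does **not** emulate: observer/species-identification error, snow
conditions beyond the validity flag, spatial clustering of real transects
(uniform placement is a modelling choice, not an observed fact), search
effort variation in nest discovery, and real weather dependence between
temperature and precipitation. Passing tests therefore demonstrate
correctness of the machinery under the model's own assumptions, not
robustness to the violations real monitoring data contain.

Default generator scale is the full scheme (1,900 transects, 29 winters);
tests and the acceptance script run reduced configurations (50–300 sites,
5–12 years) chosen to keep the whole suite within minutes on one CPU while
leaving each check statistically informative; the problem size of each
experiment is stated where it is run.

## Moran's I

`I = (n/W) Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σᵢ(xᵢ−x̄)²` with binary weights for
pairs in a half-open distance bin `(lo, hi]`, self-pairs excluded; bins of
20 km out to 750 km (last bin partial), computed per year over the sites
observed that year; a bin-year cell with fewer than 10 pairs is reported
missing (the divergence at long distances comes from exactly such cells);
the pooled SD per bin is the unweighted across-year SD of the per-year I
values. Densities (tracks/km), not raw counts, enter the correlograms.
Constant values raise an error (the statistic is undefined); the statistic
is invariant to affine transforms of the values and to site order.

## Known limitations

- Coefficient quantiles inherit the Gaussian approximation; for very small
  counts the true posterior is skewed and the reported mode (= mean) is a
  convention, accurate only in the informative-data regime (verified
  against MCMC at the 5% level on count-rich small instances).
- Range estimates shrink noticeably below truth when the design is small
  relative to the range (e.g. 150 sites on a 600 × 1,100 km region with a
  655-km range), reflecting the penalty dominating a nearly flat
  likelihood; they are accurate to ~±15% at 300 sites.
- Empirical-Bayes intervals ignore hyperparameter uncertainty; coverage at
  default settings is nevertheless within [0.85, 1.0] in calibration runs.
- The dense site-by-site Matérn matrix is exact but limits practical use to
  a few thousand sites; no sparse-mesh approximation is provided (by
  design — it avoids that approximation's artefacts).
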
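# Methods

This note documents the model, the calibration machinery, the
synthetic-data design, and the numerical and design choices behind
`socassim`. It is the authoritative description of what the package
computes; the README shows how to run it.

## The soil carbon column model

Soil organic carbon is represented by a multi-pool matrix model on a
vertical column. Each of the `n_layers` (default 10) soil layers
carries seven carbon pools — coarse woody debris (CWD), metabolic,
cellulose and lignin litter, and fast, slow and passive SOC — for 70
state variables in the default configuration. The balance is

dX/dt = B·u + A·ξ·K·X − V·X

with

* **X** (g C m⁻³): pool carbon densities;
* **u** (g C m⁻² day⁻¹): column carbon input derived from mean annual
  NPP; **B** (m⁻¹) partitions it among the four litter pools (default
  fractions 0.25/0.35/0.25/0.15 for CWD/metabolic/cellulose/lignin)
  and distributes it vertically as exp(−z/z_input) with
  z_input = 0.5 m, normalized so Σ B_i Δz_i = 1. The vertical input
  profile is the model's main free structural choice; it is a plain
  configuration constant (`ModelConstants.z_input`);
* **A** (unitless): within-layer transfer fractions, −1 on the
  diagonal and non-negative off-diagonals. Litter routing is fixed
  (CWD fragments 0.76/0.24 to cellulose/lignin litter; metabolic and
  cellulose litter feed the fast pool at 0.45/0.50; lignin feeds the
  slow pool at 0.50). The five SOC↔SOC fractions (fs1s2, fs1s3,
  fs2s1, fs2s3, fs3s1) are calibrated. With this sign convention the
  decay operator of the steady state is M = −AξK + V, and the balance
  reads dX/dt = Bu − MX;
* **K** (day⁻¹): base decomposition rates k = 1/(365·τ) from six
  calibratable base turnover times (years): tau4cwd, tau4l1 (metabolic),
  tau4l2l3 (cellulose and lignin), tau4s1/s2/s3 (fast/slow/passive);
* **ξ** (unitless, per layer, clipped to [0, 1]): product of a Q10
  temperature scalar ξ_T = Q10^((T−25)/10) with Q10 = 1.5, a moisture
  scalar ξ_W = log(ψ_min/ψ)/log(ψ_min/ψ_max) with ψ_min = −10 MPa and
  ψ_max = −0.01 MPa, and a depth scalar ξ_D = exp(−z/z_τ) whose
  e-folding length (`efolding`, m) is calibrated. No oxygen/anoxia
  scalar is included;
* **V** (day⁻¹): diffusive vertical mixing (bioturbation) between
  adjacent layers only, finite-volume discretized on the non-uniform
  grid with diffusivity 1 cm² yr⁻¹, zero-flux boundaries, advection 0.
  The discretization conserves thickness-weighted column carbon
  exactly (Σ_i Δz_i V_ij = 0 per column); plain column sums are zero
  only on a uniform grid.

The vertical grid uses node depths z_i = 0.025·(exp(0.5(i−0.5))−1) m,
giving a 1.75 cm surface layer, a 151 cm bottom layer and a 3.8 m
column for 10 layers.

Because all forcings are mean-annual constants, the steady state is
the single linear solve X = M⁻¹Bu (never an explicit inverse). The
solver verifies the balance residual to 1e−8 relative to ‖Bu‖∞ and
raises with a condition estimate otherwise. An explicit-Euler
`transient_step` exists purely as an independent oracle for tests.

### Calibrated parameters and bounds

Twelve parameters (6 τ, 5 fs*, efolding) with uniform priors on
documented ranges (`default_bounds()`), chosen to bracket the nominal
CLM-family values by roughly a factor of 3–5 each way; the
transfer-fraction ranges are capped so any in-bounds draw keeps
per-donor transfer sums below 1. The ranges are configuration, not
code. MCMC operates on range-normalized [0, 1] coordinates.

## Bayesian calibration

The misfit of a parameter vector at one site is

φ = Σ_i w_i (z_i − x_i)² / (2σ_i²)

with x_i the observed SOC concentration (kg C m⁻³), σ_i = 0.3·x_i
(a 30% observation standard deviation, the conventional assumption
for profile databases without quantitative uncertainty), and z_i the
modeled concentration linearly interpolated from layer nodes to the
observation-layer midpoint depth (constant extrapolation beyond the
first/last node). Depth weights are w_i = exp(−|depth_i|) with depth
in metres at the layer midpoint, except the shallowest and deepest
observations, which get w = 10 to pin both ends of the profile.
Profiles with a single observation are excluded before calibration.

Sampling is two-phase adaptive Metropolis, acceptance
p = min(1, exp(−(φ_new − φ_old))):

1. *test run* — uniform proposals θ′ = θ + r·range/D, r ~ U[−0.5, 0.5],
   D = 5 (maximum step 1/10 of the range); out-of-bounds proposals
   are reflected (a reject-at-bounds policy is available);
2. *formal run* — Gaussian random walk. Its initial covariance C0 is
   s_d·cov of the second half of the test run's accepted samples
   (the settled part; using the full set would inflate C0 with the
   approach trajectory from the random start), s_d = 2.38²/d. From
   iteration t0 (default 1000) the covariance adapts to
   s_d·cov(chain states so far) + s_d·ε·I with ε = 1e−8, refreshing
   the Cholesky factor every 50 iterations.

Default iteration counts: 20,000/30,000 (test/formal) per chain for
site-by-site inversions and 50,000/200,000 for the one-batch
inversion (the misfit summed over all profiles); three parallel
chains either way. Chains whose formal acceptance rate falls outside
(15%, 50%) are flagged; if no chain passes, the inversion is retried
once with fresh seeds, then the site is excluded. The first half of
each chain's *accepted* samples is discarded as burn-in; the
posterior is the post-burn-in sample of one randomly selected passing
chain, and the Gelman–Rubin statistic

GR = (W(N−1)/N + B/N)/W

is computed across passing chains (between-run B and within-run W
variances of the accepted-sample chains, truncated to common length).
Note that accepted-only chains (as opposed to full chains with
repeated states) slightly inflate posterior spread; the sampler can
optionally record full chains, which is what the correctness tests
use.

After site-by-site calibration, each site's fit is scored by the
fixed-line coefficient of determination (slope 1, intercept 0) of the
ensemble-mean prediction (500 posterior draws by default) against the
observations; sites with strictly negative R² are discarded
(R² = 0 is retained).

## Upscaling

* **one-batch** — the single continental posterior sample pool is
  used everywhere.
* **random-sampling** — per site and parameter, the posterior mode is
  extracted as the mode of a generalized-extreme-value distribution
  fitted by maximum likelihood to the posterior samples (analytic
  mode from the fitted (shape, loc, scale), verified numerically in
  tests; kernel-density mode as fallback when no interior GEV mode
  exists, which happens for posteriors piled against a bound). Modes
  from all usable sites form per-parameter continental pools; draws
  resample each parameter's pool independently and are clipped to
  bounds.
* **neural networking** — a feed-forward network maps the 60
  environmental covariates to the 12 bounds-normalized site posterior
  means: hidden layers 256/512/512/256, ReLU, MSE loss, batch size 64,
  fixed 400 epochs without early stopping, 80/20 train/test split and
  a 0.2 validation split within the training portion. Numeric
  covariates are z-scored with training-set statistics; categorical
  covariates are one-hot encoded. Predictions are clipped to [0, 1]
  and de-normalized, so they always respect bounds, and missing
  (masked) covariate cells yield missing parameters. The backend is
  scikit-learn's `MLPRegressor` driven by an explicit epoch loop (so
  train/validation loss histories are recorded); regularization is an
  L2 weight penalty (α = 1e−2 by default) in place of per-layer
  stochastic dropout, which the backend does not provide, with the
  Adam adaptive-gradient optimizer.

Ensemble predictions (`predict_with_sampling`) run the steady state
per draw (1,000 draws for continental maps, 500 for site-level
predictions by default) and report the per-layer mean and 5%/95%
quantiles (linear-interpolation sample quantiles); the same draws are
reused at every site/cell so maps are internally consistent. More
than 1% failed forward solves aborts with a diagnostic.

## Mapping and evaluation

Maps live on a regular 0.5° grid with cosine-latitude cell areas.
Stocks (kg C m⁻²) are concentration profiles integrated over the
0–30, 30–100 and 100–200 cm intervals by exact layer-overlap
weighting (intervals beyond the 3.8 m column truncate). Continental
totals convert to Pg C over land cells. Evaluation statistics are the
fixed-line R², Pearson r, and RMSE on layer-level concentrations,
optionally stratified by vegetation type (group means reported with
±0.5 standard deviation). Site-versus-map comparisons assign each
site to the half-open 0.5° cell containing it, and deviation maps
scale positive deviations by the 95% quantile of positive deviations
and negative ones by the absolute 5% quantile of negative ones,
clipped to [−1, 1].

## Synthetic world

The generator builds a fully known world on a configurable 0.5°
domain (default 32–46°N × 112–86°W, 300 sites):

* **covariates** — 56 smooth standardized surfaces (sums of three
  random low-frequency cosine waves) plus 4 categorical masks
  (quantile-discretized smooth fields); the first categorical field
  doubles as the vegetation-type grouping key;
* **forcings** — NPP (300–800 g C m⁻² yr⁻¹), soil temperature
  (4–18 °C, constant with depth) and water potential
  (−10^−2…−10^0.5 MPa, constant with depth) as smooth fields.
  Depth-constant forcing is a simplification: real soil temperature
  and moisture profiles vary with depth, so passing tests say nothing
  about depth-varying forcing;
* **true parameters** — either one constant normalized vector
  (default centre 0.45/0.55 alternating — deliberately *not* the
  nominal default parameterization, which plays the uncalibrated
  model) or a covariate-driven field: 5 informative covariates enter
  a linear map with unit-norm random weights and effect scale 0.12
  (normalized units) plus 0.02 site scatter, clipped to [0.03, 0.97];
  the other 55 covariates are distractors;
* **profiles** — the steady-state model run with the local truth,
  sampled at irregular observation depths. Layer counts follow a
  discrete distribution on [1, 10] with mean ≈ 8 (matching the ~9
  layers per profile of large harmonized profile databases) and a
  configurable single-layer fraction (default 5%) to exercise the
  exclusion filter; profile depth spans U(1.5, 3.8) m with Dirichlet
  layer boundaries. Observation noise is multiplicative truncated
  Gaussian with CV 0.3 (floor at 1% of the value so SOC stays
  positive), reusing the 30% assumed observation standard deviation
  as the generative coefficient of variation.

What the generator does not emulate: database quality flags, horizon
nomenclature, spatially correlated observation errors, measurement
method mixtures, or any real geography. Passing tests demonstrate the
machinery is correct under these idealized conditions, not that the
calibrated parameters transfer to real soils.

## Identifiability of the single-profile posterior

A structural property worth knowing: with a 30% observation σ, the
single-profile likelihood has a long, nearly flat ridge coupling
`efolding` and `tau4s3` (a deeper decomposition attenuation can be
traded against slower passive turnover with almost no change in the
modeled profile, the more so because diffusion, not decomposition,
controls the passive pool at depth). Profile-likelihood scans show
misfit changes of order 1 while `efolding` moves ±40%. Consequently
single-site posterior *means* of these parameters are skewed along
the ridge by ~25–40% even for noiseless data and fully converged
chains, while posterior *modes* and ensemble-mean SOC predictions
remain accurate (fixed-line R² > 0.95). Pooling all profiles in the
one-batch scheme sharpens the posterior by ~1/√n_sites and removes
most of the skew. This mirrors the field experience that such
parameters are "well-constrained" only in the sense of moderate
posterior variance, not unbiased point recovery.

## Problem sizes used in the test suite

The shipped tests scale the study down so the whole suite runs on one
CPU: recovery experiments use 50-site constant-truth worlds with
1-chain, 2,000/5,000-iteration inversions (and a 5,000/20,000
one-batch run, a tenfold reduction of the batch defaults); the
method-ordering experiment uses a 300-site covariate-driven world,
800/1,600-iteration site inversions, 200 ensemble draws and ~150
training epochs. The acceptance script's three quantities (steady
state residual, optimal acceptance rate, Gelman–Rubin limit) use the
full stated sizes (100 parameterizations, 2×10⁵ iterations at d=100,
three 5,000-sample chains).

## Known limitations

* The NN emulator has no dropout and no uncertainty propagation; its
  regularization strength (L2 α) substitutes for the intended
  stochastic regularization.
* Accepted-only chains (the calibration convention here) slightly
  inflate posterior spread relative to full Metropolis chains.
* The moisture scalar uses a fixed (ψ_min, ψ_max); no soil-texture
  dependence.
* No nitrogen coupling, no permafrost/cryoturbation switching, no
  transient projections; land-model coupling is out of scope.
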
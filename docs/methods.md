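# Methods

`sporecast` implements, on synthetic data, a comparison of five
citizen-science-data (CSD) occurrence models against a dynamic
colonization–extinction model for an old-forest deadwood fungus, and a
forecasting engine that projects occurrence under a forest-management
scenario splitting land into production and set-aside forest. This
note records the models, the generative assumptions behind the
synthetic data, the numerical choices, and what the tests do and do
not demonstrate.

## The synthetic world

Real inputs of this kind of study — national species-observation
portals, satellite-derived forest grids, gridded climate, inventory
plot projections — are replaced by generators that reproduce the
*statistical structure* the models assume.

**Landscape.** A rectangular grid of 100 m cells. Each covariate
(spruce volume, stand age, deadwood, temperature, precipitation,
elevation, population density, four road/urban distance fields) is a
Gaussian-process-like field: white noise smoothed with a Gaussian
kernel of scale `spatial_range` (in cells), then transformed
marginally onto its support — gamma quantiles for volumes and ages,
log-normal shapes for densities and distances, affine maps with a
north–south gradient for climate. This is cheap, exactly reproducible
under a seed, and gives the spatial autocorrelation that makes block
cross-validation meaningful. It does not reproduce real geography:
roads are not lines, rivers do not exist, and covariate cross-
correlations are only loosely realistic.

**Deadwood and stand age are coupled** so the mechanistic age filter
has a coherent generative twin: deadwood is a decaying post-harvest
pulse below age 25, exactly zero in stands aged 25–64 (the turnover
gap), and accumulates again with old-stand mortality above 64.

**Observation process.** Visits arrive per cell as Poisson with mean
`effort` times a normalized intensity exp(bias linear predictor) in
the recording-bias covariates (log population density, road
distances) — the point-process view that the joint PA/PO model
assumes. Each visit has a random recorder; an occupying species is
detected with probability inverse-logit(skill + 0.35·log recording
days). Presence-only records keep detections of the focal species and
of simulated non-focal target-group species (same bias field,
species-specific habitat coefficients — the premise of target-group
background sampling). Presence–absence records come only from
recorders flagged "thorough"; thoroughness is an input flag, not
inferred, since the underlying interview protocol is not modelled.

**Colonization–extinction surveys.** A direct generative twin of the
dynamic model below, with standard-normal plot covariates, a
configurable cut fraction, and optional per-plot survey intervals and
areas. The latent states are retained for tests.

**Forest projections.** Plots sampled from the landscape carry area
weights (their share of represented land, constant over time) and a
management class assigned greedily until the set-aside weight share
reaches the target (default 16%, the scenario's split; the remaining
84% is production). Set-aside plots age by the 5-year step and
accumulate deadwood; production plots are clear-cut with probability
0.25 per step once age ≥ 80, resetting age, dropping spruce volume to
5 m³/ha and leaving the deadwood pulse. Connectivity is recomputed at
every step from the projected plot states. Steps run 2020–2110 every
5 years (19 steps).

## Occurrence models

All covariates are standardized by division with the standard
deviation, *without centering* — coefficient magnitudes are then
comparable while zero keeps its meaning; forecast-time covariates are
divided by the training factors. Stand age is excluded from the
candidate habitat terms by default because recording effort is biased
toward old forest; a flag re-enables it.

* **GLM** — binomial/logit on presence–absence, forward selection from
  a spruce-volume-only model, a term kept iff AIC falls.
* **MaxEnt (linear features)** — with all feature classes other than
  linear switched off and no regularization, MaxEnt's maximum-entropy
  density over the background equals an unpenalized log-linear
  inhomogeneous Poisson process (IPP); we fit exactly that, with the
  background cells as equal-weight quadrature points. A config flag
  enables an L1 penalty. Variable selection removes terms with zero
  permutation importance (drop in mean presence log-density when the
  term's column is permuted, floored at 0) and re-checks AUC on
  presence–absence data after removal. Backgrounds: 40,000-cell-style
  uniform random, or target-group background (cells holding records of
  ecologically similar species), both excluding focal-presence cells.
* **Joint PA/PO point-process model** — per species s an occurrence
  intensity exp(α_s + β_s′x); presence-only records are that process
  thinned by a recording-bias factor exp(γ_s + δ′z) whose coefficients
  δ are shared across species; presence–absence responses follow
  Bernoulli with cloglog(p) = log(area) + α_s + β_s′x using the *same*
  β_s, which is what lets the PA data pin the habitat coefficients
  free of recording bias. Maximized jointly with analytic gradients;
  stepwise selection uses the focal species' likelihood contributions
  (focal AIC). With no bias variation δ is fixed at 0 with a warning;
  with no presence-only data the model reduces exactly to the cloglog
  GLM (tested to 1e-6).
* **Occupancy model** — detection histories from presence-only records
  of an indicator group: a visit is a (cell, year, day) with any
  indicator record; detected iff the focal species was among that
  day's records; the calendar year is the closed period; same-day
  duplicates collapse. The hierarchical model z ~ Bern(ψ),
  logit ψ = β′x; y|z ~ Bern(z·p), logit p = a0 + a1·log(recording
  days). log recording-days is used because raw days span orders of
  magnitude. The latent state is marginalized analytically and the
  coefficient posterior sampled with an affine-invariant ensemble
  sampler under Normal(0, 10) priors; each walker group is treated as
  a chain and split-R̂ is reported per parameter. Test-scale defaults
  are 2 chains × 8,000 iterations (burn-in 2,000, thin 2);
  `MCMCConfig.paper_scale()` gives 2 × 80,000 with 20,000 burn-in.
  Because histories exist only where something was recorded, fitted
  occupancy is conditional on the presence of the wider indicator
  group; the package preserves that interpretation.

## The colonization–extinction model

Two surveys per plot. ψ_{j,t} = (1−Z_{j,t−1})c* + Z_{j,t−1}(1−e*),
with offsets c* = 1−(1−c)^{n·a}, n = years/10, a = area/0.2 ha (the
reference survey interval and plot size). Uncut plots:
cloglog(c) = δ₂ + Σβ_l X_l, cloglog(e) = ε₂; cut plots: colonization
fixed at 0 (none was observed on cut sites; a switch estimates δ₁
instead) and cloglog(e) = ε₁. Detection is Y ~ Bern(Z·p) with p fixed
at 0.9 — no false positives, so some likelihood terms are exactly
zero. The marginal likelihood sums the four latent (Z₁, Z₂) states
exactly. First-survey occupancy ψ₁ is a free parameter per cut
status, since only the second-survey transition is specified.
Extinction and cut-site colonization are intercept-only throughout.
Fitting is by ensemble-sampler MCMC with Normal(0, 10) priors on the
unconstrained scale, or by maximum marginal likelihood with Wald
intervals from a finite-difference Hessian; forward stepwise keeps a
colonization covariate iff its 95% interval excludes zero.

Forward simulation draws Z(2020) from per-plot initial probabilities
and applies the transition every 5 years (n = 0.5 — the natural
extension of the per-decade scaling) with the plot's area and
projected covariates, including per-step cut events; Monte-Carlo
means over replicates are returned.

## Forecasting

Every fitted model predicts each projected plot at each step
(space–time substitution). Mechanistic filters then zero predictions
where the species cannot occur: where deadwood volume is 0, and where
forest age lies in the inclusive window 25–64 years (the bounds are
printed without bracket convention; we take them inclusive). Variants
`none`/`age`/`deadwood`/`both` support the sensitivity analysis over
all four combinations. Area-weighted means are reported for all land
and within management classes (weights renormalized within class);
relative change is 100·(v(2110)−v(2020))/v(2020). MaxEnt suitability
is kept on its normalized training scale (the normalizer is frozen at
fit time so temporal change is not distorted) and pools with
probabilities only through relative change, which is scale-free.
The ensemble reports mean ± sample SD of relative change across the
CSD models. Climate is held constant over the horizon: the scenario
varies management, not climate.

## Evaluation

Block cross-validation groups cells into square blocks (default side
50 cells) assigned randomly to folds (default 5), refits on k−1 folds
and scores the held-out fold; AUC is the Mann–Whitney statistic with
midrank tie handling. Single-class folds are skipped and recorded.
Fine-grid predictions aggregate to coarse maps by block means
ignoring missing cells (factor 100: 100 m → 10 km).

## Numerical choices and degenerate inputs

- Connectivity kernel exp(−d/α) with α = 1000·mean_dispersal_km and
  hard truncation at 8α (changeable); the truncation error is bounded
  by the dropped tail and verified against a full double sum. Whether
  the headline dispersal distance is the kernel scale or the realized
  2-D mean (which would be 2α) is ambiguous; we use the kernel scale.
  Old-forest sources are weighted by spruce volume by default; plots
  use the same kernel over plot coordinates.
- Wetness uses D8 steepest-descent routing with contributing area
  resolved high-to-low; tan(slope) is floored at 1e-4 so flat grids
  give a finite constant index. Multi-direction flow routing is out
  of scope.
- cloglog and offset computations use `log1p`/`expm1` forms;
  probabilities are clipped away from 0/1 only inside likelihoods.
- The ensemble sampler snapshots NumPy's global RNG at construction,
  so the package seeds it explicitly per chain for determinism.
- Zero-variance candidate terms are skipped with a warning;
  ill-conditioned GLM fits (possible complete separation) raise with
  a diagnostic rather than returning silent garbage.

## Test scales and what passing shows

Tests and the acceptance script use deliberately reduced problem
sizes — 30–71 grid sides, 200–800 plots, hundreds to thousands of
records, 2 × 10,000–16,000 sampler iterations — chosen so the whole
suite runs on a single CPU in minutes while keeping Monte-Carlo error
small relative to the tolerances checked (binomial/3-SE bounds,
coverage counts of 16/20, 5% coefficient error). Passing shows the
estimators recover the generating process under the model's own
assumptions and that the pipeline's algebraic identities hold; it
does not validate the generators against real Swedish or Finnish
data, nor the behaviour of any model under misspecification beyond
the specific contrasts tested (recording bias omitted, detection
fixed wrongly).

## Known limitations

- Single-species dynamics; no covariates on extinction; two survey
  periods only.
- MaxEnt hinge/threshold/product features, spatial random effects,
  and calibration metrics (TSS, kappa) are out of scope.
- Grid I/O is CSV only.
- Occupancy predictions are conditional on indicator-group presence,
  as discussed above.
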
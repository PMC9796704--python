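# Methods

## The model

`spomdyn` fits spatially explicit stochastic patch occupancy models
(SPOMs) to multi-year detection/non-detection data from a patch network,
with imperfect detection handled through latent occupancy states.

**Occupancy process.** The latent state z_{i,t} ∈ {0,1} of patch *i* in
year *t* follows a Markov chain. In the first year
z_{i,1} ~ Bernoulli(ψ1). Afterwards

    z_{i,t} ~ Bernoulli( (1 − z_{i,t−1}) γ_{i,t} + z_{i,t−1} (1 − ε_i) ),

i.e. an empty patch is colonized with probability γ and an occupied one
persists with probability 1 − ε.

**Extinction.** logit ε_i = δ0 + δ1 A_i, where A_i is the riparian patch
*length* in km (the system's natural measure of patch size, standing in
for population size). ε is time-invariant.

**Colonization and connectivity.** γ_{i,t} = 1 − exp(−S_{i,t}) with the
incidence-function connectivity

    S_{i,t} = β_t · Σ_{j≠i} A_j z_{j,t−1} exp(−α_t d_ij).

α (km⁻¹) sets the dispersal-kernel scale (1/α is the mean dispersal
distance), β the per-capita effective dispersal rate. The summand uses
**source-patch** weighting A_j z_j: each source contributes its own
length, switched off while it is empty. (A receiving-patch variant
A_i z_i, in which a patch's own state scales what it receives, is
available via `receiver_weighting=True` for comparison only; with that
reading occupancy weighting could not alter the relative contribution of
sources, so it is never the default.)

**The four formulations.** Two binary assumptions generate a 2×2 model
family:

| label | occupancy weighting | dispersal |
|-------|---------------------|-----------|
| UI | none (z ≡ 1, structural) | static α, β |
| UV | none (z ≡ 1) | year-specific α_t, β_t |
| DI | latent z_{j,t−1} (demographic) | static |
| DV | latent z_{j,t−1} | year-specific |

Year-specific dispersal parameters are random effects. The deviates are
placed on the log scale — log θ_t = log θ + ε_t with ε_t ~ N(0, σ_θ²) for
θ ∈ {α, β} — so every draw yields a valid (positive) kernel; an additive
deviate on the natural scale would not guarantee that. The additive
variant truncated at zero can be selected in code but is not the default.

**Detection.** y_{i,j,t} | z_{i,t} ~ Bernoulli(z_{i,t} p_t): no false
positives, year-specific detection with logit p_t ~ N(μ_p, σ_p²). Because
p is shared within a year, the per-patch-year sufficient statistics are
the visit count J_{i,t} and detection count; visits may be missing and a
patch-year may be entirely unsurveyed (J = 0).

## Priors

Defaults (all configurable through `PriorConfig`): ψ1 ~ U(0,1);
δ0, δ1 ~ N(0, 10²); α, β ~ U(0, 5); σ_α, σ_β, σ_p ~ U(0, 5);
μ_p ~ N(0, 1.65²); model indicators ~ Bernoulli(0.5). These are vague
working choices, not estimates; the N(0, 1.65²) on logit-scale μ_p is
near-uniform on the probability scale.

## Sampler

`fit_mcmc` runs Metropolis-within-Gibbs chains (default 3 chains; an
Assynt-sized production fit would use ~1e5 iterations with half
discarded; the bundled analyses and tests use shorter chains, stated
where used).

Latent states use three complementary moves per iteration, each exact
with respect to the joint posterior:

1. **single-site Gibbs** from the full conditional of z_{i,t}: detection
   terms, the incoming transition (ψ1 in year 1), the patch's own
   outgoing transition, and — for weighted models — the colonization
   factor of every other patch that was empty in year *t*, since their
   connectivity depends on z_{i,t}. Connectivity sums are maintained
   incrementally under flips (O(n) per flip). States with a detection
   are clamped at 1.
2. **trajectory-flip MH**: propose z_{i,·} → 1 − z_{i,·} for a whole
   patch. Single-site moves stall in quasi-absorbing corners of the
   parameter space (e.g. ε ≈ 0 with an empty network, where occupying
   year *t* is blocked unless year *t*+1 flips simultaneously); the
   involution proposal crosses them.
3. **process-prior refresh**: an independence proposal that forward-
   simulates a complete trajectory from the occupancy process under the
   current parameters. The process factors cancel, leaving the
   detection-likelihood ratio as the acceptance probability. It bridges
   macroscopic basins (all-occupied vs all-empty networks) and makes the
   no-data posterior mix essentially perfectly; with informative data it
   is simply rejected most of the time.

All three moves are validated jointly against exhaustive enumeration of
the 2⁹ latent configurations of a 3-patch × 3-year weighted model (total
variation distance < 0.02).

Continuous parameters: ψ1 and μ_p are conjugate (Beta, Normal) and
Gibbs-sampled; δ0, δ1 use random-walk Metropolis on the identity scale;
α, β, σ_α, σ_β, σ_p on the log scale (with the log-transform Jacobian);
logit p_t per year; year deviates ε_{α,t}, ε_{β,t} singly. Proposal
scales adapt toward 0.44 acceptance in windows of 50 iterations during
burn-in only (diminishing steps), then freeze.

**Year indexing.** Transition parameters (γ, ε, α_t, β_t) belong to the
transition *into* years 2..T; ψ1 owns year 1. Gaps in the year sequence
are rejected rather than interpolated (unit time step).

## Gibbs variable selection

`fit_gvs` samples (I_z, I_D) inside the chain. I_z switches the
connectivity sum between structural (z ≡ 1) and occupancy-weighted; I_D
switches the dispersal random effects on and off (θ_t = θ when off).

* **Pseudo-priors.** When I_D = 0 the deactivated block — the deviates
  ε_{α,t}, ε_{β,t} *and* their SDs σ_α, σ_β — is refreshed from Normal
  pseudo-priors fitted (moments, with a floored SD) to a short pilot run
  of the full DV model. Without pseudo-priors on the SDs they drift
  under their flat prior while deactivated and jam the indicator.
* **I_D update** compares the time-varying and static branches'
  colonization likelihoods plus hierarchical-prior vs pseudo-prior terms
  for the deactivated block.
* **I_z update** is a joint proposal that flips the branch *and*
  rescales β by the naive-occupancy fraction ρ (β′ = β/ρ when switching
  to weighted). Weighted connectivity sums are roughly a fraction ρ of
  structural ones, so β is scale-confounded with the branch; flipping
  the indicator alone is almost always rejected once β has adapted to
  the current branch. The proposal is a deterministic bijection on
  log β (unit Jacobian there) and reduces to the plain likelihood-ratio
  Gibbs update when ρ = 1.

Outputs are Pr(I_z = 1), Pr(I_D = 1) and the 4-cell joint over
UI/UV/DI/DV (summing to 1 by construction).

## Derived quantities

**Metapopulation capacity** λ_M is the dominant eigenvalue of
m_ij = A_i A_j exp(−α d_ij) (zero diagonal); the matrix is symmetric
non-negative so the Perron root is real. Capacity uses α only — the
classic definition, keeping λ_M a property of landscape + kernel scale —
with an optional β multiplier for sensitivity checks. `capacity_posterior`
evaluates λ_M per posterior draw (per year-draw from α_t for
time-varying models, plus an overall row from the hyper-mean α), giving
posterior means and central 95% intervals. No extinction-scaling
exponent is applied to A.

**Colonization surfaces.** For one year, each pixel centre x of a raster
over the network's bounding box buffered by 2 km receives
S(x) = β Σ_j A_j z_j exp(−α d(x, patch_j)) and γ(x) = 1 − exp(−S(x)).
Sources are weighted by *naive* occupancy (patch-year occupied iff at
least one detection; unsurveyed patch-years count as 0 — a stated
convention, it ignores imperfect detection). Default cell size 0.1 km.
Network-level summaries evaluate the same quantity at patch locations
with self-exclusion. Surfaces are written as ESRI ASCII grids.

**Goodness of fit.** Freeman–Tukey posterior-predictive check at the
patch-year level: per draw, expected counts e_{i,t} = J_{i,t} z_{i,t} p_t
against observed counts, T = Σ (√obs − √exp)²; replicate counts are
Binomial(J, z p_t) redraws, and the Bayesian p-value is Pr(T_rep ≥ T_obs).
Per-visit or per-year aggregation can be obtained by reshaping the inputs;
the patch-year level is the default. The observed discrepancy is exactly
invariant to patch/year relabelling; the p-value is invariant in
distribution (replicate noise is re-drawn per cell).

**Convergence.** `rhat` implements classic split-chain Gelman–Rubin
(each chain halved; between/within variance ratio); summaries report it
per parameter alongside posterior quantiles.

## Synthetic data

The generator emulates a fragmented riparian metapopulation of the
Assynt water-vole type, so every stage is testable without field data:

* 98 patches scattered uniformly over a 14 × 10 km extent (mean
  nearest-neighbour distance ≈ 0.6 km);
* patch lengths from a Beta distribution rescaled to [0.05, 3] km with
  the realized sample mean matched to 0.847 km by a monotone power
  transform (bounded, right-skewed: many short patches, a few long);
* occupancy simulated forward from the chosen model; the preset uses
  α = 0.446, β = 0.128 (demographically weighted time-invariant scale)
  and *tuned* extinction parameters δ0 = 0.9, δ1 = −1.2, chosen once by
  forward simulation so long-run occupancy fluctuates around the
  system's 55% average — they are calibration values, not estimates;
* 17 years, 1–4 visits per patch-year, ~10% of patch-years unsurveyed,
  year detection probabilities logit-Normal(1.4, 0.5) (p ≈ 0.8);
* year-specific dispersal deviates and detection probabilities are drawn
  once per dataset and recorded as ground truth for recovery tests;
* optional warm-up years (default 20 in the preset, discarded) let the
  chain approach quasi-equilibrium before year 1.

What the generator does **not** emulate: habitat change (the real system
is temporally stable, so none is simulated), matrix heterogeneity or
along-waterway dispersal distances (patches interact through planar
Euclidean distance; an explicit distance matrix can be supplied to
override this), density dependence within patches, and spatially
correlated detection errors. Passing tests therefore demonstrate
correctness of the machinery under the model's own assumptions, not
robustness to violations of them.

## Numerical choices

* Connectivity kernels store exp(−α d) with a zeroed diagonal so
  connectivity is a plain matrix–vector product; weighted and structural
  sums are both maintained so the selection indicator can switch cheaply.
* log(1 − γ) is computed as −S exactly; log γ via expm1. Extinction and
  detection log-probabilities are floored at 1e−300 before log to avoid
  −inf − (−inf) arithmetic in Metropolis ratios.
* Patches with coincident coordinates are rejected unless an explicit
  positive distance matrix is supplied.
* Capacity for n < 2 returns 0 with a warning (undefined quantity).
* Chain seeds derive from the config seed as (seed + 99991·(chain+1))
  mod 2³¹; pipeline stages use seed·100 + stage index, so any stage can
  be reproduced in isolation. Identical config + seed reproduces outputs
  bit-for-bit.
* Problem sizes in the bundled tests and analyses (e.g. 45–98 patches,
  chains of 4–20k iterations, 5–20 replicates per calibration
  experiment) are scaled-down study designs chosen to keep the whole
  suite quick on a single core; the statistical structure matches the
  full-scale design.

## Known limitations

* The GVS indicator for weighting (I_z) mixes through the ρ-rescaling
  proposal; in datasets where the weighted and structural likelihoods
  are nearly proportional (occupancy high and spatially even), its
  posterior is close to the prior — weak evidence is reported as such,
  not hidden.
* Detection heterogeneity is yearly only; patch- or visit-level
  covariates are out of scope.
* The extinction model has no rescue effect (connectivity does not
  reduce extinction), matching the model family implemented.
* Random-effect deviates are a priori independent across years; no
  temporal autocorrelation in dispersal.
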
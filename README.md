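# spomdyn — dynamic-connectivity stochastic patch occupancy models

Tools for asking how much the *dynamics* of connectivity matter in
spatially structured populations. Classic landscape connectivity metrics
treat connectivity as a static property of the landscape; in a
metapopulation it also depends on where the dispersers currently are and
on year-to-year variation in dispersal itself. `spomdyn` fits spatially
explicit stochastic patch occupancy models (SPOMs) to multi-year
detection/non-detection data under four connectivity assumptions, selects
among them within a single MCMC run, and propagates full posterior
uncertainty into derived landscape metrics.

It is built for fragmented patch networks surveyed repeatedly with
imperfect detection — the motivating system is a ~100-patch riparian
water-vole metapopulation monitored for 17 years — and for the analysts
of such monitoring data.

## Model

Latent occupancy z_{i,t} of patch *i* in year *t* is Markovian:

    z_{i,1} ~ Bernoulli(ψ1)
    z_{i,t} ~ Bernoulli( (1 − z_{i,t−1}) γ_{i,t} + z_{i,t−1} (1 − ε_i) )

with size-dependent extinction logit ε_i = δ0 + δ1 A_i (A_i = patch
length, km) and connectivity-driven colonization

    γ_{i,t} = 1 − exp(−S_{i,t}),      S_{i,t} = β_t Σ_{j≠i} A_j z_{j,t−1} e^{−α_t d_ij}.

Crossing two binary assumptions — demographic weighting (sum over
occupied sources vs all patches, z ≡ 1) and time-varying dispersal
(year-specific random effects on log α, log β vs static values) — gives
the four models UI, UV, DI, DV. Detections are
y_{i,j,t} | z_{i,t} ~ Bernoulli(z_{i,t} p_t) with logit p_t ~ N(μ_p, σ_p²)
(no false positives). Gibbs variable selection with indicators
I_z, I_D ~ Bernoulli(0.5) turns posterior indicator mass into model
support. Metapopulation capacity λ_M — the dominant eigenvalue of
m_ij = A_i A_j e^{−α d_ij} — is evaluated per posterior draw, so the
usual point estimate comes with a credible interval.

See `docs/methods.md` for the sampler, priors, pseudo-priors and the
synthetic-data generator.

## Worked example

The `analysis/` scripts form a complete study on a synthetic analogue of
the Assynt system (98 patches on 14 × 10 km, 17 years, demographically
weighted time-varying truth, ~55% occupancy):

```bash
python analysis/01_simulate_network.py --seed 1
python analysis/02_fit_connectivity_models.py --seed 1
python analysis/03_model_selection_gvs.py --seed 1
python analysis/04_capacity_and_colonization.py
python analysis/05_goodness_of_fit.py --seed 1 --model DV
```

Step 01 reports the simulated system:

    simulated 98 patches over 14 x 10 km
    mean patch length 0.847 km (range 0.05-2.78)
    mean occupancy across years: 0.568

Step 02 fits all four models; for the demographically weighted
time-invariant model (true α = 0.446 km⁻¹, β = 0.128, δ0 = 0.9,
δ1 = −1.2):

    === DI ===
             mean   q2.5  q97.5   rhat
    alpha   0.462  0.210  0.746  1.348
    beta    0.149  0.055  0.314  1.247
    delta0  0.848  0.583  1.110  1.004
    delta1 -1.100 -1.335 -0.871  1.001

Both dispersal parameters are recovered with truth inside the 95%
interval. Step 03 then asks which assumptions the data support:

    model  I_z  I_D  probability
    UI       0    0       0.0000
    UV       0    1       0.0067
    DI       1    0       0.0000
    DV       1    1       0.9933

    Pr(I_z = 1) = 0.993   (occupancy weighting)
    Pr(I_D = 1) = 1.000   (year-varying dispersal)

— the fully dynamic DV formulation, which is how the data were generated.
Step 04 compares derived landscape metrics across models:

    UI: MC = 18.43 [7.09-39.20], 17-yr mean landscape colonization = 0.506 (annual range 0.506-0.506)
    UV: MC = 23.37 [13.33-37.84], 17-yr mean landscape colonization = 0.523 (annual range 0.131-0.797)
    DI: MC = 17.81 [7.56-40.29], 17-yr mean landscape colonization = 0.447 (annual range 0.376-0.527)
    DV: MC = 18.56 [8.93-40.43], 17-yr mean landscape colonization = 0.465 (annual range 0.112-0.756)

The static unweighted model (UI) shows no interannual variation at all,
while the dynamic models reveal a several-fold annual range in landscape
colonization probability — the cost of assuming connectivity is static.
Step 05 closes with a posterior-predictive check:

    DV: Freeman-Tukey Bayesian p-value = 0.417
    no evidence of lack of fit

Each step writes its tables (posterior draws, summaries with split-chain
r-hat, model probabilities, per-model capacity and colonization CSVs,
optional ESRI ASCII rasters) under `results/`.

The same stages are scriptable through the CLI (`spomdyn simulate`,
`fit`, `gvs`, `capacity`, `surface`, `gof`, `run`) or a single YAML
pipeline config (`spomdyn run --config run.yaml`), which also records a
manifest with input checksums, per-stage seeds and timings.

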
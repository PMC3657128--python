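# Methods

`forestvar` quantifies plot-level variation in tree demographic rates from
re-surveyed forest-inventory data and propagates that variation through a
cohort-based stand simulator.  This note documents the models, the default
parameter values and why they were chosen, the numerical machinery, and the
limits of what the synthetic-data tests demonstrate.

## 1. Background demography

Each tree's expected annual diameter growth `G` (cm/yr) and expected
longevity `L` (yr) are products of three nonlinear terms:

    G = g0 * G_S(d) * G_C(c) * G_E(T, P)
    L = l0 * L_S(d) * L_C(c) * L_E(T, P)
    M = 1 / (1 + L)

with `d` the DBH (cm), `c` the crown-area index of strictly taller
neighbours (CAI, m²/m²), `T`/`P` mean annual temperature (°C) and
precipitation (mm/yr), and `M` the annual mortality probability (the `1 +`
caps it at 1).  The term shapes are standard forest-ecology forms:

- `G_S(d) = (d/d_opt)^α exp(−β(d − d_opt))` — hump-shaped, normalized to
  peak at 1 at `d_opt = α/β` (default 15 cm);
- `G_C(c) = exp(−γ_G c)` and `L_C(c) = exp(−γ_L c)` — exponential shading
  penalties, normalized to 1 in the open;
- `G_E`, `L_E` — Gaussian climate suitability in (0, 1] centred on per-PFT
  optima;
- `L_S(d) = d/(d + d_half) · exp(−d/35)` — longevity rises with size, then
  declines from ~35 cm onward (senescence).

Two reserved additive constants (`delta` on G, `psi` on L) default to 0.

**Calibration philosophy.**  The defaults for the seven plant functional
types (three latitudinal ranges × two leaf habits, plus a southern hydric
type) were set so that, jointly:

1. a tree under typical in-stand shading (CAI ≈ 1–2) has an annual
   mortality near 1.5 %/yr, giving an interval (≈5 yr) death fraction of
   ~0.09 in generated inventories — the scale observed in eastern-US
   remeasurement data;
2. a closed-canopy temperate stand equilibrates at roughly 200–300 Mg/ha
   aboveground biomass;
3. mortality is dominated by competition (`γ_L ≈ 1`, large open-grown
   `l0`): crowded stands self-thin strongly, open-grown trees are
   long-lived.  This makes equilibrium biomass canopy-limited, so it
   responds weakly (elasticity ≈ 0.5 rather than ≈ 1) to externally imposed
   mortality multipliers — the compensatory, gap-filling behaviour that
   data-constrained forest simulators exhibit.  Without (3), simulated
   biomass tracks 1/mortality almost proportionally and no realistic
   disturbance regime can leave the long-term mean unchanged.

Allometry: height `H = h_max(1 − exp(−0.045 d))`; crown area
`0.63 d^1.25` m²; aboveground biomass `0.1 d^2.4` kg.  A tree's shading
covariate is the CAI evaluated at its own height (crown area of strictly
taller cohorts, per m² of ground).

Recruitment is deterministic: `r_max · exp(−γ_R · CAI_ground) · suitability`
recruits/ha per 5-yr step, entering at 2.54 cm DBH (the inventory's minimum
measured size).  Shade-intolerant PFTs have large `r_max` and `γ_R` (pulse
recruitment in openings), tolerant ones the reverse.

## 2. Plot effects and their estimation

Each plot carries a six-vector of latent effects
`v = (E_G, E_M^small, E_M^large) × (earlier, recent)`:

- mortality effects act on the logit of the annual rate,
  `M′ = logit⁻¹(logit(M) + E_M)`, which for small rates is ≈ `exp(E_M)·M`,
  so `exp(E_M)` is approximately a log-normal mortality multiplier;
- growth effects are multiplicative, `G′ = exp(E_G)·G`; the vector stores
  the log multiplier so all six components are real-valued and jointly
  Gaussian.  (Whether the multiplicative growth effect enters the
  region-level Gaussian on the raw or log scale is a modelling choice; the
  log scale keeps the MVN assumption internally consistent.)

Within a forest region, `v ~ MVN(μ, Σ)`.  Tree likelihoods: death over a
census interval `Δt` is Bernoulli with `1 − (1 − M′)^Δt` (the effect acts
on the annual scale and is compounded); the diameter increment of a
surviving tree is Normal with mean `exp(E_G)·G·Δt` and sd `σ√Δt`.  Census
intervals of 3–8 yr (median 5) are taken from the plot table; the size
threshold is 12.7 cm and the period split is first measurement year < 2003.

**Sampler.**  Everything — all plot vectors, μ, Σ, σ — is estimated jointly
by MCMC:

- per component, a vectorized random-walk Metropolis step across all plots
  (proposal scale per plot from a one-point Fisher approximation of the
  tree-level information, globally adapted during burn-in toward 35%
  acceptance), followed by an independence proposal from the exact Gaussian
  conditional prior — plots with little or no data for a component mix in
  one step;
- a joint translation move that shifts `μ_c` and all `v_{·c}` together
  (the group prior is shift-invariant), which removes the slow random walk
  of weakly identified hyperparameter means through the hierarchy;
- conjugate draws for the hyperparameters: Σ via the Huang–Wand (2013)
  marginally noninformative hierarchical inverse-Wishart (`ν = 2`:
  uniform(−1, 1) correlation margins, half-t(scale 2.5) sds, auxiliary
  inverse-gamma scales), μ ~ N(0, 10²) per component, σ² inverse-gamma
  (0.01, 0.01).

A plain inverse-Wishart prior was rejected after recovery experiments: with
~20 trees per plot the tree-level likelihood barely updates individual
mortality effects, and the IW's variance–correlation coupling then
systematically inflated the weakly identified cross-period mortality
correlations (errors up to +0.45 regardless of the IW scale).  Under the
Huang–Wand prior the recovery error falls to sampling-noise level.

Convergence is assessed with split-R-hat and bulk ESS (via `arviz`) on μ
and σ across ≥2 chains; failure flags the summary and emits a
`RuntimeWarning`, never a silent result.  Posterior summaries report
per-plot means/sds for all six components; components without data are
informed through the estimated covariance (exact Gaussian conditioning,
which the test suite checks against the closed form).

**Identifiability at inventory scale.**  With ~1.5 %/yr mortality and ~10
trees per size class, a plot-level mortality effect has likelihood
information ≈ `Σ Δt·M ≈ 0.5–1` against a prior precision of ≈ 1.4–2.4, so
individual effects shrink strongly and region-level correlations among
mortality effects are the hardest parameters.  The recovery tests therefore
use the most-disturbed region (largest effect variances, hence least
shrinkage) and a fully remeasured design; in the least-disturbed regions
the cross-period mortality correlations carry posterior uncertainties
approaching ±0.1 at 2000 plots.

## 3. Disturbance statistics

- *Plot-mortality CDF*: observed per-plot-record death fractions vs the
  same quantity after replacing every tree's outcome with a Bernoulli draw
  from its background probability.  Plot-level effect variance shows up as
  an upper tail the background simulation cannot reach.
- *Fourfold elevation probability*: with the Eq-4 multiplier reading, a
  Normal effect with sd `σ_E` exceeds its mean by a factor ≥ t with
  probability `1 − Φ(ln t / σ_E)`; the threshold is 4 by default
  (an operational definition of "disturbance" over a ~5-yr interval).
  Two baselines are provided: the region mean (marginal sd) and the plot's
  own long-term mean (transient sd `√(c0_ii − c1_ii)`, treating the
  cross-period covariance as the persistent variance share).  Neither is
  privileged.
- *Effect correlations*: Pearson correlations among (posterior-mean or
  true) effects; same-period pairs pool both periods.

The default region ladder spans mortality-effect sds 0.60–0.85, i.e.
fourfold probabilities of ~1% (northeast) to ~5% (subtropical), with
growth-effect sd 0.30 everywhere; cross-size correlation 0.47, growth
persistence 0.70, small/large mortality persistence 0.25/0.45,
growth–mortality 0.  Effect means are `−sd²/2` so the mean multiplier
`E[exp(E)]` is exactly 1: plot effects redistribute, not inflate, the
background rates.

## 4. Stand simulation

State: a list of cohorts (PFT, DBH, stems/ha) plus the current 3-vector of
effects (growth, small-tree mortality, large-tree mortality).  Every 5-yr
step, in order: advance the effects; grow each cohort by
`5·exp(E_G)·G`; thin densities deterministically by the 5-yr survival
`(1 − M′)^5`, routing small vs large effects by the cohort's DBH at the
start of the step; recruit deterministically from the post-thinning
ground-level CAI (so a disturbance opens recruitment in the same step);
drop cohorts below 0.001 stems/ha and merge same-PFT cohorts within 1-cm
DBH bins to keep the state compact.

**Effect process.**  The temporal evolution of effects within a stand is a
stationary VAR(1) built from the fitted region distribution:
`c0` (within-period covariance, averaged over the two periods) is the
stationary covariance and `c1` (symmetrized cross-period block) the lag-one
cross-covariance, via `A = c1ᵀc0⁻¹`, `Q = c0 − A c0 Aᵀ`.  The estimated
cross-census correlation is treated as the one-step (≈5 yr) correlation and
effects update every step — the minimal process consistent with a Gaussian
stationary law plus between-census persistence.  Inconsistent blocks (Q not
PSD) raise an error with the remedy (shrink `c1` toward 0).

**Fixed vs variable scenarios.**  Variable mode runs the full process.
Fixed mode pins the two mortality components while growth still evolves;
the same three random normals are consumed per step either way, so paired
runs share identical growth noise.  Two pinning conventions exist:

- `rate` (default): pin at `μ + var/2`, the log of the mean multiplier
  `E[exp(E_M)]`, so the fixed scenario experiences the same long-run
  expected mortality *rate* as the variable scenario's time average.  The
  fixed-vs-variable contrast then isolates temporal variability itself,
  and the two scenarios share the long-term biomass mean (within a few
  percent in 5000-yr runs).
- `effect`: pin at the process mean μ (the literal log-scale mean).  This
  gives the fixed scenario a mortality rate lower by `exp(var/2)`
  (~20–40%), which with biomass elasticity ≈ 0.5 shifts its mean biomass
  by ~10% — a mean-rate artifact rather than a statement about
  variability.  Available for comparison.

## 5. The two experiments

*Stand variability*: one bare-ground stand per region, 5000 yr, both
scenarios on matched seeds; biomass mean and SD over years 500–5000 and the
variable/fixed SD ratio.  Expected pattern: shared means; SD ratio > 1
everywhere, increasing along the disturbance gradient.

*Chronic vs episodic mortality increase*: the four mortality components of
(μ, Σ) are rescaled jointly so the mean multiplier rises by k ∈ [1, 2]:

- background: `μ += ln k` (variance fixed — the whole distribution,
  including its mode, shifts up);
- disturbance: `μ += δ`, `var += δ` with `δ = (2/3)·ln k` (log-normal mode
  `exp(μ − var)` exactly preserved; the increase comes from a fatter upper
  tail).  Component correlations are preserved by rebuilding Σ from the
  unchanged correlation matrix and the new sds.

Both scalings achieve exactly the same mean multiplier, so biomass
differences between modes at equal k reflect the temporal pattern of
mortality only.  A sample of stands (default 50; 45 in the analysis
scripts, 5 per region) runs 500 yr per (k, mode) with matched seeds across
modes.  The k convention applies to the approximate (multiplicative) mean;
the exact-logit mean differs by O(M) and is not separately targeted.

## 6. What the synthetic data do and do not emulate

The generator reproduces the *structure* of national-inventory
remeasurement data — two census periods split at 2003, 3–8 yr intervals
(median 5), small trees (2.54–12.7 cm) sampled far more sparsely than large
ones (microplot vs subplot), region-specific climates and effect
distributions, non-forest/harvest/boundary flags for filter testing — with
tree covariates drawn from simple documented laws (log-normal DBH, uniform
shading 0–3, Gaussian climate jitter, PFT by climate suitability).

It does not emulate: spatial coordinates or autocorrelation (plots are
exchangeable within regions), species-level variation within PFTs,
measurement error in DBH or status, non-Gaussian effect distributions, or
agent-specific disturbance labels.  Passing recovery tests therefore shows
the estimator is correct *under the model's own assumptions*; it does not
validate the MVN assumption, the background-model forms, or spatial
independence against real data.

## 7. Numerical choices

- Survival log-likelihoods use `log1p`/`expm1`-stable forms
  (`ln(1−M′) = −softplus(logit M + E)`).
- `var1_from_blocks` accepts innovation-covariance eigenvalues down to a
  −1e−8 relative tolerance (clipped), errors below that, and warns when the
  process is degenerate (perfect persistence).
- Cohort merging uses 1-cm DBH bins with density-weighted means; the
  density floor is 0.001 stems/ha.
- Seeds are explicit everywhere; chain seeds derive from the user seed via
  `numpy.random.SeedSequence` spawning.
- Reduced problem sizes used in tests and in `scripts/acceptance.py`
  (e.g. 800–2000 plots, 27–50 stands, 3000–5000 yr) are chosen as the
  smallest scales at which each property is comfortably identified.

## 8. Known limitations

- The hierarchical model is fit per region independently; no pooling across
  regions.
- The VAR(1) reading of between-census persistence assumes the 5-yr step
  equals the census interval; real intervals vary 3–8 yr.
- Equilibrium biomass calibration is qualitative (150–300 Mg/ha band), not
  fit to data, and the growth/mortality parameters are illustrative of the
  eastern-US PFT structure rather than estimates.
- The multiplicative (Eq-4 style) reading of mortality effects overstates
  the exact logit-offset rate by `≈ m·(e^E − 1)` at annual rate m — up to
  ~9% at m = 0.05, E = 1 — so multiplier-scale summaries are interpreted
  accordingly.
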
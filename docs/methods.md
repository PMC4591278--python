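# Methods

This note describes the models implemented in `diadrom`, their assumptions,
the defaults and why they were chosen, and the numerical decisions made
where the design was genuinely open.

## The mechanistic model

### State representation

The population is a collection of *super-individuals*: weighted cohorts of
identical fish carrying a real-valued weight (number of fish), age (in
0.25-year steps), length (cm), natal basin, current location (a river basin
or the sea adjacent to one), a maturity flag and a spawned-before flag. By
default survival, dispersal splitting and post-spawning survival act
deterministically on weights (expected-value bookkeeping), while
recruitment and growth carry explicit log-normal noise — so runs are
stochastic but the heavy demographic multiplications are exact. An optional
`dispersal_mode="stochastic"` draws one multinomial destination per
straying cohort instead, which is the better choice when populations are
small enough that demographic dispersal noise matters.

Cohorts whose weight falls below `min_cohort_weight` (default 0.01 fish)
are dropped. At settlement, arrivals that share a destination basin and a
spawning history are merged into one cohort with weight-conserving mean age
and length. Under the nominal parameterization this merge is lossless:
settlers are mature, their subsequent survival does not depend on age or
length, and the only age statistic reported (mean age of first-time
spawners) is a weighted mean that merging preserves exactly. With a nonzero
length coefficient in the dispersal logit the merge would blur
within-basin length structure; the stochastic mode avoids merging entirely.

### Seasonal schedule

Seasons are fixed calendar quarters (winter JFM, spring AMJ, summer JAS,
fall OND); one tick is 0.25 year, so a Y-year run is exactly 4·Y ticks.
Within each tick the process order is fixed and test-pinned:

1. resolve water temperatures per basin;
2. survival — `exp(−Z_sea/4)` at sea; in river
   `[surv_optRiv·κ_riv(T)]^0.25 · exp(−H_riv/4)`, zero outside the thermal
   window;
3. growth, at sea only: ΔL = (L∞ − L)(1 − exp(−k_opt·κ_grow(T))), with
   multiplicative unit-mean log-normal noise (sd σ_ΔL) and clipping at L∞;
   the temperature used is that of the coastal basin the fish last left
   (fish at sea remain associated with a stretch of coast);
4. maturation: length ≥ L_mat;
5. season-gated migration and reproduction — in the upstream-migration
   season mature fish at sea enter rivers (see Dispersal); in the
   reproduction season every basin holding spawners produces recruits and
   post-spawning survival (Sp_sp) is applied; in the downstream-migration
   season river fish of age ≥ downMigAge (juveniles and post-spawning
   survivors alike) run to sea;
6. aging by 0.25 year (recruits skip aging in the tick they are created).

The simulation starts in summer with every basin seeded by juveniles of
length L_ini at age Δt_rec, which therefore run to sea at the first
downstream-migration step — matching the calibration protocol of
century-scale runs under a constant reference climate. A projection run is
expressed as a regime schedule: `spinup_years` under the constant-reference
regime (reference-window seasonal means, year-invariant), then the stored
series. Missing series coverage aborts with the offending (basin, year,
season) rather than falling back silently.

### Recruitment

Recruits (juveniles counted at age Δt_rec) from S spawners in basin j:

- Allee term: S' = S · logistic, anchored at 0.95 for S = η·wa_j and 0.5
  for S = η·wa_j/θ (the ln 19 construction);
- Beverton–Holt: R_det = α_j S' / (β_j + S');
- capacity: α_j = λ·wa_j with λ read as a maximum recruit density *per m²*
  (areas are carried in km², giving α_j = λ·wa_j·10⁶). This is a
  reconstruction — the basin-specific α_j, β_j are not fully specified by
  the parameter table — and the per-km² reading is numerically
  inconsistent with both the 500 000-juvenile seeding and the 50-juvenile
  populated-basin rule (it would cap recruitment below ~50 fish for every
  realistic basin). The reconstruction is isolated in
  `demography.recruitment_capacity` so an alternative can be swapped in;
- β_j = α_j / (a · surv(T)), with surv(T) = surv_optRep·κ_rep(T), so the
  low-density slope of the curve equals fecundity × temperature-dependent
  egg-to-recruit survival (times the residual zero-density Allee factor);
  R = 0 exactly when surv(T) = 0 or S = 0;
- realized R = R_det · exp(ε − σ_rep²/2), ε ~ N(0, σ_rep), so the
  expectation equals the deterministic kernel. The −σ²/2 mean correction is
  a package choice; without it the noise would inflate mean recruitment by
  exp(σ²/2).

A year counts as "reproduction occurred" when the realized R is at least
one whole fish; p_sust over a window is the fraction of such years.

### Dispersal

Upstream migration is a three-stage process. Emigration: each fish homes
with probability p_hom, otherwise strays. Transfer: homing fish return to
their natal basin; a stray weighs every basin in the network by

    logistic(α_const − α_dist·(d − d̄)/σ_d + α_TL·(L − L̄)/σ_L + α_WA·(wa − w̄)/σ_w),

where d is the distance from the natal basin. The distance term enters
negatively so the positive nominal α_dist makes nearby basins near-certain
(weight ≈ 0.96 at d = 0) and remote ones inaccessible (≈ 0.05 at d = d̄).
The length and area terms are nominally off (zero coefficients); turning
them on requires explicit standardization constants — none are invented.
A virtual death basin with fixed weight w_death joins the candidate set;
weights normalized to sum to one give settlement probabilities, and the
death basin removes the fish. Settlement imprints the destination: a
fish that spawned in a basin homes to that basin thereafter.

Distances default to great-circle between outlets (the metric is not
prescribed by the problem; along-coast matrices can be supplied and are
validated for symmetry and non-negativity).

### Parameters

`SpeciesParameters` defaults are the nominal shad-like values; the 11
parameters with uncertainty ranges (`UNCERTAIN_RANGES`) default to their
range centres: θ ∈ [1.8, 2.2], surv_optRep ∈ [5e-4, 1e-3],
TminRep ∈ [9, 12] °C, λ ∈ [3e-4, 5e-4], ToptGrow ∈ [15, 19] °C,
k_optGrow ∈ [0.2, 0.5] cm-scale per season, Z_sea ∈ [0.2, 0.6] yr⁻¹,
TminSurvRiv ∈ [8, 11] °C, L_mat ∈ [36, 44] cm, p_hom ∈ [0.6, 0.9],
w_death ∈ [0.2, 0.6]. Fixed values: η = 2.4 ind./km², fecundity 135 000
eggs, σ_rep = σ_ΔL = 0.2, Sp_sp = 0.1, L_ini = 2 cm, L∞ = 60 cm,
Δt_rec = downMigAge = 0.33 yr, H_riv = 0, surv_optRiv = 1, logit constants
(−2.9, 19.7, 0, 0) with distance standardization (300, 978) km.
`k_optGrow` is treated as the per-season Von Bertalanffy rate at the
thermal optimum (its tabulated "cm/season" unit only matches a VB rate
coefficient if read per season).

## Calibration

**Summary statistics.** SS1 = Σ_presences log(p_sust + δ) +
Σ_absences log(1 − p_sust + δ) with δ = 0.001 (natural log; maximized at
p = 1 on presences, 0 on absences). SS2 = latitude of the northernmost
basin whose terminal-decade mean recruitment strictly exceeds 50 juveniles
(NaN when none). SS3 = Σ_j (mean age of first-time spawners in j − 5)²,
weight-weighted, over basins with at least one first-time spawner.

**Sensitivity analysis.** A complete two-level factorial over the uncertain
parameters (2^k rows, replicate seeds per row). Indices are contrast
sums-of-squares shares of the total response variance: main effects from
the coded ±1 columns, pairwise interactions from their products, residual =
higher-order terms plus replicate (pure-error) variance. On an orthogonal
design these shares are exact ANOVA decompositions and sum to one.

**ABC.** Rejection sampling: couples drawn uniformly from the priors, each
simulated once, discrepancy = equal-weight sum of spread-normalized
components (−SS1, |SS3 − target|, |SS2 − target|); the configured quantile
of smallest discrepancies is accepted. An undefined SS2 is pinned to the
worst defined component value. Posterior summaries report mean, median,
KDE mode and quantile credible intervals. The original optimization used an
adaptive ABC algorithm; plain rejection with an isolated sampler interface
reproduces the objective, not that algorithm, and a sequential refinement
can be slotted in behind the same closure signature.

## The correlative model

A binomial GAM-style model: each predictor enters through a standardized
quadratic basis (linear + quadratic columns = 2 effective df), which spans
exactly the increasing, decreasing and dome-shaped responses that a 2-df
smooth is meant to allow while keeping the fit a plain IRLS GLM; the basis
is a pluggable dataclass. Surface area is log-transformed before fitting.
All subsets of 1–3 candidates are fitted on a class-stratified 75% split
(seeded; stratification is a package choice) and compared by AIC;
non-converging candidates are skipped with a warning. The winner is
evaluated on both splits with Cohen's kappa at the kappa-maximizing
threshold (scanned over all score midpoints plus {0, 1}, ties toward the
smallest threshold), rank-based AUC (Mann–Whitney, ties counted half) and
explained deviance. Projection evaluates the fitted additive predictor on
new values and flags basins outside the fitted predictor range as
extrapolated rather than refusing them.

## Synthetic data

The generators emulate the structure of the real inputs the models target:
`make_network` builds a meridian-like coastal chain (default 20 basins over
37–59.8 °N, ~133 km spacing, log-normal areas with log-mean 9.0 and log-sd
1.0 in km², i.e. median ≈ 8 100 km²); `make_climate` builds seasonal water
temperatures, annual mean 13 °C at 45 °N with a 0.7 °C per degree-latitude
lapse, ±6 °C seasonal swing (winter/summer), optional linear warming and
seeded noise; `make_virtual_distribution` derives historical presence from
a thermal dome rule on reference summer temperature with optional
contamination. These defaults place the species' thermal limits inside the
simulated coast so both range edges are observable.

What the synthetic data does *not* contain: real coastline geometry and
along-coast distances, inter-annual climate autocorrelation and extremes,
observation bias in the historical distribution, and any non-climatic
range constraint (dams, fishing, water quality). Passing tests therefore
demonstrate the internal consistency of the machinery — recovery of known
generating parameters, agreement with analytic anchors and oracles — not
the fidelity of any real-species projection.

## Problem sizes and numerical choices

Test and acceptance runs use the 20-basin fixture with 40–60-year
simulations, 2 000-draw ABC at 5% acceptance, and a 197-basin network for
the correlative fit; these sizes give stable statistics while keeping a
full pipeline run in minutes on one CPU. Tolerances: thermal-dome and
Allee anchors are exact; recruitment mean-correction is checked to 2% over
4 000 draws; ABC recovery requires the 95% credible region to cover the
truth in ≥ 9 of 10 repetitions; the correlative optimum must land within
1 °C of the generating optimum (quadratic-logit curvature estimation on
~200 contaminated points is noisier than the 0.25 °C evaluation grid).

Known limitations: basins are atomic (no within-basin spawning structure
or barriers); the sea is a set of coastal pools without explicit marine
movement; deterministic-weight dispersal under-represents colonization
variance for very small stray flows (use the stochastic mode there); no
evolutionary or anthropogenic processes; the recruitment-capacity scaling
is a documented reconstruction.
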
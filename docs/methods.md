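# Methods

## The scientific problem

Mothers who ever produced twins ("twinners") historically averaged more
lifetime births than non-twinners, which has long been read as evidence that
twinning propensity and intrinsic fertility share a physiological basis.
That reading commits an ecological fallacy: a mother's lifetime twinning
status confounds her per-birth twinning probability with her *exposure* —
the number of births over which twinning could occur.  This package
implements the full analytical programme for separating the two: life-history
GLMMs on non-aggregated birth records, an individual-based simulator of
reproductive careers under explicit mechanism scenarios, a bias-corrected
goodness-of-fit test, and manipulation experiments that vary twinning
propensity while holding everything else fixed.

## Data model and selection

The raw unit is one child (population, maternal identity, mother's birth
year/month, child's birth year/month, optional day).  Twin deliveries are
recognised purely by date proximity: exact dates at most one day apart, or —
when days are unrecorded — identical birth year and month.  Deliveries of up
to three children are accepted; more is treated as a data error.  Maternal
age is carried in whole months (days ignored), matching the monthly
resolution of parish records.

Selection is family-wise: a mother and all her births are dropped together
if her own birth month is unknown, her life course is not traced to age 45,
any child's birth month is unknown, or any consecutive delivery gap is under
nine months.  Row-wise removal would corrupt parity counts, which must run
1..births_total without gaps.  An exclusion log records one reason per
dropped mother so summary counts remain auditable.

Two derived tables drive everything downstream.  Birth level: maternal age
(months), parity, twin status, parity progression `PP` (a later birth
exists) and interbirth interval `IBI` (months to the next birth, present iff
`PP`).  Mother level: total births, twin and singleton birth counts,
lifetime twinner status, age at first birth (`AFB`, months).

## The twelve models

All models are GLMMs with Gaussian random intercepts.  Mother-level models
(population intercept only): (1) `births_total ~ twinner`, zero-truncated
negative binomial with log link — mothers have at least one birth by
construction, so the count support starts at one; (2) `twinner ~
births_total`, logit; (3) `cbind(twin_total, singleton_total) ~
births_total`, logit — the exposure-corrected model whose `births_total`
slope is the central statistic of the analysis; (7) `AFB ~
twinner * births_total_fac`, negative binomial, where `births_total_fac`
has levels 1..9 and 10+.

Birth-level models (maternal and population intercepts): (4) `PP ~ twin +
poly(age, parity)`, logit; (5) `IBI ~ twin + poly(age, parity)`, log-link
negative binomial on births that have a following birth; (6) `twin ~
poly(age, parity)`, logit.  The bivariate polynomial contains every
monomial `age^i * parity^j` with `1 <= i+j <= order`; the order (0–6) is
chosen per model by smallest marginal AIC.  Age and parity are centred and
scaled internally for conditioning (optionally QR-orthogonalised; fitted
values are invariant to that choice).  Sub-models 8–12 delete terms from
4–6 and exist to switch mechanisms off: 8 = 4 without `twin`, 9 = 5 without
`twin`, 12 = 6 without the maternal intercept, 10 = 6 without the
polynomial, 11 = 6 with neither.

The negative binomial is parameterised as NB2: variance `mu + mu^2/shape`,
with `shape` estimated jointly by maximum likelihood.  The zero-truncated
form has pmf `NB(k)/(1 - NB(0))` on `k >= 1`; its mean `mu/(1 - NB(0))` is
used for response-scale predictions and its sampler rejects zero draws.

## Fitting: Laplace and adaptive quadrature

No maintained Python library fits crossed-random-intercept GLMMs for these
families, so the fitter is implemented here.  The default approximates the
marginal likelihood by a Laplace approximation at the joint mode of fixed
effects and random effects.  Random intercepts make each within-factor
Hessian block diagonal, so the factor with most levels (maternal identity)
is eliminated analytically and only a small dense system (fixed effects
plus population intercepts) is solved per Newton step; the log-determinant
uses the same Schur structure.  Variance parameters and the NB2 shape are
profiled in an outer Nelder–Mead loop on their log scale.  Convergence:
relative penalised-likelihood change below 1e-10 in the inner loop, with
step halving; the outer optimiser's iteration cap is configurable
(`outer_maxiter`), and Monte-Carlo-heavy callers use a reduced cap since
simulation noise dominates optimiser precision there.

For single-factor instances the fitter also offers adaptive Gauss–Hermite
quadrature (`method="agq"`), with all parameters in the outer optimiser and
the integrand recentred at each group's conditional mode.  AGQ agrees with
brute-force numerical integration to better than 1e-6 on small instances
and serves as the reference in tests; the Laplace path is checked against
it at looser tolerance.

Known property: maximising with the fixed effects inside the inner
(penalised) problem — the strategy that makes thousands of maternal levels
cheap — shares the documented downward bias of Laplace-type variance
estimation for binary responses with few observations per group, and
random-effect variances of *rare* binary events (twinning at ~2% per birth)
are close to unidentifiable below a few thousand mothers regardless of
estimator.  Tests therefore assert variance recovery only in identifiable
regimes and assert fixed-effect recovery elsewhere.  Marginal AIC counts
fixed effects + variance components + shape; this convention is recorded in
the fit metadata.

## Marginal predictions

Reported quantities are population-averaged: `E[h(x'b + u)]` with `u`
integrated over the fitted random-effect distribution, where `h` is the
response-scale mean (including the truncation correction for model 1).
Independent intercepts sum to one Gaussian, so the nested quadratures
collapse to a single Gauss–Hermite rule (41 nodes by default); a Monte
Carlo integrator is available as a cross-check.  For log links the closed
form `marginal = conditional * exp(sigma2/2)` holds exactly and is used as
a test oracle.  Confidence intervals are percentile parametric bootstraps:
simulate a response from the fit with fresh random effects, refit, recompute
the statistic.

## The career simulator and the 16 scenarios

Each simulated mother starts at her observed age at first birth, parity
one, keeping her real maternal and population identities so that the fitted
conditional modes of the random effects apply to her.  Each iteration draws,
in order: the twinning outcome T of the current birth, then parity
progression PP given that outcome, then — if she continues — the interbirth
interval.  Parity progression is forced to zero at age 60 (the cap is
applied after the current birth's T draw); IBI draws below nine months are
rejected and redrawn, preserving the fitted distribution's shape on the
observed support (the filtered data contain no shorter gaps), and capped at
360 months.  Careers therefore always terminate, at most one capped
interval past the age cap.

Mechanisms map to model choices: P (twin affects parity progression) uses
model 4 vs 8; I (twin affects intervals) model 5 vs 9; S (age/parity
schedule affects twinning) and H (maternal heterogeneity in twinning) pick
the T model among 6 (both), 12 (S only), 10 (H only), 11 (neither).  The 16
on/off combinations are the simulation scenarios; replicates use seed
streams derived as `default_rng([base_seed, replicate])`, so runs are
reproducible from the base seed alone.  Triplets are not simulated (the
twinning models are binary); a simulated twin delivery contributes two
offspring.

## Goodness of fit and the double-bootstrap correction

The test statistic is the model-3 slope refitted to each simulated dataset.
The raw two-sided Monte-Carlo p-value ranks the observed slope within the
replicate slopes.  Because scenario models are fitted to the same data they
are then asked to explain, the raw test is biased (the data are more likely
under fitted than under generating parameters); the corrected p-value
calibrates it by a double bootstrap: each first-level simulated dataset is
treated as pseudo-observed, the scenario models are refitted to it, its own
raw p-value is computed from second-level simulations, and the real data's
raw p-value is ranked among those pseudo-observed p-values.  The correction
sits behind a narrow interface so an alternative calibration can be
substituted.  Non-convergent replicate slopes are excluded and counted.
Under self-simulation the corrected p-value is approximately uniform; the
test suite checks this by Kolmogorov–Smirnov at a desk scale of 30
repetitions with 150-mother worlds and 20 first- and second-level
replicates — the full published-scale calibration (16 scenarios x 200
replicates each with its own double bootstrap) is a cluster-scale
computation by design.

## Propensity manipulation and survival weighting

The manipulation experiment simulates scenario PIS (the mechanism set that
fits best) after adding a constant `delta` to the intercept of the twinning
model (logit scale; `delta = 2.5` turns a ~1.7% per-birth probability into
~17%, a roughly ten-fold twinning rate).  Per replicate it records twinning
and twinner rates, mean births, mean offspring, and survival-weighted
offspring under two published weight regimes: moderate twin mortality
(twins 0.603, singletons 0.838/0.815 by the mother's twinner status) and
severe twin mortality (twins 0.337, singletons 0.706 regardless of status).
Summaries are means and empirical 2.5–97.5 percentile ranges across
replicates.  The qualitative results — higher propensity yields more
offspring from fewer births, and the survival-weighted gain flips sign
between the two mortality regimes — are reproduced on synthetic data by the
test suite.

## The synthetic register generator

The generator runs the same career loop driven by chosen ("truth")
parameters: per-event intercepts, twin effects, polynomial age/parity
coefficients on a fixed standardised scale, population intercepts, and
maternal intercepts for the three traits drawn from a joint Gaussian with a
configurable correlation matrix (so heterogeneity-coupling worlds of either
sign can be built).  Age at first birth is a shifted negative binomial:
15 years plus NB(mean 132 months, shape 12), giving a ~26-year mean.
Careers are disaggregated into per-child rows with concrete calendar dates
(maternal births placed uniformly in 1700–1850, purely cosmetic; twins on
the same or adjacent days), which is exactly the ingestion format — so twin
identification and filtering are testable by exact round trip.  A defect
injector blanks birth months, truncates follow-up, or squeezes a gap below
nine months in disjoint families, and the selection filters must remove
precisely the corrupted families.

The `paper_like` preset was calibrated once, by simulation, to the
pre-industrial regime the analysis assumes: ~17 per mille twinning rate,
~78 per mille twinner rate, ~4.8 mean births, mean age at first birth
~26 y, a negative twin effect on parity progression, a slightly negative
twin effect on intervals, an age peak of twinning in the mid-to-late
thirties with a parity-1 excess, and a weak negative correlation between
maternal twinning and parity-progression effects.  What it does not
emulate: triplets, maternal death, marriage or migration, offspring
mortality as an event (survival enters only as weights), secular trends,
or transcription noise beyond the explicit defect injector.  Passing tests
therefore demonstrate the correctness and calibration of the machinery
under the generative assumptions of the analysis, not the historical
conclusions themselves, which require the original records.

## Problem sizes and numerical choices

Default desk scales, chosen as the package's own study sizes: 800–1500
mothers for suite fits and experiments, 30–100 replicates for slope
distributions and manipulation experiments, 20/20 double-bootstrap levels
with the floor of 20 converged slopes per Monte-Carlo p-value.  The
Nelder–Mead outer optimiser caps at 400 iterations for headline fits and 40–60
inside Monte-Carlo loops.  Degenerate inputs: variances are floored at
1e-8; a random factor can be fixed to zero variance (reducing to a GLM,
verified against an independent GLM implementation); separation-prone fits
rely on step-halving and report non-convergence rather than raising.  Ties
in AIC order selection resolve to the smaller order through the argmin over
a dict in insertion order 0..6.

## Known limitations

Coefficient-level agreement with the original spaMM fits can only be
asserted to about two significant figures in principle (different
approximations and optimisers); with the historical records unavailable,
the package asserts instead sign structure, recovery of generating
parameters, and calibration properties on synthetic data.  The corrected
p-value implements the double-bootstrap calibration described above; the
original's exact supplementary procedure may differ in convention, so
corrected p-values should be compared across implementations only at the
level of the accepted/rejected partition.  The fitter underestimates
binary-response random-effect variances in the few-observations-per-group
regime (see above); where that matters, the AGQ path or a dedicated
integrator should be preferred.
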
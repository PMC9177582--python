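# Methods

## Model

Metastasis status at four sites (bone, lung, liver, brain) is a vector of
binary flags; established metastases are assumed never to regress, so the
disease occupies one of 2⁴ = 16 states and every transition turns exactly
one site positive. Transition intensities are constant in time and shared
across patients: four primary-seeding rates out of the breast tumor (`tubo`,
`tulu`, `tuli`, `tubr`) and two secondary-seeding rates out of a lung
metastasis (`luli` to liver, `lubr` to brain). A site reachable both ways
(liver, brain, when the lung is already positive) accumulates both rates.
Each dissemination rate is a composite of circulating-tumor-cell release,
survival in transit and the probability of founding a metastasis downstream;
the model does not resolve those factors separately.

Key structural assumptions, inherited from the modelling framework rather
than estimated:

* rates are constant in time and identical across molecular subtypes unless
  the cohort is stratified and refit per stratum;
* metastases have effectively constant volume, making secondary seeding a
  constant-rate process;
* the chain starts in the metastasis-free state at tumor initiation
  (`P_1(0) = 1`);
* axillary lymph nodes are not part of the network (they mark, rather than
  source, distant spread), and the 4-site topology is fixed — arbitrary
  organ sets are out of scope.

The state-index ↔ flag mapping is not tabulated anywhere public; it is
reconstructed by constraint propagation from the published transition list
(each edge's rate label names the site it adds) and the reconstruction is
asserted unique in the tests. Two edges of that list are internally
inconsistent and are corrected to follow the generative rule: `10 → 13`
adds the lung (rate `tulu`) and `15 → 16` adds the bone (rate `tubo`).

**Units.** The rates are per **year**. The printed estimates (e.g.
`tulu = 0.00269`) are only dimensionally consistent with the observed ~1–2%
site prevalences at tumor ages of 2–7 years if read per year; the package
states this convention once here and uses years everywhere outside the
growth law.

## Tumor growth and age imputation

Primary-tumor volume follows the Gompertz law
`V(t) = V(0) exp((α/β)(1 − exp(−βt)))` with `t` in days. Defaults:
`α = 0.0359/day`, `β = 0.0013/day`, initiation as a single spherical cell
of diameter 10 µm, lethal diameter 100 mm (≈ 10¹² cells). `α` is exactly
the value `β · 3 ln(d_lethal/d₀)` that puts the asymptote at the lethal
diameter (`calibrate_alpha`). Tumors are spheres for every
diameter↔volume↔cell-count conversion; a year is 365 days. Subtype-specific
growth is deliberately not modelled: one growth law serves all strata, with
`α`, `β` exposed as configuration.

Tumor age is the exact inverse,
`t = −(1/β) ln(1 − (β/α)·3 ln(d/d₀))`. Diameters at or above the asymptote
(≥ 99.48 mm with defaults — admissible under the ≤ 100 mm inclusion rule)
have no finite preimage; the log-volume ratio is clamped to
`(1 − 10⁻⁶)·α/β`, which yields a large finite age (~29.6 years), and the
count of clamped records is logged. Diameters at or below the single-cell
diameter are rejected.

## Solver

The master equation `dP/dt = QP` is integrated by explicit Euler with a
default step of 10⁻³ years (numba-compiled loop; pure-numpy fallback), with
a stability guard requiring `Δt · max|Q_ii| < 0.1` that names the maximal
admissible step when violated. A matrix-exponential route (`expm` stepping,
exact for this time-homogeneous chain) is available as a config switch and
serves as the verification oracle: at the default step the Euler grid agrees
with `expm` to ≤ 10⁻³ and the error scales linearly in the step, as the
tests assert. Output probabilities are clamped to [0, 1]; before taking
logs in the likelihood they are floored at 10⁻³⁰⁰ so that astronomically
unlikely states at small ages do not produce −∞.

## Likelihood and estimation

The cohort likelihood is the product over patients of the model probability
of the patient's state at their tumor age. Ages are binned to the nearest
solver-grid column and patients are grouped by unique (state, age-bin)
pairs with multiplicities — an exact regrouping of the sum that makes one
likelihood evaluation cost independent of cohort size (one forward solve to
the oldest age, then a gather).

Minimization is derivative-free Nelder–Mead on the box transform
`θ = lo + (hi − lo) sin²(x)` (the same device as MATLAB's `fminsearchbnd`;
scipy's native Nelder–Mead bound handling clips at the box instead, which
behaves poorly at the `θ ≥ 0` boundary). Defaults: bounds [0, 10] per year,
start at 0.01 for all six rates, simplex tolerance 10⁻⁶, objective tolerance
10⁻⁸, 5000 evaluations per start, and 5 starts (the extras log-normally
perturbed from the initial point, seeded); the best minimum is returned and
non-convergence is flagged on the result, never raised.

Confidence intervals are parametric-bootstrap percentiles (2.5/97.5) from
B = 50 replicates: each replicate keeps the cohort's observed tumor ages
and re-simulates metastasis states from the fitted rates — bootstrapping
the conditional model given ages, since the ages are a deterministic
function of the recorded diameters, not a quantity the model explains —
then refits from the point estimate with a single start. Non-convergent
replicates are excluded and logged, and the effective B is reported. With
only 50 samples the percentile interval is itself noisy and may in
pathological fits exclude the point estimate; this is flagged, not treated
as an error.

## Synthetic cohorts

The generator emulates the structure the estimator assumes, at the
registry's scale (default n = 317,166):

* **Diameters**: the published five 20-mm bins with their printed
  frequencies, renormalized to sum to one (the printed bins cover 92.6% of
  the registry cohort; the remainder have sizes recorded outside those
  bins), uniform within a bin and truncated to [1, 100] mm — 1 mm as the
  floor because smaller tumors are effectively undetectable at diagnosis.
  A truncated lognormal is available as an alternative family.
* **Ages**: deterministic from diameters through the growth law.
* **States**: exact stochastic (Gillespie) simulation of the CTMC over each
  patient's age — draw exponential waiting times at the current total exit
  rate, choose the added site proportionally to its current rate including
  lung-secondary contributions. The first jump out of the metastasis-free
  state is drawn vectorized (its law is the same for every patient); the
  few patients whose first event falls inside their window continue in the
  per-patient loop. Agreement with the matrix-exponential distribution
  within 4 binomial standard errors per state at n = 10⁵ is the module's
  core acceptance property.
* **Subtypes**: drawn from the registry's published shares
  (HR−/HER2+ 4.2%, HR+/HER2+ 10.2%, HR+/HER2− 74.4%, HR−/HER2− 11.2%),
  with receptor columns consistent with the drawn subtype (HR+ records get
  one of the three ER/PR-positive combinations).
* Default true rates: the published whole-dataset estimates where printed
  (`tulu = 0.00269`, `luli = 0.126`, `lubr = 0.0404` per year); the three
  unprinted rates (`tubo = 0.006`, `tuli = 0.0015`, `tubr = 0.0004`) are
  chosen to respect the published descending order
  luli > lubr > tubo > tulu > tuli > tubr and the published site
  prevalences, and are overridable.

One seed drives three named substreams (diameters, states, subtypes), so a
cohort is byte-reproducible and each component independently so.

What the generator does **not** emulate: diameter measurement error or
digit preference, registry miscoding or missing-status patterns, any
dependence of dissemination rates or growth on subtype or age, treatment,
follow-up, or survival-driven selection into the registry. Passing the
recovery and cross-validation checks therefore demonstrates that the
estimation machinery is correct and well calibrated *under the model's own
assumptions* — not that the model is correctly specified for real registry
data.

## Cross-validation and prediction

Tenfold cross-validation randomly partitions the cohort into near-equal
folds (seeded), fits on nine and scores the held-out fold: for each site,
the cumulative number of patients with tumor age ≤ t and that site positive
(data) versus the sum over held-out patients with age ≤ t of the model
probability that the site is positive at their own age (model — this
definition of the model-expected cumulative curve is this package's, chosen
as the natural conditional expectation given the fold's ages). The score is
MAPE with the **model** value in the denominator, evaluated on the fold's
age range discretized at 0.25-year increments; grid points with a model
value of exactly zero are skipped with a warning, and a fold with no
positive patients at a site has that site's MAPE flagged undefined (NaN)
and excluded from the fold average.

Prediction evaluates the state distribution at any tumor age (or diameter,
converted through the growth law) with the exact propagator;
`P(any metastasis) = 1 − P₁(t)`. The "risk within 10 years" construction
used for counselling-style outputs is the probability at (imputed age at
the given diameter) + 10 years. Derived summaries: secondary/primary
seeding ratios `luli/tuli` and `lubr/tubr`; relative colonizing ability
`(luli/0.065)/(lubr/0.12)`, the lung-outflow rates normalized by the liver
and brain shares of cardiac output; and the lung influx (`tulu`) versus
outflux (`luli + lubr`) comparison. On the default rates the colonizing
ratio is 5.76; computed from the *rounded* printed rates it cannot be
expected to match an unrounded-fit value (published as 5.6) to better than
a few percent. The published lung→liver/lung→brain "transition probability
ratio" pair (0.314/0.332) has no definition reconstructable from printed
quantities and is deliberately not implemented.

## Problem sizes and seeds

Simulation-backed checks use sizes chosen to make their statistical
tolerances meaningful: parameter recovery at n = 10⁵ (the prescribed
recovery experiment; at this size the sampling error of `lubr` is ~10–12%
because only ~0.08% of patients carry the informative lung+brain
combination), cross-validation at the registry scale n = 317,166 (per-site
MAPE is dominated by binomial noise in a fold's rarest site — brain, ~0.2%
prevalence — and only at registry scale does a perfectly specified model
sit comfortably under a 15% average), and bootstrap coverage at n = 2×10⁴
with B = 50. All randomness flows from explicit integer seeds; tests fix
their seeds and the acceptance script derives every stream from its
`--seed` argument.

## Known limitations

* Fixed four-site topology; no lymph-node compartment; no metastasis
  growth dynamics (constant-volume assumption).
* One growth law for all subtypes; β is taken as a given constant rather
  than fit to doubling-time data.
* Diameter is used as recorded (no measurement-error model), and patients
  with any unknown metastasis status are excluded rather than imputed.
* Rates are identifiable only up to what diagnosis-time prevalence curves
  constrain: with ~0.2% brain prevalence, `tubr` and `lubr` carry wide
  intervals at realistic cohort sizes.
* The model describes untreated, de novo disease; nothing here transfers
  to post-treatment recurrence without re-parameterization.
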
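# metaspread

A stochastic network model of metastatic seeding for **de novo metastatic
breast cancer**, built for biostatisticians and modellers working with
diagnosis-time cancer-registry cohorts (SEER-like case listings). The
package quantifies tumor-cell **dissemination rates** between the primary
tumor and four metastatic sites — bone, lung, liver, brain — from nothing
more than each patient's tumor diameter and metastasis status at diagnosis,
and turns the fitted rates into metastasis-probability predictions for
untreated patients.

## The model

Metastasis status is a 4-bit state: each of bone/lung/liver/brain is 0 or 1,
and a positive site never regresses, giving a **16-state continuous-time
Markov chain** in which transitions add one site at a time. Six rates drive
the chain (all **per year**):

* primary seeding from the tumor: `tubo` (bone), `tulu` (lung), `tuli`
  (liver), `tubr` (brain);
* secondary seeding out of an established lung metastasis: `luli` (liver),
  `lubr` (brain).

State occupancy probabilities evolve by the master equation

```
dP/dt = Q P,        P_1(0) = 1,
```

with generator `Q[i, j]` = rate of moving from state *j* to state *i*
(columns sum to zero; the all-site state 16 is absorbing). The solver is
Euler forward on a 10⁻³-year grid, verified against the matrix exponential.

Each patient's observation time is their **tumor age**, imputed from the
recorded diameter by inverting Gompertzian growth

```
V(t) = V(0) exp((α/β)(1 − e^{−βt})),   α = 0.0359/day, β = 0.0013/day,
```

with a single 10 µm cell at initiation and a ~100 mm (≈10¹² cells)
asymptote. A 5/10/40 mm tumor is ≈ 2.4/2.9/4.9 years old.

The six rates are estimated by maximum likelihood,

```
L(θ) = ∏_j  P_{s_j}(t_j, θ),
```

the product over patients of the model probability of patient *j*'s state
at their tumor age, minimized as the negative log under box constraints
with Nelder–Mead on a sin² transform (the `fminsearchbnd` device).
Uncertainty comes from a **parametric bootstrap** (states re-simulated at
the observed ages from the fitted rates, 50 refits, percentile intervals);
validation from **tenfold cross-validation** scored by the mean absolute
percentage error (MAPE, denominator = model) between observed and
model-expected cumulative patient counts per site.

Because registry microdata are not redistributable, the package ships a
first-class **synthetic cohort generator**: diameters from the published
20-mm bin frequencies, ages through the growth law, states by exact
(Gillespie) simulation of the CTMC, plus the four HR/HER2 molecular
subtypes — the same engine that powers the bootstrap.

### Two corrected network edges

The published transition list for the state graph contains two entries that
contradict the one-site-at-a-time rule and the six-parameter set
(`10 → 13` labelled `tuli + luli` although state 10 is already
liver-positive, and `15 → 16` labelled `lubo`, which is not a model
parameter). This package implements the generative rule instead:
`10 → 13` adds the lung (rate `tulu`) and `15 → 16` adds the bone (rate
`tubo`). The index ↔ site-flag mapping is reconstructed from the transition
list by constraint propagation and its uniqueness is asserted in the tests.

## Worked example

```python
import metaspread as ms

cohort = ms.generate_cohort(ms.SimConfig(n_patients=20_000, seed=0))
fit = ms.fit_mle(cohort, multistart=2, seed=1)
```

prints (via `python examples/04_simulate_and_fit.py`):

```
simulated 20000 patients; 96.0% metastasis-free at diagnosis
rate        true   estimate
tubo     0.00600    0.00628
tulu     0.00269    0.00284
tuli     0.00150    0.00156
tubr     0.00040    0.00055
luli     0.12600    0.12061
lubr     0.04040    0.03664
```

The secondary-seeding rates (`luli`, `lubr`) exceed the primary rates by
one to two orders of magnitude: once a lung metastasis exists, it seeds the
liver and brain far faster than the primary tumor does. Prediction and
derived summaries (`python examples/05_predict_and_ratios.py`):

```
diameter  imputed age  P(any met within 10 further years)
     5 mm        2.4 y        0.123
    10 mm        2.9 y        0.128
    40 mm        4.9 y        0.146
colonizing ability liver vs brain (blood-flow normalized): 5.76
```

i.e. a ~12–15% probability of developing any metastasis within ten years of
the tumor reaching typical diagnostic sizes, and — after normalizing the two
lung-outflow rates by each organ's share of cardiac output (6.5% liver, 12%
brain) — tumor cells are ~5–6× better at colonizing liver than brain.

Each script in `examples/` is a short narrative demo of one capability
(growth law, state network, master equation, simulate+fit, predict). A thin
CLI wraps the same functions:

```bash
metaspread simulate -n 10000 --seed 1 -o cohort.csv
metaspread fit cohort.csv --bootstrap 50 -o fit.json
metaspread validate cohort.csv -k 10 -o cv.json
metaspread predict --fit-report fit.json --diameter 10 -o pred.csv
metaspread network --dot network.dot
```

## Layout

```
src/metaspread/
  states.py      16-state space, transition rules, generator Q
  growth.py      Gompertz law, age imputation, size anchors
  master.py      Euler/expm master-equation solver, probability grid
  cohort.py      cohort CSV I/O, inclusion filters, state/age assignment
  synthetic.py   registry-like cohort generator (Gillespie CTMC simulator)
  inference.py   likelihood, bounded MLE, parametric bootstrap
  validation.py  k-fold CV + MAPE, prediction tables, derived ratios
  config.py      YAML run configuration
  cli.py         thin click CLI (simulate / fit / validate / predict / network)
```

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.
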
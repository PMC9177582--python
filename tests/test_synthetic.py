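"""Synthetic cohort generator and its agreement with the master equation."""

import io

import numpy as np
import pytest

import metaspread as ms
from metaspread.synthetic import TABLE_BIN_EDGES, TABLE_BIN_WEIGHTS, _substreams

ZERO = ms.RateVector(0, 0, 0, 0, 0, 0)


def test_single_bin_weights_confine_diameters():
    cfg = ms.SimConfig(
        n_patients=500,
        seed=0,
        diameter_dist=ms.DiameterDistribution(weights=(1, 0, 0, 0, 0)),
    )
    d = ms.sample_diameters(cfg)
    assert np.all((d >= 1.0) & (d < 20.0))


def test_default_diameters_match_registry_bin_fractions():
    cfg = ms.SimConfig(n_patients=100_000, seed=0)
    d = ms.sample_diameters(cfg)
    counts, _ = np.histogram(d, bins=TABLE_BIN_EDGES)
    frac = counts / cfg.n_patients
    for f, w in zip(frac, TABLE_BIN_WEIGHTS):
        se = np.sqrt(w * (1 - w) / cfg.n_patients)
        assert abs(f - w) <= 3 * se


def test_same_seed_identical_draws():
    cfg = ms.SimConfig(n_patients=1000, seed=42)
    assert np.array_equal(ms.sample_diameters(cfg), ms.sample_diameters(cfg))


def test_lognormal_family_respects_truncation():
    cfg = ms.SimConfig(
        n_patients=2000,
        seed=1,
        diameter_dist=ms.DiameterDistribution(family="lognormal", min_mm=2.0, max_mm=60.0),
    )
    d = ms.sample_diameters(cfg)
    assert d.size == 2000 and np.all((d > 2.0) & (d <= 60.0))


def test_degenerate_distribution_rejected():
    with pytest.raises(ValueError):
        ms.DiameterDistribution(weights=(0, 0, 0, 0, 0))


def test_zero_rates_never_leave_state_one():
    rng = np.random.default_rng(0)
    for t in (0.5, 3.0, 10.0):
        assert ms.simulate_patient_state(ZERO, t, rng).index == 1
    states = ms.simulate_states(ZERO, np.full(100, 5.0), rng)
    assert np.all(states == 1)


def test_single_rate_matches_two_state_closed_form():
    theta = ms.RateVector(tubo=0.2, tulu=0, tuli=0, tubr=0, luli=0, lubr=0)
    rng = np.random.default_rng(1)
    n, t = 100_000, 3.0
    states = ms.simulate_states(theta, np.full(n, t), rng)
    p_expected = 1 - np.exp(-0.2 * t)
    frac = np.mean(states == 5)
    se = np.sqrt(p_expected * (1 - p_expected) / n)
    assert abs(frac - p_expected) <= 4 * se


def test_gillespie_frequencies_match_matrix_exponential():
    """Exact simulation and the analytic state distribution agree per state."""
    theta = ms.RateVector(tubo=0.06, tulu=0.03, tuli=0.02, tubr=0.01, luli=0.5, lubr=0.3)
    n, t = 100_000, 3.0
    rng = np.random.default_rng(2)
    states = ms.simulate_states(theta, np.full(n, t), rng)
    observed = np.bincount(states, minlength=17)[1:]
    p = ms.exact_state_distribution(theta, t)
    for i in range(16):
        se = np.sqrt(max(n * p[i] * (1 - p[i]), 1e-12))
        assert abs(observed[i] - n * p[i]) <= 4 * se + 1e-9, f"state {i + 1}"


def test_generated_cohort_matches_model_prevalence(recovery_cohort, theta_true):
    """Site prevalences in a generated cohort sit at the model expectation."""
    df = recovery_cohort.df
    ages = df["tumor_age_years"].to_numpy()
    grid = ms.solve_master(theta_true, horizon=ages.max() + 1e-3)
    bins = np.minimum(np.rint(ages / grid.dt).astype(int), grid.probs.shape[1] - 1)
    for site in ("bone", "lung", "liver", "brain"):
        expected = grid.site_marginal(site)[bins].sum()
        observed = int(df[f"met_{site}"].sum())
        se = np.sqrt(expected)
        assert abs(observed - expected) <= 4 * se, site


def test_prevalence_ordering_follows_rate_ordering(recovery_cohort):
    df = recovery_cohort.df
    prev = {s: df[f"met_{s}"].mean() for s in ("bone", "lung", "liver", "brain")}
    assert prev["bone"] > prev["lung"] > prev["liver"] > prev["brain"]


def test_same_seed_gives_byte_identical_csv():
    cfg = ms.SimConfig(n_patients=200, seed=7)

    def dump():
        buf = io.StringIO()
        ms.write_cohort(ms.generate_cohort(cfg), buf)
        return buf.getvalue()

    assert dump() == dump()


def test_generated_cohort_is_prepared_with_provenance():
    cfg = ms.SimConfig(n_patients=10, seed=0, theta_true=ZERO)
    cohort = ms.generate_cohort(cfg)
    assert len(cohort) == 10
    assert cohort.prepared
    assert np.all(cohort.df["state_index"] == 1)
    assert cohort.provenance["seed"] == 0
    assert cohort.provenance["theta_true"]["tubo"] == 0.0


def test_substreams_are_reproducible():
    a = _substreams(5)
    b = _substreams(5)
    assert all(x.random() == y.random() for x, y in zip(a, b))
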
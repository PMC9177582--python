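"""Cross-validation machinery, MAPE, prediction and derived ratios."""

import numpy as np
import pandas as pd
import pytest

import metaspread as ms


def test_mape_examples():
    assert ms.mape([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert ms.mape([100.0, 200.0], [110.0, 180.0]) == pytest.approx(10.0)
    # homogeneity: scaling both series leaves MAPE unchanged
    assert ms.mape([300.0, 600.0], [330.0, 540.0]) == pytest.approx(10.0)


def test_mape_skips_zero_model_points(caplog):
    assert ms.mape([0.0, 100.0], [5.0, 110.0]) == pytest.approx(10.0)
    assert "skipped" in caplog.text
    assert np.isnan(ms.mape([0.0], [1.0]))
    with pytest.raises(ValueError):
        ms.mape([], [])


def test_cumulative_counts_data_mode(small_cohort):
    ages = small_cohort.df["tumor_age_years"]
    t_grid = np.array([0.0, ages.max() + 1.0])
    for site in ("bone", "lung", "liver", "brain"):
        counts = ms.cumulative_counts(small_cohort, site, t_grid)
        assert counts[0] == 0.0
        assert counts[-1] == small_cohort.df[f"met_{site}"].sum()
        full = ms.cumulative_counts(small_cohort, site, np.linspace(0, ages.max(), 40))
        assert np.all(np.diff(full) >= 0)


def test_cumulative_counts_model_mode(small_cohort, theta_true):
    t_grid = np.linspace(0.0, 8.0, 20)
    zero = ms.cumulative_counts(
        small_cohort, "bone", t_grid, theta=ms.RateVector(0, 0, 0, 0, 0, 0)
    )
    assert np.all(zero == 0.0)
    model = ms.cumulative_counts(small_cohort, "bone", t_grid, theta=theta_true)
    assert np.all(np.diff(model) >= 0)
    assert model[-1] <= len(small_cohort)


def test_model_mode_matches_data_in_expectation(recovery_cohort, theta_true):
    """On a cohort generated from theta itself, observed cumulative counts
    track the model-expected curve within binomial noise."""
    t_grid = np.array([2.0, 3.0, 5.0, 8.0])
    for site in ("bone", "lung", "liver", "brain"):
        model = ms.cumulative_counts(recovery_cohort, site, t_grid, theta=theta_true)
        data = ms.cumulative_counts(recovery_cohort, site, t_grid)
        assert np.all(np.abs(data - model) <= 4 * np.sqrt(np.maximum(model, 1.0))), site


def test_mape_shrinks_with_cohort_size(theta_true, recovery_cohort):
    """Model-vs-data MAPE decreases as the simulated cohort grows."""
    errs = []
    for n, cohort in (
        (1_000, ms.generate_cohort(ms.SimConfig(n_patients=1_000, seed=5))),
        (10_000, ms.generate_cohort(ms.SimConfig(n_patients=10_000, seed=6))),
        (100_000, recovery_cohort),
    ):
        ages = cohort.df["tumor_age_years"]
        t_grid = np.arange(2.0, ages.max(), 0.5)
        model = ms.cumulative_counts(cohort, "bone", t_grid, theta=theta_true)
        data = ms.cumulative_counts(cohort, "bone", t_grid)
        errs.append(ms.mape(model, data))
    assert errs[0] > errs[1] > errs[2]


def test_cross_validate_structure_and_determinism(small_cohort):
    rep1 = ms.cross_validate(small_cohort, k=3, seed=0, multistart=1)
    rep2 = ms.cross_validate(small_cohort, k=3, seed=0, multistart=1)
    assert np.array_equal(rep1.fold_assignments, rep2.fold_assignments)
    assert len(rep1.fold_thetas) == 3
    assert rep1.fold_mape.shape == (3, 4)
    counts = np.bincount(rep1.fold_assignments)
    assert counts.sum() == len(small_cohort) and counts.max() - counts.min() <= 1
    vals = rep1.fold_mape.to_numpy().ravel()
    assert np.all(np.isnan(vals) | (vals >= 0))


def test_cross_validate_rejects_too_many_folds(small_cohort):
    with pytest.raises(ValueError):
        ms.cross_validate(small_cohort, k=len(small_cohort))


def test_metastasis_probability_closed_form(theta_true):
    row0 = ms.metastasis_probability(theta_true, t_years=0.0)
    assert row0["p_any_metastasis"] == pytest.approx(0.0, abs=1e-12)
    total = theta_true.tubo + theta_true.tulu + theta_true.tuli + theta_true.tubr
    for t in (1.0, 5.0, 12.0):
        row = ms.metastasis_probability(theta_true, t_years=t)
        assert row["p_any_metastasis"] == pytest.approx(1 - np.exp(-total * t), rel=1e-9)


def test_metastasis_probability_from_diameter(theta_true):
    row = ms.metastasis_probability(theta_true, diameter_mm=5.0)
    assert round(row["time_years"], 1) == 2.4
    with pytest.raises(ValueError):
        ms.metastasis_probability(theta_true, t_years=1.0, diameter_mm=5.0)


def test_ten_year_risk_construction(theta_true):
    """Risk within 10 years of diagnosis = probability at (imputed age + 10)."""
    for d, age in ((5.0, 2.4), (10.0, 2.9), (40.0, 4.9)):
        t = ms.diameter_to_age(d)
        assert round(t, 1) == age
        row = ms.metastasis_probability(theta_true, t_years=t + 10.0)
        assert 0.0 < row["p_any_metastasis"] < 1.0
        assert row["time_years"] == pytest.approx(t + 10.0)


def test_prediction_table_monotone(theta_true):
    table = ms.prediction_table(theta_true, times=np.linspace(0, 15, 16))
    assert np.all(np.diff(table["p_any_metastasis"]) >= 0)
    assert ((table.filter(like="P") >= 0) & (table.filter(like="P") <= 1)).all().all()


def test_derived_ratios(theta_true):
    r = ms.derived_ratios(theta_true)
    # arithmetic on the printed rounded rates
    assert r["colonizing_ability"] == pytest.approx((0.126 / 0.065) / (0.0404 / 0.12), rel=1e-12)
    assert r["colonizing_ability"] == pytest.approx(5.76, abs=0.01)
    assert r["secondary_primary_liver"] == pytest.approx(0.126 / 0.0015)
    assert r["lung_influx"] < r["lung_outflux"]  # influx 0.00269 << 0.126 + 0.0404

    unit = ms.derived_ratios(ms.RateVector(0.1, 0.1, 0.2, 0.1, 0.2, 0.1))
    assert unit["secondary_primary_liver"] == pytest.approx(1.0)

    degenerate = ms.derived_ratios(ms.RateVector(0, 0, 0, 0, 0, 0))
    assert np.isnan(degenerate["secondary_primary_liver"])
    assert np.isnan(degenerate["colonizing_ability"])
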
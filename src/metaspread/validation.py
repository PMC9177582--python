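"""Cross-validation, prediction and derived rate summaries.

Tenfold cross-validation fits the rates on nine folds and compares, on the
held-out fold, the cumulative number of patients with each metastasis at
tumor age t or younger -- observed versus model-expected -- via the mean
absolute percentage error (MAPE, denominator = model value).  Prediction
turns a fitted rate vector into per-state probabilities at any tumor age
(or diameter, converted through the growth law).  Derived summaries compare
secondary to primary seeding and normalize by organ blood-flow shares to
estimate relative colonizing ability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .growth import GompertzParams, diameter_to_age
from .inference import FitResult, fit_mle
from .master import SolverConfig, exact_state_distribution, solve_master
from .states import SITES, RateVector, enumerate_states

logger = logging.getLogger(__name__)

#: default organ shares of cardiac output used for colonizing ability
BLOOD_FLOW_LIVER = 0.065
BLOOD_FLOW_BRAIN = 0.12


def cumulative_counts(
    cohort: Cohort,
    site: str,
    t_grid: np.ndarray,
    theta: RateVector | None = None,
    solver_cfg: SolverConfig | None = None,
) -> np.ndarray:
    """Cumulative site-positive patient counts at each time in ``t_grid``.

    Data mode (``theta=None``): number of patients with tumor age <= t and
    the site positive.  Model mode: sum over patients with tumor age <= t
    of the model probability that the site is positive at *their* age.
    Both are non-decreasing in t.
    """
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}")
    t_grid = np.asarray(t_grid, dtype=float)
    if len(cohort) == 0:
        logger.warning("cumulative_counts: empty group")
        return np.zeros_like(t_grid)
    if not cohort.prepared:
        raise ValueError("cohort not prepared")
    ages = cohort.df["tumor_age_years"].to_numpy(float)
    if theta is None:
        pos_ages = np.sort(ages[cohort.df[f"met_{site}"].to_numpy(int) == 1])
        return np.searchsorted(pos_ages, t_grid, side="right").astype(float)
    cfg = solver_cfg or SolverConfig()
    grid = solve_master(
        theta, horizon=max(ages.max(), cfg.dt_years), dt=cfg.dt_years, method=cfg.method
    )
    marginal = grid.site_marginal(site)
    bins = np.minimum(np.rint(ages / cfg.dt_years).astype(int), marginal.size - 1)
    p = marginal[bins]
    order = np.argsort(ages)
    sorted_ages = ages[order]
    cum_p = np.concatenate([[0.0], np.cumsum(p[order])])
    return cum_p[np.searchsorted(sorted_ages, t_grid, side="right")]


def mape(x_model: np.ndarray, x_data: np.ndarray) -> float:
    """Mean absolute percentage error, denominator = model value.

    MAPE = (100/M) * sum |x_data - x_model| / x_model.  Points where the
    model value is exactly zero are skipped (M reduced) with a warning.
    """
    x_model = np.asarray(x_model, dtype=float)
    x_data = np.asarray(x_data, dtype=float)
    if x_model.shape != x_data.shape or x_model.size == 0:
        raise ValueError("series must be non-empty and of equal length")
    keep = x_model != 0
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.warning("mape: %d point(s) with zero model value skipped", n_skipped)
    if not keep.any():
        return float("nan")
    return float(
        100.0 / keep.sum() * np.abs((x_data[keep] - x_model[keep]) / x_model[keep]).sum()
    )


@dataclass
class CVReport:
    """Tenfold cross-validation output."""

    fold_assignments: np.ndarray
    fold_thetas: list[RateVector]
    fold_mape: pd.DataFrame  # rows = folds, columns = sites
    mean_mape_per_site: pd.Series = field(init=False)
    mean_mape_overall: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_mape_per_site = self.fold_mape.mean(axis=0, skipna=True)
        self.mean_mape_overall = float(self.mean_mape_per_site.mean())

    def to_dict(self) -> dict:
        return {
            "k": len(self.fold_thetas),
            "fold_thetas": [t.as_dict() for t in self.fold_thetas],
            "fold_mape": self.fold_mape.to_dict(orient="list"),
            "mean_mape_per_site": self.mean_mape_per_site.to_dict(),
            "mean_mape_overall": self.mean_mape_overall,
        }


def cross_validate(
    cohort: Cohort,
    k: int = 10,
    seed: int = 0,
    solver_cfg: SolverConfig | None = None,
    grid_step: float = 0.25,
    **fit_kwargs,
) -> CVReport:
    """k-fold cross-validation with per-site MAPE on cumulative counts.

    The cohort is randomly partitioned into k near-equal folds (seeded).
    For each fold the rates are fit on the remaining k-1 folds and the
    model's cumulative site-positive counts are compared with the held-out
    fold's observed counts on the fold's tumor-age range, discretized at
    ``grid_step``-year increments.  A fold with no positives at a site has
    that site's MAPE flagged undefined (NaN); fold averages skip NaNs.
    """
    n = len(cohort)
    if n < 2 * k:
        raise ValueError(f"cohort of {n} too small for {k}-fold cross-validation")
    if not cohort.prepared:
        raise ValueError("cohort not prepared")
    cfg = solver_cfg or SolverConfig()
    rng = np.random.default_rng(seed)
    assignments = rng.permutation(np.arange(n) % k)

    fold_thetas: list[RateVector] = []
    rows = []
    for fold in range(k):
        val_mask = assignments == fold
        train = cohort.subset(~val_mask)
        val = cohort.subset(val_mask)
        fit = fit_mle(train, solver_cfg=cfg, **fit_kwargs)
        fold_thetas.append(fit.theta_hat)
        ages = val.df["tumor_age_years"].to_numpy(float)
        t_grid = np.arange(ages.min(), ages.max() + grid_step, grid_step)
        row = {}
        for site in SITES:
            data_c = cumulative_counts(val, site, t_grid)
            if data_c[-1] == 0:
                logger.warning(
                    "cross_validate: fold %d has no %s-positive patients; MAPE undefined",
                    fold,
                    site,
                )
                row[site] = np.nan
                continue
            model_c = cumulative_counts(val, site, t_grid, theta=fit.theta_hat, solver_cfg=cfg)
            row[site] = mape(model_c, data_c)
        rows.append(row)
    fold_mape = pd.DataFrame(rows, columns=list(SITES))
    return CVReport(fold_assignments=assignments, fold_thetas=fold_thetas, fold_mape=fold_mape)


def metastasis_probability(
    theta: RateVector,
    t_years: float | None = None,
    diameter_mm: float | None = None,
    growth: GompertzParams = GompertzParams(),
) -> pd.Series:
    """Per-state probabilities and P(any metastasis) at one tumor age.

    Exactly one of ``t_years`` or ``diameter_mm`` must be given; a diameter
    is converted to an age through the growth law.  P(any) = 1 - P(state 1).
    Computed with the exact matrix-exponential propagator.
    """
    if (t_years is None) == (diameter_mm is None):
        raise ValueError("give exactly one of t_years or diameter_mm")
    if diameter_mm is not None:
        t_years = diameter_to_age(diameter_mm, growth)
    p = exact_state_distribution(theta, t_years)
    out = {"time_years": float(t_years)}
    for s in enumerate_states():
        out[f"P{s.index}"] = float(p[s.index - 1])
    out["p_any_metastasis"] = float(1.0 - p[0])
    return pd.Series(out)


def prediction_table(
    theta: RateVector,
    times: np.ndarray | None = None,
    diameters_mm: np.ndarray | None = None,
    growth: GompertzParams = GompertzParams(),
) -> pd.DataFrame:
    """Prediction rows (per-state probabilities, P(any)) at several ages."""
    if (times is None) == (diameters_mm is None):
        raise ValueError("give exactly one of times or diameters_mm")
    if diameters_mm is not None:
        rows = [
            metastasis_probability(theta, diameter_mm=d, growth=growth) for d in diameters_mm
        ]
    else:
        rows = [metastasis_probability(theta, t_years=t, growth=growth) for t in times]
    return pd.DataFrame(rows).reset_index(drop=True)


def derived_ratios(
    theta: RateVector,
    f_liver: float = BLOOD_FLOW_LIVER,
    f_brain: float = BLOOD_FLOW_BRAIN,
) -> dict[str, float]:
    """Secondary/primary seeding ratios, colonizing ability and lung flux.

    - secondary_primary_liver = luli / tuli, secondary_primary_brain =
      lubr / tubr: relative importance of secondary over primary seeding.
    - colonizing_ability = (luli / f_liver) / (lubr / f_brain): lung-outflow
      rates normalized by each organ's share of cardiac output, i.e. the
      relative ability of tumor cells to colonize liver versus brain.
    - lung_influx (tulu) versus lung_outflux (luli + lubr).

    Zero denominators yield NaN (flagged by a log entry), never an error.
    """
    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            logger.warning("derived_ratios: %s undefined (zero denominator)", name)
            return float("nan")
        return num / den

    sp_liver = _ratio(theta.luli, theta.tuli, "secondary_primary_liver")
    sp_brain = _ratio(theta.lubr, theta.tubr, "secondary_primary_brain")
    colonizing = _ratio(theta.luli / f_liver, theta.lubr / f_brain, "colonizing_ability")
    return {
        "secondary_primary_liver": sp_liver,
        "secondary_primary_brain": sp_brain,
        "colonizing_ability": colonizing,
        "lung_influx": float(theta.tulu),
        "lung_outflux": float(theta.luli + theta.lubr),
    }
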
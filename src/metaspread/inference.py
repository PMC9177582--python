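"""Maximum-likelihood estimation of the six dissemination rates.

Each patient contributes P_{s_j}(t_j, theta) -- the master-equation
probability of their observed metastasis state at their imputed tumor age
-- and the cohort likelihood is the product over patients.  Patients are
grouped by unique (state, age-bin) pairs on the solver grid, which leaves
the sum exactly unchanged while making the evaluation cost independent of
cohort size.

The bounded minimization is derivative-free Nelder-Mead on a sin^2 box
transform (theta = lo + (hi - lo) * sin^2(x)), the same device as MATLAB's
fminsearchbnd, with optional multi-start.  Confidence intervals come from a
parametric bootstrap: states are re-simulated at the observed tumor ages
from the fitted rates, each replicate is refit, and percentile bounds are
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cohort import Cohort
from .master import PROB_FLOOR, SolverConfig, _solve_raw
from .states import RATE_NAMES, RateVector, build_generator
from .synthetic import simulate_states

logger = logging.getLogger(__name__)

DEFAULT_BOUNDS = (0.0, 10.0)
DEFAULT_INIT = 0.01


@dataclass
class FitResult:
    """Point estimate plus diagnostics and (optionally) bootstrap CIs."""

    theta_hat: RateVector
    nll: float
    converged: bool
    n_evaluations: int
    bounds: tuple[float, float] = DEFAULT_BOUNDS
    ci_lower: Optional[RateVector] = None
    ci_upper: Optional[RateVector] = None
    bootstrap_samples: list[RateVector] = field(default_factory=list)
    n_bootstrap_requested: int = 0
    n_bootstrap_used: int = 0

    def to_dict(self) -> dict:
        out = {
            "theta_hat": self.theta_hat.as_dict(),
            "nll": self.nll,
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
            "bounds": list(self.bounds),
        }
        if self.ci_lower is not None:
            out["ci_lower"] = self.ci_lower.as_dict()
            out["ci_upper"] = self.ci_upper.as_dict()
            out["n_bootstrap_requested"] = self.n_bootstrap_requested
            out["n_bootstrap_used"] = self.n_bootstrap_used
        return out


@dataclass(frozen=True)
class _GroupedCohort:
    """Unique (state, age-bin) pairs with multiplicities on the solver grid."""

    states: np.ndarray  # 1..16
    bins: np.ndarray  # grid column indices
    counts: np.ndarray
    dt: float
    n_steps: int

    @property
    def n_patients(self) -> int:
        return int(self.counts.sum())


def _group(cohort: Cohort, solver_cfg: SolverConfig) -> _GroupedCohort:
    if not cohort.prepared:
        raise ValueError("cohort not prepared: state_index / tumor_age_years missing")
    ages = cohort.df["tumor_age_years"].to_numpy(float)
    states = cohort.df["state_index"].to_numpy(np.int64)
    dt = solver_cfg.dt_years
    bins = np.rint(ages / dt).astype(np.int64)
    n_steps = int(bins.max()) if bins.size else 0
    if solver_cfg.horizon_years is not None:
        n_steps = max(n_steps, int(np.ceil(solver_cfg.horizon_years / dt)))
    pairs, counts = np.unique(np.column_stack([states, bins]), axis=0, return_counts=True)
    return _GroupedCohort(
        states=pairs[:, 0], bins=pairs[:, 1], counts=counts.astype(float), dt=dt, n_steps=n_steps
    )


def _nll_grouped(theta_arr: np.ndarray, g: _GroupedCohort, method: str) -> float:
    Q = build_generator(RateVector.from_array(theta_arr))
    probs = _solve_raw(Q, g.dt, g.n_steps, method)
    p = probs[g.states - 1, g.bins]
    return float(-(g.counts * np.log(np.maximum(p, PROB_FLOOR))).sum())


def negative_log_likelihood(
    cohort: Cohort, theta: RateVector, solver_cfg: SolverConfig | None = None
) -> float:
    """-log L(theta) = -sum_j log P_{s_j}(t_j, theta); 0 for an empty cohort."""
    if len(cohort) == 0:
        return 0.0
    cfg = solver_cfg or SolverConfig()
    g = _group(cohort, cfg)
    return _nll_grouped(theta.as_array(), g, cfg.method)


def _to_bounded(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return lo + (hi - lo) * np.sin(x) ** 2


def _to_unbounded(theta: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    frac = np.clip((theta - lo) / (hi - lo), 1e-12, 1.0 - 1e-12)
    return np.arcsin(np.sqrt(frac))


def fit_mle(
    cohort: Cohort,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    init: RateVector | Sequence[float] | float = DEFAULT_INIT,
    solver_cfg: SolverConfig | None = None,
    multistart: int = 5,
    seed: int = 0,
    xatol: float = 1e-6,
    fatol: float = 1e-8,
    maxfev: int = 5000,
) -> FitResult:
    """Bounded Nelder-Mead MLE of the six rates.

    ``multistart`` runs start from ``init`` and from log-normally perturbed
    copies of it (seeded); the best minimum is returned.  Non-convergence is
    flagged on the result, never raised.
    """
    if len(cohort) == 0:
        raise ValueError("cannot fit an empty cohort")
    cfg = solver_cfg or SolverConfig()
    lo_s, hi_s = bounds
    if not 0 <= lo_s < hi_s:
        raise ValueError("bounds must satisfy 0 <= lo < hi")
    lo = np.full(6, float(lo_s))
    hi = np.full(6, float(hi_s))
    if isinstance(init, RateVector):
        init_arr = init.as_array()
    else:
        init_arr = np.broadcast_to(np.asarray(init, dtype=float), (6,)).copy()
    init_arr = np.clip(init_arr, lo + 1e-12, hi - 1e-12)

    g = _group(cohort, cfg)

    def objective(x: np.ndarray) -> float:
        return _nll_grouped(_to_bounded(x, lo, hi), g, cfg.method)

    rng = np.random.default_rng(seed)
    starts = [init_arr]
    for _ in range(max(0, multistart - 1)):
        pert = init_arr * np.exp(rng.normal(0.0, 1.0, size=6))
        starts.append(np.clip(pert, lo + 1e-12, hi - 1e-12))

    best = None
    total_evals = 0
    for start in starts:
        res = minimize(
            objective,
            _to_unbounded(start, lo, hi),
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxfev": maxfev, "maxiter": maxfev},
        )
        total_evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    theta_hat = RateVector.from_array(_to_bounded(best.x, lo, hi))
    if not best.success:
        logger.warning("fit_mle: optimizer did not report convergence (%s)", best.message)
    return FitResult(
        theta_hat=theta_hat,
        nll=float(best.fun),
        converged=bool(best.success),
        n_evaluations=total_evals,
        bounds=(float(lo_s), float(hi_s)),
    )


def bootstrap_ci(
    fit: FitResult,
    cohort: Cohort,
    B: int = 50,
    seed: int = 0,
    solver_cfg: SolverConfig | None = None,
    **refit_kwargs,
) -> FitResult:
    """Parametric-bootstrap 95% percentile CIs around a fitted model.

    Each replicate keeps the cohort's observed tumor ages and re-simulates
    metastasis states from ``fit.theta_hat`` (exact CTMC simulation), then
    refits starting from the point estimate.  Non-convergent replicates are
    logged and excluded; ``n_bootstrap_used`` reports the effective B.
    With B=1 the "interval" degenerates to the single replicate (warned).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if B == 1:
        logger.warning("bootstrap_ci: B=1 gives a degenerate interval")
    cfg = solver_cfg or SolverConfig()
    ages = cohort.df["tumor_age_years"].to_numpy(float)
    streams = np.random.SeedSequence(seed).spawn(B)
    refit_kwargs.setdefault("multistart", 1)
    samples: list[np.ndarray] = []
    n_failed = 0
    for b in range(B):
        rng = np.random.default_rng(streams[b])
        states_b = simulate_states(fit.theta_hat, ages, rng)
        boot = Cohort(
            df=pd.DataFrame({"state_index": states_b, "tumor_age_years": ages}),
            provenance={"source": "parametric bootstrap", "replicate": b},
        )
        fit_b = fit_mle(
            boot,
            bounds=fit.bounds,
            init=fit.theta_hat,
            solver_cfg=cfg,
            seed=b,
            **refit_kwargs,
        )
        if not fit_b.converged:
            n_failed += 1
            logger.warning("bootstrap_ci: replicate %d did not converge; excluded", b)
            continue
        samples.append(fit_b.theta_hat.as_array())
    if not samples:
        raise RuntimeError("all bootstrap replicates failed to converge")
    arr = np.vstack(samples)
    lo_q, hi_q = np.percentile(arr, [2.5, 97.5], axis=0)
    return replace(
        fit,
        ci_lower=RateVector.from_array(lo_q),
        ci_upper=RateVector.from_array(hi_q),
        bootstrap_samples=[RateVector.from_array(row) for row in arr],
        n_bootstrap_requested=B,
        n_bootstrap_used=len(samples),
    )


def fit_by_subtype(
    cohort: Cohort, solver_cfg: SolverConfig | None = None, **fit_kwargs
) -> dict[str, FitResult]:
    """Independent MLE per molecular-subtype stratum."""
    from .cohort import stratify_by_subtype

    out = {}
    for st, sub in stratify_by_subtype(cohort).items():
        if len(sub) == 0:
            logger.warning("fit_by_subtype: stratum %s empty; skipped", st)
            continue
        out[st] = fit_mle(sub, solver_cfg=solver_cfg, **fit_kwargs)
    return out
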
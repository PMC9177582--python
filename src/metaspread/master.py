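"""Master-equation (Kolmogorov forward) solver for the seeding network.

State-occupancy probabilities evolve as dP/dt = Q P from the initial
condition P_1(0) = 1 (no metastases at tumor initiation).  The production
solver is explicit Euler on a uniform grid (default step 1e-3 years),
numba-jitted when numba is importable; a matrix-exponential route
(``method="expm"`` or :func:`exact_state_distribution`) provides the exact
solution for verification and point queries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import expm

from .states import N_STATES, SITES, RateVector, build_generator, enumerate_states

#: probabilities are floored at this before taking logs
PROB_FLOOR = 1e-300

#: stability guard: require dt * max|Q_ii| below this
_STABILITY_LIMIT = 0.1


@dataclass(frozen=True)
class SolverConfig:
    """Numerical configuration for the forward solve.

    dt_years: uniform time step of the probability grid (years).
    method: "euler" (the production scheme) or "expm" (exact per-step
        propagator, used as an oracle).
    horizon_years: optional fixed horizon; when None the horizon is taken
        from the data at hand (e.g. the oldest tumor age in a cohort).
    """

    dt_years: float = 1e-3
    method: str = "euler"
    horizon_years: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dt_years <= 0:
            raise ValueError("dt_years must be positive")
        if self.method not in ("euler", "expm"):
            raise ValueError(f"unknown solver method {self.method!r}")


def _euler_core(Q, dt, n_steps):
    n = Q.shape[0]
    out = np.empty((n, n_steps + 1))
    p = np.zeros(n)
    p[0] = 1.0
    out[:, 0] = p
    for k in range(1, n_steps + 1):
        p = p + dt * (Q @ p)
        out[:, k] = p
    return out


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _euler_jit = njit(cache=True)(_euler_core)
except ImportError:  # pragma: no cover
    _euler_jit = _euler_core


def _solve_raw(Q: np.ndarray, dt: float, n_steps: int, method: str) -> np.ndarray:
    """16 x (n_steps+1) probability matrix, column k at time k*dt."""
    max_exit = float(np.max(np.abs(np.diag(Q))))
    if method == "euler":
        if dt * max_exit >= _STABILITY_LIMIT and max_exit > 0:
            raise ValueError(
                f"Euler step dt={dt} too large for max exit rate {max_exit:.4g}/y; "
                f"require dt < {_STABILITY_LIMIT / max_exit:.4g} years"
            )
        return _euler_jit(np.ascontiguousarray(Q), float(dt), int(n_steps))
    # exact propagator, stepped (time-homogeneous chain)
    M = expm(Q * dt)
    out = np.empty((Q.shape[0], n_steps + 1))
    p = np.zeros(Q.shape[0])
    p[0] = 1.0
    out[:, 0] = p
    for k in range(1, n_steps + 1):
        p = M @ p
        out[:, k] = p
    return out


@dataclass(frozen=True)
class ProbabilityGrid:
    """State-occupancy probabilities on a uniform time grid.

    ``probs[i, k]`` is the probability of being in state ``i+1`` at
    ``times[k]`` years after tumor initiation.  Columns sum to one (to
    solver accuracy); entries are clamped to [0, 1] on construction.
    """

    times: np.ndarray
    probs: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def horizon(self) -> float:
        return float(self.times[-1])

    def column_index(self, t: float) -> int:
        """Index of the grid column nearest to time ``t``."""
        if t < 0 or t > self.horizon + self.dt / 2:
            raise ValueError(f"time {t} outside grid [0, {self.horizon}]")
        return int(round(t / self.dt))

    def column_at(self, t: float) -> np.ndarray:
        return self.probs[:, min(self.column_index(t), self.probs.shape[1] - 1)]

    def state_probability(self, state_index: int, t: float) -> float:
        """P(state ``state_index``) at the grid column nearest to ``t``."""
        if not 1 <= state_index <= N_STATES:
            raise ValueError("state_index must be 1..16")
        return float(self.column_at(t)[state_index - 1])

    def site_marginal(self, site: str) -> np.ndarray:
        """P(site positive) over the whole grid (sum of site-positive states)."""
        if site not in SITES:
            raise ValueError(f"unknown site {site!r}")
        rows = [s.index - 1 for s in enumerate_states() if getattr(s, site)]
        return self.probs[rows, :].sum(axis=0)

    def any_metastasis(self) -> np.ndarray:
        """P(any metastasis) = 1 - P(state 1) over the grid."""
        return 1.0 - self.probs[0, :]

    def to_dataframe(self):
        import pandas as pd

        cols = {"time_years": self.times}
        for s in enumerate_states():
            cols[f"P{s.index}"] = self.probs[s.index - 1, :]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def solve_master(
    theta: RateVector,
    horizon: float,
    dt: float = 1e-3,
    method: str = "euler",
) -> ProbabilityGrid:
    """Solve dP/dt = QP on [0, horizon] years with uniform step ``dt``."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    Q = build_generator(theta)
    n_steps = int(np.ceil(horizon / dt - 1e-9))
    probs = _solve_raw(Q, dt, n_steps, method)
    times = np.arange(n_steps + 1) * dt
    return ProbabilityGrid(times=times, probs=np.clip(probs, 0.0, 1.0))


def exact_state_distribution(theta: RateVector, t: float) -> np.ndarray:
    """Exact state distribution expm(Q t) e1 at time ``t`` years."""
    if t < 0:
        raise ValueError("time must be non-negative")
    Q = build_generator(theta)
    p0 = np.zeros(N_STATES)
    p0[0] = 1.0
    return expm(Q * t) @ p0
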
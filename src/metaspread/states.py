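"""The 16-state metastasis seeding network.

Four metastatic sites (bone, lung, liver, brain) are binary nodes; a node
that has turned positive stays positive, so the disease state is one of the
2**4 = 16 site combinations.  Transitions add exactly one site at a time.
Six dissemination rates drive the network: four primary-seeding rates from
the breast tumor (``tubo``, ``tulu``, ``tuli``, ``tubr`` to bone, lung,
liver and brain) and two secondary-seeding rates out of an established lung
metastasis (``luli`` to liver, ``lubr`` to brain).  All rates are per year.

State indices follow the published figure's 1-16 numbering (state 1 = no
metastases, state 16 = all four sites, state 7 = bone+brain "1001" with
flag order bone/lung/liver/brain).  The index <-> flag mapping is not
tabulated anywhere; it is reconstructed here by constraint propagation from
the transition list and its uniqueness is asserted in the test suite.

Generator-matrix orientation: ``Q[i, j]`` is the rate of moving *from*
state ``j+1`` *to* state ``i+1`` (column-to-row), so the master equation
reads ``dP/dt = Q @ P`` with column sums of ``Q`` equal to zero.  This is
the transpose of the convention many CTMC texts use; it is fixed by the
model's published equations and stated here once.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
import math

import numpy as np

SITES = ("bone", "lung", "liver", "brain")
RATE_NAMES = ("tubo", "tulu", "tuli", "tubr", "luli", "lubr")
N_STATES = 16

#: primary seeding: tumor -> site
PRIMARY_RATE = {"bone": "tubo", "lung": "tulu", "liver": "tuli", "brain": "tubr"}
#: secondary seeding: lung metastasis -> site
LUNG_RATE = {"liver": "luli", "brain": "lubr"}

# Allowed ordered transitions (from_index, to_index, rate expression).
# Two entries are corrected relative to the published caption, which is
# internally inconsistent: 10 -> 13 adds the lung (rate tulu, not
# tuli+luli -- state 10 is already liver-positive) and 15 -> 16 adds the
# bone (tubo; "lubo" is not one of the six parameters).
TRANSITION_TABLE: tuple[tuple[int, int, str], ...] = (
    (1, 2, "tuli"),
    (1, 3, "tubr"),
    (1, 4, "tulu"),
    (1, 5, "tubo"),
    (2, 6, "tulu"),
    (2, 10, "tubo"),
    (2, 11, "tubr"),
    (3, 7, "tubo"),
    (3, 9, "tulu"),
    (3, 11, "tuli"),
    (4, 6, "tuli+luli"),
    (4, 8, "tubo"),
    (4, 9, "tubr+lubr"),
    (5, 7, "tubr"),
    (5, 8, "tulu"),
    (5, 10, "tuli"),
    (6, 13, "tubo"),
    (6, 15, "tubr+lubr"),
    (7, 12, "tuli"),
    (7, 14, "tulu"),
    (8, 13, "tuli+luli"),
    (8, 14, "tubr+lubr"),
    (9, 14, "tubo"),
    (9, 15, "tuli+luli"),
    (10, 12, "tubr"),
    (10, 13, "tulu"),
    (11, 12, "tubo"),
    (11, 15, "tulu"),
    (12, 16, "tulu"),
    (13, 16, "tubr+lubr"),
    (14, 16, "tuli+luli"),
    (15, 16, "tubo"),
)


@dataclass(frozen=True)
class RateVector:
    """The six dissemination rates, per year.

    Component order everywhere in the package is
    ``(tubo, tulu, tuli, tubr, luli, lubr)``.
    """

    tubo: float
    tulu: float
    tuli: float
    tubr: float
    luli: float
    lubr: float

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"dissemination rate {name!r} must be finite and >= 0, got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in RATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "RateVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (6,):
            raise ValueError(f"expected 6 rates, got shape {arr.shape}")
        return cls(*arr.tolist())

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in RATE_NAMES}

    def scaled(self, factor: float) -> "RateVector":
        return RateVector.from_array(self.as_array() * factor)


@dataclass(frozen=True)
class MetastasisState:
    """One of the 16 site combinations, with its published 1-16 index."""

    index: int
    bone: int
    lung: int
    liver: int
    brain: int

    @property
    def flags(self) -> tuple[int, int, int, int]:
        return (self.bone, self.lung, self.liver, self.brain)

    @property
    def n_sites(self) -> int:
        return sum(self.flags)

    @classmethod
    def from_index(cls, index: int) -> "MetastasisState":
        return enumerate_states()[index - 1]

    @classmethod
    def from_flags(cls, bone: int, lung: int, liver: int, brain: int) -> "MetastasisState":
        return enumerate_states()[state_index_from_flags(bone, lung, liver, brain) - 1]


def _added_site(expr: str) -> str:
    """Site added by a transition, read off its rate expression."""
    names = expr.split("+")
    for site, rate in PRIMARY_RATE.items():
        if rate in names:
            return site
    raise ValueError(f"no primary rate in expression {expr!r}")


@lru_cache(maxsize=1)
def _flag_table() -> dict[int, tuple[int, int, int, int]]:
    """Reconstruct the index -> flags bijection from the transition list.

    Starting from state 1 = (0,0,0,0), each listed transition adds the site
    named by its rate expression; propagating until fixed point pins down
    all 16 states.  Any inconsistency or non-bijectivity raises.
    """
    flags: dict[int, tuple[int, int, int, int]] = {1: (0, 0, 0, 0)}
    changed = True
    while changed:
        changed = False
        for frm, to, expr in TRANSITION_TABLE:
            if frm not in flags:
                continue
            site_pos = SITES.index(_added_site(expr))
            f = list(flags[frm])
            if f[site_pos] == 1:
                raise RuntimeError(
                    f"transition {frm}->{to} ({expr}) re-adds an existing site"
                )
            f[site_pos] = 1
            new = tuple(f)
            if to in flags:
                if flags[to] != new:
                    raise RuntimeError(
                        f"inconsistent flags for state {to}: {flags[to]} vs {new}"
                    )
            else:
                flags[to] = new
                changed = True
    if len(flags) != N_STATES or len(set(flags.values())) != N_STATES:
        raise RuntimeError("transition list does not determine a 16-state bijection")
    return flags


@lru_cache(maxsize=1)
def enumerate_states() -> tuple[MetastasisState, ...]:
    """All 16 states in index order 1..16."""
    table = _flag_table()
    return tuple(
        MetastasisState(index=i, bone=f[0], lung=f[1], liver=f[2], brain=f[3])
        for i, f in ((i, table[i]) for i in range(1, N_STATES + 1))
    )


@lru_cache(maxsize=1)
def _index_by_flags() -> dict[tuple[int, int, int, int], int]:
    return {s.flags: s.index for s in enumerate_states()}


def state_index_from_flags(bone: int, lung: int, liver: int, brain: int) -> int:
    key = (int(bone), int(lung), int(liver), int(brain))
    if any(v not in (0, 1) for v in key):
        raise ValueError(f"site flags must be 0/1, got {key}")
    return _index_by_flags()[key]


def rate_expression_value(expr: str, theta: RateVector) -> float:
    return float(sum(getattr(theta, name) for name in expr.split("+")))


def transition_rate(
    from_state: MetastasisState, to_state: MetastasisState, theta: RateVector
) -> float:
    """Rate of the single-site transition ``from_state -> to_state``.

    Zero unless ``to_state`` equals ``from_state`` with exactly one extra
    positive site *k*; then the tumor->k rate, plus the lung->k rate when
    the lung is already positive and k is liver or brain.
    """
    diff = [t - f for f, t in zip(from_state.flags, to_state.flags)]
    if any(d < 0 for d in diff) or sum(diff) != 1:
        return 0.0
    site = SITES[diff.index(1)]
    rate = getattr(theta, PRIMARY_RATE[site])
    if from_state.lung and site in LUNG_RATE:
        rate += getattr(theta, LUNG_RATE[site])
    return float(rate)


def build_generator(theta: RateVector) -> np.ndarray:
    """16x16 rate generator Q with Q[i, j] = rate of (j+1) -> (i+1).

    Column sums are zero; the all-sites state (index 16) is absorbing, so
    its column is identically zero.
    """
    if not isinstance(theta, RateVector):
        theta = RateVector.from_array(theta)
    sts = enumerate_states()
    Q = np.zeros((N_STATES, N_STATES))
    for j, sj in enumerate(sts):
        for i, si in enumerate(sts):
            if i != j:
                Q[i, j] = transition_rate(sj, si, theta)
        Q[j, j] = -Q[:, j].sum()
    return Q


def edge_list(theta: RateVector | None = None):
    """Edge list of allowed transitions as a pandas DataFrame.

    Columns: from_index, to_index, rate_expression and, when ``theta`` is
    given, the numeric rate.
    """
    import pandas as pd

    rows = [
        {"from_index": f, "to_index": t, "rate_expression": e}
        for f, t, e in TRANSITION_TABLE
    ]
    df = pd.DataFrame(rows)
    if theta is not None:
        df["rate_per_year"] = [
            rate_expression_value(e, theta) for _, _, e in TRANSITION_TABLE
        ]
    return df


def to_dot(theta: RateVector | None = None) -> str:
    """GraphViz DOT rendering of the state network."""
    lines = ["digraph metastasis_states {", "  rankdir=LR;"]
    for s in enumerate_states():
        label = f"{s.index}\\n{''.join(str(v) for v in s.flags)}"
        lines.append(f'  s{s.index} [label="{label}"];')
    for f, t, e in TRANSITION_TABLE:
        lab = e
        if theta is not None:
            lab = f"{e}={rate_expression_value(e, theta):.4g}"
        lines.append(f'  s{f} -> s{t} [label="{lab}"];')
    lines.append("}")
    return "\n".join(lines)
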
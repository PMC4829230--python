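"""Cell-to-cell heterogeneity, growth bookkeeping, and QS classification.

Heterogeneity is imposed by assigning one chosen parameter per cell from
a lognormal distribution once, at birth; the value is then held for that
cell's lifetime (it stands for the cell's average over the simulated
window). The distribution is parameterized by the mean (or median) and
standard deviation of its logarithm; the base of that logarithm is
explicit because the two conventions in circulation differ: a sigma of
0.0225 applied to the base-10 logarithm gives a coefficient of variation
of 0.052, whereas applied to the natural logarithm it gives 0.0225.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from pydantic import BaseModel, model_validator

__all__ = [
    "HeterogeneitySpec",
    "GrowthSpec",
    "CellAgent",
    "sample_parameter",
    "assign_doubling_time",
    "divide",
    "classify_lsr",
    "VARIABLE_PARAMETERS",
]

#: parameters that may carry cell-to-cell heterogeneity
VARIABLE_PARAMETERS = ("basal", "K_synth", "V_ydgG", "r_basal")


class HeterogeneitySpec(BaseModel):
    """Lognormal cell-to-cell distribution of one parameter."""

    target: str = "basal"
    mu: float | None = None  # mean of the distribution's logarithm
    median: float | None = 487.8  # equivalently base**mu
    sigma: float = 0.0225  # sd of the logarithm
    log_base: Literal["e", "10"] = "e"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "HeterogeneitySpec":
        if self.target not in VARIABLE_PARAMETERS:
            raise ValueError(
                f"HeterogeneitySpec.target must be one of {VARIABLE_PARAMETERS}, "
                f"got {self.target!r}"
            )
        if (self.mu is None) == (self.median is None):
            raise ValueError("supply exactly one of HeterogeneitySpec.mu / median")
        if self.sigma < 0:
            raise ValueError("HeterogeneitySpec.sigma must be >= 0")
        if self.median is not None and self.median <= 0:
            raise ValueError("HeterogeneitySpec.median must be > 0")
        return self

    @property
    def ln_scale(self) -> float:
        """ln(base) of the stated logarithm."""
        return 1.0 if self.log_base == "e" else math.log(10.0)

    @property
    def median_value(self) -> float:
        if self.median is not None:
            return self.median
        return math.exp(self.mu * self.ln_scale)

    @property
    def sigma_ln(self) -> float:
        """sigma expressed on the natural logarithm."""
        return self.sigma * self.ln_scale

    def cv(self) -> float:
        """Closed-form coefficient of variation, sqrt(exp(s^2) - 1)."""
        s = self.sigma_ln
        return math.sqrt(math.expm1(s * s))


class GrowthSpec(BaseModel):
    """Population growth as a supplied constant specific growth rate."""

    growth_rate: float = math.log(2.0) / 60.0  # 1/min (60 min doubling)
    cv_doubling: float = 0.05  # relative cell-to-cell spread
    floor: float = 1.0  # min, truncation floor for drawn doubling times
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GrowthSpec":
        if self.growth_rate <= 0:
            raise ValueError("GrowthSpec.growth_rate must be > 0")
        if self.cv_doubling < 0:
            raise ValueError("GrowthSpec.cv_doubling must be >= 0")
        return self

    @property
    def mean_doubling(self) -> float:
        return math.log(2.0) / self.growth_rate


@dataclass
class CellAgent:
    """One cell of the agent-based simulation."""

    id: int
    position: tuple[float, float]
    params: dict[str, float] = field(default_factory=dict)  # per-cell overrides
    model_state: object = None  # LsrCellState or LuxCellState
    T0_ref: float = 0.0  # transporter reference for the fold rule
    doubling_time: float = 60.0  # min
    division_counter: float = 60.0  # min remaining
    qs_active: bool = False


def sample_parameter(
    spec: HeterogeneitySpec, n: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` positive per-cell values of the target parameter.

    Reproducible given the spec's seed; with sigma = 0 every value equals
    the median exactly.
    """
    if n < 1:
        raise ValueError("sample_parameter: n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    med = spec.median_value
    if spec.sigma == 0:
        return np.full(n, med)
    return med * np.exp(spec.sigma_ln * rng.standard_normal(n))


def assign_doubling_time(
    spec: GrowthSpec, rng: np.random.Generator | None = None, n: int | None = None
):
    """Per-cell doubling time(s): Normal(ln2/rate, cv * ln2/rate),
    truncated at a small positive floor."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mean = spec.mean_doubling
    scalar = n is None
    m = 1 if scalar else n
    if spec.cv_doubling == 0:
        out = np.full(m, mean)
    else:
        out = np.maximum(rng.normal(mean, spec.cv_doubling * mean, size=m), spec.floor)
    return float(out[0]) if scalar else out


def divide(
    parent: CellAgent,
    het: HeterogeneitySpec,
    growth: GrowthSpec,
    rng: np.random.Generator,
    position=None,
    new_id: int | None = None,
) -> CellAgent:
    """Produce a daughter at a division event, resetting the parent.

    The daughter copies the parent's model state, QS flag, and reference
    transporter level, but draws a fresh value of the varied parameter
    and a fresh doubling time; its position is assigned by the engine's
    placement rule (passed in). The parent's division counter resets.
    """
    fresh = float(sample_parameter(het, 1, rng)[0])
    params = dict(parent.params)
    params[het.target] = fresh
    daughter = CellAgent(
        id=new_id if new_id is not None else parent.id + 1,
        position=position if position is not None else parent.position,
        params=params,
        model_state=replace(parent.model_state)
        if parent.model_state is not None
        else None,
        T0_ref=parent.T0_ref,
        doubling_time=assign_doubling_time(growth, rng),
        qs_active=parent.qs_active,
    )
    daughter.division_counter = daughter.doubling_time
    parent.division_counter = parent.doubling_time
    return daughter


def classify_lsr(cell: CellAgent, activation_fold: float = 5.0) -> bool:
    """QS-positive when the transporter level strictly exceeds
    ``activation_fold`` times the cell's initial reference.

    Classification is bookkeeping only: it never feeds back on the
    dynamics.
    """
    if cell.T0_ref <= 0:
        raise ValueError("classify_lsr: T0_ref must be > 0")
    return cell.model_state.T > activation_fold * cell.T0_ref
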
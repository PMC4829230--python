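"""Heuristic LuxIR/AHL cell model.

Rather than resolving LuxI/LuxR protein species, the circuit's essential
features are captured directly: a baseline AHL synthesis rate, a
threshold of intracellular AHL above which synthesis ramps linearly to
its maximum over a fixed delay (standing in for the cooperativity and
the transcription/translation lag of the real positive-feedback loop),
and conductance-driven exchange of the membrane-permeable AHL with the
local extracellular space. The ramp is latched: once the threshold has
been crossed, a later dip of intracellular AHL below it does not reset
the commitment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from pydantic import BaseModel, model_validator

__all__ = ["LuxCellState", "LuxParams", "lux_step", "classify_lux"]


@dataclass
class LuxCellState:
    """State of one LuxIR cell."""

    AHL_in: float = 0.0  # uM, intracellular AHL
    synth_rate: float = 1.0  # uM/min, current AHL synthesis rate
    t_since_threshold: float | None = None  # min since first crossing


class LuxParams(BaseModel):
    """LuxIR circuit constants."""

    r_basal_mean: float = 1.0  # uM/min, mean baseline AHL synthesis
    sigma: float = 0.0225  # lognormal spread of r_basal across cells
    threshold: float = 2.9  # uM, intracellular AHL induction threshold
    r_max: float = 10.0  # uM/min, maximal AHL synthesis
    ramp: float = 30.0  # min, linear ramp duration to r_max
    conductivity: float = 0.6  # 1/min, membrane exchange coefficient
    degradation: float = 0.0  # 1/min, optional AHL loss (none by default)
    active_fold: float = 5.0  # classification: synth_rate >= fold * basal

    @model_validator(mode="after")
    def _check(self) -> "LuxParams":
        if self.r_max <= self.r_basal_mean:
            raise ValueError("LuxParams.r_max must exceed r_basal_mean")
        if self.threshold <= 0:
            raise ValueError("LuxParams.threshold must be > 0")
        if self.conductivity <= 0:
            raise ValueError("LuxParams.conductivity must be > 0")
        for name in ("r_basal_mean", "sigma", "ramp", "degradation", "active_fold"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"LuxParams.{name} must be finite and >= 0")
        return self


def ramp_rate(t_since_threshold: float, r_basal: float, params: LuxParams) -> float:
    """Synthesis rate a time ``t_since_threshold`` after the crossing."""
    frac = min(t_since_threshold / params.ramp, 1.0) if params.ramp > 0 else 1.0
    return r_basal + (params.r_max - r_basal) * frac


def lux_step(
    state: LuxCellState,
    params: LuxParams,
    Ae_local: float,
    dt: float,
    r_basal: float | None = None,
) -> tuple[LuxCellState, float]:
    """Advance one LuxIR cell by ``dt`` minutes.

    Synthesis adds ``synth_rate * dt`` to intracellular AHL; membrane
    flux ``conductivity * (AHL_in - Ae_local) * dt`` leaves the cell
    (negative flux means net uptake). If the threshold was crossed at
    any prior step, the synthesis rate follows the latched linear ramp.

    Returns the new state and the net AHL exchanged with the
    environment, in uM on the cell-volume basis (positive = secreted);
    multiply by the cell volume for an amount.
    """
    if dt <= 0:
        raise ValueError("lux_step: dt must be > 0")
    if Ae_local < 0:
        raise ValueError("lux_step: Ae_local must be >= 0")
    if r_basal is None:
        r_basal = params.r_basal_mean

    t_since = state.t_since_threshold
    if t_since is not None:
        t_since += dt
        rate = ramp_rate(t_since, r_basal, params)
    else:
        rate = r_basal

    a = state.AHL_in + rate * dt
    flux = params.conductivity * (a - Ae_local) * dt
    flux = min(flux, a)  # cannot export more than the cell holds
    a -= flux
    if params.degradation > 0:
        a *= math.exp(-params.degradation * dt)

    if t_since is None and a > params.threshold:
        t_since = 0.0  # latch; ramp starts now and never resets

    return LuxCellState(AHL_in=a, synth_rate=rate, t_since_threshold=t_since), flux


def classify_lux(
    state: LuxCellState, r_basal_cell: float, params: LuxParams
) -> bool:
    """A LuxIR cell is active when AHL production reaches
    ``active_fold`` times its own baseline rate."""
    if r_basal_cell <= 0:
        raise ValueError("classify_lux: r_basal_cell must be > 0")
    return state.synth_rate >= params.active_fold * r_basal_cell
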
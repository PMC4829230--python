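"""The Lsr/AI-2 signaling ODE system.

One cell carries five states: local extracellular AI-2 ``Ae``,
intracellular AI-2 ``Ai``, phospho-AI-2 ``Ap``, lsr transcript ``M`` and
Lsr transporter protein ``T`` (all uM; ``M`` in uM-equivalent transcript
units). LsrR repression is folded into the Hill transcription term: the
de-repressing species is phospho-AI-2, which sequesters LsrR, so
transcription is written directly as an increasing Hill function of
``Ap``. (An explicit free-repressor state is the documented alternative;
it adds a fast binding equilibrium without changing the slow dynamics.)

Network topology:

* AI-2 is synthesized intracellularly via the activated methyl cycle at
  rate ``K_synth``, independent of Lsr activity, and reaches the medium
  through YdgG/TqsA export.
* Low-affinity ("basal") import and transporter-proportional induced
  import move extracellular AI-2 into the cell; YdgG exports
  intracellular AI-2 (nascent or re-imported alike).
* LsrK phosphorylates intracellular AI-2; phospho-AI-2 de-represses lsr
  transcription (positive intracellular feedback) while induced import
  depletes the shared pool (negative intercellular feedback).

Every influence is a named entry in :data:`TERMS` so each is testable in
isolation; :func:`lsr_rhs` only assembles them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dataclass_fields
from typing import Callable

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.integrate import solve_ivp

__all__ = [
    "LsrCellState",
    "LsrParams",
    "TERMS",
    "lsr_rhs",
    "integrate_batch",
    "two_cell_shared_pool",
    "exponential_density",
    "OD600_CELLS_PER_ML",
    "load_sbml",
    "save_sbml",
]

#: cells per mL per OD600 unit (standard E. coli conversion)
OD600_CELLS_PER_ML = 8.0e8
#: cell volume, um^3
CELL_VOLUME = 1.0


@dataclass
class LsrCellState:
    """Concentrations of one Lsr cell (uM)."""

    Ae: float = 0.0  # extracellular AI-2 local to the cell
    Ai: float = 0.0  # intracellular AI-2
    Ap: float = 0.0  # phospho-AI-2
    M: float = 0.0  # lsr transcript
    T: float = 0.0  # Lsr transporter protein

    def as_array(self) -> np.ndarray:
        return np.array([self.Ae, self.Ai, self.Ap, self.M, self.T])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "LsrCellState":
        return cls(*map(float, y))

    def validate(self) -> "LsrCellState":
        for f in dataclass_fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"LsrCellState.{f.name} must be finite and >= 0, got {v!r}"
                )
        return self


class LsrParams(BaseModel):
    """Rate constants of the Lsr/AI-2 network.

    Defaults are calibrated to uninduced batch-culture behavior: with
    growth from an OD600-equivalent of 0.03 (60 min doubling, minimal
    medium), extracellular AI-2 accumulates over hours and autoinduction
    (abrupt lsr transcription and the extracellular-to-intracellular shift
    of AI-2) occurs shortly after the 4 hour mark, after which the shared
    pool collapses roughly two hundred-fold. The basal import median
    487.8 uM/min is the population median used throughout.
    """

    K_synth: float = 60.0  # uM/min, intracellular AI-2 synthesis
    V_ydgG: float = 4.0  # 1/min, AI-2 export rate constant
    basal: float = 487.8  # uM/min, low-affinity import Vmax
    K_b: float = 100.0  # uM, half-saturation of basal import
    k_phos: float = 1.0  # 1/min, LsrK phosphorylation
    d_Ap: float = 0.2  # 1/min, phospho-AI-2 degradation (LsrG/F path)
    alpha0: float = 6e-5  # uM/min, basal lsr transcription leak
    alpha1: float = 1.0  # uM/min, fully de-repressed transcription
    k2: float = 480.0  # uM, Hill half-saturation of Ap de-repression
    hill: float = 4.0  # Hill coefficient
    d_M: float = 1.0  # 1/min, transcript decay
    k_T: float = 70.0  # 1/min, translation per transcript
    d_T: float = 0.7  # 1/min, transporter turnover
    V_ind: float = 200.0  # 1/(uM*min), induced import Vmax per transporter
    K_ind: float = 0.3  # uM, half-saturation of induced import
    activation_fold: float = 5.0  # QS-positive threshold on T vs initial
    extras: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "LsrParams":
        for name in (
            "K_synth", "V_ydgG", "basal", "K_b", "k_phos", "d_Ap", "alpha0",
            "alpha1", "k2", "hill", "d_M", "k_T", "d_T", "V_ind", "K_ind",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"LsrParams.{name} must be finite and >= 0")
        if self.activation_fold <= 1:
            raise ValueError("LsrParams.activation_fold must be > 1")
        return self

    def initial_state(self, Ae: float = 0.0) -> LsrCellState:
        """Uninduced steady state at negligible extracellular AI-2.

        Intracellular synthesis balances export plus phosphorylation, so
        cells carry a baseline of intracellular and phospho-AI-2 (and the
        correspondingly small transcript/transporter levels) before any
        signal accumulates outside.
        """
        Ai0 = (
            self.K_synth / (self.V_ydgG + self.k_phos)
            if self.V_ydgG + self.k_phos > 0
            else 0.0
        )
        Ap0 = self.k_phos * Ai0 / self.d_Ap if self.d_Ap > 0 else 0.0
        s = LsrCellState(Ae=Ae, Ai=Ai0, Ap=Ap0, M=0.0, T=0.0)
        M0 = transcription(s, self) / self.d_M if self.d_M > 0 else 0.0
        T0 = self.k_T * M0 / self.d_T if self.d_T > 0 else 0.0
        s.M = M0
        s.T = T0
        return s


# --- term registry -------------------------------------------------------
# Each term maps (state, params) -> flux in uM/min on the cell basis.

def synthesis(s: LsrCellState, p: LsrParams) -> float:
    """Intracellular AI-2 synthesis by the activated methyl cycle."""
    return p.K_synth


def basal_import(s: LsrCellState, p: LsrParams) -> float:
    """Low-affinity AI-2 import (ribose/PTS routes), saturable."""
    return p.basal * s.Ae / (p.K_b + s.Ae)


def induced_import(s: LsrCellState, p: LsrParams) -> float:
    """Lsr transporter import, proportional to T, saturable in Ae."""
    return p.V_ind * s.T * s.Ae / (p.K_ind + s.Ae)


def export(s: LsrCellState, p: LsrParams) -> float:
    """AI-2 export through YdgG/TqsA."""
    return p.V_ydgG * s.Ai


def phosphorylation(s: LsrCellState, p: LsrParams) -> float:
    """LsrK phosphorylation of intracellular AI-2."""
    return p.k_phos * s.Ai


def ap_degradation(s: LsrCellState, p: LsrParams) -> float:
    """Phospho-AI-2 catabolism."""
    return p.d_Ap * s.Ap


def transcription(s: LsrCellState, p: LsrParams) -> float:
    """lsr transcription: basal leak + Hill de-repression by phospho-AI-2."""
    if s.Ap <= 0:
        return p.alpha0
    aph = s.Ap**p.hill
    return p.alpha0 + p.alpha1 * aph / (p.k2**p.hill + aph)


def mrna_decay(s: LsrCellState, p: LsrParams) -> float:
    return p.d_M * s.M


def translation(s: LsrCellState, p: LsrParams) -> float:
    return p.k_T * s.M


def transporter_decay(s: LsrCellState, p: LsrParams) -> float:
    return p.d_T * s.T


TERMS: dict[str, Callable[[LsrCellState, LsrParams], float]] = {
    "synthesis": synthesis,
    "basal_import": basal_import,
    "induced_import": induced_import,
    "export": export,
    "phosphorylation": phosphorylation,
    "ap_degradation": ap_degradation,
    "transcription": transcription,
    "mrna_decay": mrna_decay,
    "translation": translation,
    "transporter_decay": transporter_decay,
}


def lsr_rhs(
    state: LsrCellState, params: LsrParams, volume_ratio: float
) -> LsrCellState:
    """Instantaneous time-derivative of every state field (uM/min).

    ``volume_ratio`` is cell volume over extracellular volume share, so
    every AI-2 molecule crossing the membrane appears on the other side
    scaled by it; synthesis (a source) and phospho-AI-2 degradation (a
    sink) are the only unbalanced AI-2 terms.
    """
    state.validate()
    if volume_ratio < 0 or not math.isfinite(volume_ratio):
        raise ValueError("volume_ratio must be finite and >= 0")
    imp = basal_import(state, params) + induced_import(state, params)
    exp_f = export(state, params)
    return LsrCellState(
        Ae=volume_ratio * (exp_f - imp),
        Ai=synthesis(state, params) + imp - exp_f - phosphorylation(state, params),
        Ap=phosphorylation(state, params) - ap_degradation(state, params),
        M=transcription(state, params) - mrna_decay(state, params),
        T=translation(state, params) - transporter_decay(state, params),
    )


def exponential_density(
    od600: float = 0.03,
    doubling_time: float = 60.0,
    cells_per_ml_per_od: float = OD600_CELLS_PER_ML,
) -> Callable[[float], float]:
    """Cell volume fraction vs time (min) for exponential batch growth."""
    phi0 = od600 * cells_per_ml_per_od * CELL_VOLUME * 1e-12  # um^3 -> mL
    mu = math.log(2.0) / doubling_time
    return lambda t: phi0 * math.exp(mu * t)


def _rhs_vec(t, y, p: LsrParams, vr_of_t) -> np.ndarray:
    Ae, Ai, Ap, M, T = y
    Ae = max(Ae, 0.0)
    Ai = max(Ai, 0.0)
    Ap = max(Ap, 0.0)
    vr = vr_of_t(t)
    imp = p.basal * Ae / (p.K_b + Ae) + p.V_ind * T * Ae / (p.K_ind + Ae)
    exp_f = p.V_ydgG * Ai
    phos = p.k_phos * Ai
    aph = Ap**p.hill
    trans = p.alpha0 + p.alpha1 * aph / (p.k2**p.hill + aph)
    return np.array(
        [
            vr * (exp_f - imp),
            p.K_synth + imp - exp_f - phos,
            phos - p.d_Ap * Ap,
            trans - p.d_M * M,
            p.k_T * M - p.d_T * T,
        ]
    )


def integrate_batch(
    params: LsrParams,
    cell_density_series: Callable[[float], float] | None = None,
    t_end: float = 400.0,
    *,
    initial_state: LsrCellState | None = None,
    n_points: int = 2001,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Integrate a well-mixed batch culture of identical Lsr cells.

    The population is represented by one cell coupled to the shared
    extracellular pool through the time-dependent cell volume fraction
    ``cell_density_series(t)`` (default: exponential growth from an
    OD600-equivalent of 0.03 with 60 min doubling). Uses a stiff-capable
    implicit integrator (LSODA) as the reference solver.

    Returns a tidy DataFrame with columns ``time, Ae, Ai, Ap, M, T``
    (time in min, concentrations uM).
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if cell_density_series is None:
        cell_density_series = exponential_density()
    y0 = (initial_state or params.initial_state()).as_array()
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        _rhs_vec,
        (0.0, t_end),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        args=(params, cell_density_series),
    )
    if not sol.success:
        raise RuntimeError(f"Lsr batch integration failed: {sol.message}")
    if not np.isfinite(sol.y).all():
        bad = t_eval[np.argmax(~np.isfinite(sol.y).all(axis=0))]
        raise RuntimeError(f"non-finite state near t = {bad:.2f} min")
    return pd.DataFrame(
        {
            "time": sol.t,
            "Ae": sol.y[0],
            "Ai": sol.y[1],
            "Ap": sol.y[2],
            "M": sol.y[3],
            "T": sol.y[4],
        }
    )


def two_cell_shared_pool(
    paramsA: LsrParams,
    paramsB: LsrParams,
    t_end: float = 400.0,
    *,
    cell_density_series: Callable[[float], float] | None = None,
    n_points: int = 2001,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Two Lsr cells coupled through one shared extracellular AI-2 pool.

    Each cell represents half the (growing) population, so each couples
    to the pool with half the total volume fraction. Columns are ``time,
    Ae`` plus per-cell ``Ai_A .. T_A, Ai_B .. T_B``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if cell_density_series is None:
        cell_density_series = exponential_density()

    def rhs(t, y):
        Ae = max(y[0], 0.0)
        vr = 0.5 * cell_density_series(t)
        out = np.empty(9)
        dAe = 0.0
        for idx, p in ((0, paramsA), (4, paramsB)):
            Ai, Ap, M, T = y[1 + idx : 5 + idx]
            Ai = max(Ai, 0.0)
            Ap = max(Ap, 0.0)
            imp = p.basal * Ae / (p.K_b + Ae) + p.V_ind * T * Ae / (p.K_ind + Ae)
            exp_f = p.V_ydgG * Ai
            phos = p.k_phos * Ai
            aph = Ap**p.hill
            trans = p.alpha0 + p.alpha1 * aph / (p.k2**p.hill + aph)
            out[1 + idx] = p.K_synth + imp - exp_f - phos
            out[2 + idx] = phos - p.d_Ap * Ap
            out[3 + idx] = trans - p.d_M * M
            out[4 + idx] = p.k_T * M - p.d_T * T
            dAe += vr * (exp_f - imp)
        out[0] = dAe
        return out

    sA = paramsA.initial_state()
    sB = paramsB.initial_state()
    y0 = np.concatenate(([0.0], sA.as_array()[1:], sB.as_array()[1:]))
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise RuntimeError(f"two-cell integration failed: {sol.message}")
    cols = {"time": sol.t, "Ae": sol.y[0]}
    for tag, idx in (("A", 0), ("B", 4)):
        for k, name in enumerate(("Ai", "Ap", "M", "T")):
            cols[f"{name}_{tag}"] = sol.y[1 + idx + k]
    return pd.DataFrame(cols)


def load_sbml(path):  # re-exported; see sbml_io
    from .sbml_io import load_sbml as _load

    return _load(path)


def save_sbml(params: LsrParams, path) -> None:
    from .sbml_io import save_sbml as _save

    _save(params, path)
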
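"""2D extracellular autoinducer field: geometry, diffusion, cell exchange.

The environment is a rectangular domain discretized into square elements
of edge ``dx`` with an implied depth, so each element is a small well of
volume ``dx**2 * depth`` (24 um^3 at the 2 um / 6 um defaults). Cells read
the concentration of the element they occupy and exchange mass with it;
the field relaxes by explicit FTCS diffusion with no-flux (impermeable)
boundaries.

Units: lengths um, concentrations uM, time seconds for the diffusion
step (engine master clock), amounts uM*um^3 (= 1e-21 mol).
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, Field, model_validator

from ._kernels import ftcs_substeps

WATER_MW = 18.015  # g/mol
#: recommended association factor for water (the original 2.6 is known to
#: overpredict; 2.26 is the widely used revision)
WATER_PHI = 2.26
#: Le Bas additive molar volume of DPD (C5H8O4), cm^3/mol
DPD_LE_BAS_VOLUME = 5 * 14.8 + 8 * 3.7 + 4 * 7.4
WATER_VISCOSITY_37C = 0.69  # cP


def wilke_chang_D(
    molecular_weight: float,
    molar_volume: float,
    temperature: float,
    solvent_viscosity: float,
    association_factor: float = WATER_PHI,
) -> float:
    """Wilke-Chang estimate of a dilute solute's diffusion coefficient.

    Parameters
    ----------
    molecular_weight
        Molar mass of the *solvent* (g/mol; water: 18.015).
    molar_volume
        Le Bas additive molar volume of the solute at its normal boiling
        point (cm^3/mol).
    temperature
        Absolute temperature (K).
    solvent_viscosity
        Solvent viscosity (cP).
    association_factor
        Solvent association factor phi (2.26 for water, 1.0 for
        unassociated solvents).

    Returns
    -------
    float
        Diffusion coefficient in um^2/s.
    """
    for name, v in (
        ("molecular_weight", molecular_weight),
        ("molar_volume", molar_volume),
        ("temperature", temperature),
        ("solvent_viscosity", solvent_viscosity),
        ("association_factor", association_factor),
    ):
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"wilke_chang_D: {name} must be positive, got {v!r}")
    d_cm2_s = (
        7.4e-8
        * math.sqrt(association_factor * molecular_weight)
        * temperature
        / (solvent_viscosity * molar_volume**0.6)
    )
    return d_cm2_s * 1e8  # cm^2/s -> um^2/s


def default_autoinducer_D(temperature: float = 310.0) -> float:
    """Default D for a DPD/AI-2-scale solute in water at body temperature."""
    return wilke_chang_D(
        WATER_MW, DPD_LE_BAS_VOLUME, temperature, WATER_VISCOSITY_37C, WATER_PHI
    )


class GridSpec(BaseModel):
    """Geometry and master time step of the finite-difference environment."""

    Lx: float = 500.0  # um
    Ly: float = 500.0  # um
    dx: float = 2.0  # um, element edge
    depth: float = 6.0  # um, implied thickness
    dt_engine: float = 0.0667  # s, master time step
    D: float = Field(default_factory=default_autoinducer_D)  # um^2/s
    max_diffusion_substeps: int = 1_000_000

    @model_validator(mode="after")
    def _check(self) -> "GridSpec":
        for name in ("Lx", "Ly", "dx", "depth", "dt_engine", "D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"GridSpec.{name} must be positive")
        for L, name in ((self.Lx, "Lx"), (self.Ly, "Ly")):
            r = L / self.dx
            if abs(r - round(r)) > 1e-9:
                raise ValueError(f"GridSpec.{name} must be an integer multiple of dx")
        return self

    @property
    def nx(self) -> int:
        return round(self.Lx / self.dx)

    @property
    def ny(self) -> int:
        return round(self.Ly / self.dx)

    @property
    def element_volume(self) -> float:
        """Volume of one element, um^3 (24 at the defaults)."""
        return self.dx * self.dx * self.depth

    def n_substeps(self, dt: float) -> int:
        """Sub-steps needed so FTCS lambda = D*dt_sub/dx^2 <= 0.2.

        The linear stability bound is 0.25, but exactly at it the
        odd-even (checkerboard) mode has amplification factor -1 and
        never decays; running at 0.2 damps it."""
        lam_full = self.D * dt / self.dx**2
        n = max(1, math.ceil(lam_full / 0.2))
        if n > self.max_diffusion_substeps:
            raise ValueError(
                f"diffusion over dt={dt} s needs {n} sub-steps "
                f"(max_diffusion_substeps={self.max_diffusion_substeps}); "
                "increase dx or lower D"
            )
        return n

    def element_of(self, x: float, y: float) -> tuple[int, int]:
        """Element (i, j) containing (x, y); half-open [i*dx, (i+1)*dx)."""
        i = min(int(x / self.dx), self.nx - 1)
        j = min(int(y / self.dx), self.ny - 1)
        return i, j


class ConcentrationField:
    """Per-element autoinducer concentration (uM) on a :class:`GridSpec`.

    ``C[i, j]`` is the element spanning [i*dx, (i+1)*dx) x [j*dx, (j+1)*dx)
    um; row-major, origin at (0, 0).
    """

    def __init__(self, grid: GridSpec, C: np.ndarray | None = None):
        self.grid = grid
        if C is None:
            C = np.zeros((grid.nx, grid.ny))
        else:
            C = np.asarray(C, dtype=float)
            if C.shape != (grid.nx, grid.ny):
                raise ValueError(
                    f"field shape {C.shape} does not match grid "
                    f"({grid.nx}, {grid.ny})"
                )
            if not np.isfinite(C).all() or (C < 0).any():
                raise ValueError("field entries must be finite and >= 0")
        self.C = C

    def total_amount(self) -> float:
        """Total autoinducer in the field, uM*um^3."""
        return float(self.C.sum()) * self.grid.element_volume

    def copy(self) -> "ConcentrationField":
        return ConcentrationField(self.grid, self.C.copy())


def diffuse(field: ConcentrationField, dt: float) -> ConcentrationField:
    """Advance the field by ``dt`` seconds of diffusion, in place.

    FTCS with no-flux boundaries; the step is automatically split into
    sub-steps keeping lambda <= 0.25 (stability), and mass is conserved
    to round-off.
    """
    if dt <= 0:
        raise ValueError("diffuse: dt must be > 0")
    g = field.grid
    n_sub = g.n_substeps(dt)
    lam = g.D * (dt / n_sub) / g.dx**2
    ftcs_substeps(field.C, lam, n_sub)
    return field


def exchange(
    field: ConcentrationField,
    element_index: tuple[int, int],
    net_amount: float,
) -> float:
    """Exchange ``net_amount`` (uM*um^3, positive = into the element) with
    one element, in place.

    A withdrawal larger than the element's content is capped: the element
    goes exactly to zero and the shortfall is reported back through the
    return value (import is supply-limited).

    Returns
    -------
    float
        The amount actually added to the element (equals ``net_amount``
        unless capping engaged; always >= -content).
    """
    i, j = element_index
    g = field.grid
    if not (0 <= i < g.nx and 0 <= j < g.ny):
        raise IndexError(f"element {element_index} outside grid")
    content = field.C[i, j] * g.element_volume
    applied = net_amount if net_amount >= -content else -content
    field.C[i, j] = (content + applied) / g.element_volume
    return applied
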
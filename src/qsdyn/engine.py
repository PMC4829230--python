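"""Time-stepping engine coupling cell agents to the 2D autoinducer field.

Per master step (``dt_engine`` seconds), in fixed order:

1. motility (swim mode) — colony-mode cells move only through division;
2. per-cell signaling update over the step with the local extracellular
   concentration, fused with cell<->element exchange so that import is
   supply-limited element by element;
3. field diffusion (FTCS, automatically sub-stepped for stability);
4. division checks and daughter placement;
5. classification and recording at the configured cadence.

Two motility modes: ``swim`` (run lengths from a normal speed
distribution, uniform directions, mirror reflection at impermeable
boundaries, a three-cell-per-element density cap) and ``colony`` (cells
occupy one element each; interior divisions push a chain of cells along
the shortest path to unoccupied space, boundary divisions fill a free
adjacent element at random).

All randomness is drawn from four independent seeded streams
(placement, motility, heterogeneity, division), so a run is exactly
reproducible from its configuration.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import _kernels
from .environment import ConcentrationField, GridSpec, diffuse
from .lsr_model import CELL_VOLUME, OD600_CELLS_PER_ML, LsrParams
from .luxir_model import LuxParams
from .population import GrowthSpec, HeterogeneitySpec

__all__ = [
    "RunConfig",
    "RunRecord",
    "draw_swim_steps",
    "move_swim",
    "colony_placement",
    "run_simulation",
    "SWIM_SPEED_MEAN",
    "SWIM_SPEED_CV",
    "DENSITY_CAP",
]

SWIM_SPEED_MEAN = 20.0  # um/s
SWIM_SPEED_CV = 0.05
DENSITY_CAP = 3  # max cells per element in swim mode

#: 8-neighborhood used for colony adjacency and push chains
_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class RunConfig(BaseModel):
    """Full specification of one simulation run."""

    model: Literal["lsr", "luxir"] = "lsr"
    motility: Literal["swim", "colony"] = "swim"
    grid: GridSpec = Field(default_factory=GridSpec)
    heterogeneity: HeterogeneitySpec = Field(default_factory=HeterogeneitySpec)
    growth: GrowthSpec = Field(default_factory=GrowthSpec)
    lsr: LsrParams = Field(default_factory=LsrParams)
    lux: LuxParams = Field(default_factory=LuxParams)
    t_end: float = 400.0  # min
    initial_density: float = 0.03  # OD600-equivalent
    cells_per_ml_per_od: float = OD600_CELLS_PER_ML
    n_initial: int | None = None  # explicit override of the OD conversion
    seed: int = 0
    record_every: float = 1.0  # min
    snapshot_every: float = 10.0  # min
    cell_substeps: int = 4  # baseline sub-steps of the per-cell update

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.t_end <= 0:
            raise ValueError("RunConfig.t_end must be > 0")
        if self.initial_density <= 0:
            raise ValueError("RunConfig.initial_density must be > 0")
        if self.n_initial is not None and self.n_initial < 1:
            raise ValueError("RunConfig.n_initial must be >= 1")
        if self.record_every <= 0 or self.snapshot_every <= 0:
            raise ValueError("recording cadences must be > 0")
        if self.cell_substeps < 1:
            raise ValueError("RunConfig.cell_substeps must be >= 1")
        return self

    def initial_cell_count(self) -> int:
        if self.n_initial is not None:
            return self.n_initial
        vol_ml = self.grid.Lx * self.grid.Ly * self.grid.depth * 1e-12
        n = round(self.initial_density * self.cells_per_ml_per_od * vol_ml)
        return max(1, n)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


@dataclass
class RunRecord:
    """Everything recorded from one run; statistics are recomputable
    from this object alone."""

    config: RunConfig
    population: pd.DataFrame  # time, cell_id, x, y, qs_active, state columns
    events: pd.DataFrame  # kind, time, cell_id, parent_id, value
    assignments: pd.DataFrame  # cell_id, parameter, value
    snapshots: dict = dfield(default_factory=dict)  # time -> field array
    field_final: np.ndarray | None = None

    def times(self) -> np.ndarray:
        return np.unique(self.population["time"].to_numpy())

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.population.to_csv(out / "population.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        self.assignments.to_csv(out / "assignments.csv", index=False)
        self.config.to_yaml(out / "config.yaml")
        try:
            import h5py

            with h5py.File(out / "snapshots.h5", "w") as h5:
                for t, arr in self.snapshots.items():
                    h5.create_dataset(f"field/{t:08.1f}", data=arr)
                if self.field_final is not None:
                    h5.create_dataset("field_final", data=self.field_final)
        except ImportError:  # pragma: no cover - h5py is a hard dependency
            np.savez(out / "snapshots.npz", **{f"{t}": a for t, a in self.snapshots.items()})

    @classmethod
    def load(cls, outdir) -> "RunRecord":
        out = Path(outdir)
        cfg = RunConfig.from_yaml(out / "config.yaml")
        rec = cls(
            config=cfg,
            population=pd.read_csv(out / "population.csv"),
            events=pd.read_csv(out / "events.csv"),
            assignments=pd.read_csv(out / "assignments.csv"),
        )
        h5path = out / "snapshots.h5"
        if h5path.exists():
            import h5py

            with h5py.File(h5path) as h5:
                if "field" in h5:
                    for key in h5["field"]:
                        rec.snapshots[float(key)] = h5["field"][key][()]
                if "field_final" in h5:
                    rec.field_final = h5["field_final"][()]
        return rec


def draw_swim_steps(
    rng: np.random.Generator,
    n: int,
    dt: float,
    speed_mean: float = SWIM_SPEED_MEAN,
    speed_cv: float = SWIM_SPEED_CV,
) -> np.ndarray:
    """Step lengths (um) for one motility update of ``n`` cells.

    Speeds are Normal(speed_mean, cv * speed_mean) truncated at zero;
    the same draw feeds the engine's swim updates and any kinematics
    diagnostics."""
    return np.maximum(
        rng.normal(speed_mean * dt, speed_cv * speed_mean * dt, n), 0.0
    )


def move_swim(
    position: tuple[float, float],
    dt: float,
    grid: GridSpec,
    occupancy: np.ndarray,
    rng: np.random.Generator,
    speed_mean: float = SWIM_SPEED_MEAN,
    speed_cv: float = SWIM_SPEED_CV,
    cap: int = DENSITY_CAP,
) -> tuple[float, float]:
    """One swim update for a single cell (reference implementation).

    Step length ~ Normal(speed_mean * dt, cv), direction uniform;
    positions projected beyond a boundary are mirror-reflected about it
    (overshoot d ends d inside); a move into an element already holding
    ``cap`` cells is rejected. ``occupancy`` is updated in place.
    """
    if dt <= 0:
        raise ValueError("move_swim: dt must be > 0")
    step = max(rng.normal(speed_mean * dt, speed_cv * speed_mean * dt), 0.0)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    pos = np.array([[position[0], position[1]]], dtype=float)
    _kernels.swim_step(
        pos,
        np.array([step]),
        np.array([theta]),
        grid.Lx,
        grid.Ly,
        grid.dx,
        occupancy,
        cap,
    )
    return float(pos[0, 0]), float(pos[0, 1])


def colony_placement(
    parent_elem: tuple[int, int],
    occupied: np.ndarray,
    rng: np.random.Generator,
) -> tuple[tuple[int, int], list[tuple[tuple[int, int], tuple[int, int]]]]:
    """Choose where a colony daughter goes, possibly pushing a chain.

    ``occupied`` is a boolean element grid (True = holds a cell). For a
    parent with free adjacent elements (colony boundary), the daughter
    occupies one uniformly at random. For an interior parent, a breadth-
    first search over occupied elements finds the nearest free element
    (the shortest path to unoccupied space, staying inside the domain);
    every cell on that path shifts one element outward and the daughter
    takes the vacated slot next to the parent. Equidistant free elements
    are tie-broken uniformly from the placement stream.

    Returns the daughter's element and the list of (src, dst) moves of
    pushed cells, in application order. ``occupied`` is updated in place.
    """
    nx, ny = occupied.shape
    pi, pj = parent_elem
    if not occupied[pi, pj]:
        raise ValueError("colony_placement: parent element is not occupied")

    free_adj = [
        (pi + di, pj + dj)
        for di, dj in _NEIGHBORS
        if 0 <= pi + di < nx and 0 <= pj + dj < ny and not occupied[pi + di, pj + dj]
    ]
    if free_adj:
        daughter = free_adj[rng.integers(len(free_adj))]
        occupied[daughter] = True
        return daughter, []

    # interior parent: BFS through occupied elements to the nearest free one
    prev: dict[tuple[int, int], tuple[int, int]] = {parent_elem: parent_elem}
    frontier = deque([(parent_elem, 0)])
    best_depth = None
    goals: list[tuple[int, int]] = []
    while frontier:
        (ci, cj), depth = frontier.popleft()
        if best_depth is not None and depth >= best_depth:
            continue
        for di, dj in _NEIGHBORS:
            ni, nj = ci + di, cj + dj
            if not (0 <= ni < nx and 0 <= nj < ny) or (ni, nj) in prev:
                continue
            prev[(ni, nj)] = (ci, cj)
            if occupied[ni, nj]:
                frontier.append(((ni, nj), depth + 1))
            else:
                if best_depth is None:
                    best_depth = depth + 1
                if depth + 1 == best_depth:
                    goals.append((ni, nj))
    if not goals:
        raise RuntimeError(
            "colony_placement: no reachable free element (domain completely full)"
        )
    goal = goals[rng.integers(len(goals))]
    # path from the free slot back to the parent
    path = [goal]
    while path[-1] != parent_elem:
        path.append(prev[path[-1]])
    path.reverse()  # parent ... goal
    # shift every cell on the path one element outward, starting at the far end
    moves = []
    for k in range(len(path) - 2, 0, -1):
        moves.append((path[k], path[k + 1]))
    for src, dst in moves:
        occupied[dst] = True
        occupied[src] = False
    daughter = path[1]
    occupied[daughter] = True
    return daughter, moves


class _Population:
    """Structure-of-arrays cell store used inside the engine."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.n = 0
        self.next_id = 0
        cap = 64
        self.ids = np.zeros(cap, dtype=np.int64)
        self.pos = np.zeros((cap, 2))
        self.doubling = np.zeros(cap)
        self.counter = np.zeros(cap)
        self.qs = np.zeros(cap, dtype=bool)
        self.varied = np.zeros(cap)  # value of the heterogeneous parameter
        if cfg.model == "lsr":
            self.basal = np.zeros(cap)
            self.K_synth = np.zeros(cap)
            self.V_ydgG = np.zeros(cap)
            self.Ai = np.zeros(cap)
            self.Ap = np.zeros(cap)
            self.M = np.zeros(cap)
            self.T = np.zeros(cap)
            self.T0_ref = np.zeros(cap)
        else:
            self.r_basal = np.zeros(cap)
            self.AHL_in = np.zeros(cap)
            self.synth_rate = np.zeros(cap)
            self.t_since = np.zeros(cap)
            self.crossed = np.zeros(cap, dtype=np.int8)

    _ARRAYS = (
        "ids", "pos", "doubling", "counter", "qs", "varied",
        "basal", "K_synth", "V_ydgG", "Ai", "Ap", "M", "T", "T0_ref",
        "r_basal", "AHL_in", "synth_rate", "t_since", "crossed",
    )

    def _grow(self) -> None:
        for name in self._ARRAYS:
            if hasattr(self, name):
                arr = getattr(self, name)
                setattr(self, name, np.concatenate([arr, np.zeros_like(arr)]))

    def append_from(self, parent: int, varied_value: float, doubling: float,
                    position: np.ndarray) -> int:
        """Daughter cell: copy of parent except varied parameter,
        doubling time and position."""
        if self.n == len(self.ids):
            self._grow()
        k = self.n
        self.n += 1
        self.ids[k] = self.next_id
        self.next_id += 1
        self.pos[k] = position
        self.doubling[k] = doubling
        self.counter[k] = doubling
        self.qs[k] = self.qs[parent]
        self.varied[k] = varied_value
        cfg = self.cfg
        het = cfg.heterogeneity.target
        if cfg.model == "lsr":
            self.basal[k] = varied_value if het == "basal" else self.basal[parent]
            self.K_synth[k] = varied_value if het == "K_synth" else self.K_synth[parent]
            self.V_ydgG[k] = varied_value if het == "V_ydgG" else self.V_ydgG[parent]
            for name in ("Ai", "Ap", "M", "T", "T0_ref"):
                getattr(self, name)[k] = getattr(self, name)[parent]
        else:
            self.r_basal[k] = varied_value if het == "r_basal" else self.r_basal[parent]
            for name in ("AHL_in", "synth_rate", "t_since", "crossed"):
                getattr(self, name)[k] = getattr(self, name)[parent]
        return k


def _element_indices(pop: _Population, grid: GridSpec) -> np.ndarray:
    i = np.minimum((pop.pos[: pop.n, 0] / grid.dx).astype(np.int64), grid.nx - 1)
    j = np.minimum((pop.pos[: pop.n, 1] / grid.dx).astype(np.int64), grid.ny - 1)
    return i * grid.ny + j


def _classify(pop: _Population, cfg: RunConfig) -> np.ndarray:
    n = pop.n
    if cfg.model == "lsr":
        return pop.T[:n] > cfg.lsr.activation_fold * pop.T0_ref[:n]
    return pop.synth_rate[:n] >= cfg.lux.active_fold * pop.r_basal[:n]


def run_simulation(config: RunConfig) -> RunRecord:
    """Run one full simulation and return its record."""
    cfg = config
    grid = cfg.grid
    ss = np.random.SeedSequence(cfg.seed)
    rng_place, rng_move, rng_het, rng_div = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    het = cfg.heterogeneity.model_copy()
    growth = cfg.growth
    n0 = cfg.initial_cell_count()

    pop = _Population(cfg)
    occ = np.zeros((grid.nx, grid.ny), dtype=np.int64)  # swim-mode occupancy
    colony = np.zeros((grid.nx, grid.ny), dtype=bool)  # colony-mode occupancy

    # --- initialization -------------------------------------------------
    from .population import assign_doubling_time, sample_parameter

    positions = []
    if cfg.motility == "swim":
        # randomly distributed cells, respecting the density cap
        while len(positions) < n0:
            x = rng_place.uniform(0, grid.Lx)
            y = rng_place.uniform(0, grid.Ly)
            i, j = grid.element_of(x, y)
            if occ[i, j] < DENSITY_CAP:
                occ[i, j] += 1
                positions.append((x, y))
    else:
        # a single colony initiated at a random interior location
        ci = rng_place.integers(grid.nx // 4, 3 * grid.nx // 4)
        cj = rng_place.integers(grid.ny // 4, 3 * grid.ny // 4)
        colony[ci, cj] = True
        positions.append(((ci + 0.5) * grid.dx, (cj + 0.5) * grid.dx))
        while len(positions) < n0:
            # grow the seed block from its rim so no pushing is needed
            occ_elems = np.argwhere(colony)
            rim = [
                (i, j)
                for i, j in map(tuple, occ_elems)
                if any(
                    0 <= i + di < grid.nx
                    and 0 <= j + dj < grid.ny
                    and not colony[i + di, j + dj]
                    for di, dj in _NEIGHBORS
                )
            ]
            pe = rim[rng_place.integers(len(rim))]
            elem, _ = colony_placement(pe, colony, rng_place)
            positions.append(((elem[0] + 0.5) * grid.dx, (elem[1] + 0.5) * grid.dx))

    values = sample_parameter(het, n0, rng_het)
    doublings = assign_doubling_time(growth, rng_div, n=n0)
    offsets = rng_div.uniform(0, 1, n0)  # random phase of the division cycle
    for k in range(n0):
        if pop.n == len(pop.ids):
            pop._grow()
        pop.ids[pop.n] = pop.next_id
        pop.next_id += 1
        pop.pos[pop.n] = positions[k]
        pop.doubling[pop.n] = doublings[k]
        pop.counter[pop.n] = doublings[k] * offsets[k]
        pop.varied[pop.n] = values[k]
        pop.n += 1

    if cfg.model == "lsr":
        p = cfg.lsr
        s0 = p.initial_state()
        pop.basal[:n0] = p.basal
        pop.K_synth[:n0] = p.K_synth
        pop.V_ydgG[:n0] = p.V_ydgG
        getattr(pop, het.target)[:n0] = values
        pop.Ai[:n0] = s0.Ai
        pop.Ap[:n0] = s0.Ap
        pop.M[:n0] = s0.M
        pop.T[:n0] = s0.T
        pop.T0_ref[:n0] = s0.T
    else:
        pop.r_basal[:n0] = values
        pop.synth_rate[:n0] = values
        pop.AHL_in[:n0] = 0.0

    field = ConcentrationField(grid)
    dt_s = grid.dt_engine
    dt_min = dt_s / 60.0
    n_steps = int(round(cfg.t_end / dt_min))
    record_stride = max(1, int(round(cfg.record_every / dt_min)))
    snap_stride = max(1, int(round(cfg.snapshot_every / dt_min)))
    V_elem = grid.element_volume

    pop_rows = []
    events = []
    was_active = np.zeros(pop.n, dtype=bool)

    def record(t_now: float) -> None:
        nonlocal was_active
        n = pop.n
        active = _classify(pop, cfg)
        if len(was_active) < n:
            was_active = np.concatenate(
                [was_active, np.zeros(n - len(was_active), dtype=bool)]
            )
        newly = np.where(active & ~was_active[:n])[0]
        for k in newly:
            events.append(
                {
                    "kind": "activation",
                    "time": t_now,
                    "cell_id": int(pop.ids[k]),
                    "parent_id": -1,
                    "value": float(pop.varied[k]),
                }
            )
        was_active[:n] |= active
        pop.qs[:n] = was_active[:n]
        active = was_active[:n]  # QS commitment is one-way for reporting
        state_cols: dict[str, np.ndarray]
        if cfg.model == "lsr":
            state_cols = {
                "Ai": pop.Ai[:n],
                "Ap": pop.Ap[:n],
                "M": pop.M[:n],
                "T": pop.T[:n],
            }
        else:
            state_cols = {
                "AHL_in": pop.AHL_in[:n],
                "synth_rate": pop.synth_rate[:n],
            }
        elem = _element_indices(pop, grid)
        pop_rows.append(
            pd.DataFrame(
                {
                    "time": t_now,
                    "cell_id": pop.ids[:n].copy(),
                    "x": pop.pos[:n, 0].copy(),
                    "y": pop.pos[:n, 1].copy(),
                    "qs_active": active,
                    "Ae_local": field.C.ravel()[elem],
                    **{k: v.copy() for k, v in state_cols.items()},
                }
            )
        )

    snapshots = {}
    record(0.0)
    snapshots[0.0] = field.C.copy()

    n_sub_diff = grid.n_substeps(dt_s)
    lam = grid.D * (dt_s / n_sub_diff) / grid.dx**2

    for step in range(1, n_steps + 1):
        t_now = step * dt_min
        n = pop.n
        # (1) motility
        if cfg.motility == "swim" and n > 0:
            steps = draw_swim_steps(rng_move, n, dt_s)
            thetas = rng_move.uniform(0.0, 2.0 * math.pi, n)
            _kernels.swim_step(
                pop.pos[:n], steps, thetas, grid.Lx, grid.Ly, grid.dx, occ, DENSITY_CAP
            )
        # (2) per-cell model + exchange (supply-limited, sequential)
        elem = _element_indices(pop, grid)
        Cflat = field.C.ravel()
        if cfg.model == "lsr":
            p = cfg.lsr
            _kernels.lsr_cells_step(
                pop.Ai[:n], pop.Ap[:n], pop.M[:n], pop.T[:n],
                pop.basal[:n], pop.K_synth[:n], pop.V_ydgG[:n],
                elem, Cflat, dt_min,
                p.K_b, p.k_phos, p.d_Ap, p.alpha0, p.alpha1, p.k2, p.hill,
                p.d_M, p.k_T, p.d_T, p.V_ind, p.K_ind,
                CELL_VOLUME, V_elem, cfg.cell_substeps,
            )
        else:
            p = cfg.lux
            _kernels.lux_cells_step(
                pop.AHL_in[:n], pop.synth_rate[:n], pop.t_since[:n],
                pop.crossed[:n], pop.r_basal[:n],
                elem, Cflat, dt_min,
                p.threshold, p.r_max, p.ramp, p.conductivity,
                CELL_VOLUME, V_elem, cfg.cell_substeps,
            )
        # (3) diffusion
        _kernels.ftcs_substeps(field.C, lam, n_sub_diff)
        # (4) division
        pop.counter[:n] -= dt_min
        due = np.where(pop.counter[:n] <= 0.0)[0]
        for parent in due:
            fresh = float(sample_parameter(het, 1, rng_het)[0])
            new_doubling = assign_doubling_time(growth, rng_div)
            placed = None
            if cfg.motility == "swim":
                pi, pj = grid.element_of(pop.pos[parent, 0], pop.pos[parent, 1])
                if occ[pi, pj] < DENSITY_CAP:
                    target = (pi, pj)
                else:
                    frees = [
                        (pi + di, pj + dj)
                        for di, dj in _NEIGHBORS
                        if 0 <= pi + di < grid.nx
                        and 0 <= pj + dj < grid.ny
                        and occ[pi + di, pj + dj] < DENSITY_CAP
                    ]
                    target = tuple(frees[rng_place.integers(len(frees))]) if frees else None
                if target is not None:
                    occ[target] += 1
                    jitter = rng_place.uniform(0.0, 1.0, 2)
                    placed = np.array(
                        [
                            (target[0] + jitter[0]) * grid.dx,
                            (target[1] + jitter[1]) * grid.dx,
                        ]
                    )
            else:
                pe = grid.element_of(pop.pos[parent, 0], pop.pos[parent, 1])
                if colony.all():
                    delem, moves = None, []  # domain completely full
                else:
                    try:
                        delem, moves = colony_placement(pe, colony, rng_place)
                    except RuntimeError:
                        moves, delem = [], None
                if delem is not None:
                    # apply push-chain relocations to the stored positions
                    if moves:
                        elem_now = _element_indices(pop, grid)
                        lookup = {int(e): k for k, e in enumerate(elem_now)}
                        for (si, sj), (di_, dj_) in moves:
                            k = lookup.pop(si * grid.ny + sj)
                            pop.pos[k] = ((di_ + 0.5) * grid.dx, (dj_ + 0.5) * grid.dx)
                            lookup[di_ * grid.ny + dj_] = k
                    placed = np.array(
                        [(delem[0] + 0.5) * grid.dx, (delem[1] + 0.5) * grid.dx]
                    )
            if placed is None:
                pop.counter[parent] = 5.0  # no room: back off and retry
                continue
            pop.counter[parent] = pop.doubling[parent]
            k_new = pop.append_from(parent, fresh, new_doubling, placed)
            events.append(
                {
                    "kind": "division",
                    "time": t_now,
                    "cell_id": int(pop.ids[k_new]),
                    "parent_id": int(pop.ids[parent]),
                    "value": fresh,
                }
            )
        # (5) classification + recording
        if step % record_stride == 0 or step == n_steps:
            if not np.isfinite(field.C).all() or (
                cfg.model == "lsr"
                and not np.isfinite(pop.Ap[: pop.n]).all()
            ):
                raise RuntimeError(
                    f"non-finite state at t = {t_now:.2f} min; aborting"
                )
            record(t_now)
        if step % snap_stride == 0:
            snapshots[t_now] = field.C.copy()

    n = pop.n
    assignments = pd.DataFrame(
        {
            "cell_id": pop.ids[:n],
            "parameter": het.target,
            "value": pop.varied[:n],
        }
    )
    return RunRecord(
        config=cfg,
        population=pd.concat(pop_rows, ignore_index=True),
        events=pd.DataFrame(events, columns=["kind", "time", "cell_id", "parent_id", "value"]),
        assignments=assignments,
        snapshots=snapshots,
        field_final=field.C.copy(),
    )
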
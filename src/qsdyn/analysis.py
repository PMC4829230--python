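"""Post-processing statistics for quorum-sensing run records.

Every statistic here is computed from a :class:`~qsdyn.engine.RunRecord`
(or plain arrays) alone; nothing reaches back into engine state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .engine import RunRecord

__all__ = [
    "ActivationSeries",
    "activation_time",
    "fraction_activated",
    "aggregate_activation",
    "median_nn_distance",
    "ae_per_induced_cell",
    "induction_center_bias",
    "first_activator_stats",
    "local_heterogeneity",
]


@dataclass
class ActivationSeries:
    """Activated fraction of the population over time."""

    time: np.ndarray  # min
    fraction: np.ndarray  # in [0, 1]

    def terminal(self) -> float:
        return float(self.fraction[-1])


def activation_time(
    time: np.ndarray,
    trace: np.ndarray,
    fit_window: tuple[float, float] = (12.0, 152.0),
) -> float | None:
    """Detect the onset of autoinduction in a population-level trace.

    A first-order line ``g(t)`` is least-squares fit to the trace over
    the baseline window (12-152 min by default); the activation time is
    the earliest sample at or after the window's end where
    ``f(t) - g(t) > 2 g(t)``, i.e. where the trace exceeds three times
    its extrapolated baseline. Returns None if the criterion is never
    met. Detection starts at the end of the fit window because the
    excess-over-baseline criterion is only meaningful where the
    extrapolated baseline is established.
    """
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    t0, t1 = fit_window
    if time[-1] < t1:
        raise ValueError(
            f"trace must cover the fit window (needs t >= {t1} min)"
        )
    m = (time >= t0) & (time <= t1)
    if m.sum() < 2:
        raise ValueError("fewer than 2 samples inside the fit window")
    A = np.vstack([np.ones(m.sum()), time[m]]).T
    coef, *_ = np.linalg.lstsq(A, trace[m], rcond=None)
    g = coef[0] + coef[1] * time
    hits = np.where((trace - g > 2.0 * g) & (time >= t1))[0]
    return float(time[hits[0]]) if len(hits) else None


def fraction_activated(record: RunRecord) -> ActivationSeries:
    """Activated count over population count at every recorded time."""
    popn = record.population
    if len(popn) == 0:
        raise ValueError("fraction_activated: empty population record")
    grp = popn.groupby("time")["qs_active"]
    frac = grp.mean()
    return ActivationSeries(
        time=frac.index.to_numpy(dtype=float), fraction=frac.to_numpy(dtype=float)
    )


def aggregate_activation(records: list[RunRecord]) -> pd.DataFrame:
    """Mean and sd of the activated fraction across replicate runs,
    on the intersection of their time grids."""
    series = [fraction_activated(r) for r in records]
    common = series[0].time
    for s in series[1:]:
        common = np.intersect1d(common, s.time)
    stack = np.vstack(
        [s.fraction[np.isin(s.time, common)] for s in series]
    )
    return pd.DataFrame(
        {
            "time": common,
            "mean": stack.mean(axis=0),
            "sd": stack.std(axis=0, ddof=1) if len(series) > 1 else 0.0,
        }
    )


def median_nn_distance(positions: np.ndarray) -> float:
    """Median over cells of each cell's nearest-neighbor distance (um)."""
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 2:
        raise ValueError("median_nn_distance needs at least 2 positions")
    tree = cKDTree(positions)
    d, _ = tree.query(positions, k=2)
    return float(np.median(d[:, 1]))


def ae_per_induced_cell(record: RunRecord, t: float) -> float | None:
    """Total extracellular autoinducer divided by the induced-cell count
    at time ``t`` (uM per cell); None when no cell is induced.

    The total is the sum of element concentrations times the element
    volume, expressed back as a domain-average concentration, i.e.
    mean(C) / induced count.
    """
    popn = record.population
    times = record.times()
    if t not in times:
        raise ValueError(f"time {t} not recorded (have {times[0]}..{times[-1]})")
    at_t = popn[popn["time"] == t]
    k = int(at_t["qs_active"].sum())
    if k == 0:
        return None
    snap_t = min(record.snapshots, key=lambda s: abs(s - t)) if record.snapshots else None
    if snap_t is not None and abs(snap_t - t) <= record.config.snapshot_every:
        mean_C = float(record.snapshots[snap_t].mean())
    else:
        mean_C = float(at_t["Ae_local"].mean())
    return mean_C / k


def induction_center_bias(
    records: list[RunRecord],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Colony center vs first-activation center across replicates.

    For each record, at the time of its first activation, the centers of
    mass of all cells and of activated cells are computed. The x and y
    coordinates of all replicates are pooled into one least-squares
    regression of activation-center on colony-center (through the data,
    with intercept). Returns (colony_center_coords, activation_center
    _coords, fitted slope) where the coordinate arrays interleave x and
    y of every replicate.
    """
    cc, ac = [], []
    for rec in records:
        popn = rec.population
        act_times = popn.loc[popn["qs_active"], "time"]
        if act_times.empty:
            continue
        t1 = act_times.min()
        at_t = popn[popn["time"] == t1]
        cc.extend([at_t["x"].mean(), at_t["y"].mean()])
        on = at_t[at_t["qs_active"]]
        ac.extend([on["x"].mean(), on["y"].mean()])
    if not cc:
        raise ValueError("induction_center_bias: no record contains an activation")
    cc_arr = np.asarray(cc)
    ac_arr = np.asarray(ac)
    A = np.vstack([np.ones_like(cc_arr), cc_arr]).T
    coef, *_ = np.linalg.lstsq(A, ac_arr, rcond=None)
    return cc_arr, ac_arr, float(coef[1])


def first_activator_stats(
    records: list[RunRecord],
) -> tuple[float, float, np.ndarray]:
    """Varied-parameter value of the earliest activated cell, per
    replicate; returns (mean, sd, population_values) where
    ``population_values`` pools every assigned value for histogramming.
    """
    firsts = []
    pool = []
    for rec in records:
        pool.append(rec.assignments["value"].to_numpy())
        ev = rec.events
        acts = ev[ev["kind"] == "activation"]
        if acts.empty:
            continue
        first = acts.sort_values(["time", "cell_id"]).iloc[0]
        firsts.append(float(first["value"]))
    if not firsts:
        raise ValueError("first_activator_stats: no activation event in any record")
    firsts_arr = np.asarray(firsts)
    sd = float(firsts_arr.std(ddof=1)) if len(firsts_arr) > 1 else 0.0
    return float(firsts_arr.mean()), sd, np.concatenate(pool)


def local_heterogeneity(
    positions: np.ndarray,
    active: np.ndarray,
    radius: float = 10.0,
) -> float:
    """Spatial discordance of QS states among nearby cells.

    The fraction of cell pairs closer than ``radius`` whose QS states
    differ, normalized by ``2 p (1 - p)`` (the expectation for states
    assigned independently at random at activated fraction ``p``), so a
    spatially random arrangement scores about 1, a perfectly sorted one
    0. The score is invariant to relabeling active and inactive. This
    discordant-pair definition is this package's choice of measure; its
    null (probabilistic state assignment at the observed fraction) is
    exactly the normalization.

    Returns NaN when there are no pairs within ``radius`` or when every
    cell shares one state (p = 0 or 1).
    """
    positions = np.asarray(positions, dtype=float)
    active = np.asarray(active, dtype=bool)
    p = active.mean() if len(active) else 0.0
    if p in (0.0, 1.0):
        return 0.0 if len(active) else math.nan
    tree = cKDTree(positions)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs) == 0:
        return math.nan
    discord = (active[pairs[:, 0]] != active[pairs[:, 1]]).mean()
    return float(discord / (2.0 * p * (1.0 - p)))


def local_heterogeneity_series(
    record: RunRecord, radius: float = 10.0
) -> pd.DataFrame:
    """:func:`local_heterogeneity` at every recorded time point."""
    rows = []
    popn = record.population
    for t, at_t in popn.groupby("time"):
        score = local_heterogeneity(
            at_t[["x", "y"]].to_numpy(), at_t["qs_active"].to_numpy(), radius
        )
        rows.append({"time": t, "score": score, "fraction": at_t["qs_active"].mean()})
    return pd.DataFrame(rows)
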
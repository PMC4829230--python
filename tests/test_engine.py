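"""Engine plumbing: motility, colony placement, division, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from qsdyn.engine import (
    DENSITY_CAP,
    RunConfig,
    colony_placement,
    move_swim,
    run_simulation,
)
from qsdyn.environment import GridSpec
from qsdyn.population import GrowthSpec, HeterogeneitySpec


class TestMoveSwim:
    def test_mirror_reflection_at_boundary(self):
        """Projected x = 503 um against the 500 um wall ends at 497."""
        g = GridSpec()  # 500 x 500, dx 2

        class FixedRng:
            def normal(self, mean, sd, size=None):
                return 23.0  # step length: 480 + 23 -> 503 projected

            def uniform(self, a, b, size=None):
                return 0.0  # theta = 0: straight +x

        occ = np.zeros((g.nx, g.ny), dtype=np.int64)
        occ[g.element_of(480.0, 250.0)] += 1
        x, y = move_swim((480.0, 250.0), 1.0, g, occ, FixedRng())
        assert x == pytest.approx(497.0)
        assert y == pytest.approx(250.0)

    def test_unobstructed_move_lands_on_projection(self):
        g = GridSpec()

        class FixedRng:
            def normal(self, mean, sd, size=None):
                return 10.0

            def uniform(self, a, b, size=None):
                return math.pi / 2  # straight +y

        occ = np.zeros((g.nx, g.ny), dtype=np.int64)
        occ[g.element_of(100.0, 100.0)] += 1
        x, y = move_swim((100.0, 100.0), 1.0, g, occ, FixedRng())
        assert (x, y) == pytest.approx((100.0, 110.0))

    def test_full_element_rejects_move(self):
        g = GridSpec(Lx=20, Ly=20, dx=2.0)
        occ = np.zeros((g.nx, g.ny), dtype=np.int64)
        occ[g.element_of(5.0, 5.0)] = 1  # the moving cell
        occ[g.element_of(15.0, 5.0)] = DENSITY_CAP  # target is full

        class FixedRng:
            def normal(self, mean, sd, size=None):
                return 10.0

            def uniform(self, a, b, size=None):
                return 0.0

        x, y = move_swim((5.0, 5.0), 0.5, g, occ, FixedRng())
        assert (x, y) == (5.0, 5.0)
        assert occ[g.element_of(5.0, 5.0)] == 1

    def test_mean_step_speed_near_twenty(self, rng):
        """Empirical mean speed over 1e5 updates is 20 um/s within 3 SE."""
        from qsdyn.engine import draw_swim_steps

        dt = 0.05
        speeds = draw_swim_steps(rng, 100_000, dt) / dt
        se = speeds.std() / math.sqrt(len(speeds))
        assert abs(speeds.mean() - 20.0) < 3 * se

    def test_kernel_step_length_matches_drawn_speed(self, rng):
        """The swim kernel displaces a free cell by exactly the drawn
        step length."""
        g = GridSpec(Lx=1000.0, Ly=1000.0, dx=10.0)
        occ = np.zeros((g.nx, g.ny), dtype=np.int64)
        pos = (500.0, 500.0)
        occ[g.element_of(*pos)] = 1
        for _ in range(200):
            new = move_swim(pos, 0.05, g, occ, rng)
            d = math.hypot(new[0] - pos[0], new[1] - pos[1])
            assert 0.0 <= d < 3.0  # ~1 um steps at dt = 0.05 s
            pos = new


class TestColonyPlacement:
    def test_isolated_cell_daughter_lands_adjacent(self, rng):
        occ = np.zeros((9, 9), dtype=bool)
        occ[4, 4] = True
        daughter, moves = colony_placement((4, 4), occ, rng)
        assert moves == []
        assert max(abs(daughter[0] - 4), abs(daughter[1] - 4)) == 1
        assert occ[daughter]

    def test_rim_parent_never_overwrites_occupied(self, rng):
        occ = np.zeros((9, 9), dtype=bool)
        occ[3:6, 3:6] = True  # 3x3 block; rim cells have free neighbors
        for _ in range(50):
            trial = occ.copy()
            daughter, moves = colony_placement((3, 3), trial, rng)
            assert moves == []
            assert not occ[daughter]

    def test_interior_parent_pushes_chain_to_nearest_free(self, rng):
        occ = np.zeros((9, 9), dtype=bool)
        occ[2:7, 2:7] = True  # 5x5 block, center (4,4) is interior
        count = occ.sum()
        daughter, moves = colony_placement((4, 4), occ, rng)
        assert occ.sum() == count + 1
        assert len(moves) >= 1
        assert max(abs(daughter[0] - 4), abs(daughter[1] - 4)) == 1

    def test_division_count_equals_occupied_elements(self, rng):
        """After N division events from one founder the colony holds
        N + 1 elements."""
        occ = np.zeros((31, 31), dtype=bool)
        occ[15, 15] = True
        cells = [(15, 15)]
        for n in range(60):
            parent = cells[rng.integers(len(cells))]
            daughter, moves = colony_placement(parent, occ, rng)
            moved = dict(moves)
            cells = [moved.get(c, c) for c in cells]
            cells.append(daughter)
            assert occ.sum() == n + 2
        # occupancy grid and tracked positions agree
        assert sorted(cells) == sorted(map(tuple, np.argwhere(occ)))

    def test_unoccupied_parent_rejected(self, rng):
        occ = np.zeros((5, 5), dtype=bool)
        with pytest.raises(ValueError):
            colony_placement((2, 2), occ, rng)


class TestRunSimulation:
    def test_identical_configs_reproduce_bit_identical_records(self, quick_lsr_config):
        rec1 = run_simulation(quick_lsr_config)
        rec2 = run_simulation(quick_lsr_config)
        pd.testing.assert_frame_equal(rec1.population, rec2.population)
        pd.testing.assert_frame_equal(rec1.events, rec2.events)
        np.testing.assert_array_equal(rec1.field_final, rec2.field_final)

    def test_all_positions_inside_domain(self, quick_lsr_config):
        rec = run_simulation(quick_lsr_config)
        g = quick_lsr_config.grid
        popn = rec.population
        assert popn["x"].between(0, g.Lx).all()
        assert popn["y"].between(0, g.Ly).all()

    def test_density_cap_never_exceeded_in_swim_mode(self, quick_lsr_config):
        rec = run_simulation(quick_lsr_config)
        g = quick_lsr_config.grid
        for _, at_t in rec.population.groupby("time"):
            i = (at_t["x"] // g.dx).astype(int).clip(upper=g.nx - 1)
            j = (at_t["y"] // g.dx).astype(int).clip(upper=g.ny - 1)
            counts = pd.Series(zip(i, j)).value_counts()
            assert counts.max() <= DENSITY_CAP

    def test_colony_mode_keeps_one_cell_per_element(self):
        cfg = RunConfig(
            model="lsr",
            motility="colony",
            grid=GridSpec(Lx=60.0, Ly=60.0, dx=4.0, dt_engine=2.0, D=2.0),
            heterogeneity=HeterogeneitySpec(target="basal", median=487.8, sigma=0.01),
            n_initial=10,
            t_end=60.0,
            seed=3,
        )
        rec = run_simulation(cfg)
        g = cfg.grid
        for _, at_t in rec.population.groupby("time"):
            i = (at_t["x"] // g.dx).astype(int)
            j = (at_t["y"] // g.dx).astype(int)
            assert pd.Series(zip(i, j)).value_counts().max() == 1

    def test_population_growth_matches_exponential_oracle(self):
        """36 founders with 40 min mean doubling grow to ~72 cells in
        40 min (mean over replicates)."""
        finals = []
        for seed in range(10):
            cfg = RunConfig(
                model="lsr",
                motility="swim",
                grid=GridSpec(Lx=100.0, Ly=100.0, dx=4.0, dt_engine=2.0, D=2.0),
                heterogeneity=HeterogeneitySpec(
                    target="basal", median=487.8, sigma=0.0
                ),
                growth=GrowthSpec(growth_rate=math.log(2) / 40.0),
                n_initial=36,
                t_end=40.0,
                seed=seed,
            )
            rec = run_simulation(cfg)
            last_t = rec.times()[-1]
            finals.append((rec.population["time"] == last_t).sum())
        assert np.mean(finals) == pytest.approx(72.0, abs=6.0)

    def test_initial_count_follows_od_conversion(self):
        cfg = RunConfig()  # full-scale defaults: 0.03 OD over 1.5e-6 mL
        assert cfg.initial_cell_count() == 36

    def test_record_round_trips_through_disk(self, quick_lsr_config, tmp_path):
        rec = run_simulation(quick_lsr_config)
        rec.save(tmp_path / "run")
        loaded = type(rec).load(tmp_path / "run")
        pd.testing.assert_frame_equal(
            loaded.population, rec.population, check_dtype=False
        )
        assert loaded.config.seed == quick_lsr_config.seed


class TestCli:
    def test_missing_field_exits_with_code_two(self):
        from click.testing import CliRunner

        from qsdyn.cli import main

        out = CliRunner().invoke(
            main, ["run", "--set", "t_end=-5", "--out", "/tmp/x"]
        )
        assert out.exit_code == 2
        assert "t_end" in out.output

    def test_run_and_analyze_round_trip(self, tmp_path, quick_lsr_config):
        from click.testing import CliRunner

        from qsdyn.cli import main

        cfgfile = tmp_path / "cfg.yaml"
        quick_lsr_config.to_yaml(cfgfile)
        runner = CliRunner()
        out = runner.invoke(
            main, ["run", "--config", str(cfgfile), "--out", str(tmp_path / "rec")]
        )
        assert out.exit_code == 0, out.output
        out2 = runner.invoke(main, ["analyze", str(tmp_path / "rec")])
        assert out2.exit_code == 0, out2.output
        assert (tmp_path / "rec" / "activation.csv").exists()
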
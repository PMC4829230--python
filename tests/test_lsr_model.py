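"""Unit and property tests of the Lsr/AI-2 ODE system."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsdyn.lsr_model import (
    TERMS,
    LsrCellState,
    LsrParams,
    exponential_density,
    integrate_batch,
    load_sbml,
    lsr_rhs,
    save_sbml,
    two_cell_shared_pool,
)

VR = 1.0 / 24.0


def batch_t5x(params, t_end=420.0, dens=None):
    """Time at which transporter protein first exceeds 5x its start."""
    df = integrate_batch(params, dens, t_end=t_end)
    T = df["T"].to_numpy()
    hits = np.where(T > 5.0 * T[0])[0]
    return df["time"].iloc[hits[0]] if len(hits) else None


class TestRhs:
    def test_no_sources_no_transport_gives_zero_ai2_flux(self):
        p = LsrParams(K_synth=0.0, basal=0.0)
        s = LsrCellState(Ae=0.0, Ai=0.0, Ap=0.0, M=0.01, T=0.0)
        d = lsr_rhs(s, p, VR)
        assert d.Ae == 0.0 and d.Ai == 0.0 and d.Ap == 0.0

    def test_export_only_closes_mole_balance(self):
        p = LsrParams(K_synth=0.0, basal=0.0, k_phos=0.0, V_ydgG=3.0)
        s = LsrCellState(Ae=0.0, Ai=2.0, Ap=0.0, M=0.0, T=0.0)
        d = lsr_rhs(s, p, VR)
        assert d.Ai == pytest.approx(-6.0)
        assert d.Ae == pytest.approx(6.0 * VR)
        # balance: dAe * V_ext + dAi * V_cell = 0
        assert d.Ae / VR + d.Ai == pytest.approx(0.0, abs=1e-14)

    def test_rhs_equals_sum_of_registry_terms(self, rng):
        """Term-by-term oracle: assemble the derivative independently
        from the named term registry and compare."""
        p = LsrParams()
        for _ in range(20):
            s = LsrCellState(*rng.uniform(0.01, 40.0, 5))
            t = {name: fn(s, p) for name, fn in TERMS.items()}
            expected = LsrCellState(
                Ae=VR * (t["export"] - t["basal_import"] - t["induced_import"]),
                Ai=t["synthesis"] + t["basal_import"] + t["induced_import"]
                - t["export"] - t["phosphorylation"],
                Ap=t["phosphorylation"] - t["ap_degradation"],
                M=t["transcription"] - t["mrna_decay"],
                T=t["translation"] - t["transporter_decay"],
            )
            got = lsr_rhs(s, p, VR)
            np.testing.assert_allclose(got.as_array(), expected.as_array(), rtol=1e-12)

    def test_negative_state_rejected_with_field_name(self):
        with pytest.raises(ValueError, match="Ai"):
            lsr_rhs(LsrCellState(Ai=-1.0), LsrParams(), VR)

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError, match="k_phos"):
            LsrParams(k_phos=-0.1)

    @given(
        ae=st.floats(0.0, 100.0),
        ai=st.floats(0.0, 100.0),
        ap=st.floats(0.0, 500.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_ai2_conservation_without_synthesis_or_degradation(self, ae, ai, ap):
        """With synthesis and degradation off, transport conserves AI-2."""
        p = LsrParams(K_synth=0.0, d_Ap=0.0)
        d = lsr_rhs(LsrCellState(Ae=ae, Ai=ai, Ap=ap, M=0.1, T=1.0), p, VR)
        total_flux = d.Ae / VR + d.Ai + d.Ap
        assert total_flux == pytest.approx(0.0, abs=1e-10)


class TestBatch:
    def test_baseline_activates_after_four_hours_with_ae_collapse(self, lsr_params):
        df = integrate_batch(lsr_params, t_end=420.0)
        T = df["T"].to_numpy()
        Ae = df["Ae"].to_numpy()
        t = df["time"].to_numpy()
        t5 = t[np.where(T > 5 * T[0])[0][0]]
        assert t5 > 240.0  # autoinduction after the 4 h mark
        ipk = Ae.argmax()
        assert t[ipk] > 200.0  # extracellular AI-2 peaks late...
        assert Ae[-1] < 0.05 * Ae[ipk]  # ...then collapses
        # transcript rise is abrupt: M spans a large fold change
        M = df["M"].to_numpy()
        assert M.max() / M[0] > 100.0

    def test_no_synthesis_means_no_signal_and_no_induction(self):
        p = LsrParams(K_synth=0.0)
        df = integrate_batch(p, t_end=200.0)
        assert df["Ap"].max() == pytest.approx(0.0, abs=1e-8)
        assert df["M"].iloc[-1] == pytest.approx(df["M"].iloc[0], rel=1e-3)

    def test_positivity_of_all_states(self, lsr_params):
        df = integrate_batch(lsr_params, t_end=420.0)
        assert (df[["Ae", "Ai", "Ap", "M", "T"]].to_numpy() >= -1e-9).all()

    @pytest.mark.parametrize(
        "name,lo,hi,earlier_at_high",
        [
            ("basal", 440.0, 540.0, True),
            ("K_synth", 54.0, 66.0, True),
            ("k_phos", 0.9, 1.1, True),
            ("V_ydgG", 3.6, 4.4, False),
            ("k2", 430.0, 530.0, False),
        ],
    )
    def test_monotone_sensitivity_of_time_to_activation(
        self, name, lo, hi, earlier_at_high
    ):
        """Raising basal, K_synth or k_phos hastens autoinduction;
        raising the export rate or the transcription threshold delays it."""
        t_lo = batch_t5x(LsrParams(**{name: lo}))
        t_hi = batch_t5x(LsrParams(**{name: hi}))
        if earlier_at_high:
            assert t_hi < t_lo
        else:
            assert t_hi > t_lo

    def test_invalid_t_end_rejected(self, lsr_params):
        with pytest.raises(ValueError):
            integrate_batch(lsr_params, t_end=-1.0)


def _b_activates(basal_B, t_end=420.0):
    pA = LsrParams(basal=510.0)
    pB = LsrParams(basal=basal_B)
    df = two_cell_shared_pool(pA, pB, t_end=t_end)
    TB = df["T_B"].to_numpy()
    return TB[-1] > 5.0 * TB[0]


class TestTwoCellSharedPool:
    def test_identical_cells_give_identical_trajectories(self, lsr_params):
        df = two_cell_shared_pool(lsr_params, lsr_params, t_end=300.0)
        for name in ("Ai", "Ap", "M", "T"):
            np.testing.assert_allclose(
                df[f"{name}_A"], df[f"{name}_B"], rtol=1e-6, atol=1e-9
            )

    def test_low_basal_cell_stagnates_while_high_basal_cell_activates(self):
        """Cell 1 at 510 uM/min autoinduces; a cell with much lower basal
        import never does, its phospho-AI-2 staying at baseline."""
        pA = LsrParams(basal=510.0)
        pB = LsrParams(basal=380.0)
        df = two_cell_shared_pool(pA, pB, t_end=420.0)
        base_ap = pA.initial_state().Ap
        assert df["Ap_A"].iloc[-1] > 3.0 * base_ap
        assert df["Ap_B"].iloc[-1] < 1.5 * base_ap
        TA, TB = df["T_A"].to_numpy(), df["T_B"].to_numpy()
        assert TA[-1] > 5 * TA[0] and TB[-1] < 5 * TB[0]

    def test_dominance_cell_a_activates_no_later_than_cell_b(self):
        for bB in (400.0, 460.0, 500.0):
            pA = LsrParams(basal=510.0)
            pB = LsrParams(basal=bB)
            df = two_cell_shared_pool(pA, pB, t_end=420.0)
            for tag_hi, tag_lo in (("A", "B"),):
                T_hi = df[f"T_{tag_hi}"].to_numpy()
                T_lo = df[f"T_{tag_lo}"].to_numpy()
                hi_hits = np.where(T_hi > 5 * T_hi[0])[0]
                lo_hits = np.where(T_lo > 5 * T_lo[0])[0]
                if len(lo_hits):
                    assert len(hi_hits) and hi_hits[0] <= lo_hits[0]

    def test_bisection_threshold_matches_fine_scan(self):
        """The smallest basal_B at which cell B still activates, found by
        bisection, agrees with a direct grid scan at equal resolution.
        (The shared-pool competition is winner-take-all: the threshold
        sits just below cell A's own basal rate.)"""
        lo, hi = 500.0, 510.0
        assert not _b_activates(lo) and _b_activates(hi)
        blo, bhi = lo, hi
        while bhi - blo > 1.0:
            mid = 0.5 * (blo + bhi)
            if _b_activates(mid):
                bhi = mid
            else:
                blo = mid
        scan = np.arange(lo, hi + 1e-9, 1.0)
        flags = [_b_activates(b) for b in scan]
        scan_threshold = scan[flags.index(True)]
        assert abs(bhi - scan_threshold) <= 1.0


class TestSbml:
    def test_round_trip_preserves_parameters(self, tmp_path, lsr_params):
        path = tmp_path / "lsr.xml"
        save_sbml(lsr_params, path)
        model = load_sbml(path)
        assert model.params == lsr_params

    def test_loaded_rhs_matches_builtin_on_random_states(self, tmp_path, rng):
        p = LsrParams()
        path = tmp_path / "lsr.xml"
        save_sbml(p, path)
        model = load_sbml(path)
        for _ in range(25):
            s = LsrCellState(*rng.uniform(0.0, 60.0, 5))
            a = lsr_rhs(s, p, model.volume_ratio).as_array()
            b = model.rhs(s).as_array()
            np.testing.assert_allclose(b, a, rtol=1e-9, atol=1e-12)

    def test_missing_parameters_raise_descriptive_error(self, tmp_path):
        path = tmp_path / "broken.xml"
        save_sbml(LsrParams(), path)
        text = path.read_text().replace('id="k_phos"', 'id="k_phos_oops"')
        path.write_text(text)
        with pytest.raises(ValueError, match="k_phos"):
            load_sbml(path)


def test_exponential_density_matches_od_conversion():
    dens = exponential_density(od600=0.03, doubling_time=60.0)
    # volume fraction = OD * cells/mL/OD * cell volume in mL
    assert dens(0.0) == pytest.approx(0.03 * 8e8 * 1e-12)
    assert dens(60.0) / dens(0.0) == pytest.approx(2.0)
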
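"""Fluorescence/gas-exchange derivation and physiological memory calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressmem.config import RunConfig
from stressmem.physiology import (
    FluorescenceReading,
    GasExchangeReading,
    chlorophyll_concentration,
    classify_all_physiology,
    classify_physiology_memory,
    derive_fluorescence,
    derive_table,
    qe_partition,
)
from stressmem.simulate import (
    SimulationSpec,
    simulate_physiology,
    simulate_raw_fluorescence,
)

GAS = GasExchangeReading(P_N=20.0, g_s=150.0, E=3.0, C_i=180.0, R_d=1.0)


def valid_reading(fs_frac, npq, fo_frac, ppfd=1500.0):
    """Construct a reading satisfying the ordering invariants."""
    fm = 4000.0
    fm_prime = fm / (1.0 + npq)
    fs = fs_frac * fm_prime
    fo = min(fo_frac * fs, fs)
    return FluorescenceReading(Fs=fs, Fm_prime=fm_prime, Fo=fo, Fm=fm, PPFD=ppfd)


class TestDerivation:
    def test_fully_closed_centers(self):
        r = FluorescenceReading(Fs=1000.0, Fm_prime=1000.0, Fo=500.0, Fm=2000.0, PPFD=1500.0)
        d = derive_fluorescence(r, GAS)
        assert d["phiPSII"] == 0.0
        assert d["qP"] == 0.0

    def test_npq_arithmetic(self):
        r = FluorescenceReading(Fs=800.0, Fm_prime=1000.0, Fo=400.0, Fm=2000.0, PPFD=1500.0)
        d = derive_fluorescence(r, GAS)
        assert d["NPQ"] == pytest.approx(1.0)

    @given(
        fs_frac=st.floats(0.2, 0.95),
        npq=st.floats(0.05, 3.0),
        fo_frac=st.floats(0.3, 0.99),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_phipsii_identity(self, fs_frac, npq, fo_frac):
        """phiPSII = qP x Fv'/Fm' algebraically for any valid reading."""
        d = derive_fluorescence(valid_reading(fs_frac, npq, fo_frac), GAS)
        assert abs(d["phiPSII"] - d["qP"] * d["FvFm_prime"]) < 1e-12
        assert 0 <= d["phiPSII"] <= 1
        assert 0 <= d["FvFm_prime"] <= 1
        assert d["qP"] >= d["phiPSII"] - 1e-12

    def test_ordering_violation_names_pair(self):
        with pytest.raises(ValueError, match="Fm_prime > Fm"):
            FluorescenceReading(Fs=900.0, Fm_prime=3000.0, Fo=400.0, Fm=2000.0, PPFD=500.0)
        with pytest.raises(ValueError, match="Fs > Fm_prime"):
            FluorescenceReading(Fs=1100.0, Fm_prime=1000.0, Fo=400.0, Fm=2000.0, PPFD=500.0)

    def test_etr_and_phico2_scale(self):
        r = valid_reading(0.4, 0.5, 0.6)
        cfg = RunConfig(absorptance=0.85, psii_fraction=0.5)
        d = derive_fluorescence(r, GAS, cfg)
        assert d["ETR"] == pytest.approx(d["phiPSII"] * 1500.0 * 0.5 * 0.85)
        assert d["A_G"] == pytest.approx(21.0)
        assert d["phiCO2"] == pytest.approx(21.0 / (1500.0 * 0.85))


class TestQePartition:
    def test_no_relaxable_quenching(self):
        r = valid_reading(0.5, 1.0, 0.5)
        qe, phi_qe = qe_partition(r, relaxed_fm_prime=r.Fm_prime)
        assert qe == pytest.approx(0.0)
        assert phi_qe == pytest.approx(0.0)

    def test_default_attributes_all_npq_to_qe(self):
        r = valid_reading(0.5, 1.0, 0.5)
        d = derive_fluorescence(r, GAS)
        qe, _ = qe_partition(r)
        assert qe == pytest.approx(d["NPQ"])
        assert not d["qe_from_relaxation"]

    def test_arithmetic_example(self):
        # Fm=2000, Fm'=1000, relaxed Fm'=1600 -> qE = 2 - 1.25 = 0.75
        r = FluorescenceReading(Fs=900.0, Fm_prime=1000.0, Fo=400.0, Fm=2000.0, PPFD=500.0)
        qe, phi_qe = qe_partition(r, relaxed_fm_prime=1600.0)
        assert qe == pytest.approx(0.75)
        assert phi_qe == pytest.approx(900 / 1000 - 900 / 1600)

    def test_qe_bounded_by_npq(self):
        r = valid_reading(0.5, 1.5, 0.5)
        npq = r.Fm / r.Fm_prime - 1
        for relaxed in np.linspace(r.Fm_prime, r.Fm, 7):
            qe, _ = qe_partition(r, relaxed_fm_prime=float(relaxed))
            assert qe <= npq + 1e-12

    def test_invalid_relaxed_value(self):
        r = valid_reading(0.5, 1.0, 0.5)
        with pytest.raises(ValueError, match="below"):
            qe_partition(r, relaxed_fm_prime=r.Fm_prime - 1)


class TestChlorophyll:
    def test_zero_absorbance(self):
        assert chlorophyll_concentration(0.0, 0.0, 0.1) == 0.0

    def test_arithmetic_oracle(self):
        # (8.02*0.5 + 20.2*0.25)/0.1 = (4.01 + 5.05)/0.1 = 90.6
        assert chlorophyll_concentration(0.5, 0.25, 0.1) == pytest.approx(90.6)

    def test_homogeneity(self):
        a = chlorophyll_concentration(0.3, 0.2, 0.05)
        b = chlorophyll_concentration(0.6, 0.4, 0.05)
        assert b == pytest.approx(2 * a)

    def test_nonpositive_dw_rejected(self):
        with pytest.raises(ValueError):
            chlorophyll_concentration(0.5, 0.25, 0.0)


class TestRawFluorescenceRoundTrip:
    def test_planted_targets_recovered(self):
        plan = {k: (m, 0.0) for k, (m, s) in SimulationSpec().physiology_plan.items()}
        spec = SimulationSpec(physiology_plan=plan, n_plants=3, seed=9)
        raw = simulate_raw_fluorescence(spec)
        table = derive_table(raw.assign(R_d=spec.r_d))
        for stage, phi, qp in [("W", 0.60, 0.85), ("S2", 0.30, 0.55)]:
            np.testing.assert_allclose(table.values_for("phiPSII", stage), phi, atol=1e-9)
            np.testing.assert_allclose(table.values_for("qP", stage), qp, atol=1e-9)
        np.testing.assert_allclose(table.values_for("qE", "S2"), 1.5, atol=1e-9)
        np.testing.assert_allclose(table.values_for("NPQ", "W"), 0.40, atol=1e-9)


class TestMemoryCalls:
    @staticmethod
    def _table(plan, n_plants=4, seed=0):
        spec = SimulationSpec(physiology_plan=plan, n_plants=n_plants, seed=seed)
        table, _ = simulate_physiology(spec)
        return table

    def test_gs_zero_noise_is_memory(self):
        table = self._table({"g_s": ((150.0, 60.0, 100.0, 30.0), 0.0)})
        call = classify_physiology_memory(table, "g_s")
        assert call.pattern == "[-/-]"
        assert call.category == "memory"

    def test_flat_parameter_non_responsive(self):
        table = self._table({"x": ((5.0, 5.0, 5.0, 5.0), 0.0)})
        call = classify_physiology_memory(table, "x")
        assert call.pattern == "[=/=]"
        assert call.category == "non-responsive"

    def test_welch_matches_textbook_formula(self):
        x = np.array([150.0, 148.0, 155.0, 149.0])
        y = np.array([60.0, 62.0, 58.0, 61.0])
        plan = None
        import pandas as pd

        from stressmem.io import PhysiologyTable

        rows = []
        for i, v in enumerate(x):
            rows.append({"plant_id": f"p{i}", "stage": "W", "parameter": "g_s", "value": v})
        for i, v in enumerate(y):
            rows.append({"plant_id": f"p{i}", "stage": "S1", "parameter": "g_s", "value": v})
        for i in range(4):
            rows.append({"plant_id": f"p{i}", "stage": "S2", "parameter": "g_s", "value": 30.0 + i})
        table = PhysiologyTable(pd.DataFrame(rows))
        call = classify_physiology_memory(table, "g_s")
        # textbook Welch: t = (mx - my)/sqrt(sx^2/nx + sy^2/ny)
        sx2, sy2 = x.var(ddof=1), y.var(ddof=1)
        t_hand = (y.mean() - x.mean()) / math.sqrt(sx2 / 4 + sy2 / 4)
        assert call.t_first == pytest.approx(t_hand, rel=1e-12)
        assert call.pattern == "[-/-]"

    def test_missing_stage_errors(self):
        table = self._table({"x": ((5.0, 5.0, 5.0, 5.0), 0.0)})
        table.data = table.data[table.data["stage"] != "S2"]
        with pytest.raises(ValueError, match="S2"):
            classify_physiology_memory(table, "x")

    def test_zero_noise_defaults_reproduce_qualitative_table(self):
        spec = SimulationSpec(
            physiology_plan={
                k: (m, 0.0) for k, (m, s) in SimulationSpec().physiology_plan.items()
            },
            n_plants=4,
            seed=1,
        )
        table, truth = simulate_physiology(spec)
        calls = classify_all_physiology(table)
        for param, expected in truth.parameter_pattern.items():
            assert calls.loc[param, "pattern"] == expected, param
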
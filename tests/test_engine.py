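"""Steady-state engine: validation, conventions, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pbr2 import (
    ComplexSignal,
    SequenceParams,
    SimulationConfig,
    TissueParams,
    add_complex_noise,
    effective_te,
    phase_curve,
    signal_phase,
    simulate_signals,
    simulate_steady_state,
    t2star_retention,
)
from conftest import oracle_steady_state


class TestValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(tr=0.0, te=0.0, flip_angle=18, phase_increment=2),
            dict(tr=3.0, te=3.0, flip_angle=18, phase_increment=2),
            dict(tr=3.0, te=1.0, flip_angle=95, phase_increment=2),
            dict(tr=3.0, te=1.0, flip_angle=18, phase_increment=0),
            dict(tr=3.0, te=1.0, flip_angle=18, phase_increment=2, field_strength=7.0),
        ],
    )
    def test_sequence_invariants_rejected(self, kw):
        with pytest.raises(ValueError):
            SequenceParams(**kw)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(r1=0.0, r2=10.0),
            dict(r1=1.0, r2=-1.0),
            dict(r1=5.0, r2=2.0),  # r2 < r1 unphysical
            dict(r1=1.0, r2=10.0, pdff=1.5),
        ],
    )
    def test_tissue_invariants_rejected(self, kw):
        with pytest.raises(ValueError):
            TissueParams(**kw)

    def test_simulation_config_invariants(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_isochromats=1)
        with pytest.raises(ValueError):
            SimulationConfig(convergence_tol=0.0)


class TestSignalPhase:
    def test_equal_components_give_45_degrees(self):
        assert signal_phase(ComplexSignal(0.3, 0.3)) == pytest.approx(45.0)

    def test_vanishing_echo_gives_zero_phase(self):
        assert signal_phase(ComplexSignal(0.0, 0.5)) == pytest.approx(0.0)

    def test_negative_echo_allowed(self):
        assert signal_phase(ComplexSignal(-0.1, 0.5)) < 0

    def test_zero_magnitude_rejected(self):
        with pytest.raises(ValueError):
            signal_phase(ComplexSignal(0.0, 0.0))

    @given(
        e=st.floats(-1, 1, allow_nan=False),
        f=st.floats(0.01, 1, allow_nan=False),
    )
    def test_phase_matches_arctangent(self, e, f):
        assert signal_phase(ComplexSignal(e, f)) == pytest.approx(
            np.degrees(np.arctan2(e, f))
        )


class TestEffectiveTE:
    @pytest.mark.parametrize("tr,expected", [(3.0, 6.0), (3.2, 6.4)])
    def test_twice_tr(self, tr, expected):
        seq = SequenceParams(tr=tr, te=1.0, flip_angle=18, phase_increment=2)
        assert effective_te(seq) == pytest.approx(expected)


class TestSteadyState:
    def test_deterministic(self, seq3, sim_config):
        t = TissueParams(r1=1.0, r2=120.0)
        a = simulate_steady_state(seq3, t, sim_config)
        b = simulate_steady_state(seq3, t, sim_config)
        assert a == b  # bit-identical

    def test_phase_in_physical_range(self, curve_tr3):
        ph = curve_tr3["phase_deg"]
        assert np.all(ph > 0) and np.all(ph < 90)

    def test_phase_monotone_decreasing_in_r2(self, curve_tr3):
        assert np.all(np.diff(curve_tr3["phase_deg"]) < 0)

    def test_shorter_tr_preserves_phase_at_high_r2(self, seq3, sim_config):
        """At fixed high R2 the TR=3 ms phase exceeds the TR=9 ms phase."""
        r2 = np.array([200.0, 300.0, 400.0])
        ph3 = phase_curve(seq3, 1.0, r2, sim_config)["phase_deg"]
        ph9 = phase_curve(seq3.with_(tr=9.0), 1.0, r2, sim_config)["phase_deg"]
        assert np.all(ph3 > ph9)

    def test_opposite_increment_negates_phase(self, seq3, sim_config):
        zp = simulate_signals(seq3, 1.0, np.array([80.0, 200.0]), sim_config)
        zm = simulate_signals(
            seq3.with_(phase_increment=-2.0), 1.0, np.array([80.0, 200.0]), sim_config
        )
        np.testing.assert_allclose(zm, np.conj(zp), rtol=1e-9)

    def test_tightening_tolerance_leaves_phase_converged(self, seq3):
        loose = SimulationConfig(convergence_tol=1e-6)
        tight = SimulationConfig(convergence_tol=1e-8)
        za = simulate_signals(seq3, 1.0, 150.0, loose)[0]
        zb = simulate_signals(seq3, 1.0, 150.0, tight)[0]
        assert abs(np.degrees(np.angle(za)) - np.degrees(np.angle(zb))) < 1e-3

    def test_phase_curve_single_point_matches_simulate(self, seq3, sim_config):
        tab = phase_curve(seq3, 1.0, np.array([150.0]), sim_config)
        sig = simulate_steady_state(seq3, TissueParams(1.0, 150.0), sim_config)
        assert tab["phase_deg"][0] == pytest.approx(sig.phase_deg, abs=1e-9)

    def test_phase_curve_rejects_unsorted_grid(self, seq3, sim_config):
        with pytest.raises(ValueError):
            phase_curve(seq3, 1.0, np.array([100.0, 50.0]), sim_config)


class TestOracleAgreement:
    def test_production_matches_independent_simulation(self, seq3, sim_config):
        """Engine phase agrees with a brute-force higher-fidelity oracle to
        within 0.1 degree on an (R1, R2) grid."""
        r1s = [0.5, 1.0, 2.0, 4.0, 8.0]
        r2s = [30.0, 80.0, 150.0, 250.0, 400.0]
        r1g, r2g = np.meshgrid(r1s, r2s, indexing="ij")
        z = simulate_signals(seq3, r1g, r2g, sim_config)
        prod = np.degrees(np.angle(z))
        for i, r1 in enumerate(r1s):
            for j, r2 in enumerate(r2s):
                zo = oracle_steady_state(
                    seq3.tr, seq3.te, seq3.flip_angle, seq3.phase_increment, r1, r2
                )
                assert prod[i, j] == pytest.approx(
                    np.degrees(np.angle(zo)), abs=0.1
                ), f"R1={r1}, R2={r2}"

    def test_frozen_oracle_values(self, seq3, sim_config):
        """Regression anchors computed with the independent oracle."""
        expected = {20.0: 52.8308, 150.0: 12.9575, 300.0: 4.6246}
        z = simulate_signals(seq3, 1.0, np.array(list(expected)), sim_config)
        np.testing.assert_allclose(
            np.degrees(np.angle(z)), list(expected.values()), atol=0.01
        )


class TestNoise:
    def test_infinite_snr_is_identity(self):
        sig = ComplexSignal(0.1, 0.2)
        out = add_complex_noise(sig, snr=1e12, seed=0)
        assert out.real_part == pytest.approx(sig.real_part, abs=1e-10)
        assert out.imag_part == pytest.approx(sig.imag_part, abs=1e-10)

    def test_seeded_reproducibility(self):
        sig = ComplexSignal(0.1, 0.2)
        assert add_complex_noise(sig, 20.0, seed=7) == add_complex_noise(
            sig, 20.0, seed=7
        )

    def test_sample_mean_recovers_signal(self):
        z = 0.02 + 0.05j
        n = 100_000
        noisy = add_complex_noise(np.full(n, z), snr=20.0, seed=1)
        se = abs(z) / 20.0 / np.sqrt(n)
        assert abs(noisy.mean() - z) < 3 * se * np.sqrt(2)

    def test_rejects_nonpositive_snr(self):
        with pytest.raises(ValueError):
            add_complex_noise(ComplexSignal(0.1, 0.2), 0.0, seed=0)


def test_t2star_retention_matches_exponential():
    assert t2star_retention(1.0, 1.0) == pytest.approx(np.exp(-1.0))
    with pytest.raises(ValueError):
        t2star_retention(1.0, 0.0)
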
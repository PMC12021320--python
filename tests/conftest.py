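"""Shared fixtures: session-scoped simulations reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pbr2 import (
    LookupTable,
    SequenceParams,
    SimulationConfig,
    build_lookup,
    phase_curve,
)
from pbr2.lookup import PHANTOM_LINES

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=25,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def seq3() -> SequenceParams:
    """TR=3 ms reference protocol: flip 18 deg, increment 2 deg."""
    return SequenceParams(tr=3.0, te=1.0, flip_angle=18.0, phase_increment=2.0)


@pytest.fixture(scope="session")
def seq_phantom_3t() -> SequenceParams:
    """3.0 T phantom protocol: TR 3.1 ms, TE 0.8 ms, flip 18, inc 1.5."""
    return SequenceParams(
        tr=3.1, te=0.8, flip_angle=18.0, phase_increment=1.5, field_strength=3.0
    )


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def curve_tr3(seq3, sim_config):
    """Noiseless phase curve at TR=3 over R2 in [1, 500] s^-1 (step 2)."""
    return phase_curve(seq3, 1.0, np.arange(1.0, 501.0, 2.0), sim_config)


@pytest.fixture(scope="session")
def lut_tr3_wide(curve_tr3, seq3) -> LookupTable:
    """Fixed-R1=1 lookup on [11, 499] s^-1 built from the session curve."""
    sel = curve_tr3["r2"] >= 11.0
    return LookupTable(
        r2_grid=curve_tr3["r2"][sel],
        phase_grid=curve_tr3["phase_deg"][sel],
        r1_model=1.0,
        seq=seq3,
    )


@pytest.fixture(scope="session")
def lut_cal_3t(seq_phantom_3t, sim_config) -> LookupTable:
    """Calibrated lookup (3.0 T vial-phantom line), 10-300 s^-1, 1 s^-1 step."""
    return build_lookup(
        seq_phantom_3t, PHANTOM_LINES[3.0], np.arange(10.0, 301.0, 1.0), sim_config
    )


@pytest.fixture(scope="session")
def lut_fixed1_3t(seq_phantom_3t, sim_config) -> LookupTable:
    """Fixed R1=1 s^-1 lookup extended to 450 s^-1 (uncorrected variant)."""
    return build_lookup(
        seq_phantom_3t, 1.0, np.arange(10.0, 451.0, 1.0), sim_config
    )


@pytest.fixture(scope="session")
def fat_tables():
    """Fat-bias tables at both fields: PDFF 0-30% (1% step), R2 up to 300."""
    from pbr2.fat import fat_bias_grid

    return fat_bias_grid(
        pdff_grid=np.arange(0.0, 0.301, 0.01),
        r2_grid=np.array([1.0, 25.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0]),
    )


def oracle_steady_state(
    tr, te, flip_deg, inc_deg, r1, r2, n_iso=3000, n_exc=2500, tail=360
):
    """Independent brute-force isochromat simulation used as test oracle.

    Deliberately different implementation: real 3-vectors, explicit 3x3
    rotation matrices assembled per excitation, fixed excitation count with
    tail averaging instead of adaptive convergence, and a higher isochromat
    count than the production default.
    """
    a = np.deg2rad(flip_deg)
    th = np.deg2rad(inc_deg)
    e1, e2 = np.exp(-r1 * tr * 1e-3), np.exp(-r2 * tr * 1e-3)
    psi = -np.pi + 2 * np.pi * np.arange(n_iso) / n_iso
    cpsi, spsi = np.cos(psi), np.sin(psi)
    M = np.zeros((n_iso, 3))
    M[:, 2] = 1.0
    ca, sa = np.cos(a), np.sin(a)
    Rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    phi = 0.0
    sigs = []
    for n in range(1, n_exc + 1):
        phi += n * th
        cp, sp = np.cos(phi), np.sin(phi)
        Rz = np.array([[cp, -sp, 0], [sp, cp, 0], [0, 0, 1]])
        R = Rz @ Rx @ Rz.T
        M = M @ R.T
        sigs.append((M[:, 0] + 1j * M[:, 1]).mean() * np.exp(-1j * phi))
        x, y = M[:, 0].copy(), M[:, 1].copy()
        M[:, 0] = (x * cpsi - y * spsi) * e2
        M[:, 1] = (x * spsi + y * cpsi) * e2
        M[:, 2] = 1 + (M[:, 2] - 1) * e1
    s = np.mean(sigs[-tail:]) * np.exp(-r2 * te * 1e-3)
    return 1j * s  # canonical orientation: FID-like on the real axis
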
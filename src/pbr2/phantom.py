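"""Ground-truthed synthetic digital phantoms.

Generates two-pass complex GRE volumes emulating the kind of data the
reconstruction pipeline sees from a scanner: vial phantoms whose (R1, R2)
values follow an iron-mimicking calibration line, liver-like volumes with a
smooth R2 field, optional fat and long-T2 vessel inclusions, spatially smooth
background phase common to both passes, and independent complex Gaussian
noise per pass.  Ground-truth maps are copied directly from the phantom spec, never
simulated, so recovery errors measure the pipeline alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import SequenceParams, SimulationConfig, simulate_signals
from .fat import DEFAULT_FAT_T1_MS, DEFAULT_FAT_T2_MS, FatSpectrum
from .lookup import PHANTOM_LINES, CalibrationLine
from .recon import ComplexVolume

__all__ = [
    "Vial",
    "PhantomSpec",
    "PhantomData",
    "default_vial_phantom",
    "generate_phantom",
    "generate_liver_volume",
]


@dataclass(frozen=True)
class Vial:
    """One cylindrical vial: center (x, y) in mm from volume center."""

    center_mm: tuple
    radius_mm: float
    r1: float
    r2: float

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError("radius_mm must be positive")
        if not (self.r1 > 0 and self.r2 > 0):
            raise ValueError("relaxation rates must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue values and degradation settings of a vial phantom.

    ``background_phase_deg`` sets the amplitude of a smooth per-slice
    quadratic phase field applied identically to both passes (0 disables);
    ``snr`` adds independent complex Gaussian noise per pass with sigma =
    mean in-vial magnitude / snr (None disables).
    """

    vials: tuple
    matrix: tuple = (100, 100, 10)
    voxel_size_mm: tuple = (4.8, 4.8, 10.0)
    background_phase_deg: float = 0.0
    snr: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        vials = tuple(self.vials)
        object.__setattr__(self, "vials", vials)
        for i, a in enumerate(vials):
            for b in vials[i + 1 :]:
                d = np.hypot(
                    a.center_mm[0] - b.center_mm[0], a.center_mm[1] - b.center_mm[1]
                )
                if d < a.radius_mm + b.radius_mm:
                    raise ValueError("vials overlap")
        if self.snr is not None and not self.snr > 0:
            raise ValueError("snr must be positive or None")


@dataclass
class PhantomData:
    """Two-pass volumes plus ground truth."""

    plus: ComplexVolume
    minus: ComplexVolume
    truth_r2: np.ndarray
    truth_r1: np.ndarray
    truth_mask: np.ndarray


def default_vial_phantom(
    field_strength: float = 3.0,
    n_vials: int = 11,
    r2_range: tuple = (50.0, 300.0),
    cal: CalibrationLine | None = None,
    ring_radius_mm: float = 150.0,
    vial_radius_mm: float = 15.0,
    **spec_kw,
) -> PhantomSpec:
    """Eleven-vial layout on a ring, R2 evenly spaced over 50-300 s^-1 and
    R1 following the field's vial-phantom calibration line."""
    cal = cal or PHANTOM_LINES[field_strength]
    r2s = np.linspace(r2_range[0], r2_range[1], n_vials)
    ang = 2 * np.pi * np.arange(n_vials) / n_vials
    vials = tuple(
        Vial(
            center_mm=(ring_radius_mm * np.cos(a), ring_radius_mm * np.sin(a)),
            radius_mm=vial_radius_mm,
            r1=float(cal(r2)),
            r2=float(r2),
        )
        for a, r2 in zip(ang, r2s)
    )
    return PhantomSpec(vials=vials, **spec_kw)


def _grid_mm(matrix, voxel_size_mm):
    nx, ny, _ = matrix
    x = (np.arange(nx) - (nx - 1) / 2) * voxel_size_mm[0]
    y = (np.arange(ny) - (ny - 1) / 2) * voxel_size_mm[1]
    return x, y


def _background_field(matrix, amplitude_deg: float) -> np.ndarray:
    """Smooth per-slice quadratic phase (radians), range ~ [-amp, +amp]."""
    nx, ny, nz = matrix
    u = np.linspace(-1.0, 1.0, nx)[:, None]
    v = np.linspace(-1.0, 1.0, ny)[None, :]
    f2d = np.deg2rad(amplitude_deg) * (u**2 + u * v + v**2 - 1.0) / 2.0
    return np.repeat(f2d[:, :, None], nz, axis=2)


def _two_pass_from_maps(
    signal_plus: np.ndarray,
    signal_minus: np.ndarray,
    mask: np.ndarray,
    spec_like_matrix: tuple,
    voxel_size_mm: tuple,
    seq: SequenceParams,
    background_phase_deg: float,
    snr: float | None,
    seed: int,
) -> tuple[ComplexVolume, ComplexVolume]:
    """Assemble ± volumes from per-voxel complex signals, degrade, wrap."""
    vol_p = np.where(mask, signal_plus, 0.0 + 0.0j)
    vol_m = np.where(mask, signal_minus, 0.0 + 0.0j)
    if background_phase_deg:
        bg = np.exp(1j * _background_field(spec_like_matrix, background_phase_deg))
        vol_p = vol_p * bg
        vol_m = vol_m * bg
    if snr is not None:
        rng = np.random.default_rng(seed)
        ref = np.abs(vol_p[mask]).mean()
        sigma = ref / snr
        for vol in (vol_p, vol_m):  # independent noise per pass
            vol += sigma * (
                rng.standard_normal(vol.shape) + 1j * rng.standard_normal(vol.shape)
            )
    seq_minus = seq.with_(phase_increment=-abs(seq.phase_increment))
    seq_plus = seq.with_(phase_increment=abs(seq.phase_increment))
    return (
        ComplexVolume(vol_p, voxel_size_mm, +1, seq_plus),
        ComplexVolume(vol_m, voxel_size_mm, -1, seq_minus),
    )


def generate_phantom(
    spec: PhantomSpec,
    seq: SequenceParams,
    config: SimulationConfig | None = None,
) -> PhantomData:
    """Simulate the two-pass acquisition of a vial phantom.

    Each vial's steady-state signal is computed once per pass sign and
    painted into all voxels whose in-plane center lies inside the vial.
    Deterministic for fixed spec.seed.
    """
    nx, ny, nz = spec.matrix
    x, y = _grid_mm(spec.matrix, spec.voxel_size_mm)
    truth_r2 = np.zeros(spec.matrix)
    truth_r1 = np.zeros(spec.matrix)
    mask = np.zeros(spec.matrix, dtype=bool)

    r1s = np.array([v.r1 for v in spec.vials])
    r2s = np.array([v.r2 for v in spec.vials])
    z_plus = simulate_signals(seq.with_(phase_increment=abs(seq.phase_increment)), r1s, r2s, config)
    z_minus = simulate_signals(seq.with_(phase_increment=-abs(seq.phase_increment)), r1s, r2s, config)

    sig_p = np.zeros(spec.matrix, dtype=complex)
    sig_m = np.zeros(spec.matrix, dtype=complex)
    for v, zp, zm in zip(spec.vials, z_plus, z_minus):
        disk = (x[:, None] - v.center_mm[0]) ** 2 + (
            y[None, :] - v.center_mm[1]
        ) ** 2 <= v.radius_mm**2
        region = np.repeat(disk[:, :, None], nz, axis=2)
        truth_r2[region] = v.r2
        truth_r1[region] = v.r1
        mask |= region
        sig_p[region] = zp
        sig_m[region] = zm

    plus, minus = _two_pass_from_maps(
        sig_p,
        sig_m,
        mask,
        spec.matrix,
        spec.voxel_size_mm,
        seq,
        spec.background_phase_deg,
        spec.snr,
        spec.seed,
    )
    return PhantomData(plus, minus, truth_r2, truth_r1, mask)


def generate_liver_volume(
    seq: SequenceParams,
    r2_field: np.ndarray,
    r1_model: CalibrationLine | float = 1.0,
    pdff_field: np.ndarray | None = None,
    vessels: list | None = None,
    vessel_r1: float = 0.66,
    vessel_r2: float = 5.0,
    vessel_attenuation: float = 0.4,
    voxel_size_mm: tuple = (4.8, 4.8, 10.0),
    background_phase_deg: float = 0.0,
    snr: float | None = None,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> PhantomData:
    """Liver-like volume from a smooth positive R2 field.

    Per-voxel signals are interpolated (separately in each quadrature
    component) from a dense steady-state curve over the field's R2 range —
    the curve is smooth, so interpolation at 1 s^-1 node spacing is exact to
    well below the noise floor.  ``vessels`` is an optional list of
    :class:`Vial`-like inclusions given long T2 (low R2) and an explicit
    magnitude attenuation (``vessel_attenuation``) standing in for the
    diffusion-driven suppression of long-T2 blood under partial spoiling.
    ``pdff_field`` routes a fat component through the multi-peak spectral
    model.
    """
    r2_field = np.asarray(r2_field, dtype=float)
    if r2_field.ndim != 3 or not np.all(np.isfinite(r2_field)) or np.any(r2_field <= 0):
        raise ValueError("r2_field must be a finite positive 3-D array")
    truth_r2 = r2_field.copy()
    truth_r1 = (
        r1_model(truth_r2)
        if isinstance(r1_model, CalibrationLine)
        else np.full_like(truth_r2, float(r1_model))
    )
    mask = np.ones(truth_r2.shape, dtype=bool)

    if vessels:
        x, y = _grid_mm(truth_r2.shape, voxel_size_mm)
        for v in vessels:
            disk = (x[:, None] - v.center_mm[0]) ** 2 + (
                y[None, :] - v.center_mm[1]
            ) ** 2 <= v.radius_mm**2
            region = np.repeat(disk[:, :, None], truth_r2.shape[2], axis=2)
            truth_r2[region] = vessel_r2
            truth_r1[region] = vessel_r1

    def interp_signals(sign: int) -> np.ndarray:
        s = seq.with_(phase_increment=sign * abs(seq.phase_increment))
        lo = max(min(truth_r2.min(), vessel_r2) - 1.0, 0.1)
        hi = truth_r2.max() + 1.0
        nodes = np.linspace(lo, hi, max(int(hi - lo) + 2, 64))
        # R1 varies along the calibration line with R2, matching the truth
        r1n = (
            r1_model(nodes)
            if isinstance(r1_model, CalibrationLine)
            else np.full_like(nodes, float(r1_model))
        )
        zn = simulate_signals(s, r1n, nodes, config)
        flat = truth_r2.ravel()
        z = np.interp(flat, nodes, zn.real) + 1j * np.interp(flat, nodes, zn.imag)
        if vessels:
            # vessel voxels carry their own (r1, r2), not the line; their
            # magnitude is attenuated to emulate the diffusion-driven
            # suppression of long-T2 blood under partial spoiling, which a
            # diffusion-free Bloch ensemble does not produce
            zv = simulate_signals(s, vessel_r1, vessel_r2, config)[0]
            z[truth_r2.ravel() == vessel_r2] = zv * vessel_attenuation
        return z.reshape(truth_r2.shape)

    sig_p = interp_signals(+1)
    sig_m = interp_signals(-1)

    if pdff_field is not None:
        pdff = np.asarray(pdff_field, dtype=float)
        if pdff.shape != truth_r2.shape or np.any((pdff < 0) | (pdff > 1)):
            raise ValueError("pdff_field must match the volume shape, in [0, 1]")
        b0 = seq.field_strength
        fat_r1 = 1e3 / DEFAULT_FAT_T1_MS[b0]
        fat_r2 = 1e3 / DEFAULT_FAT_T2_MS
        spectrum = FatSpectrum.from_ppm(b0)
        spec_fac = spectrum.phase_factor(seq.te)
        for sign, arr in ((+1, sig_p), (-1, sig_m)):
            s = seq.with_(phase_increment=sign * abs(seq.phase_increment))
            zf = simulate_signals(s, fat_r1, fat_r2, config)[0]
            arr *= 1.0 - pdff
            arr += pdff * zf * spec_fac

    plus, minus = _two_pass_from_maps(
        sig_p,
        sig_m,
        mask,
        truth_r2.shape,
        voxel_size_mm,
        seq,
        background_phase_deg,
        snr,
        seed,
    )
    return PhantomData(plus, minus, truth_r2, truth_r1, mask)
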
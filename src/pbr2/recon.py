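"""Volumetric R2 reconstruction from two-pass complex GRE volumes.

The acquisition is repeated with opposite RF phase increment signs.  Tissue
phase is antisymmetric in the increment sign while background phase (coil,
off-resonance, eddy) is common to both passes, so the half-angle of the
conjugate product, angle(S+ * conj(S-)) / 2, cancels the background exactly
and recovers the tissue phase.  The pipeline is: complex spatial averaging of
each pass (noise mitigation must happen in the complex domain, before any
phase is taken), two-pass combination, then per-voxel lookup inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi

import nibabel as nib

from .engine import SequenceParams
from .lookup import LookupTable, invert_phase_array

__all__ = [
    "ComplexVolume",
    "PhaseVolume",
    "ParameterMap",
    "ROISpec",
    "ROIStats",
    "EmptyROIError",
    "combine_two_pass",
    "spatial_average",
    "reconstruct_r2",
    "roi_stats",
    "write_complex_nifti",
    "read_complex_nifti",
    "write_map_nifti",
]

MASK_FRACTION_DEFAULT = 0.05


class EmptyROIError(ValueError):
    """Raised when an ROI contains no valid voxels."""


@dataclass
class ComplexVolume:
    """3D complex image volume from one pass of the two-pass acquisition.

    ``data`` uses the canonical signal orientation (FID-like component on the
    real axis, echo-like on the imaginary axis); ``phase_increment_sign`` is
    +1 or -1 for the sign of the RF phase increment used in this pass.
    """

    data: np.ndarray
    voxel_size: tuple
    phase_increment_sign: int
    seq: SequenceParams | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 3:
            raise ValueError("data must be a 3-D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.phase_increment_sign not in (-1, 1):
            raise ValueError("phase_increment_sign must be +1 or -1")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be three positive lengths (mm)")
        self.voxel_size = vs


@dataclass
class PhaseVolume:
    """Voxelwise tissue phase (degrees) with validity mask."""

    phase_deg: np.ndarray
    mask: np.ndarray
    voxel_size: tuple

    def __post_init__(self) -> None:
        if self.phase_deg.shape != self.mask.shape:
            raise ValueError("phase and mask shapes differ")


@dataclass
class ParameterMap:
    """Voxelwise rate map (s^-1) with clipped/validity masks and provenance."""

    values: np.ndarray
    mask: np.ndarray
    clipped: np.ndarray
    voxel_size: tuple
    quantity: str = "r2"
    provenance: dict = field(default_factory=dict)

    def masked(self) -> np.ndarray:
        out = np.where(self.mask, self.values, np.nan)
        return out


@dataclass(frozen=True)
class ROISpec:
    """Per-slice circular region of interest.

    ``center`` is the (x, y) voxel index of the circle center,
    ``slice_index`` the z index, ``area_cm2`` the prescribed area.
    """

    center: tuple
    slice_index: int
    area_cm2: float

    def __post_init__(self) -> None:
        if not self.area_cm2 > 0:
            raise ValueError("area_cm2 must be positive")

    def rasterize(self, shape: tuple, voxel_size: tuple) -> np.ndarray:
        """Boolean 3-D mask of voxel centers inside the circle."""
        nx, ny, _ = shape
        radius_mm = np.sqrt(self.area_cm2 * 100.0 / np.pi)
        x = (np.arange(nx) - self.center[0]) * voxel_size[0]
        y = (np.arange(ny) - self.center[1]) * voxel_size[1]
        disk = x[:, None] ** 2 + y[None, :] ** 2 <= radius_mm**2
        m = np.zeros(shape, dtype=bool)
        if not 0 <= self.slice_index < shape[2]:
            raise ValueError("ROI slice outside volume")
        if not disk.any():
            raise EmptyROIError("ROI rasterized to zero voxels")
        m[:, :, self.slice_index] = disk
        return m


@dataclass(frozen=True)
class ROIStats:
    mean: float
    sd: float
    n_voxels: int
    n_clipped: int


def _check_pair(plus: ComplexVolume, minus: ComplexVolume) -> None:
    if plus.data.shape != minus.data.shape:
        raise ValueError("two-pass volumes have mismatched dimensions")
    if plus.voxel_size != minus.voxel_size:
        raise ValueError("two-pass volumes have mismatched voxel sizes")
    if plus.phase_increment_sign != 1 or minus.phase_increment_sign != -1:
        raise ValueError("expected phase_increment_sign +1 (plus) and -1 (minus)")
    if plus.seq and minus.seq:
        if abs(plus.seq.phase_increment) != abs(minus.seq.phase_increment):
            raise ValueError("two-pass volumes differ in |phase increment|")


def combine_two_pass(
    plus: ComplexVolume,
    minus: ComplexVolume,
    mask_fraction: float = MASK_FRACTION_DEFAULT,
) -> PhaseVolume:
    """Background-cancelling two-pass combination.

    Tissue phase per voxel = angle(S+ * conj(S-)) / 2 in degrees.  Any
    multiplicative phase field common to both passes cancels exactly.  Voxels
    whose geometric-mean magnitude falls below ``mask_fraction`` of the
    volume's robust maximum (99th percentile) are masked out.
    """
    _check_pair(plus, minus)
    prod = plus.data * np.conj(minus.data)
    phase = np.degrees(np.angle(prod)) / 2.0
    mag = np.sqrt(np.abs(prod))
    ref = np.percentile(mag, 99.0)
    mask = mag > mask_fraction * ref if ref > 0 else np.zeros_like(mag, bool)
    return PhaseVolume(phase_deg=phase, mask=mask, voxel_size=plus.voxel_size)


def spatial_average(volume: ComplexVolume, kernel_size: int = 3) -> ComplexVolume:
    """In-plane uniform complex averaging, slice by slice.

    ``kernel_size`` must be odd; a k x k kernel with weights 1/k^2 is applied
    to the complex data of each slice before any phase extraction.  Edges use
    shrink-to-valid renormalization, so constant volumes are fixed points.
    kernel_size=1 is the identity.
    """
    if kernel_size % 2 == 0 or kernel_size < 1:
        raise ValueError("kernel_size must be a positive odd integer")
    if kernel_size == 1:
        return ComplexVolume(
            data=volume.data.copy(),
            voxel_size=volume.voxel_size,
            phase_increment_sign=volume.phase_increment_sign,
            seq=volume.seq,
        )
    size = (kernel_size, kernel_size, 1)
    num = ndi.uniform_filter(volume.data.real, size=size, mode="constant") + 1j * (
        ndi.uniform_filter(volume.data.imag, size=size, mode="constant")
    )
    den = ndi.uniform_filter(
        np.ones(volume.data.shape[:2]), size=size[:2], mode="constant"
    )[:, :, None]
    return ComplexVolume(
        data=num / den,
        voxel_size=volume.voxel_size,
        phase_increment_sign=volume.phase_increment_sign,
        seq=volume.seq,
    )


def reconstruct_r2(
    plus: ComplexVolume,
    minus: ComplexVolume,
    lut: LookupTable,
    kernel_size: int = 3,
    mask: np.ndarray | None = None,
    mask_fraction: float = MASK_FRACTION_DEFAULT,
) -> tuple[ParameterMap, ParameterMap | None]:
    """Full reconstruction: average, combine, invert.

    Returns an R2 map and, when the lookup carries an R1-R2 calibration
    line, the derived R1 map (both s^-1).  The uncorrected variant of the
    pipeline is obtained with a fixed-R1 lookup and kernel_size=1.
    """
    _check_pair(plus, minus)
    if lut.seq is not None and plus.seq is not None:
        ls, ps = lut.seq, plus.seq
        if (
            ls.tr != ps.tr
            or ls.flip_angle != ps.flip_angle
            or abs(ls.phase_increment) != abs(ps.phase_increment)
        ):
            raise ValueError(
                "lookup table was built for different sequence parameters "
                f"(lut: TR={ls.tr}, flip={ls.flip_angle}, |inc|={abs(ls.phase_increment)}; "
                f"volume: TR={ps.tr}, flip={ps.flip_angle}, |inc|={abs(ps.phase_increment)})"
            )
    p_avg = spatial_average(plus, kernel_size)
    m_avg = spatial_average(minus, kernel_size)
    phase = combine_two_pass(p_avg, m_avg, mask_fraction)
    valid = phase.mask if mask is None else (phase.mask & mask)
    r2, clipped = invert_phase_array(lut, phase.phase_deg)
    prov = {
        "kernel_size": kernel_size,
        "lookup_range": [float(lut.r2_grid[0]), float(lut.r2_grid[-1])],
        "lookup_grid_step": lut.grid_step,
        "r1_model": "calibrated" if lut.calibrated else float(lut.r1_model),
        "effective_inplane_footprint_mm": [
            kernel_size * plus.voxel_size[0],
            kernel_size * plus.voxel_size[1],
        ],
    }
    r2_map = ParameterMap(
        values=r2,
        mask=valid,
        clipped=clipped & valid,
        voxel_size=plus.voxel_size,
        quantity="r2",
        provenance=prov,
    )
    r1_map = None
    if lut.calibrated:
        r1_map = ParameterMap(
            values=lut.r1_model(r2),
            mask=valid,
            clipped=clipped & valid,
            voxel_size=plus.voxel_size,
            quantity="r1",
            provenance=prov,
        )
    return r2_map, r1_map


def roi_stats(target: ParameterMap | PhaseVolume, roi: ROISpec) -> ROIStats:
    """Mean/SD statistics over the unmasked voxels of a circular ROI."""
    if isinstance(target, ParameterMap):
        values, mask, clipped = target.values, target.mask, target.clipped
        vs = target.voxel_size
    else:
        values, mask, clipped = target.phase_deg, target.mask, None
        vs = target.voxel_size
    m = roi.rasterize(values.shape, vs) & mask
    if not m.any():
        raise EmptyROIError("no valid voxels inside ROI after masking")
    sel = values[m]
    n_clipped = int(np.sum(clipped[m])) if clipped is not None else 0
    return ROIStats(
        mean=float(sel.mean()),
        sd=float(sel.std(ddof=1)) if sel.size > 1 else 0.0,
        n_voxels=int(sel.size),
        n_clipped=n_clipped,
    )


# -- NIfTI I/O -------------------------------------------------------------

def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def write_complex_nifti(
    volume: ComplexVolume, base_path: str | Path, dialect: str = "real_imag"
) -> tuple[Path, Path]:
    """Write one pass as a pair of NIfTI volumes.

    ``dialect`` selects the component pair: "real_imag" or "mag_phase"
    (phase in radians).  Returns the two paths written.
    """
    base = Path(base_path)
    aff = _affine(volume.voxel_size)
    if dialect == "real_imag":
        parts = {"real": volume.data.real, "imag": volume.data.imag}
    elif dialect == "mag_phase":
        parts = {"mag": np.abs(volume.data), "phase": np.angle(volume.data)}
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    paths = []
    for suffix, arr in parts.items():
        p = base.with_name(base.name + f"_{suffix}.nii.gz")
        nib.save(nib.Nifti1Image(arr.astype(np.float32), aff), p)
        paths.append(p)
    return tuple(paths)


def read_complex_nifti(
    base_path: str | Path,
    phase_increment_sign: int,
    dialect: str = "real_imag",
    seq: SequenceParams | None = None,
) -> ComplexVolume:
    """Read a pass written by :func:`write_complex_nifti`."""
    base = Path(base_path)
    sfx = ("real", "imag") if dialect == "real_imag" else ("mag", "phase")
    imgs = [nib.load(base.with_name(base.name + f"_{s}.nii.gz")) for s in sfx]
    a, b = (np.asanyarray(i.dataobj, dtype=np.float64) for i in imgs)
    data = a + 1j * b if dialect == "real_imag" else a * np.exp(1j * b)
    vs = tuple(float(z) for z in imgs[0].header.get_zooms()[:3])
    return ComplexVolume(
        data=data, voxel_size=vs, phase_increment_sign=phase_increment_sign, seq=seq
    )


def write_map_nifti(pmap: ParameterMap, path: str | Path) -> Path:
    """Write a parameter map (invalid voxels as NaN) plus JSON provenance."""
    import json

    p = Path(path)
    nib.save(
        nib.Nifti1Image(pmap.masked().astype(np.float32), _affine(pmap.voxel_size)), p
    )
    meta = dict(pmap.provenance, quantity=pmap.quantity)
    p.with_suffix("").with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return p
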
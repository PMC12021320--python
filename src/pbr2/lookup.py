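"""Phase-vs-R2 lookup tables and their inversion.

A lookup table tabulates the noiseless steady-state signal phase of the RF
phase-modulated GRE sequence over a grid of R2 values.  Because a single
measured phase cannot determine (R1, R2) jointly, the R1 entering each table
node comes from an *R1 model*: either a fixed assumed R1 (the uncorrected
variant) or a linear R1-R2 calibration line, R1c(R2) = slope * R2 + intercept,
reflecting the empirical coupling of both rates to tissue iron.  Inverting a
measured phase through a calibrated table yields an R1-corrected R2 estimate
and, through the same line, a derived R1 estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .engine import SequenceParams, SimulationConfig, simulate_signals, signal_phase

__all__ = [
    "CalibrationLine",
    "LookupTable",
    "R2Estimate",
    "LookupBuildError",
    "r1_from_r2",
    "build_lookup",
    "invert_phase",
    "invert_phase_array",
    "max_measurable_r2",
    "LITERATURE_LINES",
    "PHANTOM_LINES",
    "FIXED_T1_MS",
    "default_r2_grid",
]


@dataclass(frozen=True)
class CalibrationLine:
    """Linear R1-R2 coupling: R1c(R2) = slope * R2 + intercept (s^-1)."""

    slope: float
    intercept: float
    field_strength: float
    source: str = "user"

    def __post_init__(self) -> None:
        if not self.intercept > 0:
            raise ValueError("intercept must be positive")
        if self.slope < 0:
            raise ValueError("slope must be non-negative")

    def __call__(self, r2):
        return self.slope * np.asarray(r2, dtype=float) + self.intercept


#: Literature iron-overload liver calibration (multi-center study), per field.
LITERATURE_LINES = {
    1.5: CalibrationLine(6.5e-3, 1.23, 1.5, source="literature"),
    3.0: CalibrationLine(3.8e-3, 0.89, 3.0, source="literature"),
}

#: MnCl2 agarose vial phantom calibration, per field.
PHANTOM_LINES = {
    1.5: CalibrationLine(0.14, 0.59, 1.5, source="phantom"),
    3.0: CalibrationLine(9.2e-2, 1.3, 3.0, source="phantom"),
}

#: Fixed-T1 defaults (ms) for the uncorrected lookup variant.
FIXED_T1_MS = {"phantom": 1000.0, 1.5: 576.0, 3.0: 812.0}


def default_r2_grid(lo: float = 10.0, hi: float = 300.0, step: float = 1.0):
    """Default lookup grid: R2 from 10 to 300 s^-1 at 1 s^-1 spacing."""
    return np.arange(lo, hi + step / 2, step)


def r1_from_r2(cal: CalibrationLine, r2):
    """Evaluate the calibration line at r2 (s^-1)."""
    r2 = np.asarray(r2, dtype=float)
    if np.any(r2 < 0):
        raise ValueError("r2 must be non-negative")
    return cal(r2)


class LookupBuildError(ValueError):
    """Raised when a constructed phase grid is not strictly monotone."""


@dataclass(frozen=True)
class LookupTable:
    """Monotone phase-vs-R2 table for a fixed sequence parameter set.

    ``r1_model`` is either a fixed R1 value (float, s^-1) or a
    :class:`CalibrationLine`; it records how R1 was coupled to R2 when the
    table was built and enables the derived R1 estimate on inversion.
    """

    r2_grid: np.ndarray
    phase_grid: np.ndarray
    r1_model: float | CalibrationLine
    seq: SequenceParams

    def __post_init__(self) -> None:
        object.__setattr__(self, "r2_grid", np.asarray(self.r2_grid, dtype=float))
        object.__setattr__(self, "phase_grid", np.asarray(self.phase_grid, dtype=float))
        if self.r2_grid.shape != self.phase_grid.shape or self.r2_grid.ndim != 1:
            raise ValueError("r2_grid and phase_grid must be matching 1-D arrays")
        if not np.all(np.diff(self.r2_grid) > 0):
            raise ValueError("r2_grid must be strictly increasing")
        d = np.diff(self.phase_grid)
        if not np.all(d < 0):
            i = int(np.argmax(d >= 0))
            raise LookupBuildError(
                "phase grid is not strictly decreasing on "
                f"[{self.r2_grid[i]:g}, {self.r2_grid[i + 1]:g}] s^-1"
            )

    @property
    def grid_step(self) -> float:
        return float(np.max(np.diff(self.r2_grid)))

    @property
    def calibrated(self) -> bool:
        return isinstance(self.r1_model, CalibrationLine)

    def r1_values(self) -> np.ndarray:
        """R1 (s^-1) used at each table node."""
        if self.calibrated:
            return self.r1_model(self.r2_grid)
        return np.full_like(self.r2_grid, float(self.r1_model))

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        meta = {
            "seq": {
                "tr": self.seq.tr,
                "te": self.seq.te,
                "flip_angle": self.seq.flip_angle,
                "phase_increment": self.seq.phase_increment,
                "field_strength": self.seq.field_strength,
            },
            "r1_model": (
                {
                    "slope": self.r1_model.slope,
                    "intercept": self.r1_model.intercept,
                    "field_strength": self.r1_model.field_strength,
                    "source": self.r1_model.source,
                }
                if self.calibrated
                else float(self.r1_model)
            ),
            "r2_grid": self.r2_grid.tolist(),
            "phase_grid": self.phase_grid.tolist(),
        }
        Path(path).write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LookupTable":
        meta = json.loads(Path(path).read_text())
        r1m = meta["r1_model"]
        if isinstance(r1m, dict):
            r1m = CalibrationLine(**r1m)
        return cls(
            r2_grid=np.asarray(meta["r2_grid"]),
            phase_grid=np.asarray(meta["phase_grid"]),
            r1_model=r1m,
            seq=SequenceParams(**meta["seq"]),
        )

    def to_csv(self, path: str | Path) -> None:
        arr = np.column_stack([self.r2_grid, self.phase_grid])
        np.savetxt(path, arr, delimiter=",", header="r2_s-1,phase_deg", comments="")


@dataclass(frozen=True)
class R2Estimate:
    """Result of inverting one measured phase.

    ``clipped`` is set when the raw phase fell outside the table's phase
    range and the estimate was pinned to a grid boundary.
    """

    r2: float
    r1: float | None = None
    clipped: bool = False


def build_lookup(
    seq: SequenceParams,
    r1_model: float | CalibrationLine,
    r2_grid=None,
    config: SimulationConfig | None = None,
) -> LookupTable:
    """Build a phase-vs-R2 lookup table by steady-state simulation.

    For a fixed r1_model the same R1 is used at every node; for a
    :class:`CalibrationLine`, R1 follows the line at each node.  The table is
    validated to be strictly decreasing in phase before being returned.
    """
    r2_grid = default_r2_grid() if r2_grid is None else np.asarray(r2_grid, float)
    if not np.all(np.diff(r2_grid) > 0):
        raise ValueError("r2_grid must be strictly increasing")
    if isinstance(r1_model, CalibrationLine):
        r1 = r1_model(r2_grid)
    else:
        r1 = np.full_like(r2_grid, float(r1_model))
    z = simulate_signals(seq, r1, r2_grid, config)
    return LookupTable(
        r2_grid=r2_grid, phase_grid=signal_phase(z), r1_model=r1_model, seq=seq
    )


def invert_phase_array(lut: LookupTable, measured_phase) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized inversion of measured phases (degrees) through a table.

    Returns ``(r2, clipped)`` arrays.  Phases at or below the table minimum
    (including non-physical negative phases) map to max(r2_grid) with the
    clipped flag set; phases at or above the table maximum map to
    min(r2_grid) with the clipped flag set.  NaN phases yield NaN estimates.
    Linear interpolation is used between grid nodes.
    """
    ph = np.asarray(measured_phase, dtype=float)
    # phase_grid is strictly decreasing; np.interp needs increasing x
    r2 = np.interp(-ph, -lut.phase_grid, lut.r2_grid)
    lo, hi = lut.phase_grid[-1], lut.phase_grid[0]
    with np.errstate(invalid="ignore"):
        clipped = (ph <= lo) | (ph >= hi)
    r2 = np.where(np.isnan(ph), np.nan, r2)
    clipped = clipped & ~np.isnan(ph)
    return r2, clipped


def invert_phase(lut: LookupTable, measured_phase: float) -> R2Estimate:
    """Invert one measured phase (degrees) to an R2 (and derived R1) estimate."""
    r2, clipped = invert_phase_array(lut, measured_phase)
    r2 = float(r2)
    r1 = None
    if lut.calibrated and not np.isnan(r2):
        r1 = float(lut.r1_model(r2))
    return R2Estimate(r2=r2, r1=r1, clipped=bool(clipped))


def max_measurable_r2(lut: LookupTable, phase_floor: float) -> R2Estimate:
    """R2 at which the lookup phase falls to ``phase_floor`` (degrees).

    The crossing is linearly interpolated on the table.  A floor below the
    table's minimum phase returns max(r2_grid) with the clipped flag set.
    """
    if not 0 < phase_floor < lut.phase_grid[0]:
        raise ValueError(
            "phase_floor must lie in (0, max(phase_grid)) = "
            f"(0, {lut.phase_grid[0]:.3f})"
        )
    if phase_floor < lut.phase_grid[-1]:
        return R2Estimate(r2=float(lut.r2_grid[-1]), clipped=True)
    r2 = float(np.interp(-phase_floor, -lut.phase_grid, lut.r2_grid))
    return R2Estimate(r2=r2, clipped=False)
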
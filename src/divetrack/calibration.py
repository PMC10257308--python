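"""Per-axis affine calibration of raw accelerometer/magnetometer counts.

Before deployment each tag is rotated through all orientations; the raw
minimum and maximum recorded on each axis are mapped linearly onto the
physical range (+-4 G for acceleration, the local field magnitude for the
magnetometer).  Only independent per-axis affine maps are fitted here;
soft/hard-iron ellipsoid correction is deliberately out of scope.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np


class DegenerateCalibrationError(ValueError):
    """raw_max <= raw_min: the rotation sweep did not exercise the axis."""


@dataclass(frozen=True)
class AxisCalibration:
    raw_min: float
    raw_max: float
    target_min: float
    target_max: float

    @property
    def slope(self) -> float:
        return (self.target_max - self.target_min) / (self.raw_max - self.raw_min)

    @property
    def intercept(self) -> float:
        return self.target_min - self.slope * self.raw_min

    def apply(self, raw):
        return self.slope * np.asarray(raw, dtype=float) + self.intercept

    def invert(self, value):
        return (np.asarray(value, dtype=float) - self.intercept) / self.slope


def fit_axis_calibration(
    raw_min: float, raw_max: float, target_min: float, target_max: float
) -> AxisCalibration:
    """Linear map sending [raw_min, raw_max] onto [target_min, target_max]."""
    if raw_max <= raw_min:
        raise DegenerateCalibrationError(
            f"raw_max ({raw_max}) must exceed raw_min ({raw_min})"
        )
    if target_max <= target_min:
        raise ValueError(f"target_max ({target_max}) must exceed target_min ({target_min})")
    return AxisCalibration(raw_min, raw_max, target_min, target_max)


def apply_calibration(series, calibrations: Mapping[str, AxisCalibration]):
    """Apply per-axis calibrations to an AccelSeries or MagSeries.

    ``calibrations`` maps field names of the series (e.g. 'surge', 'sway',
    'heave' or 'mx', 'my', 'mz') to AxisCalibration.  Timestamps unchanged.
    """
    updates = {}
    for axis, cal in calibrations.items():
        if not hasattr(series, axis):
            raise ValueError(f"series has no axis {axis!r}")
        updates[axis] = cal.apply(getattr(series, axis))
    return replace(series, **updates)


def read_calibration_file(path: str | Path) -> dict[str, AxisCalibration]:
    """Read a calibration CSV: axis, raw_min, raw_max, target_min, target_max."""
    out: dict[str, AxisCalibration] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["axis"]] = fit_axis_calibration(
                float(row["raw_min"]), float(row["raw_max"]),
                float(row["target_min"]), float(row["target_max"]),
            )
    return out


def write_calibration_file(path: str | Path, cals: Mapping[str, AxisCalibration]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["axis", "raw_min", "raw_max", "target_min", "target_max"])
        for axis, c in cals.items():
            w.writerow([axis, c.raw_min, c.raw_max, c.target_min, c.target_max])
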
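"""Reading, validating, time-aligning and pre-filtering the four sensor streams.

A deployment yields four asynchronous streams: tri-axial acceleration at a
nominal 25 Hz (G), tri-axial magnetic field at 2 Hz (microtesla), depth at
1 Hz (m, positive down) and intermittent GPS fixes (only while the animal is
at the surface).  This module brings them onto a common footing:

* satellite-count and speed filters discard unreliable GPS fixes;
* the depth record is zero-offset corrected for pressure-transducer drift so
  that surface readings sit at 0 m;
* all streams are cropped to the foraging-trip window and merged onto the
  1 Hz depth clock (acceleration averaged per second, magnetometer linearly
  interpolated).

The 1 Hz depth clock is the master grid because depth drives both dive
segmentation and the dead-reckoning timestep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .geo import haversine_m

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """A sensor file does not have the declared columns/shape."""


class ValidationError(ValueError):
    """A sensor stream violates a structural invariant (e.g. time order)."""


def _check_monotonic(t: np.ndarray, name: str) -> None:
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"{name}: timestamps not strictly increasing at row {bad[0] + 1} "
            f"(t={t[bad[0] + 1]!r} follows t={t[bad[0]]!r})"
        )


@dataclass
class AccelSeries:
    """Tri-axial acceleration: surge (fwd), sway (right), heave (down), in G."""

    t: np.ndarray
    surge: np.ndarray
    sway: np.ndarray
    heave: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        for ax in ("surge", "sway", "heave"):
            setattr(self, ax, np.asarray(getattr(self, ax), dtype=float))
        _check_monotonic(self.t, "accel")

    def __len__(self):
        return self.t.size

    def xyz(self) -> np.ndarray:
        return np.column_stack([self.surge, self.sway, self.heave])

    def crop(self, t0: float, t1: float) -> "AccelSeries":
        m = (self.t >= t0) & (self.t <= t1)
        return AccelSeries(self.t[m], self.surge[m], self.sway[m], self.heave[m])


@dataclass
class MagSeries:
    """Tri-axial magnetic field in device axes (x fwd, y right, z down), microtesla."""

    t: np.ndarray
    mx: np.ndarray
    my: np.ndarray
    mz: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        for ax in ("mx", "my", "mz"):
            v = np.asarray(getattr(self, ax), dtype=float)
            setattr(self, ax, v)
        _check_monotonic(self.t, "mag")

    def __len__(self):
        return self.t.size

    def crop(self, t0: float, t1: float) -> "MagSeries":
        m = (self.t >= t0) & (self.t <= t1)
        return MagSeries(self.t[m], self.mx[m], self.my[m], self.mz[m])


@dataclass
class DepthSeries:
    """1 Hz depth in metres, positive down."""

    t: np.ndarray
    depth: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        _check_monotonic(self.t, "depth")
        gaps = np.nonzero(np.diff(self.t) > 1.5)[0]
        if gaps.size:
            log.warning("depth: %d gap(s) > 1 s; first at t=%.0f", gaps.size, self.t[gaps[0]])

    def __len__(self):
        return self.t.size

    def crop(self, t0: float, t1: float) -> "DepthSeries":
        m = (self.t >= t0) & (self.t <= t1)
        return DepthSeries(self.t[m], self.depth[m])


@dataclass
class FixSeries:
    """GPS fixes: time, WGS84 lat/lon in degrees, satellite count."""

    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    nsat: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.nsat = np.asarray(self.nsat, dtype=int)
        _check_monotonic(self.t, "fixes")
        if self.lat.size and (np.abs(self.lat).max() > 90 or np.abs(self.lon).max() > 180):
            raise ValidationError("fixes: lat/lon outside WGS84 bounds")

    def __len__(self):
        return self.t.size

    def take(self, idx) -> "FixSeries":
        return FixSeries(self.t[idx], self.lat[idx], self.lon[idx], self.nsat[idx])

    def crop(self, t0: float, t1: float) -> "FixSeries":
        return self.take((self.t >= t0) & (self.t <= t1))


@dataclass
class SensorBundle:
    """All four streams for one foraging trip, cropped to the trip window."""

    accel: AccelSeries
    mag: MagSeries
    depth: DepthSeries
    fixes: FixSeries
    trip_window: tuple[float, float]

    def crop(self, t0: float, t1: float) -> "SensorBundle":
        return SensorBundle(
            self.accel.crop(t0, t1),
            self.mag.crop(t0, t1),
            self.depth.crop(t0, t1),
            self.fixes.crop(t0, t1),
            (t0, t1),
        )


# Default CSV column names per stream.
DEFAULT_COLUMNS: Mapping[str, Sequence[str]] = {
    "accel": ("time", "ax", "ay", "az"),
    "mag": ("time", "mx", "my", "mz"),
    "depth": ("time", "depth"),
    "gps": ("time", "lat", "lon", "nsat"),
}


def _read_csv(path: str | Path, cols: Sequence[str], name: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with stream name
        raise FormatError(f"{name}: cannot parse {path}: {exc}") from exc
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{name}: {path} is missing column(s) {missing}; has {list(df.columns)}")
    return df[list(cols)]


def read_sensor_bundle(
    paths: Mapping[str, str | Path],
    config: RunConfig | None = None,
    columns: Mapping[str, Sequence[str]] | None = None,
    trip_window: tuple[float, float] | None = None,
) -> SensorBundle:
    """Read accel/mag/depth(/gps) CSVs and crop all streams to the trip window.

    ``paths`` maps stream names ('accel', 'mag', 'depth', 'gps') to files.
    ``trip_window`` defaults to the intersection of the accel/mag/depth time
    ranges ("data prior to the start and following the end of a foraging trip
    is omitted"); an empty intersection is an error.
    """
    config = config or RunConfig()
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    frames = {}
    for name in ("accel", "mag", "depth", "gps"):
        if name not in paths:
            raise FormatError(f"missing required input file for stream {name!r}")
        frames[name] = _read_csv(paths[name], cols[name], name)
        log.info("%s: read %d rows from %s", name, len(frames[name]), paths[name])

    a, m, d, g = frames["accel"], frames["mag"], frames["depth"], frames["gps"]
    accel = AccelSeries(*(a[c].to_numpy() for c in cols["accel"]))
    mag = MagSeries(*(m[c].to_numpy() for c in cols["mag"]))
    depth = DepthSeries(*(d[c].to_numpy() for c in cols["depth"]))
    fixes = FixSeries(*(g[c].to_numpy() for c in cols["gps"]))

    if np.abs(accel.xyz()).max(initial=0.0) > config.accel_range_g * 1.001:
        raise ValidationError(
            f"accel: values exceed configured sensor range +-{config.accel_range_g} G"
        )

    if trip_window is None:
        t0 = max(accel.t[0], mag.t[0], depth.t[0])
        t1 = min(accel.t[-1], mag.t[-1], depth.t[-1])
    else:
        t0, t1 = trip_window
    if t1 <= t0:
        raise ValidationError(
            f"streams have an empty common time range (intersection [{t0}, {t1}])"
        )
    bundle = SensorBundle(accel, mag, depth, fixes, (t0, t1)).crop(t0, t1)
    log.info(
        "trip window [%.0f, %.0f] s: %d accel / %d mag / %d depth / %d gps rows",
        t0, t1, len(bundle.accel), len(bundle.mag), len(bundle.depth), len(bundle.fixes),
    )
    return bundle


def filter_satellites(fixes: FixSeries, min_sat: int = 5) -> FixSeries:
    """Keep fixes computed from at least ``min_sat`` satellites.

    Fastloc positions derived from four or fewer satellites are unreliable,
    hence the default keeps nsat >= 5.
    """
    if min_sat < 0:
        raise ValueError("min_sat must be >= 0")
    return fixes.take(fixes.nsat >= min_sat)


def speed_filter(fixes: FixSeries, vmax: float = 6.0) -> FixSeries:
    """Drop fixes implying unrealistic travel speed (default > 6 m/s).

    Forward-sequential rule: walking the series in time order, a fix whose
    great-circle speed from the *last retained* fix exceeds ``vmax`` is
    dropped.  Idempotent: retained consecutive pairs all satisfy the bound.
    """
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    n = len(fixes)
    if n <= 1:
        return fixes
    keep = [0]
    for i in range(1, n):
        j = keep[-1]
        dt = fixes.t[i] - fixes.t[j]
        dist = haversine_m(fixes.lat[j], fixes.lon[j], fixes.lat[i], fixes.lon[i])
        if dt > 0 and dist / dt <= vmax:
            keep.append(i)
    dropped = n - len(keep)
    if dropped:
        log.info("speed_filter: dropped %d of %d fixes above %.1f m/s", dropped, n, vmax)
    return fixes.take(np.asarray(keep, dtype=int))


def zero_offset_correct(
    depth: DepthSeries,
    window_s: float = 7200.0,
    quantile: float = 0.10,
    surface_max_m: float = 3.0,
    clip_negative: bool = True,
) -> DepthSeries:
    """Remove slow pressure-transducer drift so surface readings sit at 0 m.

    The baseline is the rolling ``quantile`` (default 10th percentile) of
    near-surface samples (raw depth < ``surface_max_m``) over a ``window_s``
    window, interpolated across dives and subtracted from the whole record.
    With no surface candidates at all (an always-submerged record) the series
    is returned unchanged with a warning.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if len(depth) == 0:
        raise ValueError("empty depth series")
    s = pd.Series(depth.depth, index=pd.Index(depth.t))
    surface = s.where(s < surface_max_m)
    if surface.notna().sum() == 0:
        log.warning("zero_offset_correct: no surface candidates below %.1f m; identity applied",
                    surface_max_m)
        return replace(depth)
    win = max(int(round(window_s)), 1)  # samples; depth is nominally 1 Hz
    baseline = surface.rolling(win, center=True, min_periods=1).quantile(quantile)
    baseline = baseline.interpolate(method="index", limit_direction="both")
    corrected = (s - baseline).to_numpy()
    if clip_negative:
        corrected = np.maximum(corrected, 0.0)
    return DepthSeries(depth.t, corrected)


def align_streams(bundle: SensorBundle) -> pd.DataFrame:
    """Merge all streams onto the 1 Hz depth clock.

    Returns a DataFrame with one row per depth sample: ``t``, per-second mean
    acceleration (``ax, ay, az``), per-second mean VeDBA-ready sample count
    ``n_accel``, linearly interpolated magnetometer (``mx, my, mz``) and
    ``depth``.  Rows where any channel is unavailable have NaN there and
    ``ok=False``; downstream dead-reckoning skips (and interpolates across)
    them.
    """
    t0 = max(bundle.accel.t[0], bundle.mag.t[0], bundle.depth.t[0])
    t1 = min(bundle.accel.t[-1], bundle.mag.t[-1], bundle.depth.t[-1])
    if t1 <= t0:
        raise ValidationError("align_streams: streams do not overlap in time")
    m = (bundle.depth.t >= t0) & (bundle.depth.t <= t1)
    grid = bundle.depth.t[m]
    out = pd.DataFrame({"t": grid, "depth": bundle.depth.depth[m]})

    # accel: mean of samples with floor(t) == grid second
    sec = np.floor(bundle.accel.t).astype(np.int64)
    acc = pd.DataFrame(
        {"sec": sec, "ax": bundle.accel.surge, "ay": bundle.accel.sway, "az": bundle.accel.heave}
    )
    per_sec = acc.groupby("sec").agg(
        ax=("ax", "mean"), ay=("ay", "mean"), az=("az", "mean"), n_accel=("ax", "size")
    )
    key = np.floor(grid).astype(np.int64)
    out = out.join(per_sec.reindex(key).set_index(out.index))
    out["n_accel"] = out["n_accel"].fillna(0).astype(int)

    # mag: linear interpolation onto the grid (no extrapolation)
    for ch in ("mx", "my", "mz"):
        v = getattr(bundle.mag, ch)
        interp = np.interp(grid, bundle.mag.t, v, left=np.nan, right=np.nan)
        inside = (grid >= bundle.mag.t[0]) & (grid <= bundle.mag.t[-1])
        interp[~inside] = np.nan
        out[ch] = interp

    out["ok"] = out[["ax", "ay", "az", "mx", "my", "mz", "depth"]].notna().all(axis=1)
    n_bad = int((~out["ok"]).sum())
    if n_bad:
        log.warning("align_streams: %d of %d rows have missing channels", n_bad, len(out))
    return out
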
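"""Dead-reckoning: from calibrated sensors to a georeferenced 3-D track.

The reconstruction follows the standard biologging recipe:

1. a 3-s centred running mean splits acceleration into *static* (gravity,
   i.e. body orientation) and *dynamic* (locomotion) components;
2. pitch and roll come from the static gravity vector, heading from the
   tilt-compensated magnetometer plus the local magnetic declination;
3. speed is estimated per second (by default from the vertical depth rate and
   pitch, with a fallback when the animal is near-horizontal; a VeDBA-
   proportional strategy is available as an alternative);
4. heading/speed/pitch are integrated into a dead-reckoned "pseudo-track" in
   local east/north metres;
5. the pseudo-track is coerced through the filtered GPS fixes: within each
   inter-fix segment the position error (drift) is distributed linearly in
   time, so the track passes through every fix exactly.

Axis convention (fixed for the whole package): x surge forward, y sway right,
z heave down, so level posture gives a static vector of (0, 0, +1) G, pitch
is positive nose-up and roll positive right-side-down.  Headings are radians
clockwise from true north in [0, 2*pi).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MagneticModel, RunConfig
from .geo import enu_offset_m, haversine_m, offset_to_latlon, wrap_heading
from .sensor_io import AccelSeries, FixSeries

log = logging.getLogger(__name__)


@dataclass
class Attitude:
    """Per-sample pitch/roll in radians; ``flagged`` marks interpolated samples."""

    t: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    flagged: np.ndarray


@dataclass
class PseudoTrack:
    """Dead-reckoned path in metres east/north of the trip origin."""

    t: np.ndarray
    x_east: np.ndarray
    y_north: np.ndarray
    depth: np.ndarray


@dataclass
class GeoTrack:
    """Georeferenced 1 Hz track; ``step_dist`` is metres from the previous sample."""

    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    depth: np.ndarray
    step_dist: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "lat": self.lat, "lon": self.lon,
             "depth": self.depth, "step_dist": self.step_dist}
        )

    def total_distance_m(self) -> float:
        return float(np.nansum(self.step_dist))


def split_static_dynamic(accel: AccelSeries, window_s: float = 3.0):
    """Split acceleration into static (gravity) and dynamic components.

    Static is the centred running mean over ``window_s`` per axis (a high-pass
    filter in the complementary sense: dynamic = input - static, an exact
    decomposition).  Window edges use shrunken windows.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n = len(accel)
    if n < 2:
        raise ValueError("accel series too short")
    dt = np.median(np.diff(accel.t))
    win = max(int(round(window_s / dt)), 1)
    if n <= win:
        raise ValueError(f"accel series ({n} samples) shorter than window ({win} samples)")
    df = pd.DataFrame({"x": accel.surge, "y": accel.sway, "z": accel.heave})
    sm = df.rolling(win, center=True, min_periods=1).mean()
    static = AccelSeries(accel.t, sm["x"].to_numpy(), sm["y"].to_numpy(), sm["z"].to_numpy())
    dynamic = AccelSeries(
        accel.t,
        accel.surge - static.surge,
        accel.sway - static.sway,
        accel.heave - static.heave,
    )
    return static, dynamic


def vedba(dynamic: AccelSeries) -> np.ndarray:
    """Vectorial dynamic body acceleration per sample (G)."""
    return np.sqrt(dynamic.surge**2 + dynamic.sway**2 + dynamic.heave**2)


def _interp_flagged(t, values, flagged, circular=False):
    good = ~flagged
    if good.sum() == 0:
        return values
    v = values.copy()
    if circular:
        unwrapped = np.unwrap(values[good])
        v[flagged] = np.interp(t[flagged], t[good], unwrapped)
        v[flagged] = wrap_heading(v[flagged])
    else:
        v[flagged] = np.interp(t[flagged], t[good], values[good])
    return v


def attitude_from_static(static: AccelSeries, min_norm_g: float = 0.2) -> Attitude:
    """Pitch/roll from the static gravity vector.

    pitch = atan2(-gx, hypot(gy, gz)) (nose-up positive),
    roll  = atan2(gy, gz) (right-side-down positive).
    Samples whose static norm falls below ``min_norm_g`` (free-fall or sensor
    dropouts) are flagged and attitude is interpolated from the neighbours.
    """
    gx, gy, gz = static.surge, static.sway, static.heave
    norm = np.sqrt(gx**2 + gy**2 + gz**2)
    flagged = ~np.isfinite(norm) | (norm < min_norm_g)
    with np.errstate(invalid="ignore", divide="ignore"):
        pitch = np.arctan2(-gx, np.hypot(gy, gz))
        roll = np.arctan2(gy, gz)
    pitch = _interp_flagged(static.t, pitch, flagged)
    roll = _interp_flagged(static.t, roll, flagged)
    if flagged.any():
        log.warning("attitude: %d low-|g| samples interpolated", int(flagged.sum()))
    return Attitude(static.t, pitch, roll, flagged)


def tilt_compensated_heading(
    mx, my, mz, pitch, roll,
    model: MagneticModel,
    t=None,
    min_horizontal=1e-6,
):
    """True heading from tilt-compensated magnetometer readings.

    The body-frame field is de-rotated by roll then pitch back to the
    horizontal plane:

        mxh = mx*cosP + (my*sinR + mz*cosR)*sinP
        myh = my*cosR - mz*sinR

    and heading = wrap(atan2(-myh, mxh) + declination).  Samples whose
    horizontal field magnitude is below ``min_horizontal`` (gimbal-degenerate
    or dropout) are flagged and interpolated along ``t`` when given.
    """
    mx, my, mz = (np.asarray(v, dtype=float) for v in (mx, my, mz))
    cp, sp = np.cos(pitch), np.sin(pitch)
    cr, sr = np.cos(roll), np.sin(roll)
    mxh = mx * cp + (my * sr + mz * cr) * sp
    myh = my * cr - mz * sr
    horiz = np.hypot(mxh, myh)
    flagged = ~np.isfinite(horiz) | (horiz < min_horizontal)
    decl = np.radians(model.declination_deg)
    with np.errstate(invalid="ignore"):
        heading = wrap_heading(np.arctan2(-myh, mxh) + decl)
    if t is not None and flagged.any():
        heading = _interp_flagged(np.asarray(t, dtype=float), heading, flagged, circular=True)
        log.warning("heading: %d degenerate samples interpolated", int(flagged.sum()))
    return heading, flagged


def estimate_speed(
    depth_rate,
    pitch,
    fallback: float = 1.0,
    pitch_min_deg: float = 5.0,
    clip: float = 12.0,
):
    """Swim speed from vertical rate and pitch: |dz/dt| / |sin(pitch)|.

    Near-horizontal samples (|pitch| < ``pitch_min_deg``) carry no usable
    vertical signal and get ``fallback``.  Results are clipped to [0, clip];
    multiplicative speed error is later absorbed by the GPS coercion.
    """
    if fallback <= 0:
        raise ValueError("fallback must be positive")
    depth_rate = np.asarray(depth_rate, dtype=float)
    pitch = np.asarray(pitch, dtype=float)
    steep = np.abs(pitch) >= np.radians(pitch_min_deg)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.abs(depth_rate) / np.abs(np.sin(pitch))
    s = np.where(steep, s, fallback)
    return np.clip(np.nan_to_num(s, nan=fallback), 0.0, clip)


def estimate_speed_interpolated(
    depth_rate,
    pitch,
    t,
    fallback: float = 1.0,
    pitch_min_deg: float = 5.0,
    clip: float = 12.0,
    max_gap_s: float = 30.0,
):
    """Depth-rate speed with time-interpolated low-pitch gaps.

    Swim speed is continuous, so samples too level for the vertical-rate
    estimate (|pitch| < ``pitch_min_deg``) take the linear interpolation of
    the nearest reliable estimates when those are within ``max_gap_s``; only
    isolated stretches (e.g. surface transit) drop to the constant
    ``fallback``.  Reliable estimates are median-filtered (5 samples) first:
    at phase transitions the attitude and depth-rate smoothing kernels
    disagree briefly, and the raw ratio spikes there.
    """
    from scipy.signal import medfilt

    t = np.asarray(t, dtype=float)
    depth_rate = np.asarray(depth_rate, dtype=float)
    pitch = np.asarray(pitch, dtype=float)
    steep = np.abs(pitch) >= np.radians(pitch_min_deg)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.abs(depth_rate) / np.abs(np.sin(pitch))
    s = np.clip(np.nan_to_num(s, nan=fallback), 0.0, clip)
    if not steep.any():
        return np.full_like(t, fallback)
    out = s.copy()
    tg, sg = t[steep], s[steep]
    if sg.size >= 5:
        sg = medfilt(sg, kernel_size=5)
    out[steep] = sg
    idx = np.nonzero(~steep)[0]
    if idx.size:
        out[idx] = np.interp(t[idx], tg, sg)
        # distance to nearest reliable sample; beyond max_gap use the constant
        pos = np.searchsorted(tg, t[idx])
        left = np.where(pos > 0, t[idx] - tg[np.maximum(pos - 1, 0)], np.inf)
        right = np.where(pos < tg.size, tg[np.minimum(pos, tg.size - 1)] - t[idx], np.inf)
        far = np.minimum(left, right) > max_gap_s
        out[idx[far]] = fallback
    return out


def integrate_pseudo_track(heading, speed, pitch, t, depth=None, origin=(0.0, 0.0)) -> PseudoTrack:
    """Integrate heading/speed/pitch into a local east/north pseudo-track.

    Per step the horizontal displacement is speed*dt*cos(pitch) along the
    heading; the reported position at sample i includes step i's displacement
    (so 60 one-second steps due east at 1 m/s end at x_east = 60 m).
    """
    heading = np.asarray(heading, dtype=float)
    speed = np.asarray(speed, dtype=float)
    pitch = np.asarray(pitch, dtype=float)
    t = np.asarray(t, dtype=float)
    dt = np.empty_like(t)
    dt[1:] = np.diff(t)
    dt[0] = dt[1] if t.size > 1 else 1.0
    d = speed * dt * np.cos(pitch)
    x = origin[0] + np.cumsum(d * np.sin(heading))
    y = origin[1] + np.cumsum(d * np.cos(heading))
    if depth is None:
        depth = np.zeros_like(t)
    return PseudoTrack(t, x, y, np.asarray(depth, dtype=float))


def georeference(pseudo: PseudoTrack, fixes: FixSeries) -> GeoTrack:
    """Coerce the pseudo-track through consecutive GPS fixes.

    For each inter-fix segment the drift (fix position minus dead-reckoned
    position, in local metres) is distributed linearly in elapsed time, so the
    corrected track passes through every fix; before the first and after the
    last fix the nearest fix's constant drift is applied.  Conversion between
    degrees and metres uses equirectangular scaling at the mean fix latitude;
    step distances are haversine on the final coordinates.
    """
    inside = (fixes.t >= pseudo.t[0]) & (fixes.t <= pseudo.t[-1])
    if inside.sum() < len(fixes):
        log.warning("georeference: %d fix(es) outside track range trimmed",
                    int(len(fixes) - inside.sum()))
    fx = fixes.take(np.nonzero(inside)[0])
    if len(fx) < 2:
        raise ValueError("georeference needs at least 2 fixes inside the track time range")

    lat0 = float(np.mean(fx.lat))
    lon0 = float(np.mean(fx.lon))
    fe, fn = enu_offset_m(lat0, lon0, fx.lat, fx.lon)

    # pseudo-track position at each fix time (snap to nearest sample)
    idx = np.searchsorted(pseudo.t, fx.t)
    idx = np.clip(idx, 0, pseudo.t.size - 1)
    prev = np.clip(idx - 1, 0, pseudo.t.size - 1)
    closer_prev = np.abs(pseudo.t[prev] - fx.t) < np.abs(pseudo.t[idx] - fx.t)
    idx = np.where(closer_prev, prev, idx)

    drift_e = fe - pseudo.x_east[idx]
    drift_n = fn - pseudo.y_north[idx]

    # piecewise-linear drift in time, constant beyond the first/last fix
    ce = np.interp(pseudo.t, pseudo.t[idx], drift_e)
    cn = np.interp(pseudo.t, pseudo.t[idx], drift_n)
    e = pseudo.x_east + ce
    n = pseudo.y_north + cn
    lat, lon = offset_to_latlon(lat0, lon0, e, n)

    step = np.zeros_like(lat)
    step[1:] = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    return GeoTrack(pseudo.t, lat, lon, pseudo.depth, step)


def dead_reckon(merged: pd.DataFrame, fixes: FixSeries, config: RunConfig,
                accel_25hz: AccelSeries | None = None) -> GeoTrack:
    """Full dead-reckoning driver on an aligned 1 Hz frame.

    ``merged`` is the output of :func:`divetrack.sensor_io.align_streams`
    (with the zero-offset-corrected depth).  When the native 25 Hz
    acceleration is supplied the static/dynamic split runs at 25 Hz and the
    static vector is averaged per second; otherwise the split runs on the
    per-second means.
    """
    t = merged["t"].to_numpy(dtype=float)
    depth = merged["depth"].to_numpy(dtype=float)

    if accel_25hz is not None:
        static25, dynamic25 = split_static_dynamic(accel_25hz, config.highpass_window_s)
        sec = np.floor(accel_25hz.t).astype(np.int64)
        df = pd.DataFrame({
            "sec": sec,
            "sx": static25.surge, "sy": static25.sway, "sz": static25.heave,
            "v": vedba(dynamic25),
        }).groupby("sec").mean()
        key = np.floor(t).astype(np.int64)
        df = df.reindex(key)
        static = AccelSeries(t, df["sx"].to_numpy(), df["sy"].to_numpy(), df["sz"].to_numpy())
        vedba_1hz = df["v"].to_numpy()
    else:
        acc = AccelSeries(
            t, merged["ax"].to_numpy(), merged["ay"].to_numpy(), merged["az"].to_numpy()
        )
        static, dynamic = split_static_dynamic(acc, config.highpass_window_s)
        vedba_1hz = vedba(dynamic)

    att = attitude_from_static(static)
    heading, _ = tilt_compensated_heading(
        merged["mx"].to_numpy(), merged["my"].to_numpy(), merged["mz"].to_numpy(),
        att.pitch, att.roll, config.magnetic, t=t,
    )

    # depth rate from lightly smoothed depth (same scale as the attitude window)
    win = max(int(round(config.highpass_window_s)), 1)
    depth_s = pd.Series(depth).rolling(win, center=True, min_periods=1).mean().to_numpy()
    depth_rate = np.gradient(depth_s, t)

    if config.speed_strategy == "vedba":
        speed = np.clip(config.vedba_speed_coeff * np.nan_to_num(vedba_1hz),
                        0.0, config.speed_clip_ms)
    else:
        speed = estimate_speed_interpolated(
            depth_rate, att.pitch, t,
            fallback=config.speed_fallback_ms,
            pitch_min_deg=config.speed_pitch_min_deg,
            clip=config.speed_clip_ms,
        )
    # at the surface the animal transits rather than swims on a heading fix:
    # keep the estimate but zero speed where the record says missing channels
    bad = ~merged["ok"].to_numpy(dtype=bool)
    if bad.any():
        speed = np.where(bad, 0.0, speed)

    pseudo = integrate_pseudo_track(heading, speed, att.pitch, t, depth=depth)
    return georeference(pseudo, fixes)
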
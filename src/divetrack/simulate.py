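"""Seeded synthetic foraging-trip simulator with known ground truth.

Emulates the sensor payload of a benthic-foraging, central-place diver: a
1 Hz depth record, 25 Hz tri-axial acceleration (gravity rotated into the
body frame plus locomotion dynamics and noise), 2 Hz tri-axial magnetic
field (the local Earth field rotated into the body frame plus noise) and
surface-only GPS fixes on a ~2-minute clock — all generated from one true
1 Hz path so that every pipeline stage can be scored against truth.

The trip alternates surface transits with dive cycles.  Each dive descends
at a fixed pitch to a per-dive seabed depth, works the bottom, and ascends.
Two dive archetypes model low- versus high-effort benthic foraging: the
high-effort archetype has a longer bottom duration, larger and more
persistent depth undulations (rugose substrate) and a more volatile heading
(tortuous search), while per-dive swim speed and the dive's position along
the trip are drawn independently of archetype — so bottom speed and colony
distance carry no class signal.  Archetype contrasts are >= 2 pooled
within-archetype standard deviations on bottom time and depth variability
(the tension between a large bottom-distance contrast and keeping
bottom time/distance below the collinearity threshold is discussed in the
methods note).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .deadreckon import GeoTrack
from .geo import enu_offset_m, haversine_m, local_scale_m_per_deg, offset_to_latlon
from .sensor_io import AccelSeries, DepthSeries, FixSeries, MagSeries, SensorBundle


@dataclass
class DiveArchetype:
    """Behavioural parameters of one benthic dive mode.

    The bottom depth profile is the seabed plus a slow sinusoidal substrate
    undulation (amplitude a per-dive draw from ``substrate_amp_frac`` x seabed
    depth, period from ``substrate_period_s``) plus a short-scale OU texture;
    the high-effort mode follows markedly rougher terrain for longer, with a
    more volatile (tortuous) heading.
    """

    name: str
    bottom_duration_mean_s: float
    bottom_duration_sd_s: float
    substrate_amp_frac: tuple[float, float]   # fraction of seabed depth
    substrate_period_s: tuple[float, float]
    rugosity_sd_m: float       # stationary sd of the fine-scale OU texture
    rugosity_tau_s: float      # correlation time of the texture
    heading_sd_rad: float      # stationary sd of the weave about the entry bearing
    heading_tau_s: float       # correlation time of the weave
    seabed_range_m: tuple[float, float] = (30.0, 90.0)
    bottom_duration_min_s: float = 30.0


def default_archetypes() -> tuple[DiveArchetype, DiveArchetype]:
    low = DiveArchetype("low_effort", 75.0, 20.0, (0.0, 0.02), (80.0, 140.0),
                        0.3, 2.0, 0.25, 10.0)
    high = DiveArchetype("high_effort", 135.0, 20.0, (0.06, 0.12), (80.0, 140.0),
                         1.0, 8.0, 1.0, 20.0)
    return low, high


@dataclass
class TripConfig:
    """Simulation parameters; ``seed`` is mandatory for reproducibility."""

    seed: int
    colony_lat: float = -35.994
    colony_lon: float = 137.317
    duration_h: float = 48.0
    transit_speed_ms: float = 1.8
    archetypes: tuple[DiveArchetype, DiveArchetype] = field(default_factory=default_archetypes)
    mixture_weight: float = 0.5          # P(high-effort archetype)
    swim_speed_mean_ms: float = 1.1
    swim_speed_sd_ms: float = 0.25
    swim_speed_range: tuple[float, float] = (0.5, 1.9)
    stationary_frac_range: tuple[float, float] = (0.0, 0.2)
    descent_pitch_deg: float = 60.0
    descent_vrate_ms: float = 1.6
    course_drift_rad: float = 0.25   # per-surface-interval wander of the transit course
    surface_interval_mean_s: float = 90.0
    surface_interval_sd_s: float = 20.0
    surface_interval_min_s: float = 40.0
    fix_interval_s: float = 120.0
    gps_noise_m: float = 15.0        # position error sd of good (>=6 satellite) fixes
    gps_outlier_prob: float = 0.08   # chance a 5-satellite fix is degraded
    gps_outlier_m: float = 350.0     # max error of a degraded 5-satellite fix
    nsat_range: tuple[int, int] = (4, 10)
    accel_hz: int = 25
    mag_hz: int = 2
    accel_noise_g: float = 0.05
    stroke_amp_g: float = 0.15
    stroke_freq_hz: float = 1.4
    mag_noise_ut: float = 0.5
    field_intensity_ut: float = 60.0
    depth_noise_m: float = 0.15
    depth_offset_m: float = 0.8
    declination_deg: float = 7.698
    inclination_deg: float = -68.012

    @classmethod
    def noiseless(cls, seed: int, **overrides) -> "TripConfig":
        """A deterministic-behaviour, noise-free configuration.

        All sensor/GPS noise is zero and the behavioural nuisance draws that
        the reconstruction model cannot observe (per-dive swim-speed spread,
        stationary grubbing, speed bursts) are switched off, with every phase
        swum at the reconstruction's low-pitch fallback speed (1 m/s).
        Isolates the attitude / heading / integration / georeferencing chain
        for exact recovery tests.
        """
        base = dict(
            seed=seed,
            accel_noise_g=0.0, stroke_amp_g=0.0, mag_noise_ut=0.0,
            depth_noise_m=0.0, depth_offset_m=0.0,
            gps_noise_m=0.0, gps_outlier_prob=0.0, nsat_range=(8, 10),
            swim_speed_mean_ms=1.0, swim_speed_sd_ms=0.0,
            transit_speed_ms=1.0,
            descent_vrate_ms=float(np.sin(np.radians(60.0))),
            stationary_frac_range=(0.0, 0.0),
        )
        base.update(overrides)
        return cls(**base)

    def validate(self) -> "TripConfig":
        if self.duration_h <= 0 or self.transit_speed_ms <= 0:
            raise ValueError("duration and transit speed must be positive")
        if not (0.0 < self.mixture_weight < 1.0):
            raise ValueError("mixture_weight must be in (0, 1)")
        for a in self.archetypes:
            if a.bottom_duration_mean_s <= 0 or a.rugosity_tau_s <= 0:
                raise ValueError(f"archetype {a.name}: durations/taus must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        return self


@dataclass
class TripTruth:
    """Ground truth: the 1 Hz path, attitude and the per-dive behaviour table."""

    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    depth: np.ndarray
    heading: np.ndarray
    pitch: np.ndarray
    speed: np.ndarray
    dives: pd.DataFrame  # dive_id, archetype, t_start, t_end, bottom_start, bottom_end, ...


def _wrap_diff(a, b):
    """Smallest signed angle a-b."""
    return (a - b + np.pi) % (2 * np.pi) - np.pi


class _SeqBuilder:
    """Accumulates per-second behaviour segments and the running position."""

    def __init__(self):
        self.depth: list[np.ndarray] = []
        self.pitch: list[np.ndarray] = []
        self.heading: list[np.ndarray] = []
        self.speed: list[np.ndarray] = []
        self.t = 0
        self.x = 0.0
        self.y = 0.0
        self.last_heading = 0.0

    def add(self, depth, pitch, heading, speed):
        depth, pitch, heading, speed = (np.asarray(v, dtype=float)
                                        for v in (depth, pitch, heading, speed))
        self.depth.append(depth)
        self.pitch.append(pitch)
        self.heading.append(heading)
        self.speed.append(speed)
        d = speed * np.cos(pitch)
        self.x += float(np.sum(d * np.sin(heading)))
        self.y += float(np.sum(d * np.cos(heading)))
        self.t += depth.size
        self.last_heading = float(heading[-1])


def _ou_path(rng, n, x0, target, sigma, tau):
    """Discrete OU pulled toward ``target``; returns n samples starting near x0."""
    x = np.empty(n)
    cur = x0
    alpha = 1.0 / max(tau, 1.0)
    for i in range(n):
        cur = cur + alpha * (target - cur) + sigma * rng.standard_normal()
        x[i] = cur
    return x


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return float(np.clip(mean, lo, hi))


def simulate_trip(config: TripConfig) -> tuple[SensorBundle, TripTruth]:
    """Generate one trip's sensor bundle and its ground truth."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_h * 3600))
    sb = _SeqBuilder()
    sb.last_heading = rng.uniform(0, 2 * np.pi)
    outbound = sb.last_heading
    dive_rows = []
    dive_id = 0
    # reserve a final surface stretch so the trip ends (and GPS can fix) at the surface
    reserve = int(max(cfg.surface_interval_mean_s * 2, 180))

    course = outbound

    def surface(dur):
        nonlocal course
        dur = int(dur)
        if dur <= 0:
            return
        # the transit course meanders slowly; the homeward leg tracks the
        # bearing back to the colony from the current position
        course += rng.normal(0.0, cfg.course_drift_rad)
        if sb.t < 0.6 * n:
            target = course
        else:
            target = float(np.mod(np.arctan2(-sb.x, -sb.y), 2 * np.pi))
        h = _ou_path(rng, dur, sb.last_heading,
                     sb.last_heading + _wrap_diff(target, sb.last_heading),
                     0.03, 20.0)
        sb.add(np.zeros(dur), np.zeros(dur), h, np.full(dur, cfg.transit_speed_ms))

    surface(max(300, int(rng.normal(600, 60))))
    down = np.radians(cfg.descent_pitch_deg)
    while True:
        arch_i = int(rng.random() < cfg.mixture_weight)
        arch = cfg.archetypes[arch_i]
        seabed = rng.uniform(*arch.seabed_range_m)
        s = _truncnorm(rng, cfg.swim_speed_mean_ms, cfg.swim_speed_sd_ms, *cfg.swim_speed_range)
        vrate = cfg.descent_vrate_ms
        s_desc = vrate / np.sin(down)
        n_desc = int(np.ceil(seabed / vrate))
        n_bot = int(max(arch.bottom_duration_min_s,
                        rng.normal(arch.bottom_duration_mean_s, arch.bottom_duration_sd_s)))
        surf_dur = int(max(cfg.surface_interval_min_s,
                           rng.normal(cfg.surface_interval_mean_s, cfg.surface_interval_sd_s)))
        if sb.t + 2 * n_desc + n_bot + surf_dur > n - reserve:
            break
        t_start = sb.t

        # descent (vertical rate fixed; burst swimming at s_desc)
        d_desc = np.minimum(vrate * np.arange(1, n_desc + 1), seabed)
        h_desc = _ou_path(rng, n_desc, sb.last_heading, sb.last_heading, 0.03, 10.0)
        sb.add(d_desc, np.full(n_desc, -down), h_desc, np.full(n_desc, s_desc))

        # bottom: seabed + slow substrate undulation + fine OU texture;
        # some seconds stationary (grubbing), speed zero there
        bottom_start = sb.t
        stat_frac = rng.uniform(*cfg.stationary_frac_range)
        moving = rng.random(n_bot) >= stat_frac
        amp = rng.uniform(*arch.substrate_amp_frac) * seabed
        period = rng.uniform(*arch.substrate_period_s)
        phase = rng.uniform(0, 2 * np.pi)
        und = amp * np.sin(2 * np.pi * np.arange(n_bot) / period + phase)
        alpha = 1.0 / arch.rugosity_tau_s
        innov_sd = arch.rugosity_sd_m * np.sqrt(max(2 * alpha - alpha**2, 1e-9))
        w = np.empty(n_bot)
        cur = 0.0
        for i in range(n_bot):
            cur = cur * (1 - alpha) + innov_sd * rng.standard_normal()
            w[i] = cur
        d_bot = np.maximum(seabed + und + w, 1.0)
        # tortuous search: the heading weaves about the entry bearing (bounded
        # OU), so high-effort dives curl without degenerating into closed loops
        h_alpha = 1.0 / arch.heading_tau_s
        h_innov = arch.heading_sd_rad * np.sqrt(max(2 * h_alpha - h_alpha**2, 1e-9))
        dev = np.empty(n_bot)
        cur_h = 0.0
        for i in range(n_bot):
            cur_h = cur_h * (1 - h_alpha) + h_innov * rng.standard_normal()
            dev[i] = cur_h
        h_bot = np.mod(sb.last_heading + dev, 2 * np.pi)
        sp_bot = np.where(moving, s, 0.0)
        sb.add(d_bot, np.zeros(n_bot), h_bot, sp_bot)
        bottom_end = sb.t - 1

        # ascent from wherever the bottom ended
        d0 = d_bot[-1]
        n_asc = int(np.ceil(d0 / vrate))
        d_asc = np.maximum(d0 - vrate * np.arange(1, n_asc + 1), 0.0)
        h_asc = _ou_path(rng, n_asc, sb.last_heading, sb.last_heading, 0.03, 10.0)
        sb.add(d_asc, np.full(n_asc, down), h_asc, np.full(n_asc, s_desc))

        dive_rows.append({
            "dive_id": dive_id, "archetype": arch_i, "archetype_name": arch.name,
            "t_start": t_start, "t_end": sb.t - 1,
            "bottom_start": bottom_start, "bottom_end": bottom_end,
            "seabed_m": seabed, "swim_speed_ms": s,
            "bottom_duration_s": n_bot, "stationary_frac": stat_frac,
        })
        dive_id += 1
        surface(surf_dur)

    surface(n - sb.t)

    depth = np.concatenate(sb.depth)[:n]
    heading = np.concatenate(sb.heading)[:n]
    speed = np.concatenate(sb.speed)[:n]
    t = np.arange(n, dtype=float)

    # Real animals turn and pitch smoothly; smooth the raw behavioural
    # sequences over ~3 s and re-derive pitch from the smoothed depth so the
    # emitted sensors, depth record and true path are mutually consistent.
    depth = np.maximum(
        pd.Series(depth).rolling(3, center=True, min_periods=1).mean().to_numpy(), 0.0)
    heading = np.mod(
        pd.Series(np.unwrap(heading)).rolling(3, center=True, min_periods=1)
        .mean().to_numpy(), 2 * np.pi)
    ddepth = np.concatenate([[0.0], np.diff(depth)])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(speed > 0, -ddepth / np.maximum(speed, 1e-9), 0.0)
    pitch = np.arcsin(np.clip(ratio, -0.95, 0.95))

    # true positions: per-second displacement along heading, reduced by pitch
    d = speed * np.cos(pitch)
    x = np.cumsum(d * np.sin(heading))
    y = np.cumsum(d * np.cos(heading))
    lat, lon = offset_to_latlon(cfg.colony_lat, cfg.colony_lon, x, y)

    truth = TripTruth(t, lat, lon, depth, heading, pitch, speed,
                      pd.DataFrame(dive_rows))

    bundle = _emit_sensors(cfg, rng, t, depth, pitch, heading, speed, lat, lon)
    return bundle, truth


def _emit_sensors(cfg, rng, t, depth, pitch, heading, speed, lat, lon) -> SensorBundle:
    n = t.size
    # ---- depth at 1 Hz: noise + constant transducer offset
    d_obs = depth + cfg.depth_offset_m + rng.normal(0.0, cfg.depth_noise_m, n)
    depth_series = DepthSeries(t.copy(), d_obs)

    # ---- accel at 25 Hz: gravity in body frame (roll = 0) + stroking + noise
    hz = cfg.accel_hz
    ta = np.repeat(t, hz) + np.tile(np.arange(hz) / hz, n)
    p25 = np.repeat(pitch, hz)
    moving25 = np.repeat(speed > 0, hz)
    gx = -np.sin(p25)
    gy = np.zeros_like(p25)
    gz = np.cos(p25)
    stroke = cfg.stroke_amp_g * np.sin(2 * np.pi * cfg.stroke_freq_hz * ta) * moving25
    ax = gx + stroke + rng.normal(0.0, cfg.accel_noise_g, ta.size)
    ay = gy + rng.normal(0.0, cfg.accel_noise_g, ta.size)
    az = gz + 0.6 * cfg.stroke_amp_g * np.cos(2 * np.pi * cfg.stroke_freq_hz * ta) * moving25 \
        + rng.normal(0.0, cfg.accel_noise_g, ta.size)
    accel = AccelSeries(ta, np.clip(ax, -4, 4), np.clip(ay, -4, 4), np.clip(az, -4, 4))

    # ---- mag at 2 Hz: Earth field rotated into the body frame + noise
    mhz = cfg.mag_hz
    tm = np.repeat(t, mhz) + np.tile(np.arange(mhz) / mhz, n)
    pm = np.repeat(pitch, mhz)
    hm = np.repeat(heading, mhz)
    D = np.radians(cfg.declination_deg)
    I = np.radians(cfg.inclination_deg)
    B = cfg.field_intensity_ut
    fN, fE, fD = B * np.cos(I) * np.cos(D), B * np.cos(I) * np.sin(D), B * np.sin(I)
    # body = Rx(roll)^T Ry(pitch)^T Rz(yaw)^T * NED, roll = 0
    c, s_ = np.cos(hm), np.sin(hm)
    x1, y1, z1 = c * fN + s_ * fE, -s_ * fN + c * fE, np.full_like(hm, fD)
    cp, sp = np.cos(pm), np.sin(pm)
    mx = cp * x1 - sp * z1
    my = y1
    mz = sp * x1 + cp * z1
    mag = MagSeries(
        tm,
        mx + rng.normal(0.0, cfg.mag_noise_ut, tm.size),
        my + rng.normal(0.0, cfg.mag_noise_ut, tm.size),
        mz + rng.normal(0.0, cfg.mag_noise_ut, tm.size),
    )

    # ---- GPS: attempts on the fix-interval clock, succeed only at the surface
    times, lats, lons, nsats = [], [], [], []
    mlat, mlon = local_scale_m_per_deg(cfg.colony_lat)
    for ft in np.arange(0.0, n, cfg.fix_interval_s):
        i = int(ft)
        if depth[i] >= 1.0:
            continue
        nsat = int(rng.integers(cfg.nsat_range[0], cfg.nsat_range[1] + 1))
        # position error scales with satellite count: 4-satellite solutions
        # are unreliable (hence the downstream filter), 5-satellite ones are
        # occasionally degraded, the rest carry only gps_noise_m of scatter
        if nsat <= 4:
            err_m = rng.uniform(300.0, 4.0 * cfg.gps_outlier_m)
        elif nsat == 5 and rng.random() < cfg.gps_outlier_prob:
            err_m = rng.uniform(150.0, cfg.gps_outlier_m)
        else:
            err_m = abs(rng.normal(0.0, cfg.gps_noise_m))
        ang = rng.uniform(0, 2 * np.pi)
        la = lat[i] + err_m * np.cos(ang) / mlat
        lo = lon[i] + err_m * np.sin(ang) / mlon
        times.append(float(ft))
        lats.append(la)
        lons.append(lo)
        nsats.append(nsat)
    fixes = FixSeries(np.array(times), np.array(lats), np.array(lons), np.array(nsats))
    return SensorBundle(accel, mag, depth_series, fixes, (float(t[0]), float(n)))


def linear_interpolation_track(fixes: FixSeries, t: np.ndarray, depth=None) -> GeoTrack:
    """Straight-line (linearly interpolated) track between fixes — the baseline
    dead-reckoning is compared against."""
    lat = np.interp(t, fixes.t, fixes.lat)
    lon = np.interp(t, fixes.t, fixes.lon)
    if depth is None:
        depth = np.zeros_like(t)
    step = np.zeros_like(lat)
    step[1:] = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    return GeoTrack(np.asarray(t, dtype=float), lat, lon, np.asarray(depth, dtype=float), step)


def track_rmse_m(track: GeoTrack, truth: TripTruth) -> float:
    """RMS great-circle position error of a track against the true path."""
    tl = np.interp(track.t, truth.t, truth.lat)
    tn = np.interp(track.t, truth.t, truth.lon)
    err = haversine_m(track.lat, track.lon, tl, tn)
    return float(np.sqrt(np.mean(err**2)))


def match_dives_to_truth(dive_df: pd.DataFrame, truth: TripTruth) -> pd.DataFrame:
    """Map each detected dive to the true dive overlapping it most.

    Returns a frame indexed by detected dive_id with ``true_dive`` and
    ``archetype`` columns (NaN where no true dive overlaps).
    """
    rows = {}
    td = truth.dives
    for _, row in dive_df.iterrows():
        s, e = row["t_start"], row["t_end"]
        overlap = np.minimum(td["t_end"], e) - np.maximum(td["t_start"], s)
        if len(overlap) == 0 or overlap.max() <= 0:
            rows[row["dive_id"]] = (np.nan, np.nan)
        else:
            j = overlap.idxmax()
            rows[row["dive_id"]] = (int(td.loc[j, "dive_id"]), int(td.loc[j, "archetype"]))
    return pd.DataFrame.from_dict(rows, orient="index", columns=["true_dive", "archetype"])


def truth_score(
    truth: TripTruth,
    track: GeoTrack | None = None,
    dive_df: pd.DataFrame | None = None,
    cluster_labels: pd.Series | None = None,
) -> dict:
    """Recovery report: track RMSE, dive detection precision/recall, cluster ARI."""
    report: dict = {"n_true_dives": int(len(truth.dives))}
    if track is not None:
        report["track_rmse_m"] = track_rmse_m(track, truth)
    if dive_df is not None:
        report["n_detected_dives"] = int(len(dive_df))
        matched = match_dives_to_truth(dive_df, truth)
        tp = int(matched["true_dive"].notna().sum())
        report["dive_precision"] = tp / max(len(dive_df), 1)
        report["dive_recall"] = (matched["true_dive"].dropna().nunique()
                                 / max(len(truth.dives), 1))
        if cluster_labels is not None:
            joined = matched.join(cluster_labels.rename("pred"), how="inner").dropna()
            report["cluster_ari"] = float(
                adjusted_rand_score(joined["archetype"].astype(int), joined["pred"].astype(int))
            )
    return report


def write_trip_csvs(bundle: SensorBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle in the CSV dialects the ingest stage reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    frames = {
        "accel": pd.DataFrame({"time": bundle.accel.t, "ax": bundle.accel.surge,
                               "ay": bundle.accel.sway, "az": bundle.accel.heave}),
        "mag": pd.DataFrame({"time": bundle.mag.t, "mx": bundle.mag.mx,
                             "my": bundle.mag.my, "mz": bundle.mag.mz}),
        "depth": pd.DataFrame({"time": bundle.depth.t, "depth": bundle.depth.depth}),
        "gps": pd.DataFrame({"time": bundle.fixes.t, "lat": bundle.fixes.lat,
                             "lon": bundle.fixes.lon, "nsat": bundle.fixes.nsat}),
    }
    for name, df in frames.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6f")
        paths[name] = p
    return paths


def write_truth(truth: TripTruth, out_dir: str | Path) -> None:
    """Truth as CSV (path) + CSV (dives) + JSON (scalars)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "t": truth.t, "lat": truth.lat, "lon": truth.lon, "depth": truth.depth,
        "heading": truth.heading, "pitch": truth.pitch, "speed": truth.speed,
    }).to_csv(out / "truth_path.csv", index=False, float_format="%.6f")
    truth.dives.to_csv(out / "truth_dives.csv", index=False, float_format="%.4f")
    (out / "truth_meta.json").write_text(json.dumps(
        {"n_dives": int(len(truth.dives)),
         "n_seconds": int(truth.t.size)}, indent=2))
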
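"""Run configuration: every tunable processing parameter in one place.

The defaults are the values used for the Australian sea lion deployments this
package was built around: GPS speed threshold 6 m/s, satellite minimum 5,
3-s static/dynamic split, 20-s depth smoothing, bottom defined at >80 % of
maximum dive depth, Pearson |r| > 0.750 collinearity cutoff, stepwise alpha
0.05, and the local geomagnetic model (declination 7.698 deg, inclination
-68.012 deg for the study area).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class MagneticModel:
    """Local geomagnetic field direction.

    declination_deg: angle of magnetic north east of true north.
    inclination_deg: dip below horizontal (negative = field points upward,
    as in the southern hemisphere).
    """

    declination_deg: float = 7.698
    inclination_deg: float = -68.012

    def __post_init__(self):
        if not (-180.0 < self.declination_deg <= 180.0):
            raise ValueError("declination must be in (-180, 180]")
        if not (-90.0 <= self.inclination_deg <= 90.0):
            raise ValueError("inclination must be in [-90, 90]")


@dataclass
class RunConfig:
    """Parameters for the full ingest -> cluster pipeline."""

    # colony (central place) position, WGS84 degrees
    colony_lat: float = -35.994
    colony_lon: float = 137.317

    # sensor_io
    min_satellites: int = 5
    vmax_ms: float = 6.0
    zoc_window_s: float = 7200.0
    zoc_quantile: float = 0.10
    zoc_surface_max_m: float = 3.0
    clip_negative_depth: bool = True
    accel_range_g: float = 4.0

    # dead_reckoning
    highpass_window_s: float = 3.0
    magnetic: MagneticModel = field(default_factory=MagneticModel)
    speed_fallback_ms: float = 1.0
    speed_pitch_min_deg: float = 5.0
    speed_clip_ms: float = 12.0  # 2x the GPS speed threshold
    speed_strategy: str = "depth_rate"  # or "vedba"
    vedba_speed_coeff: float = 1.0

    # dive_segmentation
    smooth_window_s: float = 20.0
    dive_threshold_m: float = 5.0
    bottom_fraction: float = 0.8

    # bottom_metrics
    r_max: float = 0.750
    sinuosity_cap: float = 50.0

    # cluster_model
    k_min: int = 2
    k_max: int = 8
    n_restarts: int = 25
    alpha: float = 0.05
    stepwise_family: str = "ols"  # or "logistic"
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.vmax_ms <= 0:
            raise ValueError("vmax_ms must be positive")
        if not (0.0 < self.bottom_fraction < 1.0):
            raise ValueError("bottom_fraction must be in (0, 1)")
        if self.min_satellites < 0:
            raise ValueError("min_satellites must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.speed_strategy not in ("depth_rate", "vedba"):
            raise ValueError("speed_strategy must be 'depth_rate' or 'vedba'")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        mag = d.pop("magnetic", None)
        cfg = cls(**{k: v for k, v in d.items() if k in _FIELD_NAMES})
        if mag is not None:
            cfg.magnetic = MagneticModel(**mag)
        return cfg.validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a plain ``key = value`` text config (or JSON if it starts with '{')."""
        text = Path(path).read_text()
        if text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        flat: dict = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            flat[key] = val
        d: dict = {}
        mag: dict = {}
        for key, val in flat.items():
            if key in ("declination", "declination_deg"):
                mag["declination_deg"] = float(val)
            elif key in ("inclination", "inclination_deg"):
                mag["inclination_deg"] = float(val)
            elif key in _FIELD_NAMES:
                d[key] = _coerce(key, val)
            else:
                raise ValueError(f"unknown config key {key!r}")
        if mag:
            d["magnetic"] = mag
        return cls.from_dict(d)


_FIELD_NAMES = {f.name for f in dataclasses.fields(RunConfig)}
_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(RunConfig)}


def _coerce(key: str, val: str):
    t = _FIELD_TYPES[key]
    if t == "bool":
        return val.lower() in ("1", "true", "yes", "on")
    if t == "int":
        return int(val)
    if t == "float":
        return float(val)
    return val
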
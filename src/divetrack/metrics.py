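"""Per-dive bottom-use / foraging-effort metrics and the collinearity screen.

Seven predictors characterise each bottom phase of a benthic forager:

========================  =====================================================
bottom_time (s)           first-to-last-sample span of the bottom phase
tad_index (s/m)           time-at-depth index: bottom_time / max dive depth
bottom_distance (m)       horizontal distance travelled during the bottom phase
depth_var_index (-)       sd of bottom depths / mean bottom depth (rugosity proxy)
bottom_speed (m/s)        mean horizontal speed: bottom_distance / bottom_time
sinuosity (-)             bottom_distance / straight-line start-to-end distance
colony_distance (km)      mean great-circle distance of bottom samples to colony
========================  =====================================================

Pairs of predictors with Pearson |r| strictly above 0.750 are collinear and
one member is dropped before clustering.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .deadreckon import GeoTrack
from .dives import BottomPhase, Dive
from .geo import haversine_m

log = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "bottom_time", "tad_index", "bottom_distance", "depth_var_index",
    "bottom_speed", "sinuosity", "colony_distance",
]


def compute_dive_metrics(
    bottom: BottomPhase,
    track: GeoTrack,
    max_depth: float,
    colony: tuple[float, float],
    sinuosity_cap: float = 50.0,
) -> dict:
    """The seven bottom-use predictors for one dive's bottom phase.

    ``bottom.idx`` must index into ``track`` (the 1 Hz georeferenced record).
    When the bottom path starts and ends at the same position the sinuosity
    is undefined and set to ``sinuosity_cap``.
    """
    if bottom.idx.size < 2:
        raise ValueError("bottom phase needs >= 2 positioned samples")
    i = bottom.idx
    bottom_time = float(bottom.t[-1] - bottom.t[0])
    tad = bottom_time / max_depth
    dist = float(np.sum(track.step_dist[i[1:]]))
    depths = bottom.depths
    mean_depth = float(np.mean(depths))
    dvi = float(np.std(depths, ddof=1) / mean_depth) if mean_depth > 0 else 0.0
    speed = dist / bottom_time if bottom_time > 0 else 0.0
    chord = float(haversine_m(track.lat[i[0]], track.lon[i[0]], track.lat[i[-1]], track.lon[i[-1]]))
    if chord < 1e-9:
        sinuosity = sinuosity_cap
        log.warning("dive %d: degenerate bottom chord; sinuosity capped at %.1f",
                    bottom.dive_id, sinuosity_cap)
    else:
        sinuosity = min(max(dist / chord, 1.0), sinuosity_cap)
    colony_d = float(np.mean(haversine_m(track.lat[i], track.lon[i], colony[0], colony[1]))) / 1e3
    return {
        "dive_id": bottom.dive_id,
        "bottom_time": bottom_time,
        "tad_index": tad,
        "bottom_distance": dist,
        "depth_var_index": dvi,
        "bottom_speed": speed,
        "sinuosity": sinuosity,
        "colony_distance": colony_d,
    }


def compute_metrics_table(
    dives: list[Dive],
    bottoms: list[BottomPhase],
    track: GeoTrack,
    colony: tuple[float, float],
    sinuosity_cap: float = 50.0,
) -> pd.DataFrame:
    """One row of metrics per dive with a valid bottom phase."""
    rows = []
    for dv, bp in zip(dives, bottoms):
        if bp.idx.size < 2:
            log.warning("dive %d: bottom phase too short for metrics; skipped", dv.dive_id)
            continue
        rows.append(compute_dive_metrics(bp, track, dv.max_depth, colony, sinuosity_cap))
    df = pd.DataFrame(rows, columns=["dive_id"] + METRIC_COLUMNS)
    return df.set_index("dive_id")


def collinearity_screen(
    table: pd.DataFrame, r_max: float = 0.750
) -> tuple[list[str], pd.DataFrame, list[str]]:
    """Drop predictors until no pair has Pearson |r| strictly above ``r_max``.

    While a violating pair exists, the member of the *worst* pair with the
    larger mean |r| against all other retained columns is dropped (ties break
    toward the later column — deterministic).  Constant columns have no
    defined correlation and are dropped up front with a warning.

    Returns (retained column names, full correlation matrix of the input,
    dropped column names).
    """
    if table.shape[0] < 3:
        raise ValueError("need at least 3 rows to screen collinearity")
    if table.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    cols = list(table.columns)
    dropped: list[str] = []
    for c in cols[:]:
        if np.isclose(table[c].std(ddof=1), 0.0):
            log.warning("collinearity_screen: constant column %r dropped", c)
            cols.remove(c)
            dropped.append(c)
    corr_full = table[cols].corr(method="pearson")
    work = corr_full.abs()
    while len(cols) >= 2:
        sub = work.loc[cols, cols].copy()
        np.fill_diagonal(sub.values, 0.0)
        worst = float(sub.values.max())
        if worst <= r_max + 1e-12:  # the cutoff is strictly greater-than
            break
        i, j = np.unravel_index(np.argmax(sub.values), sub.shape)
        a, b = sub.columns[i], sub.columns[j]
        others_a = [c for c in cols if c not in (a, b)]
        mean_a = sub.loc[a, others_a].mean() if others_a else 0.0
        mean_b = sub.loc[b, others_a].mean() if others_a else 0.0
        victim = b if mean_b >= mean_a else a
        log.info("collinearity_screen: |r|=%.3f between %s and %s; dropping %s",
                 worst, a, b, victim)
        cols.remove(victim)
        dropped.append(victim)
    return cols, corr_full, dropped
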
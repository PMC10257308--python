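"""Dive detection and descent/bottom/ascent phase labelling from 1 Hz depth.

A dive is a maximal run of (20-s smoothed) depth at or above the dive
threshold (default 5 m).  Within a dive the *bottom phase* is the contiguous
span from the first to the last sample deeper than 80 % of the dive's
maximum depth — the operative definition for a benthic forager, which keeps
brief excursions above the 80 % line (e.g. over rugose substrate) inside the
bottom.  Descent and ascent are the samples before and after that span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sensor_io import DepthSeries

PHASE_DESCENT = "descent"
PHASE_BOTTOM = "bottom"
PHASE_ASCENT = "ascent"
PHASE_SURFACE = "surface"


@dataclass
class Dive:
    dive_id: int
    t_start: float
    t_end: float
    max_depth: float
    # sample indices into the depth series and per-sample phase labels
    idx: np.ndarray
    phases: np.ndarray


@dataclass
class BottomPhase:
    dive_id: int
    idx: np.ndarray       # indices into the depth series (contiguous)
    t: np.ndarray
    depths: np.ndarray

    @property
    def duration_s(self) -> float:
        """First-to-last-sample span of the bottom phase, seconds."""
        return float(self.t[-1] - self.t[0])


def smooth_depth(depth: DepthSeries, window_s: float = 20.0) -> DepthSeries:
    """Centred running mean over ``window_s`` (shrunken windows at the edges)."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    dt = np.median(np.diff(depth.t)) if len(depth) > 1 else 1.0
    win = max(int(round(window_s / dt)), 1)
    sm = pd.Series(depth.depth).rolling(win, center=True, min_periods=1).mean()
    return DepthSeries(depth.t, sm.to_numpy())


def detect_dives(depth: DepthSeries, threshold_m: float = 5.0,
                 smooth_window_s: float = 20.0) -> list[Dive]:
    """Detect dives as maximal runs of smoothed depth >= ``threshold_m``.

    Phase labels are attached later by :func:`label_phases`; max_depth is
    taken from the *raw* (unsmoothed) record within the run.
    """
    if threshold_m <= 0:
        raise ValueError("threshold_m must be positive")
    sm = smooth_depth(depth, smooth_window_s) if smooth_window_s else depth
    submerged = sm.depth >= threshold_m
    dives: list[Dive] = []
    if not submerged.any():
        return dives
    edges = np.diff(submerged.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)  # exclusive
    if submerged[0]:
        starts.insert(0, 0)
    if submerged[-1]:
        ends.append(len(submerged))
    for k, (s, e) in enumerate(zip(starts, ends)):
        idx = np.arange(s, e)
        dives.append(Dive(
            dive_id=k,
            t_start=float(depth.t[s]),
            t_end=float(depth.t[e - 1]),
            max_depth=float(depth.depth[s:e].max()),
            idx=idx,
            phases=np.full(idx.size, "", dtype=object),
        ))
    return dives


def label_phases(dive: Dive, depth: DepthSeries,
                 bottom_fraction: float = 0.8) -> tuple[Dive, BottomPhase]:
    """Label descent/bottom/ascent; bottom = first-to-last sample > 80 % of max depth."""
    if dive.idx.size < 3:
        raise ValueError("dive needs at least 3 samples to label phases")
    if not (0.0 < bottom_fraction < 1.0):
        raise ValueError("bottom_fraction must be in (0, 1)")
    d = depth.depth[dive.idx]
    line = bottom_fraction * dive.max_depth
    deep = np.nonzero(d > line)[0]
    if deep.size == 0:
        # max_depth sample itself sits exactly on the line only if fraction==1;
        # guard numerically by taking the argmax sample
        deep = np.array([int(np.argmax(d))])
    b0, b1 = int(deep[0]), int(deep[-1])
    phases = np.empty(dive.idx.size, dtype=object)
    phases[:b0] = PHASE_DESCENT
    phases[b0:b1 + 1] = PHASE_BOTTOM
    phases[b1 + 1:] = PHASE_ASCENT
    dive.phases = phases
    bottom_idx = dive.idx[b0:b1 + 1]
    bottom = BottomPhase(
        dive_id=dive.dive_id,
        idx=bottom_idx,
        t=depth.t[bottom_idx],
        depths=depth.depth[bottom_idx],
    )
    return dive, bottom


def segment_dives(depth: DepthSeries, threshold_m: float = 5.0,
                  smooth_window_s: float = 20.0, bottom_fraction: float = 0.8):
    """Detect dives and label phases in one pass; returns (dives, bottoms)."""
    dives = detect_dives(depth, threshold_m, smooth_window_s)
    out_d, out_b = [], []
    for dv in dives:
        if dv.idx.size < 3:
            continue
        dv, bp = label_phases(dv, depth, bottom_fraction)
        out_d.append(dv)
        out_b.append(bp)
    return out_d, out_b


def dive_table(dives: list[Dive], bottoms: list[BottomPhase]) -> pd.DataFrame:
    """Per-dive summary table (one row per dive with a labelled bottom phase)."""
    rows = []
    for dv, bp in zip(dives, bottoms):
        rows.append({
            "dive_id": dv.dive_id,
            "t_start": dv.t_start,
            "t_end": dv.t_end,
            "max_depth": dv.max_depth,
            "bottom_start": bp.t[0],
            "bottom_end": bp.t[-1],
            "bottom_n": bp.idx.size,
        })
    return pd.DataFrame(rows, columns=[
        "dive_id", "t_start", "t_end", "max_depth",
        "bottom_start", "bottom_end", "bottom_n",
    ])
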
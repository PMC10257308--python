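"""End-to-end orchestration: sensors in, clustered bottom-use out.

``process_bundle`` runs the stages in order — GPS filtering, zero-offset
correction, stream alignment, dead-reckoning, dive segmentation, bottom
metrics, collinearity screen, clustering with stepwise confirmation — and
``write_artifacts`` serialises every product (CSV/JSON/GeoJSON) with the full
parameter set echoed for provenance.  A MANIFEST records which stages
completed, so a failed run leaves inspectable partial artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import exports
from .cluster import BottomUseClusterer, summarize
from .config import RunConfig
from .deadreckon import GeoTrack, dead_reckon
from .dives import BottomPhase, Dive, dive_table, segment_dives
from .metrics import collinearity_screen, compute_metrics_table
from .sensor_io import (
    DepthSeries,
    FixSeries,
    SensorBundle,
    align_streams,
    filter_satellites,
    speed_filter,
    zero_offset_correct,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: RunConfig
    fixes: FixSeries                 # after satellite + speed filtering
    track: GeoTrack
    dives: list[Dive]
    bottoms: list[BottomPhase]
    dive_df: pd.DataFrame
    metrics: pd.DataFrame            # all seven predictors, one row per bottom phase
    retained_columns: list[str]      # after the collinearity screen
    correlation: pd.DataFrame
    clusterer: BottomUseClusterer | None
    summary: dict

    @property
    def assignments(self) -> pd.Series | None:
        if self.clusterer is None:
            return None
        return pd.Series(self.clusterer.labels_, index=self.metrics.index, name="cluster")


def process_bundle(bundle: SensorBundle, config: RunConfig | None = None) -> PipelineResult:
    """Run the full analysis on one trip's sensor bundle."""
    config = (config or RunConfig()).validate()

    fixes = filter_satellites(bundle.fixes, config.min_satellites)
    fixes = speed_filter(fixes, config.vmax_ms)
    log.info("fixes: %d retained of %d", len(fixes), len(bundle.fixes))

    depth_c = zero_offset_correct(
        bundle.depth, config.zoc_window_s, config.zoc_quantile,
        config.zoc_surface_max_m, config.clip_negative_depth,
    )
    corrected = SensorBundle(bundle.accel, bundle.mag, depth_c, fixes, bundle.trip_window)
    merged = align_streams(corrected)
    track = dead_reckon(merged, fixes, config, accel_25hz=bundle.accel)

    # segment on the corrected depth restricted to the aligned grid so bottom
    # sample indices address GeoTrack rows directly
    grid_depth = DepthSeries(track.t, merged["depth"].to_numpy())
    dives, bottoms = segment_dives(
        grid_depth, config.dive_threshold_m, config.smooth_window_s, config.bottom_fraction
    )
    dive_df = dive_table(dives, bottoms)
    log.info("detected %d dives", len(dives))

    metrics = compute_metrics_table(
        dives, bottoms, track, (config.colony_lat, config.colony_lon), config.sinuosity_cap
    )

    clusterer = None
    retained = list(metrics.columns)
    corr = pd.DataFrame()
    if len(metrics) >= max(8, config.k_max + 2):
        retained, corr, dropped = collinearity_screen(metrics, config.r_max)
        clusterer = BottomUseClusterer(
            k_min=config.k_min, k_max=config.k_max, n_restarts=config.n_restarts,
            alpha=config.alpha, family=config.stepwise_family, seed=config.seed,
        ).fit(metrics[retained])
    else:
        log.warning("only %d bottom phases; skipping clustering", len(metrics))

    duration_h = (bundle.trip_window[1] - bundle.trip_window[0]) / 3600.0
    if clusterer is not None:
        summary = summarize(clusterer, metrics, dive_df,
                            n_locations=len(fixes), trip_duration_h=duration_h)
    else:
        summary = {"n_locations": len(fixes),
                   "trip_duration_h": round(duration_h, 2),
                   "n_bottom_phases": int(len(metrics))}

    return PipelineResult(config, fixes, track, dives, bottoms, dive_df, metrics,
                          retained, corr, clusterer, summary)


def bottom_centroids(result: PipelineResult) -> pd.DataFrame:
    """Mean bottom-phase position per dive (for mapping / GeoJSON export)."""
    rows = []
    for bp in result.bottoms:
        rows.append({
            "dive_id": bp.dive_id,
            "lat": float(np.mean(result.track.lat[bp.idx])),
            "lon": float(np.mean(result.track.lon[bp.idx])),
            "bottom_time": float(bp.t[-1] - bp.t[0]),
        })
    df = pd.DataFrame(rows, columns=["dive_id", "lat", "lon", "bottom_time"])
    df = df.set_index("dive_id")
    a = result.assignments
    df["cluster"] = a.reindex(df.index) if a is not None else 0
    return df.reset_index()


FLOAT_FMT = "%.8g"


def write_artifacts(result: PipelineResult, out_dir: str | Path) -> list[str]:
    """Serialise all pipeline products; returns the artifact names written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _note(name: str):
        written.append(name)

    (out / "config.json").write_text(result.config.to_json() + "\n")
    _note("config.json")

    result.track.to_frame().to_csv(out / "geotrack.csv", index=False, float_format=FLOAT_FMT)
    _note("geotrack.csv")
    (out / "track.geojson").write_text(
        json.dumps(exports.track_to_geojson(result.track, result.config), indent=None))
    _note("track.geojson")

    result.dive_df.to_csv(out / "dives.csv", index=False, float_format=FLOAT_FMT)
    _note("dives.csv")
    result.metrics.to_csv(out / "metrics.csv", float_format=FLOAT_FMT)
    _note("metrics.csv")
    if len(result.correlation):
        result.correlation.to_csv(out / "correlation.csv", float_format=FLOAT_FMT)
        _note("correlation.csv")

    if result.clusterer is not None:
        est = result.clusterer
        assign = pd.DataFrame({
            "dive_id": result.metrics.index,
            "cluster": est.labels_,
            "silhouette": est.solution_.silhouette_samples,
        })
        assign.to_csv(out / "assignments.csv", index=False, float_format=FLOAT_FMT)
        _note("assignments.csv")
        solution = {
            "k": est.k_,
            "retained_predictors": est.columns_,
            "sizes": [int(v) for v in est.solution_.sizes],
            "wcss": est.solution_.wcss,
            "bcss": est.solution_.bcss,
            "total_ss": est.solution_.total_ss,
            "avg_silhouette": est.solution_.avg_silhouette,
            "silhouette_curve": {str(k): v for k, v in est.silhouette_curve_.items()},
            "centroids": {str(c): {k: float(v) for k, v in row.items()}
                          for c, row in est.solution_.centroids.iterrows()},
            "stepwise": None if est.stepwise_ is None else {
                "retained": est.stepwise_.retained,
                "pvalues": est.stepwise_.pvalues,
                "adjusted_r2": est.stepwise_.adj_r2,
                "removal_history": est.stepwise_.history,
            },
            "config": result.config.to_dict(),
        }
        (out / "solution.json").write_text(json.dumps(solution, indent=2, sort_keys=True))
        _note("solution.json")
        cents = bottom_centroids(result)
        (out / "clusters.geojson").write_text(
            json.dumps(exports.clusters_to_geojson(cents, result.config), indent=None))
        _note("clusters.geojson")

    (out / "summary.json").write_text(
        json.dumps({"summary": result.summary, "config": result.config.to_dict()},
                   indent=2, sort_keys=True))
    _note("summary.json")
    return written


def run_pipeline(bundle: SensorBundle, config: RunConfig, out_dir: str | Path) -> PipelineResult:
    """Process a bundle and write all artifacts plus a MANIFEST.

    On a stage failure the MANIFEST names the failed stage and the exception
    is re-raised (a CLI caller converts it to a nonzero exit status).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "process"
    try:
        result = process_bundle(bundle, config)
        stage = "write"
        written = write_artifacts(result, out)
        (out / "MANIFEST").write_text(
            "status: ok\n" + "".join(f"artifact: {w}\n" for w in written))
        return result
    except Exception as exc:
        (out / "MANIFEST").write_text(f"status: failed\nstage: {stage}\nerror: {exc}\n")
        raise
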
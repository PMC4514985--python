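"""Readers, writers, configuration and pipeline orchestration.

GPS tracks arrive as CSV (animal_id, timestamp, lon, lat — or x, y with
a CRS declaration); ping logs as CSV (receiver_id, timestamp, optional
code).  Isopleths are exported as GeoJSON FeatureCollections in WGS84
longitude/latitude; all areas are computed in the projected plane before
reprojection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import mapping
from shapely.ops import transform as shp_transform

from . import acoustics, coverage, simulate
from .locoh import (
    DEFAULT_QUANTILES,
    Hull,
    Isopleth,
    LocohParams,
    Track,
    utilization_distribution,
)
from .projection import UTM20N, TransverseMercator, utm_zone

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "read_gps_csv",
    "write_gps_csv",
    "read_ping_csv",
    "write_isopleths_geojson",
    "read_isopleths_geojson",
    "write_hull_table_csv",
    "run_pipeline",
]

log = logging.getLogger("bioprobe")


class SchemaError(ValueError):
    """An input file is missing a required column or has a bad row."""


@dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end pipeline.

    Defaults match the study settings: individual mode k=10, s=0.03;
    collective mode k=5, s=0; quantiles 25/50/75/95 %.
    """

    crs_zone: int = 20
    individual: LocohParams = field(
        default_factory=lambda: LocohParams(k=10, s=0.03))
    collective_k: int = 5
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES
    match_max_gap_min: float = 30.0
    interp_grid_min: float = 15.0
    use_interpolated_matching: bool = False
    gps_csv: str | None = None
    ping_csv: str | None = None
    drift_t0: str | None = None
    drift_t_retrieval: str | None = None
    drift_total_s: float = 0.0
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)

    @property
    def projection(self) -> TransverseMercator:
        return utm_zone(self.crs_zone)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "individual" in kwargs:
            kwargs["individual"] = LocohParams(**kwargs["individual"])
        if "quantiles" in kwargs:
            kwargs["quantiles"] = tuple(kwargs["quantiles"])
        if "sim" in kwargs:
            sim_raw = dict(kwargs["sim"])
            if "hotspots" in sim_raw:
                sim_raw["hotspots"] = tuple(
                    simulate.Hotspot(**h) for h in sim_raw["hotspots"])
            if "transmitters" in sim_raw:
                sim_raw["transmitters"] = tuple(
                    simulate.Transmitter(**t)
                    for t in sim_raw["transmitters"])
            for key in ("transmission_period_s", "inter_ping_interval_s",
                        "detection_range_m", "colony_xy",
                        "haulout_duration_range_h"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            kwargs["sim"] = simulate.SimConfig(**sim_raw)
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# readers / writers


def read_gps_csv(path, projection: TransverseMercator = UTM20N,
                 ) -> list[Track]:
    """Read a GPS CSV into per-animal, time-sorted tracks.

    Requires columns ``animal_id`` and ``timestamp`` plus either
    ``lon``/``lat`` (projected via ``projection``) or ``x``/``y``
    (already metres).  Duplicate (animal, timestamp) rows are collapsed
    with a warning.
    """
    df = pd.read_csv(path)
    for col in ("animal_id", "timestamp"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if {"lon", "lat"} <= set(df.columns):
        geographic = True
    elif {"x", "y"} <= set(df.columns):
        geographic = False
    else:
        raise SchemaError("need either lon/lat or x/y columns")
    try:
        ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError):
        bad = None
        for i, v in enumerate(df["timestamp"]):
            try:
                pd.to_datetime(v, utc=True)
            except (ValueError, TypeError):
                bad = i
                break
        raise SchemaError(
            f"unparseable timestamp at data row {bad}: "
            f"{df['timestamp'].iloc[bad]!r}") from None
    df = df.assign(timestamp=ts)
    n0 = len(df)
    df = df.drop_duplicates(subset=["animal_id", "timestamp"])
    if len(df) < n0:
        log.warning("collapsed %d duplicate (animal, timestamp) rows",
                    n0 - len(df))
    if geographic:
        x, y = projection.forward(df["lon"].to_numpy(),
                                  df["lat"].to_numpy())
    else:
        x, y = df["x"].to_numpy(float), df["y"].to_numpy(float)
    df = df.assign(x=x, y=y)
    if "at_sea" not in df.columns:
        df["at_sea"] = True
    tracks = []
    for aid, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        tracks.append(Track(str(aid), grp["timestamp"],
                            grp["x"].to_numpy(), grp["y"].to_numpy(),
                            grp["at_sea"].to_numpy(bool)))
    return tracks


def write_gps_csv(tracks: list[Track], path,
                  projection: TransverseMercator = UTM20N) -> None:
    """Write tracks as a GPS CSV (lon/lat plus projected x/y)."""
    frames = []
    for tr in tracks:
        lon, lat = projection.inverse(tr.x, tr.y)
        frames.append(pd.DataFrame({
            "animal_id": tr.animal_ids,
            "timestamp": tr.t.strftime("%Y-%m-%dT%H:%M:%S.%f%z"),
            "lon": lon, "lat": lat, "x": tr.x, "y": tr.y,
            "at_sea": tr.at_sea,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_ping_csv(path) -> pd.DataFrame:
    """Read a ping-log CSV (receiver_id, timestamp, optional code)."""
    df = pd.read_csv(path)
    for col in ("receiver_id", "timestamp"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True,
                                     format="ISO8601")
    return df.sort_values(["receiver_id", "timestamp"],
                          kind="stable").reset_index(drop=True)


def _reproject_geom(geom, projection: TransverseMercator):
    return shp_transform(
        lambda x, y, z=None: projection.inverse(np.asarray(x),
                                                np.asarray(y)),
        geom)


def write_isopleths_geojson(isopleths: list[Isopleth], path,
                            projection: TransverseMercator = UTM20N,
                            ) -> None:
    """Write isopleths as a WGS84 GeoJSON FeatureCollection.

    One feature per quantile level (ascending), with properties level,
    area_km2 (computed in the projected plane) and n_fixes.
    """
    features = []
    for iso in sorted(isopleths, key=lambda i: i.level):
        geom = _reproject_geom(iso.geom, projection)
        features.append({
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {
                "level": iso.level,
                "area_km2": iso.area_km2,
                "n_fixes": iso.n_fixes,
            },
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))


def read_isopleths_geojson(path, projection: TransverseMercator = UTM20N,
                           ) -> list[Isopleth]:
    """Round-trip reader for the package's own GeoJSON output."""
    fc = json.loads(Path(path).read_text())
    out = []
    for feat in fc["features"]:
        geom_ll = shapely.geometry.shape(feat["geometry"])
        geom = shp_transform(
            lambda lon, lat, z=None: projection.forward(
                np.asarray(lon), np.asarray(lat)),
            geom_ll)
        props = feat["properties"]
        out.append(Isopleth(level=props["level"], geom=geom,
                            area_km2=props["area_km2"],
                            n_fixes=props["n_fixes"]))
    return out


def write_hull_table_csv(hulls: list[Hull], path) -> None:
    """Per-hull attribute table (one row per parent fix)."""
    pd.DataFrame([{
        "parent_idx": h.parent_idx,
        "parent_t": h.parent.t.isoformat(),
        "area_km2": h.area_km2,
        "perimeter_km": h.perimeter_km,
        "n_enclosed": h.n_enclosed,
        "occupancy_h": h.occupancy_h,
        "time_selected": h.time_selected,
    } for h in hulls]).to_csv(path, index=False)


def write_transmissions_csv(transmissions, path) -> None:
    pd.DataFrame([{
        "t_mid": tx.t_mid.isoformat(),
        "n_pings": tx.n_pings,
        "complete": tx.complete,
        "matched_animal": tx.matched_fix.animal_id if tx.matched_fix
        else "",
        "matched_t": tx.matched_fix.t.isoformat() if tx.matched_fix else "",
        "quantile_level": tx.quantile_level
        if tx.quantile_level is not None else "",
    } for tx in transmissions]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}"
                                   ) from exc
        return wrapper
    return deco


def run_pipeline(cfg: PipelineConfig, mode: str, out_dir,
                 tracks: list[Track] | None = None,
                 pings: pd.DataFrame | None = None) -> dict:
    """Run one pipeline mode end to end and write its outputs.

    Modes: ``individual`` (per-animal isopleths + hull diagnostics),
    ``collective`` (monthly isopleths + summary CSV), ``tpue``
    (transmission assembly, matching and TPUE summaries).  Returns a
    manifest dict of the files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proj = cfg.projection
    if tracks is None:
        if not cfg.gps_csv:
            raise ValueError("no tracks given and no gps_csv configured")
        tracks = _stage("read_gps")(read_gps_csv)(cfg.gps_csv, proj)
    manifest: dict = {"mode": mode, "outputs": [], "parameters": {
        "crs_zone": cfg.crs_zone,
        "individual_k": cfg.individual.k, "individual_s": cfg.individual.s,
        "collective_k": cfg.collective_k,
        "quantiles": list(cfg.quantiles),
    }}
    log.info("pipeline mode=%s (%d tracks)", mode, len(tracks))

    if mode == "individual":
        for tr in tracks:
            hulls, isos = _stage("utilization_distribution")(
                utilization_distribution)(tr, cfg.individual)
            gj = out / f"isopleths_{tr.animal_id}.geojson"
            hc = out / f"hulls_{tr.animal_id}.csv"
            write_isopleths_geojson(isos, gj, proj)
            write_hull_table_csv(hulls, hc)
            manifest["outputs"] += [str(gj), str(hc)]
    elif mode == "collective":
        summaries, detail = _stage("monthly_summaries")(
            coverage.monthly_summaries)(tracks, k=cfg.collective_k,
                                        quantiles=cfg.quantiles)
        rows = pd.concat([s.to_frame() for s in summaries],
                         ignore_index=True)
        csv_path = out / "monthly_summary.csv"
        rows.to_csv(csv_path, index=False)
        manifest["outputs"].append(str(csv_path))
        for month, (_, isos) in detail.items():
            gj = out / f"isopleths_{month}.geojson"
            write_isopleths_geojson(isos, gj, proj)
            manifest["outputs"].append(str(gj))
    elif mode == "tpue":
        if len(tracks) != 1:
            raise ValueError("tpue mode expects exactly one track")
        tr = tracks[0]
        if pings is None:
            if not cfg.ping_csv:
                raise ValueError("no pings given and no ping_csv configured")
            pings = _stage("read_pings")(read_ping_csv)(cfg.ping_csv)
        times = pd.DatetimeIndex(pings["timestamp"]
                                 if "timestamp" in pings else pings["t"])
        if cfg.drift_t0 and cfg.drift_t_retrieval:
            model = acoustics.ClockDriftModel(
                t0=pd.Timestamp(cfg.drift_t0),
                t_retrieval_raw=pd.Timestamp(cfg.drift_t_retrieval),
                total_drift_s=cfg.drift_total_s)
            times = acoustics.correct_clock_drift(times, model)
        records = _stage("classify")(acoustics.classify_ping_intervals)(
            times, receiver_id=tr.animal_id)
        txs = _stage("assemble")(acoustics.assemble_transmissions)(records)
        hulls, isos = _stage("utilization_distribution")(
            utilization_distribution)(tr, cfg.individual)
        locations = acoustics.interpolate_track(
            tr, cfg.interp_grid_min) if cfg.use_interpolated_matching else tr
        recs = _stage("effort")(acoustics.effort_records)(
            txs, hulls, isos, locations, cfg.match_max_gap_min)
        summary = acoustics.summarize_by_quantile(recs)
        tx_path = out / "transmissions.csv"
        sm_path = out / "tpue_summary.csv"
        gj = out / f"isopleths_{tr.animal_id}.geojson"
        write_transmissions_csv(txs, tx_path)
        summary.to_csv(sm_path, index=False)
        write_isopleths_geojson(isos, gj, proj)
        manifest["outputs"] += [str(tx_path), str(sm_path), str(gj)]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2))
    manifest["manifest"] = str(man_path)
    return manifest
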
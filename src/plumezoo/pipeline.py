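"""End-to-end orchestration: ingest -> hydrography -> regimes -> optics
-> plankton -> stats, with a reproducible run manifest.

A run consumes either a CSV store directory (stations.csv,
profiles.csv, particles.csv, volumes.csv, nets.csv) or a ``simulate``
config block, and produces:

* ``stations_out.csv`` — metadata plus detected regime and turbidity
  summaries;
* ``metrics_out.csv``  — per-station derived metrics (euphotic depth,
  fluorescence maximum, stratification, Calanus WMD, layer means,
  surface ratio);
* ``stats_out.csv``    — regime contrasts (Kruskal-Wallis + Dunn on the
  scalar metrics; PERMANOVA on net stage composition when available);
* ``manifest.json``    — config snapshot, seeds, stage timings, outputs.

Identical config (seeds included) reproduces identical outputs.
"""

from __future__ import annotations

import json
import time as _clock
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .station_io import (DepthProfile, read_stations, read_profiles,
                         write_stations)
from .hydrography import sigma_t, brunt_vaisala_n2, stratification_class
from .turbidity_regimes import (assign_regime, turbidity_summary,
                                TURBIDITY_THRESHOLD_FTU)
from .bio_optics import euphotic_depth, fluorescence_summary
from .plankton_metrics import (ParticleRecord, LayerAbundance,
                               classify_calanus, bin_particles,
                               weighted_mean_depth, layer_means,
                               surface_ratio, ESD_RANGE_MM, AI_MIN)
from .stats_suite import kruskal_wallis, dunn_posthoc, distance_matrix, permanova

__all__ = ["RunManifest", "run_pipeline", "summarize_by_regime"]


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    version: str = __version__
    timings: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1,
                                         default=str))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, station: str | None, msg: str):
        self.stage, self.station = stage, station
        where = f" (station {station})" if station else ""
        super().__init__(f"stage {stage!r}{where}: {msg}")


def _load_store(store: str | Path) -> list:
    store = Path(store)
    if not (store / "stations.csv").exists():
        raise PipelineError("ingest", None, f"no stations.csv in {store}")
    records = read_stations(store / "stations.csv")
    profiles = read_profiles(store / "profiles.csv") \
        if (store / "profiles.csv").exists() else {}
    particles: dict[str, list[ParticleRecord]] = {}
    volumes: dict[str, pd.DataFrame] = {}
    nets: dict[str, list[LayerAbundance]] = {}
    if (store / "particles.csv").exists():
        df = pd.read_csv(store / "particles.csv", dtype={"station_id": str})
        for sid, g in df.groupby("station_id"):
            particles[sid] = [ParticleRecord(sid, r.depth_m, r.esd_mm,
                                             r.attenuance_index)
                              for r in g.itertuples(index=False)]
    if (store / "volumes.csv").exists():
        df = pd.read_csv(store / "volumes.csv", dtype={"station_id": str})
        for sid, g in df.groupby("station_id"):
            volumes[sid] = g.sort_values("depth_m")
    if (store / "nets.csv").exists():
        df = pd.read_csv(store / "nets.csv", dtype={"station_id": str})
        for sid, g in df.groupby("station_id"):
            nets[sid] = [LayerAbundance(r.layer, r.taxon_stage,
                                        r.abundance_ind_m3)
                         for r in g.itertuples(index=False)]
    stations = []
    for rec in records:
        sid = rec.station_id
        stations.append({
            "record": rec,
            "profiles": {var: prof for (s, var), prof in profiles.items()
                         if s == sid},
            "particles": particles.get(sid, []),
            "volumes": volumes.get(sid),
            "nets": nets.get(sid, []),
        })
    return stations


def _stations_from_bundles(bundles) -> list:
    out = []
    for b in bundles:
        vols = None
        if b.lopc_volumes is not None:
            vols = pd.DataFrame({"depth_m": b.depths,
                                 "volume_m3": b.lopc_volumes})
        out.append({"record": b.record, "profiles": b.profiles,
                    "particles": b.particles, "volumes": vols,
                    "nets": b.nets})
    return out


def run_pipeline(config: dict, out_dir: str | Path | None = None
                 ) -> tuple[RunManifest, dict]:
    """Run every stage the inputs support; see module docstring.

    Returns the manifest and a dict of output DataFrames
    ({'stations', 'metrics', 'stats'}); writes CSVs when ``out_dir``
    (or config['out']) is given.
    """
    cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    threshold = float(cfg.get("threshold", TURBIDITY_THRESHOLD_FTU))
    smooth = int(cfg.get("smooth_window", 5))
    esd_range = (float(cfg.get("esd_min", ESD_RANGE_MM[0])),
                 float(cfg.get("esd_max", ESD_RANGE_MM[1])))
    ai_min = float(cfg.get("ai_min", AI_MIN))
    n_perm = int(cfg.get("permutations", 999))
    manifest = RunManifest(config=cfg, seeds={"master": seed})
    timings: dict[str, float] = {}

    t0 = _clock.perf_counter()
    if "simulate" in cfg:
        from .synthetic_data import generate_survey
        sim = dict(cfg["simulate"])
        sim_seed = int(sim.get("seed", seed))
        manifest.seeds["simulate"] = sim_seed
        bundles = generate_survey(
            n_per_regime=tuple(sim.get("n_per_regime", (8, 8, 9))),
            seed=sim_seed,
            bottom_depth=sim.get("bottom_depth"))
        stations = _stations_from_bundles(bundles)
    elif "store" in cfg:
        stations = _load_store(cfg["store"])
    else:
        raise PipelineError("ingest", None,
                            "config needs a 'store' path or 'simulate' block")
    if not stations:
        raise PipelineError("ingest", None, "empty input store")
    timings["ingest"] = _clock.perf_counter() - t0

    station_rows, metric_rows = [], []
    t0 = _clock.perf_counter()
    for st in stations:
        rec = st["record"]
        sid = rec.station_id
        profs = st["profiles"]
        row = {"station_id": sid, "region": rec.region,
               "max_depth_m": rec.bottom_depth,
               "lat_dd": rec.latitude, "lon_dd": rec.longitude}
        met = {"station_id": sid}
        try:
            if "temperature" in profs and "salinity" in profs:
                st_prof = sigma_t(profs["temperature"], profs["salinity"])
                n2 = brunt_vaisala_n2(profs["temperature"], profs["salinity"])
                profs["sigma_t"], profs["n2"] = st_prof, n2
                n2max = float(np.nanmax(n2.values))
                met["n2_max"] = n2max
                met["stratification"] = stratification_class(n2max).label
            if "turbidity" in profs:
                asg = assign_regime(profs["turbidity"], threshold, smooth)
                summ = turbidity_summary(profs["turbidity"])
                row["regime"] = asg.regime
                row["turbidity_change_m"] = asg.turbidity_change_depth
                row["mean_turbidity_ftu"] = summ.mean_turbidity_50m
                row["max_turbidity_ftu"] = summ.max_turbidity
                row["depth_max_turbidity_m"] = summ.depth_of_max_turbidity
            elif rec.regime is not None:
                row["regime"] = rec.regime
                row["turbidity_change_m"] = rec.turbidity_change_depth
                row["mean_turbidity_ftu"] = rec.mean_turbidity_50m
            if "par" in profs:
                eu = euphotic_depth(profs["par"])
                met["euphotic_depth_m"] = eu.depth
                met["euphotic_truncated"] = eu.truncated
            if "fluorescence" in profs:
                fs = fluorescence_summary(profs["fluorescence"])
                met["max_fluorescence"] = fs.max_fluorescence
                met["depth_max_fluorescence_m"] = fs.depth_of_max
                met["fluor_surface_confined"] = fs.surface_confined
            if st["particles"] and st["volumes"] is not None:
                kept = classify_calanus(st["particles"], esd_range, ai_min)
                prof = bin_particles(kept,
                                     st["volumes"]["volume_m3"].to_numpy(),
                                     st["volumes"]["depth_m"].to_numpy(),
                                     sid)
                met["calanus_wmd_50m"] = weighted_mean_depth(prof)
                for la in layer_means(prof, bottom=rec.bottom_depth):
                    met[f"calanus_lopc_{la.layer}"] = la.abundance
            if st["nets"]:
                try:
                    met["calanus_net_ratio"] = surface_ratio(st["nets"],
                                                             "Calanus")
                except ValueError:
                    pass
        except Exception as exc:  # noqa: BLE001 - report stage + station
            raise PipelineError("metrics", sid, str(exc)) from exc
        met["regime"] = row.get("regime")
        station_rows.append(row)
        metric_rows.append(met)
    timings["metrics"] = _clock.perf_counter() - t0

    stations_df = pd.DataFrame(station_rows)
    metrics_df = pd.DataFrame(metric_rows)

    t0 = _clock.perf_counter()
    stats_rows = []
    if "regime" in metrics_df.columns and metrics_df["regime"].nunique() >= 2:
        for metric in ("euphotic_depth_m", "calanus_wmd_50m",
                       "calanus_net_ratio", "mean_turbidity_ftu"):
            src = metrics_df if metric in metrics_df.columns else stations_df
            if metric not in src.columns:
                continue
            sub = (src[["regime", metric]].dropna()
                   if metric in src.columns else None)
            if metric == "mean_turbidity_ftu":
                sub = stations_df[["regime", metric]].dropna()
            groups = [g[metric].to_numpy()
                      for _, g in sub.groupby("regime") if len(g) > 0]
            if len(groups) < 2 or sum(len(g) for g in groups) < 3:
                continue
            kw = kruskal_wallis(groups)
            stats_rows.append({"test": "kruskal-wallis", "metric": metric,
                               "statistic": kw.h_statistic,
                               "p_value": kw.p_value,
                               "n": int(sum(kw.group_sizes))})
            dunn = dunn_posthoc(groups)
            for (i, j), z, p in zip(dunn.pairs, dunn.z_statistics,
                                    dunn.p_values):
                stats_rows.append({"test": f"dunn[{i}-{j}]", "metric": metric,
                                   "statistic": z, "p_value": p,
                                   "n": int(sum(kw.group_sizes))})
    # PERMANOVA on net stage composition (log10 Bray-Curtis), per station
    net_rows = []
    for st in stations:
        stages = {la.taxon_or_stage: la.abundance for la in st["nets"]
                  if la.layer == "0-10"}
        reg = next((r["regime"] for r in station_rows
                    if r["station_id"] == st["record"].station_id
                    and "regime" in r), None)
        if stages and reg is not None:
            net_rows.append({"station_id": st["record"].station_id,
                             "regime": reg, **stages})
    if len(net_rows) >= 6:
        net_df = pd.DataFrame(net_rows).set_index("station_id")
        counts = net_df["regime"].value_counts()
        if (counts >= 2).sum() >= 2:
            keep = net_df["regime"].isin(counts[counts >= 2].index)
            net_df = net_df[keep]
            dm = distance_matrix(net_df.drop(columns="regime"),
                                 metric="bray-curtis", preprocess="log10")
            pr = permanova(dm, net_df["regime"].to_numpy(),
                           n_perm=n_perm, seed=seed)
            stats_rows.append({"test": "permanova", "metric":
                               "stage_composition_0-10",
                               "statistic": pr.pseudo_f,
                               "p_value": pr.p_value, "n": dm.n})
    stats_df = pd.DataFrame(stats_rows,
                            columns=["test", "metric", "statistic",
                                     "p_value", "n"])
    timings["stats"] = _clock.perf_counter() - t0
    manifest.timings = timings

    out = out_dir or cfg.get("out")
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        stations_df.to_csv(out / "stations_out.csv", index=False)
        metrics_df.to_csv(out / "metrics_out.csv", index=False)
        stats_df.to_csv(out / "stats_out.csv", index=False)
        manifest.outputs = ["stations_out.csv", "metrics_out.csv",
                            "stats_out.csv"]
        manifest.write(out / "manifest.json")
    return manifest, {"stations": stations_df, "metrics": metrics_df,
                      "stats": stats_df}


def summarize_by_regime(metrics: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of every numeric metric, per regime."""
    if metrics.empty or "regime" not in metrics.columns:
        raise ValueError("metrics table needs a regime column")
    num = metrics.select_dtypes("number")
    rows = []
    for regime, g in metrics.groupby("regime"):
        for col in num.columns:
            vals = g[col].dropna()
            if vals.empty:
                continue
            rows.append({"regime": regime, "metric": col,
                         "median": float(vals.median()),
                         "q1": float(vals.quantile(0.25)),
                         "q3": float(vals.quantile(0.75)),
                         "n": int(len(vals))})
    return pd.DataFrame(rows, columns=["regime", "metric", "median",
                                       "q1", "q3", "n"])
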
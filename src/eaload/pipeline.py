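"""End-to-end pipeline driver: simulate (or load) -> detect -> delimit ->
classify -> segment -> summarize, with every intermediate persisted.

The pipeline is idempotent given the seed, writes a resolved-config
snapshot next to its outputs, and logs every data-derived threshold it
applies.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bursts as bursts_mod
from . import io as io_mod
from . import phases as phases_mod
from . import sim as sim_mod
from .classify import (ClassifiedBurst, cluster_nodes, extract_features,
                       train_som, assign_bursts, MIN_SPIKES_FOR_SOM)

log = logging.getLogger("eaload.pipeline")

ARTIFACTS = ("spikes.csv", "events.csv", "classified.csv", "phases.tsv",
             "statistics.csv")


def _strict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    return cls(**d)


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    seed: int = 0
    n_sessions: int = 8
    session_duration: float = 9000.0
    group_threshold: float = bursts_mod.GROUP_THRESHOLD
    join_threshold: float = bursts_mod.JOIN_THRESHOLD
    som_rows: int = 6
    som_cols: int = 4
    som_epochs: int = 30
    n_categories: int | None = 3
    segmentation: phases_mod.SegmentationConfig = field(
        default_factory=phases_mod.SegmentationConfig
    )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = _strict(
                phases_mod.SegmentationConfig, d["segmentation"]
            )
        return _strict(cls, d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages on a simulated dataset and persist artifacts.

    Returns a summary dict with per-session background and high-load
    rates. Deterministic for a fixed config (byte-identical tables).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.json").write_text(json.dumps(config.to_dict(), indent=2))

    sim_cfg = sim_mod.SimulationConfig(
        n_sessions=config.n_sessions,
        session_duration=config.session_duration,
        rng_seed=config.seed,
    )

    # stage 1: spike series
    records = sim_mod.simulate_dataset(sim_cfg)
    spike_rows = []
    for i, r in enumerate(records):
        sid = f"s{i:03d}"
        r["session_id"] = sid
        for t, prov in zip(r["session"].spike_times, r["session"].provenance):
            spike_rows.append({"session_id": sid, "time_s": t,
                               "polarity": 1, "source": prov})
    pd.DataFrame(spike_rows).to_csv(out / "spikes.csv", index=False,
                                    float_format="%.17g")

    # stage 2: event series
    series = {}
    for r in records:
        ev = bursts_mod.delimit_bursts(
            r["session"].spike_times, config.group_threshold,
            config.join_threshold, session_id=r["session_id"],
        )
        series[r["session_id"]] = ev
    io_mod.write_events(out / "events.csv", list(series.values()))

    # stage 3: SOM classification on pooled bursts
    pool = [b for ev in series.values() for b in ev.bursts
            if b.n_spikes >= MIN_SPIKES_FOR_SOM]
    if len(pool) < config.som_rows * config.som_cols:
        raise RuntimeError(
            f"only {len(pool)} classifiable bursts; enlarge the dataset or "
            "shrink the map"
        )
    feats, params = extract_features(pool)
    model = train_som(feats, rows=config.som_rows, cols=config.som_cols,
                      epochs=config.som_epochs, seed=config.seed, params=params)
    cluster_nodes(model, k=config.n_categories)
    log.info("SOM trained: %d nodes, %d categories, H*=%d",
             model.n_nodes, model.n_categories, model.hstar_node)
    (out / "som_model.json").write_text(model.to_json())

    classified: dict[str, list[ClassifiedBurst]] = {}
    frames = []
    for sid, ev in series.items():
        classified[sid] = assign_bursts(model, ev.bursts)
        frames.append(io_mod.classified_frame(sid, classified[sid]))
    pd.concat(frames, ignore_index=True).to_csv(
        out / "classified.csv", index=False, float_format="%.17g"
    )

    # stage 4: phases (depression pool across sessions)
    pre = {
        sid: (evs, phases_mod.delimit_high_load_clusters(
            [cb.burst.start for cb in evs if cb.category == "high-load"],
            [cb.burst.end for cb in evs if cb.category == "high-load"],
            config.segmentation.cluster_gap))
        for sid, evs in classified.items()
    }
    pool_intervals = np.concatenate([
        phases_mod.unassigned_interburst_intervals(
            evs, clusters, config.session_duration)
        for evs, clusters in pre.values()
    ]) if pre else np.array([])
    if pool_intervals.size:
        thr = phases_mod.depression_threshold(
            pool_intervals, config.segmentation.depression_percentile)
        log.info("depression threshold (pooled %dth percentile): %.1f s",
                 int(config.segmentation.depression_percentile), thr)
    phase_sets = {
        sid: phases_mod.segment_session(
            evs, config.session_duration, config.segmentation,
            depression_pool=pool_intervals if pool_intervals.size else None,
        )
        for sid, (evs, _) in pre.items()
    }
    io_mod.write_phases(out / "phases.tsv", phase_sets)

    # stage 5: statistics report
    stats_rows = []
    for sid, evs in classified.items():
        phs = phase_sets[sid]
        row = {"session_id": sid,
               "rate_high_per_s": phases_mod.high_load_rate(
                   evs, config.session_duration)}
        try:
            row["bg_low_rate_per_s"] = phases_mod.background_rates(
                evs, phs, category="low-load")
            row["bg_time_s"] = sum(
                p.duration for p in phs if p.kind == "background")
        except ValueError:
            row["bg_low_rate_per_s"] = np.nan
            row["bg_time_s"] = 0.0
        stats_rows.append(row)
    stats = pd.DataFrame(stats_rows)
    stats.to_csv(out / "statistics.csv", index=False, float_format="%.17g")
    return {"n_sessions": len(records), "statistics": stats}


def require_artifact(out_dir, name: str) -> Path:
    """Resolve a persisted artifact, failing with a clear message."""
    p = Path(out_dir) / name
    if not p.exists():
        raise FileNotFoundError(
            f"missing pipeline artifact '{name}' in {out_dir}; run the "
            "earlier stages first"
        )
    return p
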
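"""File formats for spikes, events, classified events and phases.

Event tables are CSV and phase tables are BED-like TSV; times are 64-bit
float seconds from session start, intervals half-open [start, end).
Round-trips are exact. LFP traces travel as NPZ containers with a
``sampling_rate`` attribute.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .bursts import Burst, EventSeries
from .classify import ClassifiedBurst
from .phases import Phase
from .spikes import LfpRecording, SpikeSeries

EVENT_COLUMNS = ["session_id", "event_type", "start_s", "end_s", "n_spikes"]
CLASSIFIED_COLUMNS = EVENT_COLUMNS + ["category", "load_index", "node_id"]
PHASE_COLUMNS = ["session_id", "start_s", "end_s", "kind", "complete"]
SPIKE_COLUMNS = ["session_id", "time_s", "polarity", "source"]


class SchemaError(ValueError):
    pass


def _require(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


# -- spikes -----------------------------------------------------------------

def write_spikes(path, series: SpikeSeries) -> None:
    pd.DataFrame({
        "session_id": series.session_id,
        "time_s": series.times,
        "polarity": series.polarity,
        "source": series.source,
    }).to_csv(path, index=False, float_format="%.17g")


def read_spikes(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, SPIKE_COLUMNS, path)
    return df


# -- events -----------------------------------------------------------------

def events_frame(series: EventSeries) -> pd.DataFrame:
    rows = [
        {"session_id": series.session_id, "event_type": "burst",
         "start_s": b.start, "end_s": b.end, "n_spikes": b.n_spikes,
         "spike_times": ";".join(f"{t:.17g}" for t in b.spike_times)}
        for b in series.bursts
    ] + [
        {"session_id": series.session_id, "event_type": "solitary",
         "start_s": t, "end_s": t, "n_spikes": 1,
         "spike_times": f"{t:.17g}"}
        for t in series.solitary_spikes
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS + ["spike_times"])


def write_events(path, series_list: Sequence[EventSeries]) -> None:
    pd.concat([events_frame(s) for s in series_list], ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_events(path) -> dict[str, EventSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, EVENT_COLUMNS + ["spike_times"], path)
    out: dict[str, EventSeries] = {}
    for sid, grp in df.groupby("session_id", sort=False):
        bursts = [
            Burst(tuple(float(x) for x in row.spike_times.split(";")))
            for row in grp.itertuples()
            if row.event_type == "burst"
        ]
        solitary = [
            float(row.start_s) for row in grp.itertuples()
            if row.event_type == "solitary"
        ]
        out[str(sid)] = EventSeries(tuple(bursts), tuple(solitary), str(sid))
    return out


def classified_frame(session_id: str, events: Sequence[ClassifiedBurst]) -> pd.DataFrame:
    rows = [
        {"session_id": session_id, "event_type": "burst",
         "start_s": cb.burst.start, "end_s": cb.burst.end,
         "n_spikes": cb.burst.n_spikes, "category": cb.category,
         "load_index": cb.load_index, "node_id": cb.node,
         "spike_times": ";".join(f"{t:.17g}" for t in cb.burst.spike_times)}
        for cb in events
    ]
    return pd.DataFrame(rows, columns=CLASSIFIED_COLUMNS + ["spike_times"])


def read_classified(path) -> dict[str, list[ClassifiedBurst]]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, CLASSIFIED_COLUMNS, path)
    out: dict[str, list[ClassifiedBurst]] = {}
    for sid, grp in df.groupby("session_id", sort=False):
        out[str(sid)] = [
            ClassifiedBurst(
                burst=Burst(tuple(float(x) for x in row.spike_times.split(";"))),
                category=row.category,
                load_index=None if pd.isna(row.load_index) else float(row.load_index),
                node=None if pd.isna(row.node_id) else int(row.node_id),
            )
            for row in grp.itertuples()
        ]
    return out


# -- phases -----------------------------------------------------------------

def write_phases(path, phase_sets: dict[str, Sequence[Phase]]) -> None:
    rows = [
        {"session_id": sid, "start_s": p.start, "end_s": p.end,
         "kind": p.kind, "complete": p.complete}
        for sid, plist in phase_sets.items()
        for p in plist
    ]
    pd.DataFrame(rows, columns=PHASE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_phases(path) -> dict[str, list[Phase]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require(df, PHASE_COLUMNS, path)
    out: dict[str, list[Phase]] = {}
    for sid, grp in df.groupby("session_id", sort=False):
        plist = sorted(
            (Phase(kind=row.kind, start=float(row.start_s), end=float(row.end_s),
                   complete=bool(row.complete))
             for row in grp.itertuples()),
            key=lambda p: p.start,
        )
        for a, b in zip(plist, plist[1:]):
            if b.start < a.end - 1e-9:
                raise SchemaError(
                    f"{path}: phases overlap in session {sid}: "
                    f"[{a.start}, {a.end}) and [{b.start}, {b.end})"
                )
        out[str(sid)] = plist
    return out


# -- LFP --------------------------------------------------------------------

def write_lfp(path, rec: LfpRecording) -> None:
    np.savez(
        path,
        samples=rec.samples,
        sampling_rate=rec.sampling_rate,
        artifact_mask=np.asarray(rec.artifact_mask, dtype=float).reshape(-1, 2),
        session_id=rec.session_id,
        animal_id=rec.animal_id,
        discard_head=rec.discard_head,
    )


def read_lfp(path) -> LfpRecording:
    with np.load(path, allow_pickle=False) as z:
        for key in ("samples", "sampling_rate"):
            if key not in z:
                raise SchemaError(f"{path}: missing array '{key}'")
        return LfpRecording(
            samples=z["samples"],
            sampling_rate=float(z["sampling_rate"]),
            artifact_mask=tuple(map(tuple, z["artifact_mask"])),
            session_id=str(z["session_id"]) if "session_id" in z else "",
            animal_id=str(z["animal_id"]) if "animal_id" in z else "",
            discard_head=float(z["discard_head"]) if "discard_head" in z else 600.0,
        )
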
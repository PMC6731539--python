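#!/usr/bin/env python
"""Run the full event pipeline on a simulated dataset: delimit bursts,
train the SOM on pooled >= 5-spike bursts, derive load categories by
Ward clustering, segment every session into phases, and summarize rates.

Writes all intermediate artifacts (spikes, events, classified events,
phases, statistics) under results/pipeline/.
"""

from pathlib import Path

import pandas as pd

from eaload import io as io_mod
from eaload.pipeline import PipelineConfig, run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "pipeline"


def main(seed: int = 0) -> None:
    cfg = PipelineConfig.from_dict({
        "seed": seed, "n_sessions": 12, "session_duration": 9000.0,
        "som_rows": 6, "som_cols": 4, "n_categories": 3,
    })
    summary = run_pipeline(cfg, OUT)
    stats = summary["statistics"]

    classified = io_mod.read_classified(OUT / "classified.csv")
    counts = pd.Series(
        [cb.category for evs in classified.values() for cb in evs]
    ).value_counts()
    print("burst category counts across sessions:")
    for cat, n in counts.items():
        print(f"  {cat:12s} {n}")

    phase_sets = io_mod.read_phases(OUT / "phases.tsv")
    total = sum(p.duration for ps in phase_sets.values() for p in ps)
    print("fraction of time per phase kind:")
    for kind in ("high_load_cluster", "pre", "post", "pre_post", "short",
                 "background", "excluded"):
        t = sum(p.duration for ps in phase_sets.values()
                for p in ps if p.kind == kind)
        print(f"  {kind:18s} {t / total:.3f}")

    print("per-session high-load rate (/h): "
          f"median {stats.rate_high_per_s.median() * 3600:.2f}")
    print("per-session background low-load rate (/min): "
          f"median {stats.bg_low_rate_per_s.median() * 60:.2f}")


if __name__ == "__main__":
    main()
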
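"""Segment a session of classified bursts into dynamical phases.

The timeline of a session is tiled, step-wise, by:

1. **high-load clusters** — high-load bursts closer than 3 min grouped
   together (a cluster may consist of a single high-load burst), spanning
   first-burst onset to last-burst offset;
2. **pre / post transition phases** — periods of densified bursting
   flanking clusters, delimited by CUSUM change points in the z-scored
   inter-burst interval sequence, kept only if their burst occupancy
   exceeds that of the unassigned remainder of the session; burst-free
   periods after a cluster longer than the 95th percentile of unassigned
   inter-burst intervals become depression post-phases;
3. **background phases** — the remaining epochs, excluding session
   borders and artifact neighborhoods, epochs shorter than 90 s
   ("short"), and epochs with > 15% medium-load burst occupancy
   ("pre|post").

All intervals are half-open ``[start, end)`` seconds from session start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .classify import ClassifiedBurst

PhaseKind = Literal[
    "high_load_cluster", "pre", "post", "pre_post", "short", "background", "excluded"
]


@dataclass(frozen=True)
class Phase:
    kind: str
    start: float
    end: float
    complete: bool = True
    annotations: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds of the step-wise phase definition (all seconds unless noted)."""

    cluster_gap: float = 180.0
    cusum_threshold: float = 1.5
    cusum_drift: float = 0.1
    depression_percentile: float = 95.0
    background_min: float = 90.0
    medload_occupancy_max: float = 0.15
    head_exclusion: float = 180.0
    tail_exclusion: float = 300.0

    def __post_init__(self) -> None:
        for name in ("cluster_gap", "cusum_threshold", "cusum_drift",
                     "background_min", "head_exclusion", "tail_exclusion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 < self.medload_occupancy_max < 1.0):
            raise ValueError("medload_occupancy_max must lie in (0, 1)")
        if not (0.0 < self.depression_percentile < 100.0):
            raise ValueError("depression_percentile must lie in (0, 100)")


# ---------------------------------------------------------------------------
# high-load clusters
# ---------------------------------------------------------------------------

def delimit_high_load_clusters(
    high_starts: Sequence[float],
    high_ends: Sequence[float],
    cluster_gap: float = 180.0,
) -> list[Phase]:
    """Group high-load bursts whose offset-to-onset gap is below the
    cluster gap (3 min). Singleton clusters are allowed. Each cluster
    spans its first burst's onset to its last burst's offset."""
    starts = np.asarray(high_starts, dtype=float)
    ends = np.asarray(high_ends, dtype=float)
    if starts.size == 0:
        return []
    clusters: list[Phase] = []
    c_start, c_end, size = starts[0], ends[0], 1
    for s, e in zip(starts[1:], ends[1:]):
        if s - c_end < cluster_gap:
            c_end, size = e, size + 1
        else:
            clusters.append(Phase("high_load_cluster", c_start, c_end,
                                  annotations={"size": size}))
            c_start, c_end, size = s, e, 1
    clusters.append(Phase("high_load_cluster", c_start, c_end,
                          annotations={"size": size}))
    return clusters


# ---------------------------------------------------------------------------
# CUSUM change points
# ---------------------------------------------------------------------------

def cusum_change_points(
    z: Sequence[float], threshold: float = 1.5, drift: float = 0.1
) -> list[tuple[int, str]]:
    """Two one-sided CUSUM detectors on a (z-scored) sequence.

    Returns ``(index, direction)`` pairs where ``direction`` is ``"up"``
    for a shift toward larger values and ``"down"`` toward smaller ones.
    A change is reported when a cumulative sum exceeds ``threshold`` and
    is localized at the sample following the last zero of that sum. Both
    sums reset after an alarm.
    """
    x = np.asarray(z, dtype=float)
    if x.size < 2:
        return []
    out: list[tuple[int, str]] = []
    s_up = s_dn = 0.0
    zero_up = zero_dn = -1  # last index at which the sum was (still) zero
    armed_up = armed_dn = True  # one alarm per excursion above threshold
    for i, v in enumerate(x):
        s_up = max(0.0, s_up + v - drift)
        s_dn = max(0.0, s_dn - v - drift)
        if s_up == 0.0:
            zero_up, armed_up = i, True
        if s_dn == 0.0:
            zero_dn, armed_dn = i, True
        if armed_up and s_up > threshold:
            out.append((zero_up + 1, "up"))
            armed_up = False
        if armed_dn and s_dn > threshold:
            out.append((zero_dn + 1, "down"))
            armed_dn = False
    return out


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

def _burst_time_in(events: Sequence[ClassifiedBurst], start: float, end: float) -> float:
    """Total time covered by bursts within [start, end)."""
    total = 0.0
    for cb in events:
        b = cb.burst
        total += max(0.0, min(b.end, end) - max(b.start, start))
    return total


def _bursts_between(
    events: Sequence[ClassifiedBurst], start: float, end: float
) -> list[ClassifiedBurst]:
    return [cb for cb in events if cb.burst.start >= start and cb.burst.end <= end]


def delimit_transitions(
    events: Sequence[ClassifiedBurst],
    clusters: Sequence[Phase],
    duration: float,
    config: SegmentationConfig = SegmentationConfig(),
) -> list[Phase]:
    """Pre/post transition phases around high-load clusters.

    Within each inter-cluster gap the sequence of inter-burst intervals is
    z-scored (per gap) and scanned with CUSUM. The last change point
    toward shorter intervals before a cluster starts the pre-phase; the
    first change point toward longer intervals after a cluster ends the
    post-phase. A candidate is kept only if its burst occupancy exceeds
    the occupancy of the remaining unassigned portion of the session.
    """
    candidates: list[Phase] = []
    edges = [0.0] + [c.end for c in clusters]
    nexts = [c.start for c in clusters] + [duration]
    for gap_start, gap_end, has_prev, has_next in zip(
        edges, nexts, [False] + [True] * len(clusters),
        [True] * len(clusters) + [False],
    ):
        if gap_end <= gap_start:
            continue
        gap_bursts = _bursts_between(events, gap_start, gap_end)
        if len(gap_bursts) < 3:
            continue
        ib = np.array([
            gap_bursts[i + 1].burst.start - gap_bursts[i].burst.end
            for i in range(len(gap_bursts) - 1)
        ])
        sd = ib.std(ddof=1)
        if sd == 0:
            continue
        z = (ib - ib.mean()) / sd
        cps = cusum_change_points(z, config.cusum_threshold, config.cusum_drift)
        if has_next:
            down = [i for i, d in cps if d == "down"]
            if down:
                j = down[-1]  # last shift toward shorter intervals
                start = gap_bursts[j].burst.start
                if start < gap_end:
                    candidates.append(Phase("pre", start, gap_end))
        if has_prev:
            up = [i for i, d in cps if d == "up"]
            if up:
                j = up[0]  # first shift toward longer intervals
                end = gap_bursts[j].burst.end
                if end > gap_start:
                    candidates.append(Phase("post", gap_start, end))

    # a post-phase and the next pre-phase may meet inside one gap; the
    # earlier (post) phase keeps its extent and the pre-phase is clipped
    candidates.sort(key=lambda p: (p.start, p.kind != "post"))
    clipped: list[Phase] = []
    cursor = -np.inf
    for cand in candidates:
        start = max(cand.start, cursor)
        if start < cand.end:
            clipped.append(replace(cand, start=start))
            cursor = cand.end
    # occupancy validity check, applied against the unassigned remainder
    assigned: list[Phase] = list(clusters)
    accepted: list[Phase] = []
    total_burst = _burst_time_in(events, 0.0, duration)
    for cand in clipped:
        occupied = sum(p.duration for p in assigned + [cand])
        rest = duration - occupied
        if rest <= 0:
            continue
        cand_occ = _burst_time_in(events, cand.start, cand.end) / cand.duration
        rest_burst = total_burst - sum(
            _burst_time_in(events, p.start, p.end) for p in assigned + [cand]
        )
        if cand_occ > rest_burst / rest:
            accepted.append(cand)
            assigned.append(cand)
    return accepted


# ---------------------------------------------------------------------------
# depression post-phases
# ---------------------------------------------------------------------------

def unassigned_interburst_intervals(
    events: Sequence[ClassifiedBurst],
    assigned: Sequence[Phase],
    duration: float,
) -> np.ndarray:
    """Inter-burst intervals lying entirely in unassigned portions."""
    spans = sorted([(p.start, p.end) for p in assigned])
    out: list[float] = []
    bs = sorted(events, key=lambda cb: cb.burst.start)
    for a, b in zip(bs, bs[1:]):
        lo, hi = a.burst.end, b.burst.start
        if hi <= lo:
            continue
        if any(s < hi and lo < e for s, e in spans):
            continue
        out.append(hi - lo)
    return np.asarray(out)


def depression_threshold(
    interval_pool: Sequence[float], percentile: float = 95.0
) -> float:
    """Percentile (linear interpolation) of pooled unassigned inter-burst
    intervals; gaps after clusters longer than this become depression
    post-phases. On the published data this evaluated to 112 s."""
    pool = np.asarray(interval_pool, dtype=float)
    if pool.size == 0:
        raise ValueError("empty interval pool")
    return float(np.percentile(pool, percentile))


def detect_depression(
    events: Sequence[ClassifiedBurst],
    clusters: Sequence[Phase],
    transitions: Sequence[Phase],
    threshold: float,
    duration: float,
) -> list[Phase]:
    """Burst-free periods after a cluster longer than the threshold become
    depression post-phases (only where no post-phase was assigned yet)."""
    have_post = {p.start for p in transitions if p.kind == "post"}
    starts = np.array([cb.burst.start for cb in events])
    out: list[Phase] = []
    for c in clusters:
        if c.end in have_post:
            continue
        later = starts[starts >= c.end]
        nxt = float(later.min()) if later.size else duration
        complete = bool(later.size)
        if nxt - c.end > threshold:
            out.append(Phase("post", c.end, nxt, complete=complete,
                             annotations={"depression": True}))
    return out


# ---------------------------------------------------------------------------
# background assembly
# ---------------------------------------------------------------------------

def assemble_background(
    events: Sequence[ClassifiedBurst],
    assigned: Sequence[Phase],
    duration: float,
    config: SegmentationConfig = SegmentationConfig(),
    artifact_intervals: Sequence[tuple[float, float]] = (),
) -> list[Phase]:
    """Label the remaining epochs and return the complete phase tiling.

    Epochs overlapping an artifact interval are excluded in full. The
    first ``head_exclusion`` seconds are excluded unless a high-load
    cluster ends within that window; the last ``tail_exclusion`` seconds
    are always excluded from background. Remaining epochs become
    ``pre_post`` (> 15% medium-load occupancy), ``short`` (< 90 s) or
    ``background``. The returned list tiles ``[0, duration)`` exactly.
    """
    phases = sorted(assigned, key=lambda p: p.start)
    for a, b in zip(phases, phases[1:]):
        if b.start < a.end - 1e-9:
            raise ValueError("assigned phases overlap")

    head_waived = any(
        p.kind == "high_load_cluster" and 0 <= p.end <= config.head_exclusion
        for p in phases
    )
    cuts: list[tuple[float, float]] = []
    if config.head_exclusion > 0 and not head_waived:
        cuts.append((0.0, config.head_exclusion))
    if config.tail_exclusion > 0:
        cuts.append((max(duration - config.tail_exclusion, 0.0), duration))

    out: list[Phase] = list(phases)
    edges = [0.0] + [p.end for p in phases]
    nexts = [p.start for p in phases] + [duration]
    for lo, hi in zip(edges, nexts):
        if hi <= lo:
            continue
        out.extend(_label_epoch(events, lo, hi, duration, config, cuts,
                                artifact_intervals))
    out.sort(key=lambda p: p.start)
    return out


def _label_epoch(events, lo, hi, duration, config, cuts, artifacts) -> list[Phase]:
    # split the epoch at border-exclusion windows
    pieces: list[tuple[float, float, str]] = [(lo, hi, "open")]
    for c_lo, c_hi in cuts:
        nxt: list[tuple[float, float, str]] = []
        for a, b, tag in pieces:
            if tag == "excluded" or b <= c_lo or a >= c_hi:
                nxt.append((a, b, tag))
                continue
            if a < c_lo:
                nxt.append((a, c_lo, tag))
            nxt.append((max(a, c_lo), min(b, c_hi), "excluded"))
            if b > c_hi:
                nxt.append((c_hi, b, tag))
        pieces = nxt
    out = []
    for a, b, tag in pieces:
        if b <= a:
            continue
        if tag == "excluded" or any(s < b and a < e for s, e in artifacts):
            out.append(Phase("excluded", a, b))
            continue
        med = [cb for cb in events if cb.category == "medium-load"]
        occ = _burst_time_in(med, a, b) / (b - a)
        complete = a > 0.0 and b < duration and (a, b) == (lo, hi)
        if occ > config.medload_occupancy_max:
            out.append(Phase("pre_post", a, b, complete=complete))
        elif b - a < config.background_min:
            out.append(Phase("short", a, b, complete=complete))
        else:
            out.append(Phase("background", a, b, complete=complete))
    return out


def segment_session(
    events: Sequence[ClassifiedBurst],
    duration: float,
    config: SegmentationConfig = SegmentationConfig(),
    artifact_intervals: Sequence[tuple[float, float]] = (),
    depression_pool: Sequence[float] | None = None,
    include_transitions: bool = True,
) -> list[Phase]:
    """Run the full step-wise segmentation for one session.

    ``depression_pool`` supplies the cross-session pool of unassigned
    inter-burst intervals; if None, the session's own intervals are used
    (single-session fallback). ``include_transitions=False`` reproduces
    the simplified segmentation used for the simulated surrogate dataset
    (clusters + background only, no border exclusions).
    """
    highs = sorted(
        (cb for cb in events if cb.category == "high-load"),
        key=lambda cb: cb.burst.start,
    )
    clusters = delimit_high_load_clusters(
        [cb.burst.start for cb in highs], [cb.burst.end for cb in highs],
        config.cluster_gap,
    )
    if not include_transitions:
        simple = replace(config, head_exclusion=0.0, tail_exclusion=0.0,
                         background_min=0.0)
        # every non-cluster epoch is background, regardless of content
        out: list[Phase] = list(clusters)
        edges = [0.0] + [p.end for p in clusters]
        nexts = [p.start for p in clusters] + [duration]
        for lo, hi in zip(edges, nexts):
            if hi > lo:
                out.append(Phase("background", lo, hi,
                                 complete=lo > 0.0 and hi < duration))
        out.sort(key=lambda p: p.start)
        return out

    transitions = delimit_transitions(events, clusters, duration, config)
    pool = (
        np.asarray(depression_pool, dtype=float)
        if depression_pool is not None
        else unassigned_interburst_intervals(events, clusters + transitions, duration)
    )
    if pool.size:
        thr = depression_threshold(pool, config.depression_percentile)
        transitions = transitions + detect_depression(
            events, clusters, transitions, thr, duration
        )
    return assemble_background(events, clusters + transitions, duration,
                               config, artifact_intervals)


# ---------------------------------------------------------------------------
# phase statistics
# ---------------------------------------------------------------------------

def events_in_phase(
    events: Sequence[ClassifiedBurst], phase: Phase
) -> list[ClassifiedBurst]:
    return [cb for cb in events if phase.start <= cb.burst.start < phase.end]


def phase_spike_rate(spikes: Sequence[float], phase: Phase) -> float:
    s = np.asarray(spikes, dtype=float)
    n = int(np.sum((s >= phase.start) & (s < phase.end)))
    return n / phase.duration


def background_rates(
    events: Sequence[ClassifiedBurst],
    phases: Sequence[Phase],
    category: str | None = None,
) -> float:
    """Per-session background rate: events counted across all background
    phases divided by total background time. Undefined (ValueError) for
    sessions without background phases."""
    bg = [p for p in phases if p.kind == "background"]
    if not bg:
        raise ValueError("session has no background phases")
    total_t = sum(p.duration for p in bg)
    n = 0
    for p in bg:
        for cb in events_in_phase(events, p):
            if category is None or cb.category == category:
                n += 1
    return n / total_t


def high_load_rate(
    events: Sequence[ClassifiedBurst],
    duration: float,
    excluded_time: float = 0.0,
) -> float:
    """High-load bursts per second of session, border/artifact time removed."""
    n = sum(1 for cb in events if cb.category == "high-load")
    return n / (duration - excluded_time)


def ea_free_episodes(
    event_intervals: Sequence[tuple[float, float]], phase: Phase
) -> list[tuple[float, float]]:
    """Periods within a background phase containing no EA events.

    ``event_intervals`` are (start, end) spans of events (bursts; solitary
    spikes as zero-length spans). Gaps to the phase borders count.
    """
    spans = sorted(
        (max(s, phase.start), min(e, phase.end))
        for s, e in event_intervals
        if s < phase.end and e > phase.start
    )
    out: list[tuple[float, float]] = []
    cursor = phase.start
    for s, e in spans:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if phase.end > cursor:
        out.append((cursor, phase.end))
    return out


def relative_placement(
    episode: tuple[float, float], phase: Phase
) -> float:
    """Relative midpoint position of an episode within its phase, in [0, 1]."""
    mid = 0.5 * (episode[0] + episode[1])
    return (mid - phase.start) / phase.duration


def cluster_offset_delays(
    events: Sequence[ClassifiedBurst], clusters: Sequence[Phase], duration: float
) -> list[float]:
    """Delay between the end of each cluster's last (high-load) burst and
    the start of the first following burst."""
    starts = np.array(sorted(cb.burst.start for cb in events))
    out = []
    for c in clusters:
        later = starts[starts >= c.end]
        if later.size:
            out.append(float(later.min() - c.end))
    return out


def weighted_average(values: Sequence[float], weights: Sequence[float]) -> float:
    """Duration-weighted average (per-animal summaries)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0 or w.sum() == 0:
        raise ValueError("cannot average an empty or zero-weight set")
    return float(np.sum(v * w) / w.sum())
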
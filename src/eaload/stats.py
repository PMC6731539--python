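"""Point-process and correlation statistics for epileptiform event series.

Implements the statistical toolbox used throughout the pipeline:

* burstiness coefficient of inter-event intervals,
* dead-time-adjusted Poisson surrogate event series,
* empirical (surrogate / permutation) p values,
* Kendall tau, Theil–Sen regression, Kaplan–Meier survival,
* standard group-difference tests with Bonferroni correction,
* a chi-square test for uniform placement of episodes.

All times are seconds. Surrogate generators are seeded explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats as sps

Tail = Literal["left", "right"]

SPIKE_DEAD_TIME = 0.0833
"""Detector dead time (s): refractory period of the spike detector."""

BURST_DEAD_TIME = 3.5
"""Burst dead time (s): two bursts closer than this would have been joined."""


# ---------------------------------------------------------------------------
# burstiness
# ---------------------------------------------------------------------------

def burstiness(intervals: Sequence[float]) -> float:
    """Burstiness coefficient (SD - mean)/(SD + mean) of inter-event intervals.

    Ranges from -1 (perfectly regular intervals) over 0 (Poissonian,
    exponential intervals) toward +1 (extremely bursty). Uses the sample SD
    (``ddof=1``).

    Raises
    ------
    ValueError
        If fewer than two intervals are given, or any interval is
        non-positive (an event series cannot have zero-length intervals).
    """
    x = np.asarray(intervals, dtype=float)
    if x.size < 2:
        raise ValueError("burstiness requires at least 2 intervals")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("intervals must be positive and finite")
    sd = x.std(ddof=1)
    mu = x.mean()
    return float((sd - mu) / (sd + mu))


# ---------------------------------------------------------------------------
# surrogate event series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateSpec:
    """Parameters of a dead-time-adjusted Poisson surrogate series.

    ``rate_observed`` is the event rate the surrogates should reproduce
    after dead time ``t_dead`` and event durations ``t_event`` are inserted.
    For spike surrogates ``t_dead = 0.0833 s`` and ``t_event = 0``; for burst
    surrogates ``t_dead = 3.5 s`` and ``t_event`` equals the mean duration of
    the pooled burst events, whose durations are re-drawn from
    ``duration_pool``.
    """

    rate_observed: float
    t_dead: float = 0.0
    t_event: float = 0.0
    duration: float = 3600.0
    duration_pool: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not np.isfinite(self.rate_observed) or self.rate_observed <= 0:
            raise ValueError("rate_observed must be positive and finite")
        if self.t_dead < 0 or self.t_event < 0 or self.duration <= 0:
            raise ValueError("t_dead, t_event must be >= 0; duration > 0")
        if self.rate_observed * (self.t_dead + self.t_event) >= 1:
            raise ValueError(
                "rate_observed * (t_dead + t_event) must be < 1; the "
                "requested rate cannot be realized with this dead time"
            )


def adjust_rate(spec: SurrogateSpec) -> float:
    """Poisson rate whose dead-time-padded realization matches the observed rate.

    ``rate_adjusted = rate_observed / (1 - rate_observed * (t_dead + t_event))``

    so that the mean cycle length ``1/rate_adjusted + t_dead + t_event``
    equals ``1/rate_observed``.
    """
    return spec.rate_observed / (
        1.0 - spec.rate_observed * (spec.t_dead + spec.t_event)
    )


def surrogate_events(
    spec: SurrogateSpec,
    kind: Literal["spikes", "bursts"] = "spikes",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Generate one surrogate event series (event onset times, seconds).

    Events are laid out by concatenating exponential waiting times at the
    adjusted rate, each followed by the dead time and — for burst
    surrogates — an event duration drawn from ``spec.duration_pool``.
    The series is truncated at ``spec.duration``.
    """
    rng = np.random.default_rng(rng)
    rate = adjust_rate(spec)
    if kind == "bursts":
        if len(spec.duration_pool) == 0:
            raise ValueError("burst surrogates need a non-empty duration pool")
        pool = np.asarray(spec.duration_pool, dtype=float)
    elif kind != "spikes":
        raise ValueError(f"unknown surrogate kind: {kind!r}")

    # cycle = exponential wait + dead time (+ event duration for bursts);
    # draw in blocks until the session is covered
    chunks: list[np.ndarray] = []
    t_end = 0.0
    n_guess = int(spec.duration * spec.rate_observed * 1.2) + 32
    while t_end < spec.duration:
        waits = rng.exponential(1.0 / rate, size=n_guess)
        pads = (
            spec.t_dead + rng.choice(pool, size=n_guess)
            if kind == "bursts"
            else np.full(n_guess, spec.t_dead)
        )
        cycles = np.cumsum(waits + pads)
        onsets = t_end + cycles - pads  # event time = end of the wait
        chunks.append(onsets)
        t_end += cycles[-1]
    times = np.concatenate(chunks)
    return times[times < spec.duration]


def p_surrogate(observed: float, surrogate_values: Sequence[float], tail: Tail) -> float:
    """Empirical p value: fraction of surrogate values beyond the observed one.

    Right tail counts surrogates >= observed, left tail counts <= observed
    (ties count as exceeding, which is conservative). A zero fraction is
    conventionally reported as "< 1/N"; this function returns the raw
    fraction — use :func:`format_p` for reporting.
    """
    s = np.asarray(surrogate_values, dtype=float)
    if s.size == 0:
        raise ValueError("need at least one surrogate value")
    if tail == "right":
        return float(np.mean(s >= observed))
    if tail == "left":
        return float(np.mean(s <= observed))
    raise ValueError(f"tail must be 'left' or 'right', got {tail!r}")


def format_p(p: float, n_surrogates: int) -> str:
    """Report an empirical p value, rendering an exact zero as ``< 1/N``."""
    if p == 0.0:
        return f"< {1.0 / n_surrogates:g}"
    return f"{p:g}"


def permute_animals(
    episode_values: Sequence[float],
    animal_labels: Sequence,
    statistic: Callable[[np.ndarray, np.ndarray], float],
    n_perm: int = 1000,
    tail: Tail = "right",
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Permutation test across animals, preserving per-animal episode counts.

    Episodes (e.g. background phases or sessions) are randomly reallocated
    to surrogate animals so that each surrogate animal receives exactly as
    many episodes as the real animal contributed. ``statistic`` receives
    ``(values, labels)`` and returns a scalar (e.g. Kendall tau between
    per-animal means and some per-animal covariate computed inside).

    Returns ``(observed, p, permuted_statistics)``.
    """
    values = np.asarray(episode_values, dtype=float)
    labels = np.asarray(animal_labels)
    if len(values) != len(labels):
        raise ValueError("episode_values and animal_labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("permutation test requires at least 2 animals")
    rng = np.random.default_rng(rng)
    observed = float(statistic(values, labels))
    perms = np.empty(n_perm)
    for i in range(n_perm):
        perms[i] = statistic(rng.permutation(values), labels)
    return observed, p_surrogate(observed, perms, tail), perms


# ---------------------------------------------------------------------------
# correlation / regression / survival
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    """Kendall correlation with analytic and (optional) empirical p values."""

    tau: float
    n: int
    p_tau: float
    p_surrogate: float | None = None
    tail: Tail | None = None


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Kendall's tau-b (tie-corrected) with the analytic p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need paired samples with n >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau undefined for a constant sample")
    res = sps.kendalltau(x, y)
    return CorrelationResult(tau=float(res.statistic), n=int(x.size),
                             p_tau=float(res.pvalue))


def theil_sen(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Theil–Sen line: median pairwise slope, intercept = median(y - slope*x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("Theil-Sen requires at least 2 distinct x values")
    res = sps.theilslopes(y, x, method="joint")
    return float(res.slope), float(res.intercept)


def km_survival(
    durations: Sequence[float], censored: Sequence[bool] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan–Meier survival S(t) of episode durations.

    ``censored[i]`` marks episodes whose full duration was not observed
    (e.g. background phases cut off by the end of a session). Returns
    ``(times, survival)`` where ``survival[k]`` is S at ``times[k]``.
    """
    from lifelines import KaplanMeierFitter

    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("empty duration set")
    if np.any(d < 0):
        raise ValueError("durations must be >= 0")
    observed = (
        np.ones_like(d, dtype=bool)
        if censored is None
        else ~np.asarray(censored, dtype=bool)
    )
    kmf = KaplanMeierFitter()
    kmf.fit(d, event_observed=observed)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    return times, surv


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni correction: multiply by the family size, cap at 1."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * p.size, 1.0)


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    stat, p = sps.kruskal(*groups)
    return float(stat), float(p)


def mann_whitney_pairs(
    groups: dict[str, Sequence[float]]
) -> dict[tuple[str, str], float]:
    """All pairwise Mann–Whitney U tests, Bonferroni-corrected as one family."""
    names = list(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    raw = [float(sps.mannwhitneyu(groups[a], groups[b]).pvalue) for a, b in pairs]
    corrected = bonferroni(raw)
    return dict(zip(pairs, corrected.tolist()))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    if len(x) != len(y):
        raise ValueError("paired test requires equal lengths")
    stat, p = sps.wilcoxon(x, y)
    return float(stat), float(p)


def slopes_t_test(slopes: Sequence[float]) -> tuple[float, float]:
    """One-sample t test of fitted regression slopes against zero mean."""
    stat, p = sps.ttest_1samp(np.asarray(slopes, dtype=float), 0.0)
    return float(stat), float(p)


def uniform_placement_test(
    positions: Sequence[float], n_bins: int = 10
) -> tuple[float, float]:
    """Chi-square test of relative positions in [0, 1] against uniformity.

    Used for the placement of long EA-free episodes within background
    phases. Returns ``(chi2, p)``.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise ValueError("no positions given")
    if np.any(pos < 0) or np.any(pos > 1):
        raise ValueError("positions must lie in [0, 1]")
    counts, _ = np.histogram(pos, bins=n_bins, range=(0.0, 1.0))
    stat, p = sps.chisquare(counts)
    return float(stat), float(p)
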
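"""Stochastic and deterministic synthetic morphokinetic cohorts.

The generator emulates a multi-run in-vitro embryo-production experiment
observed by time-lapse imaging. Each embryo draws a cleavage pattern from
cohort-level frequencies, realizes the defining event sequence of that
pattern, and draws a blastocyst outcome from a pattern-conditional
probability. Event times follow a *tempo* model: one lognormal pace
factor per embryo (median 1) multiplies a fixed milestone template, plus
small per-event Gaussian jitter, snapped to the 5-minute acquisition grid
of the incubator. Because the tempo has median 1 and the jitter median 0,
cohort median times reproduce the template by construction.

Default parameters are the pooled composition of a 36-run, 1,021-embryo
bovine IVF experiment (normal 702 — 431 synchronous / 271 asynchronous —
and abnormal 319 — 193 direct / 95 unequal / 27 reverse / 4 with more
than one abnormal pattern), pattern-conditional blastocyst rates from the
same pooled counts, and median milestone times of 29.0 / 38.7 / 51.0 h
for the first three cleavages and 113.0 / 130.5 / 159.5 / 166.5 h for
morula through expanded blastocyst.

:func:`make_fixture_cohort` builds the deterministic, noise-free
counterpart: exact per-category record counts and outcome counts, for
classifier round-trip testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from morphokin.events import (
    Cohort,
    EmbryoRecord,
    RunInfo,
    Stage,
    Symmetry,
    TransitionEvent,
    FULL_RECORD_HOURS,
    TIME_GRID_H,
)
from morphokin.classify import ASYNCHRONOUS_COUNTS

PATTERNS = ("synchronous", "asynchronous", "direct", "unequal", "reverse",
            "multiple_abnormal")

#: Pooled per-category record counts (2- to 4-cell embryos over 36 runs).
STUDY_COMPOSITION: dict[str, int] = {
    "synchronous": 431,
    "asynchronous": 271,
    "direct": 193,
    "unequal": 95,
    "reverse": 27,
    "multiple_abnormal": 4,
}

#: Pooled blastocyst counts per category.
STUDY_BLASTOCYST_COUNTS: dict[str, int] = {
    "synchronous": 65,
    "asynchronous": 81,
    "direct": 24,
    "unequal": 4,
    "reverse": 0,
    "multiple_abnormal": 0,
}

#: Pooled early-blastocyst counts per category (reference only).
STUDY_EARLY_BLASTOCYST_COUNTS: dict[str, int] = {
    "synchronous": 94,
    "asynchronous": 117,
    "direct": 35,
    "unequal": 7,
    "reverse": 0,
    "multiple_abnormal": 0,
}

_N_TOTAL = sum(STUDY_COMPOSITION.values())  # 1021

DEFAULT_TIMING_TEMPLATE: dict[str, float] = {
    "cleavage1": 29.0,
    "cleavage2": 38.7,
    "cleavage3": 51.0,
    # 16-cell (4th-round) time: not reliably observed in typical datasets;
    # extrapolated from the ~12-13 h inter-division spacing.
    "cleavage4": 66.0,
    "morula": 113.0,
    "early_blastocyst": 130.5,
    "blastocyst": 159.5,
    "expanded_blastocyst": 166.5,
}

_STAGE_KEYS = ("morula", "early_blastocyst", "blastocyst", "expanded_blastocyst")
_STAGE_OF_KEY = {
    "morula": Stage.MORULA,
    "early_blastocyst": Stage.EARLY_BLASTOCYST,
    "blastocyst": Stage.BLASTOCYST,
    "expanded_blastocyst": Stage.EXPANDED_BLASTOCYST,
}

#: Ordered asynchronous intermediate counts used to build trajectories.
_ASYNC_POOL = (3, 5, 6, 7, 10, 12)


def study_composition() -> tuple[dict[str, int], dict[str, int]]:
    """Per-category record and blastocyst counts of the pooled study table."""
    return dict(STUDY_COMPOSITION), dict(STUDY_BLASTOCYST_COUNTS)


@dataclass(frozen=True)
class SimParams:
    """Cohort-simulation parameters.

    ``pattern_freqs`` must sum to 1 over :data:`PATTERNS`;
    ``async_event_dist`` gives probabilities of 1..6 asynchronous events
    for asynchronous embryos; ``tempo_sigma`` is the log-scale SD of the
    per-embryo pace factor (dimensionless), ``jitter_sigma_h`` the SD in
    hours of per-event noise.
    """

    n_runs: int = 36
    embryos_per_run: int | Sequence[int] = 28
    pattern_freqs: dict[str, float] = field(
        default_factory=lambda: {k: v / _N_TOTAL for k, v in STUDY_COMPOSITION.items()}
    )
    blastocyst_prob: dict[str, float] = field(
        default_factory=lambda: {
            k: (STUDY_BLASTOCYST_COUNTS[k] / v if v else 0.0)
            for k, v in STUDY_COMPOSITION.items()
        }
    )
    async_event_dist: tuple[float, ...] = (0.235, 0.235, 0.235, 0.235, 0.03, 0.03)
    timing_template: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TIMING_TEMPLATE)
    )
    tempo_sigma: float = 0.10
    jitter_sigma_h: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = np.array([self.pattern_freqs.get(p, 0.0) for p in PATTERNS])
        if np.any(freqs < 0) or np.any(freqs > 1) or not math.isclose(freqs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("pattern_freqs must be a probability vector over the six patterns")
        dist = np.asarray(self.async_event_dist, dtype=float)
        if dist.size != 6 or np.any(dist < 0) or not math.isclose(dist.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("async_event_dist must be six non-negative probabilities summing to 1")
        for k, p in self.blastocyst_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"blastocyst_prob[{k!r}] outside [0, 1]")
        t = self.timing_template
        keys = ["cleavage1", "cleavage2", "cleavage3", "cleavage4", *_STAGE_KEYS]
        vals = [t[k] for k in keys]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("timing_template must be strictly increasing over milestones")
        if self.tempo_sigma < 0 or self.jitter_sigma_h < 0:
            raise ValueError("noise scales must be non-negative")
        if self.n_runs < 1:
            raise ValueError("n_runs must be positive")

    @property
    def run_sizes(self) -> list[int]:
        if isinstance(self.embryos_per_run, int):
            return [self.embryos_per_run] * self.n_runs
        sizes = list(self.embryos_per_run)
        if len(sizes) != self.n_runs:
            raise ValueError("per-run size list must have n_runs entries")
        return sizes


@dataclass(frozen=True)
class TruthLabel:
    """Generating truth for one simulated embryo."""

    embryo_id: str
    pattern: str
    n_async_events: int
    blastocyst: bool


def _nominal_count_time(count: int, template: Mapping[str, float]) -> float:
    """Nominal hours at which a given blastomere count is reached.

    Anchored at the 2/4/8/16-cell template times; intermediate counts are
    placed by linear interpolation on the log2(count) axis.
    """
    anchors = [(1.0, template["cleavage1"]), (2.0, template["cleavage2"]),
               (3.0, template["cleavage3"]), (4.0, template["cleavage4"])]
    x = math.log2(count)
    if x <= anchors[0][0]:
        return anchors[0][1]
    for (x0, t0), (x1, t1) in zip(anchors, anchors[1:]):
        if x <= x1:
            return t0 + (t1 - t0) * (x - x0) / (x1 - x0)
    return anchors[-1][1]


def _snap(t: float) -> float:
    return round(t / TIME_GRID_H) * TIME_GRID_H


def _trajectory(pattern: str, rng: np.random.Generator) -> tuple[list[int], list[Symmetry], int]:
    """Counts, symmetry flags and async-event count for one embryo."""
    eq, uneq, na = Symmetry.EQUAL, Symmetry.UNEQUAL, Symmetry.NOT_APPLICABLE
    if pattern == "synchronous":
        return [2, 4, 8, 16], [eq, na, na, na], 0
    if pattern == "asynchronous":
        return [2, 4, 8, 16], [eq, na, na, na], 0  # replaced by caller
    if pattern == "direct":
        c1 = 3 if rng.random() < 0.7 else 4
        counts = [c1, 8, 16]
        return counts, [na] * len(counts), 0
    if pattern == "unequal":
        return [2, 4, 8, 16], [uneq, na, na, na], 0
    if pattern == "reverse":
        return [2, 1], [eq, na], 0
    if pattern == "multiple_abnormal":
        return [2, 1], [uneq, na], 0
    raise ValueError(f"unknown pattern {pattern!r}")


def _async_trajectory(k: int, rng: np.random.Generator | None) -> list[int]:
    """Counts for an asynchronous embryo with exactly ``k`` async events."""
    if not 1 <= k <= 6:
        raise ValueError("asynchronous embryos have 1..6 async events")
    if rng is None:
        extra = list(_ASYNC_POOL[:k])
    else:
        extra = sorted(rng.choice(_ASYNC_POOL, size=k, replace=False).tolist())
    return [2] + sorted(set(extra) | {4, 8, 16})


def _timed_events(counts: Sequence[int], syms: Sequence[Symmetry],
                  stage_keys: Sequence[str], template: Mapping[str, float],
                  tempo: float, jitter: np.ndarray) -> list[TransitionEvent]:
    """Place events on the clock: tempo x template + jitter, 5-min grid,
    strictly increasing."""
    events: list[TransitionEvent] = []
    prev = 0.0
    j = 0
    for count, sym in zip(counts, syms):
        if count == 1:
            nominal = _nominal_count_time(2, template) + 1.0  # reverse merge
        else:
            nominal = _nominal_count_time(count, template)
        t = _snap(tempo * nominal + float(jitter[j])); j += 1
        t = max(t, prev + TIME_GRID_H)
        events.append(TransitionEvent(time_h=t, stage=Stage.CLEAVAGE,
                                      cell_count=count, symmetry=sym))
        prev = t
    for key in stage_keys:
        t = _snap(tempo * template[key] + float(jitter[j])); j += 1
        t = max(t, prev + TIME_GRID_H)
        events.append(TransitionEvent(time_h=t, stage=_STAGE_OF_KEY[key]))
        prev = t
    return events


def simulate_cohort(params: SimParams, seed: int | None = None) -> tuple[Cohort, list[TruthLabel]]:
    """Draw a stochastic cohort with truth labels.

    Reproducible: the same ``params`` (including ``params.seed``, unless
    overridden by ``seed``) gives an identical cohort; per-embryo random
    substreams are derived from one root ``SeedSequence`` so cohorts are
    stable under partial regeneration.
    """
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    n_total = sum(params.run_sizes)
    children = root.spawn(n_total + 1)
    head = np.random.default_rng(children[0])

    freqs = np.array([params.pattern_freqs.get(p, 0.0) for p in PATTERNS])
    patterns = head.choice(len(PATTERNS), size=n_total, p=freqs)

    records: list[EmbryoRecord] = []
    labels: list[TruthLabel] = []
    idx = 0
    for r, size in enumerate(params.run_sizes):
        run_id = f"run{r + 1:02d}"
        for _ in range(size):
            rng = np.random.default_rng(children[idx + 1])
            pattern = PATTERNS[patterns[idx]]
            embryo_id = f"sim{idx + 1:05d}"
            n_async = 0
            if pattern == "asynchronous":
                n_async = 1 + int(rng.choice(6, p=np.asarray(params.async_event_dist)))
                counts = _async_trajectory(n_async, rng)
                syms = [Symmetry.EQUAL] + [Symmetry.NOT_APPLICABLE] * (len(counts) - 1)
            else:
                counts, syms, _ = _trajectory(pattern, rng)

            develops = rng.random() < params.blastocyst_prob.get(pattern, 0.0)
            if develops:
                stage_keys: tuple[str, ...] = _STAGE_KEYS
            else:
                # arrest uniformly at a post-cleavage milestone
                arrest = rng.integers(0, 3)
                stage_keys = _STAGE_KEYS[:arrest]

            tempo = math.exp(rng.normal(0.0, params.tempo_sigma)) if params.tempo_sigma else 1.0
            jitter = (rng.normal(0.0, params.jitter_sigma_h, size=len(counts) + len(stage_keys))
                      if params.jitter_sigma_h else np.zeros(len(counts) + len(stage_keys)))
            events = _timed_events(counts, syms, stage_keys, params.timing_template,
                                   tempo, jitter)
            end_h = None if stage_keys else FULL_RECORD_HOURS
            records.append(EmbryoRecord(embryo_id=embryo_id, run_id=run_id,
                                        events=events, end_of_record_h=end_h))
            labels.append(TruthLabel(embryo_id=embryo_id, pattern=pattern,
                                     n_async_events=n_async, blastocyst=bool(develops)))
            idx += 1

    runs = {f"run{r + 1:02d}": RunInfo(run_id=f"run{r + 1:02d}",
                                       n_oocytes=params.run_sizes[r])
            for r in range(params.n_runs)}
    return Cohort(records=records, runs=runs), labels


def make_fixture_cohort(
    composition: Mapping[str, int],
    blastocysts: Mapping[str, int] | None = None,
    async_classes: Mapping[int, int] | None = None,
    n_runs: int = 36,
    template: Mapping[str, float] | None = None,
) -> tuple[Cohort, list[TruthLabel]]:
    """Deterministic, noise-free cohort with exact per-category counts.

    ``composition`` maps pattern to record count; ``blastocysts`` maps
    pattern to the exact number of records of that pattern that reach the
    blastocyst stage (the first so-many records of the category).
    ``async_classes`` optionally fixes how many asynchronous records carry
    1..6 async events (remainder defaults to one event). Records are
    assigned to ``n_runs`` runs round-robin. Classifying the result
    reproduces ``composition`` exactly.
    """
    template = dict(template or DEFAULT_TIMING_TEMPLATE)
    blastocysts = dict(blastocysts or {})
    for pat, n in composition.items():
        if pat not in PATTERNS:
            raise ValueError(f"unknown pattern {pat!r}")
        if n < 0 or blastocysts.get(pat, 0) > n:
            raise ValueError(f"invalid counts for {pat!r}: "
                             f"{blastocysts.get(pat, 0)} outcomes of {n}")

    async_plan: list[int] = []
    if async_classes:
        for k, cnt in sorted(async_classes.items()):
            if not 1 <= k <= 6:
                raise ValueError("async classes are 1..6")
            async_plan.extend([k] * cnt)
    n_async_total = composition.get("asynchronous", 0)
    if len(async_plan) > n_async_total:
        raise ValueError("async_classes exceed the asynchronous count")
    async_plan.extend([1] * (n_async_total - len(async_plan)))

    records: list[EmbryoRecord] = []
    labels: list[TruthLabel] = []
    idx = 0
    for pattern in PATTERNS:
        n = composition.get(pattern, 0)
        n_blast = blastocysts.get(pattern, 0)
        for i in range(n):
            embryo_id = f"fix{idx + 1:05d}"
            run_id = f"run{(idx % n_runs) + 1:02d}"
            n_async = 0
            if pattern == "asynchronous":
                n_async = async_plan[i]
                counts = _async_trajectory(n_async, rng=None)
                syms = [Symmetry.EQUAL] + [Symmetry.NOT_APPLICABLE] * (len(counts) - 1)
            else:
                counts, syms, _ = _trajectory(pattern, rng=_DETERMINISTIC_RNG)
            develops = i < n_blast
            stage_keys = _STAGE_KEYS if develops else ()
            jitter = np.zeros(len(counts) + len(stage_keys))
            events = _timed_events(counts, syms, stage_keys, template, 1.0, jitter)
            end_h = None if stage_keys else FULL_RECORD_HOURS
            records.append(EmbryoRecord(embryo_id=embryo_id, run_id=run_id,
                                        events=events, end_of_record_h=end_h))
            labels.append(TruthLabel(embryo_id=embryo_id, pattern=pattern,
                                     n_async_events=n_async, blastocyst=develops))
            idx += 1
    runs = {f"run{r + 1:02d}": RunInfo(run_id=f"run{r + 1:02d}") for r in range(n_runs)}
    return Cohort(records=records, runs=runs), labels


class _FixedDirectRNG:
    """Degenerate stand-in: fixture 'direct' records always cleave 1 -> 3."""

    def random(self) -> float:
        return 0.0


_DETERMINISTIC_RNG = _FixedDirectRNG()
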
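"""Developmental-timing extraction and rank-based group comparison.

Cleavage timing is indexed by division *round*: round ``i`` ends at the
first attainment of more than ``2**i`` cells, so for a synchronous embryo
the 1st/2nd/3rd cleavage times are the 2-, 4- and 8-cell times, and for an
asynchronous embryo passing 2→3→4 the 2nd-cleavage time is the 3-cell
time (first count above 2). All times are hours post-fertilization.

Group comparisons use the Wilcoxon rank-sum (Mann–Whitney) test and the
Kruskal–Wallis test. Both are implemented here from first principles:
the rank-sum test enumerates the exact permutation distribution of the
rank sum whenever the pooled sample is small, and otherwise uses the
normal approximation with tie and continuity corrections; Kruskal–Wallis
uses the tie-corrected H statistic with a chi-square reference
distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from morphokin.events import EmbryoRecord, Stage, STAGE_ORDER

#: Pooled-sample-size cutoff below which the rank-sum test enumerates the
#: exact permutation distribution (C(12,6) = 924 splits at worst).
EXACT_CUTOFF = 12

#: 16-cell timings rest on few embryos in typical datasets; profiles carry
#: a low-n flag for the 4th round rather than suppressing it.
LOW_N_ROUND = 4


@dataclass(frozen=True)
class KineticProfile:
    """Milestone times (hours post-fertilization) for one embryo.

    ``t_cleave`` maps division round (1-based) to hours; ``t_stage`` maps
    post-cleavage stages to their onset. Missing milestones are absent.
    """

    t_cleave: dict[int, float] = field(default_factory=dict)
    t_stage: dict[Stage, float] = field(default_factory=dict)

    def milestone(self, key: int | Stage) -> float | None:
        if isinstance(key, Stage):
            return self.t_stage.get(key)
        return self.t_cleave.get(key)


@dataclass(frozen=True)
class BoxSummary:
    """Box-and-whisker summary: quartiles plus 10th/95th-percentile whiskers."""

    n: int
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float

    def __post_init__(self) -> None:
        assert self.q25 <= self.median <= self.q75
        assert self.whisker_low <= self.q25 and self.q75 <= self.whisker_high


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    method: str  # "exact_enumeration" | "normal_approx" | "chi2_approx"

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0


def extract_kinetics(record: EmbryoRecord, max_rounds: int = 4) -> KineticProfile:
    """Cleavage-round and stage-onset times for one complete record.

    Round ``i``'s time is the time of the first cleavage event whose
    resulting count exceeds ``2**(i-1)`` cells. Stage onsets are copied
    from stage events; a stage order that contradicts development (e.g.
    blastocyst before morula) raises ``ValueError``.
    """
    t_cleave: dict[int, float] = {}
    for i in range(1, max_rounds + 1):
        threshold = 2 ** (i - 1)
        for ev in record.cleavage_events:
            if ev.cell_count > threshold:
                t_cleave[i] = ev.time_h
                break
    t_stage: dict[Stage, float] = {}
    for ev in record.stage_events:
        t_stage.setdefault(ev.stage, ev.time_h)
    seen = [t_stage[s] for s in STAGE_ORDER if s in t_stage]
    if any(b < a for a, b in zip(seen, seen[1:])):
        raise ValueError(
            f"embryo {record.embryo_id!r}: stage onsets out of developmental order"
        )
    return KineticProfile(t_cleave=t_cleave, t_stage=t_stage)


def summarize_times(values: Sequence[float]) -> BoxSummary:
    """Box summary with linear-interpolation (type-7) percentiles.

    Whiskers are the 10th and 95th percentiles, the convention used for
    timing box plots of cleaved embryos.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("summarize_times: empty input")
    q10, q25, q50, q75, q95 = np.percentile(arr, [10, 25, 50, 75, 95])
    return BoxSummary(
        n=int(arr.size), median=float(q50), q25=float(q25), q75=float(q75),
        whisker_low=float(q10), whisker_high=float(q95),
    )


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _tie_term(pooled: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  exact_cutoff: int = EXACT_CUTOFF) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum test.

    The statistic reported is the Mann–Whitney U of ``x``. With pooled
    ``n <= exact_cutoff`` the p-value is computed by full enumeration of
    all C(n, n_x) assignments of the (mid)ranks, which is exact under the
    permutation null even with ties; otherwise the normal approximation
    with tie correction and a 0.5 continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test: both groups must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w_obs = float(ranks[:nx].sum())
    u_obs = w_obs - nx * (nx + 1) / 2.0
    n = nx + ny

    if n <= exact_cutoff:
        mu = nx * float(ranks.mean())
        d_obs = abs(w_obs - mu)
        hits = total = 0
        for idx in combinations(range(n), nx):
            w = float(ranks[list(idx)].sum())
            total += 1
            if abs(w - mu) >= d_obs - 1e-9:
                hits += 1
        return RankTestResult(statistic=u_obs, p_value=hits / total,
                              method="exact_enumeration")

    mu_u = nx * ny / 2.0
    tie = _tie_term(pooled)
    var_u = nx * ny / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var_u <= 0:  # all values identical
        return RankTestResult(statistic=u_obs, p_value=1.0, method="normal_approx")
    z = (abs(u_obs - mu_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return RankTestResult(statistic=u_obs, p_value=p, method="normal_approx")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> RankTestResult:
    """Tie-corrected Kruskal–Wallis H with chi-square (k-1 df) p-value."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis: need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("kruskal_wallis: every group must be non-empty")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start:start + a.size]
        h += r.sum() ** 2 / a.size
        start += a.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    tie = _tie_term(pooled)
    denom = 1.0 - tie / (n**3 - n)
    if denom <= 0:  # every pooled value identical
        return RankTestResult(statistic=0.0, p_value=1.0, method="chi2_approx")
    h /= denom
    h = max(h, 0.0)
    p = float(sps.chi2.sf(h, df=len(groups) - 1))
    return RankTestResult(statistic=float(h), p_value=p, method="chi2_approx")


def milestone_table(profiles: dict[str, list[KineticProfile]],
                    milestones: Sequence[int | Stage] = (1, 2, 3, Stage.MORULA,
                                                         Stage.EARLY_BLASTOCYST,
                                                         Stage.BLASTOCYST,
                                                         Stage.EXPANDED_BLASTOCYST),
                    ) -> "pd.DataFrame":
    """Per-group box summaries for a set of milestones.

    ``profiles`` maps a group label to the group's kinetic profiles.
    Returns a tidy DataFrame (group, milestone, n, median, q25, q75,
    whisker_low, whisker_high, low_n_flag); milestones with no
    observations in a group are omitted.
    """
    import pandas as pd

    rows = []
    for group, plist in profiles.items():
        for m in milestones:
            vals = [p.milestone(m) for p in plist]
            vals = [v for v in vals if v is not None]
            if not vals:
                continue
            s = summarize_times(vals)
            rows.append({
                "group": group,
                "milestone": m.value if isinstance(m, Stage) else f"cleavage{m}",
                "n": s.n, "median": s.median, "q25": s.q25, "q75": s.q75,
                "whisker_low": s.whisker_low, "whisker_high": s.whisker_high,
                "low_n_flag": (m == LOW_N_ROUND) if isinstance(m, int) else False,
            })
    return pd.DataFrame(rows)
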
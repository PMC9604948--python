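"""Cohort-level statistics for morphokinetic analyses.

Two complementary summaries of the same data are supported, matching how
in-vitro embryo-production experiments are usually reported:

* **run-level proportions** — the IVF run is the experimental replicate;
  per-run percentages are summarized as mean ± SEM, and an
  arcsin(√p) variance-stabilizing transform feeds the ANOVA / t-test
  pathway;
* **pooled contingency analysis** — embryos pooled over runs form a 2×K
  outcome table; pattern–outcome association is quantified by odds
  ratios against a reference level (the saturated one-factor logistic
  model, whose fitted ORs equal the per-level cross-product ratios),
  with Wald 95% CIs on the log-odds scale, a Pearson chi-square over the
  K levels, and a two-sided Fisher exact test for 2×2 tables.

The pattern–outcome association is exposed statsmodels-style:
``CleavageOutcomeModel(...).fit()`` returns a
:class:`CleavageOutcomeResults` carrying estimates, intervals and a
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

Z_95 = 1.959963984540054  # standard-normal 97.5% quantile

GRADE_LEVELS = ("good", "fair", "poor")


def arcsine_sqrt(p: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilizing arcsin(√p) transform for proportions in [0, 1]."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# run-level proportions

@dataclass(frozen=True)
class CohortSummary:
    """Run-level percentage summary plus pooled counts.

    ``mean_pct``/``sem_pct`` are on the raw percentage scale; the
    arcsine-transformed per-run values (radians) are kept alongside for
    the ANOVA/t pathway.
    """

    per_run_pct: dict[str, float]
    mean_pct: float
    sem_pct: float
    pooled_numer: int
    pooled_denom: int
    transform_used: str = "none"
    per_run_arcsine: dict[str, float] = field(default_factory=dict)

    @property
    def pooled_pct(self) -> float:
        return 100.0 * self.pooled_numer / self.pooled_denom


def run_level_summary(
    df: pd.DataFrame,
    numerator: Callable[[pd.Series], bool] | pd.Series,
    denominator: Callable[[pd.Series], bool] | pd.Series | None = None,
    run_col: str = "run_id",
) -> CohortSummary:
    """Mean ± SEM of per-run percentages of a per-embryo predicate.

    ``df`` has one row per embryo with a ``run_col`` column. ``numerator``
    and ``denominator`` are boolean Series aligned to ``df`` or callables
    applied row-wise; ``denominator=None`` means all rows. Runs whose
    denominator is empty are excluded (with a warning via ``warnings``).
    SEM = sd / √n over contributing runs (ddof = 1).
    """
    import warnings

    def as_mask(pred) -> pd.Series:
        if pred is None:
            return pd.Series(True, index=df.index)
        if isinstance(pred, pd.Series):
            return pred.astype(bool)
        return df.apply(pred, axis=1).astype(bool)

    num = as_mask(numerator)
    den = as_mask(denominator)
    if (num & ~den).any():
        raise ValueError("numerator rows must be a subset of denominator rows")

    per_run: dict[str, float] = {}
    skipped = []
    for run_id, idx in df.groupby(run_col).groups.items():
        d = int(den.loc[idx].sum())
        if d == 0:
            skipped.append(run_id)
            continue
        per_run[str(run_id)] = 100.0 * int(num.loc[idx].sum()) / d
    if skipped:
        warnings.warn(f"run_level_summary: excluded runs with empty denominator: {skipped}")
    if not per_run:
        raise ValueError("run_level_summary: no run has a non-empty denominator")

    vals = np.array(list(per_run.values()))
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
    return CohortSummary(
        per_run_pct=per_run,
        mean_pct=mean,
        sem_pct=sem,
        pooled_numer=int(num[den].sum()),
        pooled_denom=int(den.sum()),
        transform_used="arcsine_sqrt",
        per_run_arcsine={k: arcsine_sqrt(v / 100.0) for k, v in per_run.items()},
    )


# ---------------------------------------------------------------------------
# pattern-outcome association (Model / Results)

@dataclass(frozen=True)
class ContingencyResult:
    """2×K counts with per-level odds ratios against a reference level."""

    table: pd.DataFrame  # index: [success, failure]; columns: levels
    reference: str
    odds_ratios: dict[str, tuple[float, float, float]]  # level -> (OR, lo, hi)
    chi2: float
    chi2_p: float
    fisher_p: float | None = None
    continuity_applied: tuple[str, ...] = ()


class CleavageOutcomeModel:
    """Association between a categorical exposure and a binary outcome.

    The model is the saturated one-factor logistic regression
    ``logit P(outcome) = α + β_level``; its fitted odds ratios equal the
    per-level 2×2 cross-product ratios against the reference level, which
    is how :meth:`fit` computes them. Zero cells are handled by the
    Haldane–Anscombe correction (+0.5 to all four cells of the affected
    comparison only) and flagged.

    Parameters
    ----------
    successes, totals
        Mapping from level label to outcome count and group size.
    reference
        Level against which odds ratios are normalized.
    """

    def __init__(self, successes: Mapping[str, int], totals: Mapping[str, int],
                 reference: str) -> None:
        if reference not in successes:
            raise ValueError(f"reference level {reference!r} not present")
        if set(successes) != set(totals):
            raise ValueError("successes and totals must cover the same levels")
        for lv in successes:
            s, t = int(successes[lv]), int(totals[lv])
            if s < 0 or t < 0 or s > t:
                raise ValueError(f"invalid counts for level {lv!r}: {s}/{t}")
        if totals[reference] == 0:
            raise ValueError("reference level has no observations")
        self.levels = list(successes)
        self.successes = {lv: int(successes[lv]) for lv in self.levels}
        self.totals = {lv: int(totals[lv]) for lv in self.levels}
        self.reference = reference

    @classmethod
    def from_table(cls, table: pd.DataFrame, reference: str) -> "CleavageOutcomeModel":
        """From a 2×K table with rows [success, failure] and level columns."""
        if table.shape[0] != 2:
            raise ValueError("table must have exactly two rows (success, failure)")
        succ = table.iloc[0]
        tot = table.iloc[0] + table.iloc[1]
        return cls(succ.to_dict(), tot.to_dict(), reference)

    @classmethod
    def from_calls(cls, calls: pd.DataFrame, outcome: pd.Series,
                   group_col: str = "category", reference: str = "synchronous",
                   levels: Sequence[str] | None = None) -> "CleavageOutcomeModel":
        """From a per-embryo call table plus an aligned boolean outcome."""
        grp = calls[group_col]
        levels = list(levels) if levels is not None else sorted(grp.unique())
        succ = {lv: int(outcome[grp == lv].sum()) for lv in levels}
        tot = {lv: int((grp == lv).sum()) for lv in levels}
        return cls(succ, tot, reference)

    def fit(self) -> "CleavageOutcomeResults":
        ref_s = self.successes[self.reference]
        ref_f = self.totals[self.reference] - ref_s
        ors: dict[str, tuple[float, float, float]] = {}
        log_or: dict[str, float] = {}
        se: dict[str, float] = {}
        wald_p: dict[str, float] = {}
        corrected: list[str] = []
        for lv in self.levels:
            if lv == self.reference:
                ors[lv] = (1.0, 1.0, 1.0)
                log_or[lv], se[lv], wald_p[lv] = 0.0, 0.0, 1.0
                continue
            a = self.successes[lv]
            b = self.totals[lv] - a
            c, d = ref_s, ref_f
            if min(a, b, c, d) == 0:
                a, b, c, d = (v + 0.5 for v in (a, b, c, d))
                corrected.append(lv)
            o = (a * d) / (b * c)
            s = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            lo, hi = math.exp(math.log(o) - Z_95 * s), math.exp(math.log(o) + Z_95 * s)
            ors[lv] = (o, lo, hi)
            log_or[lv], se[lv] = math.log(o), s
            wald_p[lv] = float(2 * sps.norm.sf(abs(math.log(o)) / s))

        table = pd.DataFrame(
            {
                lv: [self.successes[lv], self.totals[lv] - self.successes[lv]]
                for lv in self.levels
            },
            index=["success", "failure"],
        )
        chi2, chi2_p = _pearson_chi2(table.to_numpy())
        fisher_p = None
        if len(self.levels) == 2:
            fisher_p = float(sps.fisher_exact(table.to_numpy())[1])
        return CleavageOutcomeResults(
            model=self, table=table, odds_ratios=ors, log_odds=log_or,
            bse=se, wald_p=wald_p, chi2=chi2, chi2_p=chi2_p,
            fisher_p=fisher_p, continuity_applied=tuple(corrected),
        )


@dataclass(frozen=True)
class CleavageOutcomeResults:
    """Fitted pattern-outcome association.

    ``odds_ratios[level] = (OR, ci_low, ci_high)`` against the model's
    reference level, Wald 95% intervals on the log-odds scale.
    """

    model: CleavageOutcomeModel
    table: pd.DataFrame
    odds_ratios: dict[str, tuple[float, float, float]]
    log_odds: dict[str, float]
    bse: dict[str, float]
    wald_p: dict[str, float]
    chi2: float
    chi2_p: float
    fisher_p: float | None
    continuity_applied: tuple[str, ...]

    def conf_int(self, level: str) -> tuple[float, float]:
        _, lo, hi = self.odds_ratios[level]
        return lo, hi

    def summary(self) -> str:
        lines = [
            "Pattern-outcome association (saturated logistic / cross-product ORs)",
            f"reference level: {self.model.reference}",
            f"chi-square ({len(self.model.levels) - 1} df): "
            f"{self.chi2:.4f}, p = {self.chi2_p:.4g}",
        ]
        if self.fisher_p is not None:
            lines.append(f"Fisher exact (two-sided): p = {self.fisher_p:.4g}")
        lines.append(f"{'level':<18}{'n':>7}{'events':>8}{'OR':>9}{'95% CI':>18}{'p':>10}")
        for lv in self.model.levels:
            o, lo, hi = self.odds_ratios[lv]
            n, s = self.model.totals[lv], self.model.successes[lv]
            flag = " (HA+0.5)" if lv in self.continuity_applied else ""
            if lv == self.model.reference:
                lines.append(f"{lv:<18}{n:>7}{s:>8}{'1 (ref)':>9}{'':>18}{'':>10}")
            else:
                lines.append(
                    f"{lv:<18}{n:>7}{s:>8}{o:>9.3f}"
                    f"{f'[{lo:.3f}, {hi:.3f}]':>18}{self.wald_p[lv]:>10.3g}{flag}"
                )
        return "\n".join(lines)

    def as_contingency_result(self) -> ContingencyResult:
        return ContingencyResult(
            table=self.table, reference=self.model.reference,
            odds_ratios=dict(self.odds_ratios), chi2=self.chi2,
            chi2_p=self.chi2_p, fisher_p=self.fisher_p,
            continuity_applied=self.continuity_applied,
        )


def contingency_analysis(counts: pd.DataFrame | np.ndarray, reference: str,
                         levels: Sequence[str] | None = None) -> ContingencyResult:
    """Functional wrapper over :class:`CleavageOutcomeModel`.

    ``counts`` is a 2×K array or DataFrame (rows: success, failure).
    """
    if isinstance(counts, pd.DataFrame):
        table = counts
    else:
        arr = np.asarray(counts)
        if levels is None:
            levels = [f"level{i}" for i in range(arr.shape[1])]
        table = pd.DataFrame(arr, index=["success", "failure"], columns=list(levels))
    if np.any(table.to_numpy() < 0):
        raise ValueError("counts must be non-negative")
    return CleavageOutcomeModel.from_table(table, reference).fit().as_contingency_result()


def _pearson_chi2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square without continuity correction; empty rows/columns
    are dropped from the degrees of freedom."""
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 0.0, 1.0
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    chi2 = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return chi2, float(sps.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# grade distributions

def grade_distribution_test(grade_counts: pd.DataFrame) -> dict:
    """Compare morphology-grade distributions between groups.

    ``grade_counts``: rows = group labels, columns ⊆ {good, fair, poor},
    integer counts. Returns the overall Pearson chi-square over all groups
    and grades, plus — for every pair of groups and every grade — a
    two-sided Fisher exact test on the grade-vs-rest 2×2 collapse.
    Groups with no graded embryos are excluded with a warning.
    """
    import warnings

    df = grade_counts.reindex(columns=[g for g in GRADE_LEVELS if g in grade_counts.columns])
    empty = df.index[df.sum(axis=1) == 0].tolist()
    if empty:
        warnings.warn(f"grade_distribution_test: excluded group(s) with no grades: {empty}")
        df = df.drop(index=empty)
    if df.shape[0] < 2:
        raise ValueError("grade_distribution_test: need at least two non-empty groups")

    chi2, chi2_p = _pearson_chi2(df.to_numpy())
    pairwise = []
    groups = list(df.index)
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            for grade in df.columns:
                a = int(df.loc[ga, grade]); b = int(df.loc[ga].sum()) - a
                c = int(df.loc[gb, grade]); d = int(df.loc[gb].sum()) - c
                p = float(sps.fisher_exact([[a, b], [c, d]])[1])
                pairwise.append({"group_a": ga, "group_b": gb, "grade": grade,
                                 "fisher_p": p})
    return {"chi2": chi2, "chi2_p": chi2_p,
            "pairwise": pd.DataFrame(pairwise), "table": df}


# ---------------------------------------------------------------------------
# correlation, ANOVA

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int

    def __post_init__(self) -> None:
        assert -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation; constant input is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(r=min(1.0, max(-1.0, r)), n=int(x.size))


def anova_f(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F and p (between/within mean squares).

    Callers comparing run-level proportions should pass arcsine-transformed
    values. When both between- and within-group variance are zero, F is
    defined as 0 (p = 1).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("anova_f: need at least two groups")
    k = len(arrays)
    n = sum(a.size for a in arrays)
    if n <= k:
        raise ValueError("anova_f: need more observations than groups")
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    if msw == 0:
        if msb == 0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = float(msb / msw)
    return f, float(sps.f.sf(f, k - 1, n - k))


def pairwise_t(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Unadjusted pairwise two-sample Student's t tests (equal variances).

    Companion to :func:`anova_f` for post-hoc pair comparisons; the
    studentized-range (Tukey–Kramer) procedure is deliberately not
    provided.
    """
    labels = list(groups)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            t, p = sps.ttest_ind(np.asarray(groups[a], float),
                                 np.asarray(groups[b], float))
            rows.append({"group_a": a, "group_b": b, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)
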
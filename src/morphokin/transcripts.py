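"""Differential-expression list operations and qPCR relative quantification.

Works on gene-level summary tables (id, signed fold change, p, FDR q) —
the standard output of array or RNA-seq differential testing — rather
than raw intensities. Fold changes use the signed-magnitude convention:
+2.5 means 2.5-fold higher in group A, −2.5 means 2.5-fold higher in
group B, and |fold| >= 1 always. Significance gates are strict:
|fold| > 2, p < 0.05 and q < 0.05.

qPCR quantification follows the 2^-ddCt method with dual reference
genes; "geometric mean of the reference genes" in expression space is
the arithmetic mean of their Ct values, which is how the normalizer is
computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Strict significance gates for calling a gene differentially expressed.
FOLD_GATE = 2.0
P_GATE = 0.05
Q_GATE = 0.05

#: Cap for -log10(p) when p underflows to 0 in volcano coordinates.
VOLCANO_Y_CAP = 300.0


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression summary."""

    gene_id: str
    fold_change: float  # signed magnitude, |fold| >= 1
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if abs(self.fold_change) < 1.0:
            raise ValueError(
                f"{self.gene_id}: |fold_change| must be >= 1 under the "
                f"signed-magnitude convention, got {self.fold_change}"
            )
        if not (0.0 <= self.p_value <= 1.0 and 0.0 <= self.q_value <= 1.0):
            raise ValueError(f"{self.gene_id}: p and q must lie in [0, 1]")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_filter(records: Iterable[DEGRecord],
              fold_gate: float = FOLD_GATE, p_gate: float = P_GATE,
              q_gate: float = Q_GATE) -> list[DEGRecord]:
    """Retain genes with |fold| > fold_gate, p < p_gate and q < q_gate
    (all strict)."""
    return [
        r for r in records
        if abs(r.fold_change) > fold_gate and r.p_value < p_gate and r.q_value < q_gate
    ]


def direction_tally(records: Iterable[DEGRecord]) -> tuple[int, int]:
    """(n_up, n_down) by fold-change sign; up = higher in group A."""
    n_up = n_down = 0
    for r in records:
        if r.fold_change > 0:
            n_up += 1
        else:
            n_down += 1
    return n_up, n_down


def venn_partition(list_a: Iterable[str], list_b: Iterable[str]) -> tuple[set[str], set[str], set[str]]:
    """(only_a, only_b, shared) exact set partition of two gene lists."""
    a, b = set(list_a), set(list_b)
    return a - b, b - a, a & b


def volcano_coords(records: Iterable[DEGRecord]) -> pd.DataFrame:
    """Signed log2 fold change vs. -log10 p per gene.

    Columns: gene_id, x (sign(fold) * log2|fold|), y (-log10 p, capped at
    ``VOLCANO_Y_CAP`` when p underflows), passes (de_filter gates).
    Threshold guide lines sit at x = ±1 (fold 2) and y = -log10(0.05).
    """
    rows = []
    for r in records:
        x = math.copysign(math.log2(abs(r.fold_change)), r.fold_change)
        y = VOLCANO_Y_CAP if r.p_value == 0 else min(-math.log10(r.p_value), VOLCANO_Y_CAP)
        passes = abs(r.fold_change) > FOLD_GATE and r.p_value < P_GATE and r.q_value < Q_GATE
        rows.append({"gene_id": r.gene_id, "x": x, "y": y, "passes": passes})
    return pd.DataFrame(rows, columns=["gene_id", "x", "y", "passes"])


# ---------------------------------------------------------------------------
# DEG table I/O

_DEG_COLUMNS = ["gene_id", "fold_change", "p_value", "q_value"]


def read_deg_table(path: str | Path) -> list[DEGRecord]:
    """Read a TSV with columns gene_id, fold_change, p_value, q_value."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_DEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        DEGRecord(str(r.gene_id), float(r.fold_change), float(r.p_value), float(r.q_value))
        for r in df.itertuples()
    ]


def write_deg_table(records: Iterable[DEGRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.gene_id, r.fold_change, r.p_value, r.q_value) for r in records],
        columns=_DEG_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# qPCR 2^-ddCt

@dataclass(frozen=True)
class CtTable:
    """Tidy qPCR Ct observations.

    ``data`` columns: sample_id, group (test/control), gene, role
    (target/reference), ct (cycles, > 0). Every sample needs at least one
    reference-gene observation.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "gene", "role", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CtTable missing columns {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        bad_role = set(self.data["role"]) - {"target", "reference"}
        if bad_role:
            raise ValueError(f"unknown role(s) {sorted(bad_role)}")
        bad_group = set(self.data["group"]) - {"test", "control"}
        if bad_group:
            raise ValueError(f"unknown group(s) {sorted(bad_group)}")
        refs = self.data[self.data["role"] == "reference"]
        samples = set(self.data["sample_id"])
        without_ref = samples - set(refs["sample_id"])
        if without_ref:
            raise ValueError(f"sample(s) without reference gene: {sorted(without_ref)}")


def read_ct_table(path: str | Path) -> CtTable:
    """Read a tidy TSV Ct table (sample_id, group, gene, role, ct)."""
    return CtTable(pd.read_csv(path, sep="\t"))


def ddct_fold_change(ct: CtTable) -> pd.DataFrame:
    """Per-target 2^-ddCt fold change of test vs. control.

    Per sample, dCt = Ct_target − mean(reference Cts) (the arithmetic
    mean in Ct space equals the geometric mean in expression space);
    ddCt = mean dCt(test) − mean dCt(control); fold = 2^−ddCt with the
    control normalized to 1. A two-sample t-test on the per-sample dCt
    values gives the p-value.

    Returns one row per target gene: gene, fold_change (test vs control),
    ddct, p_value, n_test, n_control.
    """
    df = ct.data
    if not {"test", "control"} <= set(df["group"]):
        raise ValueError("both test and control groups must be represented")
    ref_mean = (
        df[df["role"] == "reference"].groupby("sample_id")["ct"].mean()
    )
    targets = df[df["role"] == "target"].copy()
    if targets.empty:
        raise ValueError("no target-gene observations")
    # replicate wells of a (sample, gene) pair average in Ct space first
    per_sample = targets.groupby(["gene", "sample_id", "group"], as_index=False)["ct"].mean()
    per_sample["dct"] = per_sample["ct"] - per_sample["sample_id"].map(ref_mean).to_numpy()

    rows = []
    for gene, sub in per_sample.groupby("gene"):
        d_test = sub.loc[sub["group"] == "test", "dct"].to_numpy()
        d_ctrl = sub.loc[sub["group"] == "control", "dct"].to_numpy()
        if d_test.size == 0 or d_ctrl.size == 0:
            raise ValueError(f"gene {gene!r}: both groups must be represented")
        ddct = float(d_test.mean() - d_ctrl.mean())
        if d_test.size > 1 and d_ctrl.size > 1:
            p = float(sps.ttest_ind(d_test, d_ctrl)[1])
        else:
            p = float("nan")
        rows.append({"gene": gene, "fold_change": 2.0 ** (-ddct), "ddct": ddct,
                     "p_value": p, "n_test": int(d_test.size), "n_control": int(d_ctrl.size)})
    return pd.DataFrame(rows, columns=["gene", "fold_change", "ddct", "p_value",
                                       "n_test", "n_control"])


# ---------------------------------------------------------------------------
# synthetic DEG tables

def simulate_deg_table(
    n_genes: int = 24_415,
    frac_up: float = 0.015,
    frac_down: float = 0.025,
    effect_log2: float = 2.0,
    effect_spread: float = 0.5,
    planted_p_log10_range: tuple[float, float] = (2.5, 8.0),
    seed: int | np.random.Generator = 0,
) -> tuple[list[DEGRecord], np.ndarray]:
    """Synthetic gene-level DE table with planted truth.

    Null genes draw p ~ Uniform(0, 1) and |fold| near 1 (lognormal around
    0 on the log2 scale). Planted genes draw |log2 fold| ~ effect_log2 +
    |N(0, effect_spread)| (so |fold| exceeds the gate) and log-uniform p,
    p = 10^-U(planted_p_log10_range) — a decreasing density concentrated
    near zero, as produced by genuinely perturbed genes. q is computed by
    BH over the whole table. Returns the records plus a truth vector
    (+1 up, −1 down, 0 null).

    The default table size matches a standard bovine expression array
    (24,415 displayed genes).
    """
    if frac_up < 0 or frac_down < 0 or frac_up + frac_down > 1:
        raise ValueError("planted fractions must be non-negative and sum to <= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_up = int(round(frac_up * n_genes))
    n_down = int(round(frac_down * n_genes))
    truth = np.zeros(n_genes, dtype=int)
    truth[:n_up] = 1
    truth[n_up:n_up + n_down] = -1
    rng.shuffle(truth)

    log2fold = np.zeros(n_genes)
    p = np.empty(n_genes)
    null = truth == 0
    log2fold[null] = rng.normal(0.0, 0.2, size=null.sum())
    p[null] = rng.uniform(0.0, 1.0, size=null.sum())
    planted = ~null
    mag = effect_log2 + np.abs(rng.normal(0.0, effect_spread, size=planted.sum()))
    log2fold[planted] = np.sign(truth[planted]) * mag
    lo, hi = planted_p_log10_range
    p[planted] = 10.0 ** -rng.uniform(lo, hi, size=planted.sum())

    q = bh_adjust(p)
    fold = np.sign(log2fold) * (2.0 ** np.abs(log2fold))
    fold[fold == 0] = 1.0
    records = [
        DEGRecord(f"gene{i + 1:06d}", float(fold[i]), float(p[i]), float(q[i]))
        for i in range(n_genes)
    ]
    return records, truth
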
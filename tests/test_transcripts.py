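"""DE-list gates, BH adjustment, Venn partition, volcano, 2^-ddCt."""

import math


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from morphokin.transcripts import (
    CtTable,
    DEGRecord,
    bh_adjust,
    ddct_fold_change,
    de_filter,
    direction_tally,
    read_ct_table,
    read_deg_table,
    simulate_deg_table,
    venn_partition,
    volcano_coords,
    write_deg_table,
)


def brute_force_bh(p):
    """Step-up definition applied literally: q_(i) = min_{j>=i} p_(j)*m/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        q[i] = min(
            min(p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)), 1.0
        )
    return q


def test_bh_worked_example():
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_single_and_cap():
    assert bh_adjust([0.5]) == pytest.approx([0.5])
    p = list(np.linspace(0.01, 1.0, 100))
    assert bh_adjust(p)[-1] == pytest.approx(1.0)


def test_bh_rejects_bad_p():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(max_examples=200, deadline=None)
@given(st.lists(st.integers(0, 100).map(lambda k: k / 100), min_size=1, max_size=8))
def test_bh_equals_brute_force_on_grid(p):
    assert list(bh_adjust(p)) == pytest.approx(brute_force_bh(p))


def test_bh_preserves_input_order():
    p = [0.9, 0.001, 0.5, 0.02]
    q = bh_adjust(p)
    # smallest p keeps the smallest q at the same position
    assert int(np.argmin(q)) == 1


# ---------------------------------------------------------------------------
# DE gates

def rec(fold, p, q, gid="g"):
    return DEGRecord(gene_id=gid, fold_change=fold, p_value=p, q_value=q)


@pytest.mark.parametrize(
    "fold,p,q,kept",
    [
        (2.14, 0.0004, 0.01, True),    # passes all three strict gates
        (1.9, 1e-6, 1e-5, False),      # fold-change gate
        (-2.5, 0.01, 0.02, True),      # magnitude rule is symmetric
        (2.0, 0.0001, 0.0001, False),  # strict: fold must exceed 2
        (3.0, 0.05, 0.01, False),      # strict: p must be below 0.05
        (3.0, 0.01, 0.05, False),      # strict: q must be below 0.05
    ],
)
def test_de_filter_gates(fold, p, q, kept):
    assert (len(de_filter([rec(fold, p, q)])) == 1) is kept


def test_de_filter_monotone_in_thresholds():
    rng = np.random.default_rng(0)
    records = [rec(float(f), float(p), float(q), f"g{i}")
               for i, (f, p, q) in enumerate(zip(
                   rng.uniform(1, 5, 200) * rng.choice([-1, 1], 200),
                   rng.uniform(0, 0.2, 200), rng.uniform(0, 0.2, 200)))]
    base = {r.gene_id for r in de_filter(records)}
    relaxed = {r.gene_id for r in de_filter(records, fold_gate=1.5, p_gate=0.1,
                                            q_gate=0.1)}
    assert base <= relaxed


def test_direction_tally_totals():
    records = ([rec(2.5, 0.01, 0.01, f"u{i}") for i in range(330)]
               + [rec(-2.5, 0.01, 0.01, f"d{i}") for i in range(565)])
    assert direction_tally(records) == (330, 565)
    assert direction_tally([]) == (0, 0)


# ---------------------------------------------------------------------------
# Venn

def test_venn_study_scale_partition():
    a = {f"g{i}" for i in range(895)}
    b = {f"g{i}" for i in range(435, 435 + 643)}  # overlap = 895 - 435 = 460
    only_a, only_b, shared = venn_partition(a, b)
    assert (len(only_a), len(only_b), len(shared)) == (435, 183, 460)


def test_venn_disjoint_and_identical():
    assert tuple(map(len, venn_partition({"a", "b"}, {"c"}))) == (2, 1, 0)
    assert tuple(map(len, venn_partition({"a", "b"}, {"a", "b"}))) == (0, 0, 2)


@settings(max_examples=100, deadline=None)
@given(st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50)))
def test_venn_inclusion_exclusion(a, b):
    only_a, only_b, shared = venn_partition(map(str, a), map(str, b))
    assert len(only_a) == len(a) - len(a & b)
    assert len(only_b) == len(b) - len(a & b)
    assert len(only_a) + len(only_b) + len(shared) == len(a | b)


# ---------------------------------------------------------------------------
# volcano

def test_volcano_exact_logs():
    df = volcano_coords([rec(2.0, 0.01, 0.01, "a"), rec(-4.0, 0.1, 0.2, "b"),
                         rec(2.14, 0.05, 0.1, "c")])
    assert df.loc[0, ["x", "y"]].tolist() == pytest.approx([1.0, 2.0])
    assert df.loc[1, ["x", "y"]].tolist() == pytest.approx([-2.0, 1.0])
    assert df.loc[2, "x"] == pytest.approx(math.log2(2.14))


def test_volcano_p_zero_capped():
    df = volcano_coords([rec(2.0, 0.0, 0.0)])
    assert df.loc[0, "y"] == 300.0


# ---------------------------------------------------------------------------
# ddCt

def ct_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "role", "ct"])


def test_ddct_identity_is_exactly_one():
    rows = []
    for sid, grp in (("s1", "test"), ("s2", "control")):
        rows += [(sid, grp, "HSPA1A", "target", 24.0),
                 (sid, grp, "YWHAZ", "reference", 20.0),
                 (sid, grp, "SDHA", "reference", 22.0)]
    out = ddct_fold_change(CtTable(ct_frame(rows)))
    assert out.loc[0, "fold_change"] == 1.0


def test_ddct_one_cycle_halves_expression():
    rows = [("s1", "test", "g", "target", 25.0),
            ("s1", "test", "r1", "reference", 20.0),
            ("s2", "control", "g", "target", 24.0),
            ("s2", "control", "r1", "reference", 20.0)]
    out = ddct_fold_change(CtTable(ct_frame(rows)))
    assert out.loc[0, "fold_change"] == pytest.approx(0.5)


def test_ddct_dual_reference_hand_computed():
    """test: target 24, refs 20/22 -> dCt 3; control: target 23 -> dCt 2;
    ddCt = 1 -> fold 0.5."""
    rows = [("s1", "test", "g", "target", 24.0),
            ("s1", "test", "YWHAZ", "reference", 20.0),
            ("s1", "test", "SDHA", "reference", 22.0),
            ("s2", "control", "g", "target", 23.0),
            ("s2", "control", "YWHAZ", "reference", 20.0),
            ("s2", "control", "SDHA", "reference", 22.0)]
    out = ddct_fold_change(CtTable(ct_frame(rows)))
    assert out.loc[0, "ddct"] == pytest.approx(1.0)
    assert out.loc[0, "fold_change"] == pytest.approx(0.5)


def test_ddct_missing_reference_errors():
    rows = [("s1", "test", "g", "target", 24.0),
            ("s2", "control", "g", "target", 23.0),
            ("s2", "control", "r", "reference", 20.0)]
    with pytest.raises(ValueError, match="reference"):
        CtTable(ct_frame(rows))


def test_ddct_replicate_wells_average_in_ct_space():
    rows = [("s1", "test", "g", "target", 24.0),
            ("s1", "test", "g", "target", 26.0),     # duplicate well
            ("s1", "test", "r", "reference", 20.0),
            ("s2", "control", "g", "target", 24.0),
            ("s2", "control", "r", "reference", 20.0)]
    out = ddct_fold_change(CtTable(ct_frame(rows)))
    assert out.loc[0, "ddct"] == pytest.approx(1.0)  # mean Ct 25 vs 24


def test_ddct_groupwise_p_value_from_replicates():
    rng = np.random.default_rng(1)
    rows = []
    for i in range(4):
        rows += [(f"t{i}", "test", "g", "target", 25.0 + rng.normal(0, 0.05)),
                 (f"t{i}", "test", "r", "reference", 20.0)]
        rows += [(f"c{i}", "control", "g", "target", 24.0 + rng.normal(0, 0.05)),
                 (f"c{i}", "control", "r", "reference", 20.0)]
    out = ddct_fold_change(CtTable(ct_frame(rows)))
    assert out.loc[0, "p_value"] < 0.01
    assert out.loc[0, "n_test"] == out.loc[0, "n_control"] == 4


# ---------------------------------------------------------------------------
# synthetic DEG tables

def test_simulated_table_shape_and_determinism():
    recs1, truth1 = simulate_deg_table(n_genes=500, frac_up=0.1, frac_down=0.1, seed=3)
    recs2, truth2 = simulate_deg_table(n_genes=500, frac_up=0.1, frac_down=0.1, seed=3)
    assert len(recs1) == 500
    assert recs1 == recs2 and (truth1 == truth2).all()
    assert (truth1 == 1).sum() == 50 and (truth1 == -1).sum() == 50


def test_simulated_planted_genes_detectable():
    recs, truth = simulate_deg_table(n_genes=2000, frac_up=0.05, frac_down=0.05,
                                     seed=4)
    kept = {r.gene_id for r in de_filter(recs)}
    planted = {r.gene_id for r, t in zip(recs, truth) if t != 0}
    # most retained genes are planted (FDR gate) and a decent share of
    # planted genes are recovered
    assert len(kept & planted) / max(len(kept), 1) > 0.9
    assert len(kept & planted) / len(planted) > 0.5


def test_invalid_fractions_rejected():
    with pytest.raises(ValueError):
        simulate_deg_table(n_genes=10, frac_up=0.7, frac_down=0.6)


def test_null_tables_respect_fdr_gate():
    """With no planted genes, tables with any q < 0.05 discovery are rare:
    empirical rate <= 0.075 over 200 seeds (BH family-wise control at the
    table level under independence)."""
    n_bad = 0
    for seed in range(200):
        recs, _ = simulate_deg_table(n_genes=400, frac_up=0.0, frac_down=0.0,
                                     seed=seed)
        if any(r.q_value < 0.05 for r in recs):
            n_bad += 1
    assert n_bad / 200 <= 0.075


# ---------------------------------------------------------------------------
# I/O

def test_deg_table_round_trip(tmp_path):
    recs, _ = simulate_deg_table(n_genes=50, frac_up=0.1, frac_down=0.1, seed=6)
    path = tmp_path / "degs.tsv"
    write_deg_table(recs, path)
    back = read_deg_table(path)
    assert [r.gene_id for r in back] == [r.gene_id for r in recs]
    assert np.allclose([r.fold_change for r in back], [r.fold_change for r in recs])


def test_ct_table_io_and_validation(tmp_path):
    path = tmp_path / "ct.tsv"
    ct_frame([("s1", "test", "g", "target", 24.0),
              ("s1", "test", "r", "reference", 20.0),
              ("s2", "control", "g", "target", 24.0),
              ("s2", "control", "r", "reference", 20.0)]).to_csv(
        path, sep="\t", index=False)
    ct = read_ct_table(path)
    assert len(ct.data) == 4
    with pytest.raises(ValueError, match="positive"):
        CtTable(ct_frame([("s1", "test", "g", "target", -1.0),
                          ("s1", "test", "r", "reference", 20.0)]))
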
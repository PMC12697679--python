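import math
from math import comb

import numpy as np
import pytest

from racoon.exceptions import DataError
from racoon.shift_analysis import (conditional_jsd, fisher_bh, kendall_tau_stability,
                                   label_shift, mutual_information,
                                   protein_level_groups, shift_scan)


def jsd_oracle(a, b, bins, eps):
    """Direct histogram + divergence computation, independent of scipy."""
    def hist(x):
        h = np.zeros(bins)
        for v in x:
            h[min(int(v * bins), bins - 1)] += 1
        p = h / h.sum() + eps
        return p / p.sum()

    p, q = hist(a), hist(b)
    m = (p + q) / 2

    def kl(u, v):
        return sum(ui * math.log(ui / vi) for ui, vi in zip(u, v) if ui > 0)

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


class TestConditionalJSD:
    def test_identical_samples_give_zero(self):
        x = np.tile(np.linspace(0.1, 0.9, 50), 2)
        mask = np.repeat([True, False], 50)
        labels = np.tile([1.0, 0.0], 50)
        assert conditional_jsd(x, mask, labels) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_supports_approach_maximum(self):
        rng = np.random.default_rng(0)
        n = 2000
        mask = np.repeat([True, False], n)
        labels = np.tile([1.0, 0.0], n)
        x = np.where(mask, rng.uniform(0.0, 0.3, 2 * n), rng.uniform(0.7, 1.0, 2 * n))
        div = conditional_jsd(x, mask, labels)
        # smoothing keeps the estimate a hair below the theoretical maximum
        assert div == pytest.approx(2 * math.log(2), rel=5e-3)
        assert div < 2 * math.log(2)

    def test_eight_point_toy_matches_oracle(self):
        x = np.array([0.05, 0.15, 0.35, 0.75, 0.10, 0.55, 0.60, 0.95])
        mask = np.array([True, True, True, True, False, False, False, False])
        labels = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        eps = math.exp(-12)
        expected = sum(
            jsd_oracle(x[mask & (labels == l)], x[~mask & (labels == l)], 100, eps)
            for l in (1.0, 0.0))
        assert conditional_jsd(x, mask, labels) == pytest.approx(expected, rel=1e-10)

    def test_symmetric_in_attribute_relabeling(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 400)
        mask = rng.random(400) < 0.4
        labels = (rng.random(400) < 0.5).astype(float)
        assert conditional_jsd(x, mask, labels) == pytest.approx(
            conditional_jsd(x, ~mask, labels), abs=1e-12)

    def test_empty_cell_is_named(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        mask = np.array([True, True, False, False])
        labels = np.array([1.0, 1.0, 1.0, 0.0])
        with pytest.raises(DataError, match="benign"):
            conditional_jsd(x, mask, labels)

    def test_divergence_decreases_toward_equality(self):
        # interpolate one generating distribution toward the other; the
        # divergence should fall monotonically over the grid
        rng = np.random.default_rng(2)
        n = 20_000
        base = rng.beta(2, 5, n)
        other = rng.beta(5, 2, n)
        labels = np.tile([1.0, 0.0], n)[:n]
        divs = []
        for t in np.linspace(0, 1, 5):
            a = (1 - t) * other + t * base  # t=1 -> same distribution as base
            x = np.concatenate([a, base])
            mask = np.repeat([True, False], n)
            divs.append(conditional_jsd(x, mask, np.tile(labels, 2)))
        assert all(d1 > d2 for d1, d2 in zip(divs, divs[1:]))
        assert divs[-1] < 0.01

    def test_shifting_attribute_outranks_null_attribute(self, synthetic_table):
        t = synthetic_table
        y = t.labels
        from racoon.shift_analysis import minmax_to_unit
        x = minmax_to_unit(t.scores)
        d_shift = conditional_jsd(x, t.attribute_values("disordered") == 1.0, y)
        d_null = conditional_jsd(x, t.attribute_values("long_protein") == 1.0, y)
        assert d_shift > d_null


class TestLabelShift:
    def test_full_mask_gives_zero(self):
        y = np.array([1.0, 0.0, 1.0, 0.0])
        assert label_shift(y, np.ones(4, bool)) == 0.0

    def test_pooled_vs_subgroup_example(self):
        # pooled rate 0.31, subgroup rate 0.10 -> shift 0.21
        y = np.concatenate([np.ones(31), np.zeros(69), np.ones(10), np.zeros(90)])
        mask = np.concatenate([np.zeros(100, bool), np.ones(100, bool)])
        pooled = y.mean()
        assert label_shift(y, mask) == pytest.approx(abs(pooled - 0.10))

    def test_all_pathogenic_subgroup(self):
        y = np.array([1.0, 1.0, 0.0, 0.0])
        mask = np.array([True, True, False, False])
        assert label_shift(y, mask) == pytest.approx(0.5)

    def test_empty_subgroup_rejected(self):
        with pytest.raises(DataError):
            label_shift(np.array([1.0, 0.0]), np.zeros(2, bool))


class TestMutualInformation:
    def test_group_equals_label_recovers_label_entropy(self):
        rng = np.random.default_rng(3)
        y = (rng.random(5000) < 0.3).astype(int)
        est = mutual_information(y, y, bootstrap=50, seed=0)
        p = y.mean()
        h = -p * math.log(p) - (1 - p) * math.log(1 - p)
        assert est.point == pytest.approx(h, rel=1e-9)
        assert est.mean == pytest.approx(h, abs=0.02)

    def test_independent_label_and_group_near_zero(self):
        rng = np.random.default_rng(4)
        y = (rng.random(20_000) < 0.5).astype(int)
        g = rng.integers(0, 3, 20_000)
        est = mutual_information(y, g, bootstrap=30, seed=0)
        assert est.point < 5e-4

    def test_seeded_reproducibility(self):
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0] * 10)
        g = np.array([0, 0, 1, 1, 0, 1, 0, 1] * 10)
        a = mutual_information(y, g, bootstrap=100, seed=7)
        b = mutual_information(y, g, bootstrap=100, seed=7)
        assert (a.mean, a.sd) == (b.mean, b.sd)


class TestProteinLevelGroups:
    def test_grouping_is_protein_constant(self, synthetic_table):
        groups = protein_level_groups(synthetic_table, "disordered")
        df = synthetic_table.df.assign(g=groups)
        assert (df.groupby("protein_id")["g"].nunique() == 1).all()

    def test_three_distinct_fractions_get_three_groups(self):
        from conftest import labeled_table
        t = labeled_table(
            scores=[-1.0] * 6,
            labels=[0, 1] * 3,
            protein_ids=["A", "A", "B", "B", "C", "C"],
            disordered=[0, 0, 1, 0, 1, 1],
        )
        groups = protein_level_groups(t, "disordered", n_bins=3)
        assert sorted(set(groups)) == [0, 1, 2]

    def test_uniform_fractions_single_group(self):
        from conftest import labeled_table
        t = labeled_table(scores=[-1.0] * 4, labels=[0, 1, 0, 1],
                          protein_ids=["A", "A", "B", "B"],
                          disordered=[0, 0, 0, 0])
        assert set(protein_level_groups(t, "disordered")) == {0}


class TestFisherBH:
    def test_no_association(self):
        (orr, p, p_adj), = fisher_bh([[[5, 5], [5, 5]]])
        assert orr == pytest.approx(1.0)
        assert p == pytest.approx(1.0)
        assert p_adj == pytest.approx(1.0)

    def test_perfect_association_matches_enumeration(self):
        # hypergeometric enumeration: only the two extreme tables are as
        # improbable as the observed one
        (_, p, _), = fisher_bh([[[10, 0], [0, 10]]])
        expected = 2 / comb(20, 10)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_single_table_bh_identity(self):
        (_, p, p_adj), = fisher_bh([[[8, 2], [3, 7]]])
        assert p_adj == pytest.approx(p)

    def test_bh_adjustment_is_monotone_step_up(self):
        tables = [[[10, 0], [0, 10]], [[6, 4], [4, 6]], [[5, 5], [5, 5]]]
        res = fisher_bh(tables)
        ps = [r[1] for r in res]
        adj = [r[2] for r in res]
        # oracle: classic step-up with monotonicity enforcement
        order = np.argsort(ps)
        m = len(ps)
        raw = np.array(ps)[order] * m / (np.arange(m) + 1)
        stepped = np.minimum.accumulate(raw[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(adj, expected, rtol=1e-12)

    def test_all_zero_table_rejected(self):
        with pytest.raises(DataError):
            fisher_bh([[[0, 0], [0, 0]]])


class TestKendallTau:
    def test_identical_and_reversed(self):
        d = {25: {"a": 1.0, "b": 2.0, "c": 3.0},
             50: {"a": 1.5, "b": 2.5, "c": 3.5},
             100: {"a": 3.0, "b": 2.0, "c": 1.0}}
        mat = kendall_tau_stability(d)
        assert mat.loc[25, 50] == pytest.approx(1.0)
        assert mat.loc[25, 100] == pytest.approx(-1.0)

    def test_five_attribute_toy_matches_pair_counting(self):
        a = {"a": 0.1, "b": 0.7, "c": 0.3, "d": 0.9, "e": 0.5}
        b = {"a": 0.2, "b": 0.4, "c": 0.8, "d": 1.0, "e": 0.6}
        mat = kendall_tau_stability({10: a, 20: b})
        keys = sorted(a)
        va = [a[k] for k in keys]
        vb = [b[k] for k in keys]
        conc = disc = 0
        for i in range(5):
            for j in range(i + 1, 5):
                s = (va[i] - va[j]) * (vb[i] - vb[j])
                conc += s > 0
                disc += s < 0
        expected = (conc - disc) / comb(5, 2)
        assert mat.loc[10, 20] == pytest.approx(expected)

    def test_mismatched_attribute_sets_rejected(self):
        with pytest.raises(DataError):
            kendall_tau_stability({10: {"a": 1.0}, 20: {"b": 1.0}})


class TestShiftScan:
    def test_report_shape_and_content(self, synthetic_table):
        rep = shift_scan(synthetic_table)
        assert list(rep.columns) == ["attribute", "n_M", "n_notM", "label_shift",
                                     "divergence", "OR", "p", "p_adj"]
        row = rep.set_index("attribute").loc["disordered"]
        assert row["label_shift"] == pytest.approx(0.21, abs=0.02)
        assert row["p_adj"] < 1e-10
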
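"""Contrast tests, BH correction, cluster logic and the dCT formula."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from adiporeg.clustering import (
    CD2314ClusterAssigner,
    COMPARATORS,
    _vectorized_moderated,
    assign_clusters,
    bh_fdr,
    compute_contrasts,
    qpcr_relative_expression,
    welch_t_test,
)
from adiporeg.simulate import ExpressionSimConfig, default_design, simulate_expression


class TestWelch:
    def test_identity_groups(self):
        t, p, d = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == 1 and d == 0

    def test_hand_computed_statistic(self):
        # mean diff -6, pooled se sqrt(2/3), df=4 by Welch-Satterthwaite
        t, p, d = welch_t_test([1, 2, 3], [7, 8, 9])
        assert t == pytest.approx(-6 / np.sqrt(2 / 3), rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(6 / np.sqrt(2 / 3), df=4), rel=1e-9)
        assert d == -1

    def test_zero_variance_unequal_means_is_maximally_significant(self):
        t, p, d = welch_t_test([5, 5, 5], [6, 6, 6])
        assert p == 0.0 and d == -1

    def test_too_small_group_raises(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1, 2, 3])
        with pytest.raises(ValueError):
            welch_t_test([1, 2, np.nan], [1, 2, 3])

    @given(
        a=st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        b=st.lists(st.floats(-50, 50), min_size=2, max_size=6),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_swapping_groups_negates_t_and_direction(self, a, b):
        t1, p1, d1 = welch_t_test(a, b)
        t2, p2, d2 = welch_t_test(b, a)
        assert d1 == -d2
        if np.isfinite(t1):
            assert t1 == pytest.approx(-t2, rel=1e-9, abs=1e-12)
            assert p1 == pytest.approx(p2, rel=1e-9, abs=1e-12)


def _bh_bruteforce(p, q):
    """Step-up definition evaluated literally."""
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, bool)
    if k_star:
        reject[order[:k_star]] = True
    return reject


class TestBH:
    @pytest.mark.parametrize(
        "pvals,q,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], 0.05, [True] * 4),
            ([0.04], 0.05, [True]),
            ([0.06, 0.7], 0.05, [False, False]),
        ],
    )
    def test_worked_examples(self, pvals, q, expected):
        assert list(bh_fdr(pvals, q)) == expected

    @given(
        p=st.lists(st.floats(0, 1), min_size=1, max_size=8),
        q=st.floats(0.01, 0.2),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_bruteforce_step_up(self, p, q):
        assert np.array_equal(bh_fdr(p, q), _bh_bruteforce(np.array(p), q))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([], 0.05)


def _contrast_rows(gene, sig_by_tp):
    """sig_by_tp: {tp: (list of significant flags, direction)}"""
    rows = []
    for tp, (flags, direction) in sig_by_tp.items():
        for comp, flag in zip(COMPARATORS, flags):
            rows.append(
                dict(gene_id=gene, time_point=tp, comparator=comp,
                     t_statistic=0.0, p_value=0.01, direction=direction,
                     fdr_significant=flag)
            )
    return rows


class TestClusterAssignment:
    def _assign(self, sig_by_tp, **kw):
        df = pd.DataFrame(_contrast_rows("g", sig_by_tp))
        out = assign_clusters(df, **kw)
        return int(out.loc[out.gene_id == "g", "cluster"].iloc[0])

    def test_up_in_all_three_at_day6_only_is_cluster1(self):
        assert self._assign({"d6": ([1, 1, 1], 1), "d11": ([0, 0, 0], 1)}) == 1

    def test_down_at_day6_and_day11_give_clusters_2_and_4(self):
        assert self._assign({"d6": ([1, 1, 1], -1), "d11": ([0, 0, 0], -1)}) == 2
        assert self._assign({"d6": ([0, 0, 0], -1), "d11": ([1, 1, 1], -1)}) == 4

    def test_up_at_day11_only_is_cluster3(self):
        assert self._assign({"d6": ([0, 0, 0], 1), "d11": ([1, 1, 1], 1)}) == 3

    def test_two_of_three_significant_is_never_assigned(self):
        assert self._assign({"d6": ([1, 1, 0], 1), "d11": ([0, 0, 0], 1)}) == 0

    def test_both_time_points_same_direction_is_cluster5(self):
        assert self._assign({"d6": ([1, 1, 1], 1), "d11": ([1, 1, 1], 1)}) == 5

    def test_discordant_directions_fall_back_to_day6_cluster(self):
        df = pd.DataFrame(
            _contrast_rows("g", {"d6": ([1, 1, 1], 1)})
            + _contrast_rows("g", {"d11": ([1, 1, 1], -1)})
        )
        out = assign_clusters(df)
        assert int(out.cluster.iloc[0]) == 1
        out_any = assign_clusters(df, cluster5_direction="any")
        assert int(out_any.cluster.iloc[0]) == 5

    def test_mixed_directions_within_time_point_not_assigned(self):
        rows = []
        for comp, direction in zip(COMPARATORS, [1, 1, -1]):
            rows.append(
                dict(gene_id="g", time_point="d6", comparator=comp,
                     t_statistic=0.0, p_value=0.001, direction=direction,
                     fdr_significant=True)
            )
        rows += _contrast_rows("g", {"d11": ([0, 0, 0], 1)})
        out = assign_clusters(pd.DataFrame(rows))
        assert int(out.cluster.iloc[0]) == 0

    def test_missing_comparator_raises(self):
        df = pd.DataFrame(_contrast_rows("g", {"d6": ([1, 1, 1], 1)}))
        df = df[df.comparator != "BIO"]
        with pytest.raises(ValueError):
            assign_clusters(df)


class TestModeratedT:
    def test_matches_bioconductor_limma(self, tmp_path):
        """Moderated t, p and prior df agree with limma's eBayes exactly."""
        rng = np.random.default_rng(42)
        a = rng.normal(8, 0.4, size=(60, 3))
        b = rng.normal(8, 0.4, size=(60, 3))
        a[:10] += 1.5
        np.savetxt(tmp_path / "a.txt", a)
        np.savetxt(tmp_path / "b.txt", b)
        script = tmp_path / "mod.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'a <- as.matrix(read.table("{tmp_path}/a.txt"))\n'
            f'b <- as.matrix(read.table("{tmp_path}/b.txt"))\n'
            "x <- cbind(a, b)\n"
            "design <- cbind(Intercept=1, grp=c(rep(1,ncol(a)), rep(0,ncol(b))))\n"
            "fit <- eBayes(lmFit(x, design))\n"
            'write.table(cbind(fit$t[,2], fit$p.value[,2]),'
            f' "{tmp_path}/out.txt", row.names=FALSE, col.names=FALSE)\n'
        )
        res = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True
        )
        if res.returncode != 0:
            pytest.skip(f"Rscript/limma unavailable: {res.stderr[:200]}")
        ref = np.loadtxt(tmp_path / "out.txt")
        t, p, _ = _vectorized_moderated(a, b)
        np.testing.assert_allclose(t, ref[:, 0], rtol=1e-9)
        np.testing.assert_allclose(p, ref[:, 1], rtol=1e-9)

    def test_moderation_beats_welch_at_three_replicates(self):
        cfg = ExpressionSimConfig(n_per_cluster={1: 50})
        m, truth = simulate_expression(800, config=cfg, seed=11)
        planted = set(truth.loc[truth.planted_cluster == 1, "gene_id"])
        sens = {}
        for flavour in ("moderated", "welch"):
            a = CD2314ClusterAssigner(test=flavour).fit(m, default_design())
            rec = set(a.cluster_genes(1))
            sens[flavour] = len(rec & planted) / len(planted)
        assert sens["moderated"] >= sens["welch"]
        assert sens["moderated"] >= 0.9


class TestContrastTable:
    def test_day3_excluded_and_families_complete(self):
        m, _ = simulate_expression(40, config=ExpressionSimConfig(n_per_cluster={}),
                                   seed=0)
        c = compute_contrasts(m, default_design())
        assert set(c.time_point) == {"d6", "d11"}
        assert set(c.comparator) == set(COMPARATORS)
        assert len(c) == 40 * 2 * 3
        assert c.p_value.between(0, 1).all()

    def test_missing_replicates_raise(self):
        m, _ = simulate_expression(10, config=ExpressionSimConfig(n_per_cluster={}),
                                   seed=0)
        design = default_design()
        broken = design[design.sample_id != "d6_BIO_r2"]
        broken = broken[broken.sample_id != "d6_BIO_r3"]
        with pytest.raises(ValueError):
            compute_contrasts(m.drop(columns=["d6_BIO_r2", "d6_BIO_r3"]), broken)


class TestQpcr:
    def test_worked_example(self):
        assert qpcr_relative_expression(25, [20, 21, 22]) == pytest.approx(0.0625)

    def test_zero_delta_ct_gives_unity(self):
        assert qpcr_relative_expression(21, [20, 21, 22]) == pytest.approx(1.0)

    def test_one_cycle_less_doubles_expression(self):
        x = qpcr_relative_expression(25, [20, 21, 22])
        assert qpcr_relative_expression(24, [20, 21, 22]) == pytest.approx(2 * x)

    def test_reference_count_enforced(self):
        with pytest.raises(ValueError):
            qpcr_relative_expression(25, [])
        with pytest.raises(ValueError):
            qpcr_relative_expression(25, [20, 21], n_refs=3)
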
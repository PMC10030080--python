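"""Native DE procedures: rank-sum test, count GLM, pseudobulk,
meta-analysis combiners, BH correction and the external-result adapter."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_count_matrix, make_de_result

from scdebench.containers import DEResult, NormalizedMatrix
from scdebench.de_methods import (
    MetaConfig,
    bh_adjust,
    covariate_glm_de,
    lognorm_ttest_de,
    meta_combine,
    meta_de,
    pseudobulk_aggregate,
    pseudobulk_de,
    read_external_result,
    signed_score,
    wilcoxon_de,
)
from scdebench.preprocess import log_normalize
from scdebench.sim_splat import SplatParams, simulate_counts


def _norm(values, groups, batch=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    return NormalizedMatrix(
        values=values,
        gene_ids=np.array([f"G{i:04d}" for i in range(n_genes)], dtype=object),
        cell_ids=np.array([f"C{j:04d}" for j in range(n_cells)], dtype=object),
        batch=np.array(batch or ["b1"] * n_cells, dtype=object),
        group=np.array(groups, dtype=object),
        provenance="corrected",
    )


def _bh_brute_force(p):
    """Literal step-up definition: q_(i) = min over j >= i of p_(j) m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBhAdjust:
    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for n in (1, 5, 37, 200):
            p = rng.random(n)
            assert np.allclose(bh_adjust(p), _bh_brute_force(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(500)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), q_ref)

    def test_stepup_example(self):
        assert np.allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_degenerate_inputs(self):
        assert np.allclose(bh_adjust(np.ones(5)), np.ones(5))
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_nan_propagates_and_excluded_from_m(self):
        q = bh_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(q[1])
        # only two valid tests: q = p * 2 / rank
        assert q[0] == pytest.approx(0.02)
        assert q[2] == pytest.approx(0.04)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_q_dominates_p_and_monotone(self, plist):
        p = np.array(plist)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestSignedScore:
    def test_p_one_scores_zero(self):
        res = make_de_result([1.0], logfc=[2.0])
        assert signed_score(res)[0] == 0.0

    def test_base10_example(self):
        res = make_de_result([0.01], logfc=[-1.0])
        assert signed_score(res, log_base=10)[0] == pytest.approx(-2.0)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(2)
        p = rng.random(20)
        a = make_de_result(p, logfc=np.ones(20))
        b = make_de_result(p, logfc=-np.ones(20))
        assert np.allclose(signed_score(a), -signed_score(b))

    def test_zero_p_clamped(self):
        res = make_de_result([0.0], logfc=[1.0])
        assert np.isfinite(signed_score(res)[0])


class TestWilcoxon:
    def test_identical_multisets_p_one(self):
        vals = [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]]
        res = wilcoxon_de(_norm(vals, ["case"] * 3 + ["control"] * 3))
        assert res.p_value[0] == pytest.approx(1.0)

    def test_complete_separation_matches_exact_enumeration(self):
        # 4 vs 4, case all larger: two-sided exact p = 2 / C(8,4)
        vals = [[5.0, 6.0, 7.0, 8.0, 1.0, 2.0, 3.0, 4.0]]
        res = wilcoxon_de(_norm(vals, ["case"] * 4 + ["control"] * 4))
        assert res.p_value[0] == pytest.approx(2.0 / scipy.special.comb(8, 4))

    def test_constant_gene(self):
        vals = [[2.0] * 10]
        res = wilcoxon_de(_norm(vals, ["case"] * 5 + ["control"] * 5))
        assert res.p_value[0] == 1.0
        assert res.sign[0] == 0

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(0.0, 1.0, size=(1000, 120))
        res = wilcoxon_de(_norm(vals, ["case"] * 60 + ["control"] * 60))
        frac = (res.p_value < 0.05).mean()
        # binomial 99% CI around 0.05 at n=1000: ~0.05 +- 0.0178
        assert abs(frac - 0.05) < 0.018

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.random((30, 40))
        groups = ["case"] * 20 + ["control"] * 20
        res = wilcoxon_de(_norm(vals, groups))
        perm = rng.permutation(30)
        res_perm = wilcoxon_de(_norm(vals[perm], groups))
        lookup = dict(zip(res_perm.gene_ids, res_perm.p_value))
        # gene ids are reassigned positionally, so match via the permutation
        assert np.allclose(res.p_value[perm], res_perm.p_value)


class TestCovariateGlm:
    def test_single_batch_block_is_noop(self, null_splat):
        counts, _ = null_splat
        single = counts.subset_cells(counts.batch == "batch1")
        with_b, _ = covariate_glm_de(single, include_batch=True)
        without_b, _ = covariate_glm_de(single, include_batch=False)
        assert np.allclose(with_b.p_value, without_b.p_value, atol=1e-8)

    def test_unbalanced_batch_rejected(self):
        counts = make_count_matrix(
            np.random.default_rng(5).poisson(5, (10, 40)),
            batch=["b1"] * 20 + ["b2"] * 20,
            group=["case"] * 20 + ["control"] * 20,
        )
        with pytest.raises(ValueError, match="b1"):
            covariate_glm_de(counts, include_batch=True)

    def test_type_one_error_calibrated(self, null_splat):
        counts, _ = null_splat
        res, fit = covariate_glm_de(counts, include_batch=True)
        ok = ~fit["fit_failed"].to_numpy()
        frac = (res.p_value[ok] < 0.05).mean()
        n = ok.sum()
        half = 2.576 * np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < half + 0.01

    def test_covariate_model_improves_effect_recovery(self):
        """Mean absolute error of the group effect is smaller with batch
        covariates than with the pooled naive model under substantial
        batch effects (paired over seeds)."""
        wins = 0
        for seed in range(5):
            params = SplatParams(
                n_genes=100,
                batch_sizes=[120, 180],
                group_ratios=[0.3, 0.7],
                batch_facLoc=0.4,
                batch_facScale=0.4,
                libsize_loc=10.0,
                seed=seed,
            )
            counts, truth = simulate_counts(params)
            de = truth.de_mask()
            true_lfc = np.log2(truth.effect)
            cov, _ = covariate_glm_de(counts, include_batch=True)
            naive, _ = covariate_glm_de(counts, include_batch=False)
            mae_cov = np.abs(cov.logfc[de] - true_lfc[de]).mean()
            mae_naive = np.abs(naive.logfc[de] - true_lfc[de]).mean()
            wins += mae_cov < mae_naive
        assert wins >= 4

    def test_offset_mode_runs(self, null_splat):
        counts, _ = null_splat
        sub = counts.subset_genes(np.arange(20))
        res, _ = covariate_glm_de(sub, libsize_as="offset")
        assert ((res.p_value >= 0) & (res.p_value <= 1)).all()

    def test_lrt_agrees_with_wald_in_order(self, null_splat):
        counts, _ = null_splat
        sub = counts.subset_genes(np.arange(30))
        wald, _ = covariate_glm_de(sub, test="wald")
        lrt, _ = covariate_glm_de(sub, test="lrt")
        rho = scipy.stats.spearmanr(wald.p_value, lrt.p_value).statistic
        assert rho > 0.9


class TestPseudobulk:
    def test_identity_aggregation(self):
        cm = make_count_matrix(
            np.arange(12).reshape(3, 4),
            group=["case", "case", "control", "control"],
        )
        units = np.array(["u1", "u2", "u3", "u4"], dtype=object)
        out = pseudobulk_aggregate(cm, unit=units)
        assert np.array_equal(out.counts, cm.counts)

    def test_total_count_conservation_and_toy_sums(self):
        counts = np.arange(18).reshape(3, 6)
        cm = make_count_matrix(
            counts,
            batch=["b1", "b1", "b2", "b1", "b1", "b2"],
            group=["case"] * 3 + ["control"] * 3,
        )
        out = pseudobulk_aggregate(cm)
        assert out.counts.sum() == counts.sum()
        case_b1 = counts[:, [0, 1]].sum(axis=1)
        assert np.array_equal(out.counts[:, list(out.cell_ids).index("b1|case")], case_b1)

    def test_single_unit_group_rejected(self):
        cm = make_count_matrix(
            np.ones((2, 4), dtype=int),
            batch=["b1"] * 4,
            group=["case", "case", "control", "control"],
        )
        with pytest.raises(ValueError, match="replication"):
            pseudobulk_aggregate(cm)

    def test_identical_profiles_p_one(self):
        counts = np.tile(np.array([[3], [5]]), (1, 4))
        bulk = make_count_matrix(
            counts, group=["case", "case", "control", "control"]
        )
        res = pseudobulk_de(bulk)
        assert (res.p_value == 1.0).all()

    def test_spiked_gene_detected(self):
        rng = np.random.default_rng(6)
        base = rng.poisson(1000, size=(20, 8))
        base[0, :4] *= 4  # 4-fold in the 4 case units
        bulk = make_count_matrix(base, group=["case"] * 4 + ["control"] * 4)
        res = pseudobulk_de(bulk)
        assert res.p_value[0] < 0.05
        assert res.sign[0] == 1

    def test_null_simulation_no_false_discoveries(self):
        fds = []
        for seed in (0, 1, 2):
            params = SplatParams(
                n_genes=200,
                batch_sizes=[40] * 7,
                de_prob=0.0,
                libsize_loc=9.0,
                dropout_mid=0.01,
                seed=seed,
            )
            counts, _ = simulate_counts(params)
            res = pseudobulk_de(pseudobulk_aggregate(counts))
            fds.append(int((res.q_value < 0.05).sum()))
        assert np.median(fds) == 0

    def test_aggregate_permutation_commutes(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(4, (15, 30))
        batch = ["b1"] * 15 + ["b2"] * 15
        group = (["case"] * 8 + ["control"] * 7) * 2
        cm = make_count_matrix(counts, batch=batch, group=group)
        perm = rng.permutation(30)
        cm_perm = cm.subset_cells(perm)
        a = pseudobulk_aggregate(cm)
        b = pseudobulk_aggregate(cm_perm)
        for u in a.cell_ids:
            ia = list(a.cell_ids).index(u)
            ib = list(b.cell_ids).index(u)
            assert np.array_equal(a.counts[:, ia], b.counts[:, ib])


class TestMetaCombine:
    def _result(self, p, sign, logfc=None, se=None, method="m"):
        p = np.asarray(p, dtype=float)
        n = p.size
        return DEResult(
            gene_ids=np.array([f"G{i:04d}" for i in range(n)], dtype=object),
            p_value=p,
            q_value=bh_adjust(p),
            logfc=np.asarray(logfc if logfc is not None else sign, dtype=float),
            sign=np.asarray(sign, dtype=int),
            method=method,
            se=None if se is None else np.asarray(se, dtype=float),
        )

    def test_single_batch_identity(self):
        res = self._result([0.02, 0.8, 0.4], [1, -1, 1])
        out = meta_combine([res], MetaConfig(combiner="weighted_fisher"))
        assert np.allclose(out.p_value, res.p_value)
        assert np.array_equal(out.sign, res.sign)

    def test_rem_reduces_to_fem_without_heterogeneity(self):
        a = self._result([0.1, 0.2], [1, 1], logfc=[1.0, 0.5], se=[0.2, 0.2])
        b = self._result([0.1, 0.2], [1, 1], logfc=[1.0, 0.5], se=[0.2, 0.2])
        fem = meta_combine([a, b], MetaConfig(combiner="fixed_effects"))
        rem = meta_combine([a, b], MetaConfig(combiner="random_effects"))
        assert np.allclose(fem.p_value, rem.p_value)
        assert np.allclose(fem.logfc, rem.logfc)

    def test_two_batches_consensus_strengthens(self):
        # identical one-sided p = 0.05: chi2(4 df) tail of -2*2*ln(0.1/2)
        a = self._result([0.1], [1])
        b = self._result([0.1], [1])
        out = meta_combine([a, b], MetaConfig(combiner="weighted_fisher"))
        expected = 2 * scipy.stats.chi2.sf(-2 * 2 * np.log(0.05), df=4)
        assert out.p_value[0] == pytest.approx(expected, rel=1e-6)
        assert out.p_value[0] < 0.05
        assert out.sign[0] == 1

    def test_batch_order_symmetry(self):
        rng = np.random.default_rng(8)
        p1, p2 = rng.random(20), rng.random(20)
        s1 = rng.choice([-1, 1], 20)
        s2 = rng.choice([-1, 1], 20)
        a, b = self._result(p1, s1), self._result(p2, s2)
        cfg = MetaConfig(combiner="weighted_fisher", weights=[3.0, 5.0])
        cfg_rev = MetaConfig(combiner="weighted_fisher", weights=[5.0, 3.0])
        ab = meta_combine([a, b], cfg)
        ba = meta_combine([b, a], cfg_rev)
        assert np.allclose(ab.p_value, ba.p_value)

    def test_monotone_in_consensus_direction(self):
        a = self._result([0.2], [1])
        out_hi = meta_combine(
            [a, self._result([0.3], [1])], MetaConfig(combiner="weighted_fisher")
        )
        out_lo = meta_combine(
            [a, self._result([0.05], [1])], MetaConfig(combiner="weighted_fisher")
        )
        assert out_lo.p_value[0] <= out_hi.p_value[0]

    def test_gene_union_with_missing_batches(self):
        a = self._result([0.01, 0.5], [1, 1])
        b = DEResult(
            gene_ids=np.array(["G0000"], dtype=object),
            p_value=np.array([0.02]),
            q_value=np.array([0.02]),
            logfc=np.array([1.0]),
            sign=np.array([1]),
        )
        out = meta_combine([a, b], MetaConfig(combiner="weighted_fisher"))
        assert set(out.gene_ids) == {"G0000", "G0001"}

    def test_meta_de_end_to_end(self, small_splat):
        counts, truth = small_splat
        res = meta_de(counts, MetaConfig(combiner="fixed_effects"))
        de = truth.subset(res.gene_ids).de_mask()
        # DE genes should be enriched among small combined p-values
        assert res.p_value[de].mean() < res.p_value[~de].mean()

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            MetaConfig(weights=[1.0, 0.0])


class TestExternalAdapter:
    def _write(self, tmp_path, text, name="r.tsv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    def test_well_formed_with_recomputed_q(self, tmp_path):
        path = self._write(
            tmp_path,
            "gene_id\tlogfc\tpvalue\nA\t1.0\t0.01\nB\t-0.5\t0.5\nC\t0.2\t1.0\n",
        )
        res = read_external_result(path)
        assert res.n_genes_tested == 3
        assert np.allclose(res.q_value, bh_adjust(res.p_value))
        assert list(res.sign) == [1, -1, 1]

    def test_qvalue_passthrough(self, tmp_path):
        path = self._write(
            tmp_path,
            "gene_id\tlogfc\tpvalue\tqvalue\nA\t1.0\t0.01\t0.9\n",
        )
        res = read_external_result(path)
        assert res.q_value[0] == 0.9

    def test_out_of_range_p_rejected(self, tmp_path):
        path = self._write(
            tmp_path, "gene_id\tlogfc\tpvalue\nA\t1.0\t1.5\n"
        )
        with pytest.raises(ValueError, match="row"):
            read_external_result(path)

    def test_missing_column_rejected(self, tmp_path):
        path = self._write(tmp_path, "gene_id\tpvalue\nA\t0.5\n")
        with pytest.raises(ValueError, match="logfc"):
            read_external_result(path)

    def test_duplicate_gene_rejected(self, tmp_path):
        path = self._write(
            tmp_path, "gene_id\tlogfc\tpvalue\nA\t1\t0.5\nA\t1\t0.4\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_external_result(path)


class TestLognormTtest:
    def test_null_calibration(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(800, 80))
        res = lognorm_ttest_de(_norm(vals, ["case"] * 40 + ["control"] * 40))
        frac = (res.p_value < 0.05).mean()
        assert abs(frac - 0.05) < 0.025

    def test_reports_standard_errors(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=(10, 30))
        res = lognorm_ttest_de(_norm(vals, ["case"] * 15 + ["control"] * 15))
        assert res.se is not None and np.isfinite(res.se).all()
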
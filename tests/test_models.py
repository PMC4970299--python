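import numpy as np
import pytest

from gemscan import models, oracle, simulate
from gemscan.data_io import AssociationRecord, FeatureAnnotation
from gemscan.errors import ValidationError
from gemscan.models import ScanConfig

from conftest import make_matrix


def ann(chrom, start, end, fid="x"):
    return FeatureAnnotation(fid, chrom, start, end)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "snp, cpg, window, expected",
        [
            (ann("chr1", 500, 501), ann("chr2", 500, 502), 0, "trans"),
            (ann("chr1", 10_000, 10_001), ann("chr1", 900_000, 900_002), 0, "cis"),
            (ann("chr1", 100, 101), ann("chr1", 100, 102), 0, "disrupting"),
            # gap between [150,151) and [100,102) is 150-102 = 48 bp
            (ann("chr1", 150, 151), ann("chr1", 100, 102), 47, "cis"),
            (ann("chr1", 150, 151), ann("chr1", 100, 102), 48, "disrupting"),
        ],
    )
    def test_definitions(self, snp, cpg, window, expected):
        assert models.classify_pair(snp, cpg, window) == expected

    def test_symmetric_in_chromosome_rule(self):
        # disrupting implies same chromosome, whatever the window
        got = models.classify_pair(
            ann("chr1", 0, 1), ann("chr2", 0, 2), window_bp=10**9
        )
        assert got == "trans"


class TestBhFdr:
    def test_single_p(self):
        np.testing.assert_allclose(models.bh_fdr([0.03]), [0.03])

    def test_all_equal(self):
        np.testing.assert_allclose(models.bh_fdr([0.2] * 5), [0.2] * 5)

    def test_step_up_hand_evaluated(self):
        # q_(i) = min_{j>=i} p_(j)*m/j for p=(.01,.02,.03,.04), m=4:
        # all reduce to 0.04
        np.testing.assert_allclose(
            models.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_external_family_size(self):
        # thresholded stream: 2 smallest p of a family of 100
        q = models.bh_fdr([0.0001, 0.0002], m=100)
        np.testing.assert_allclose(q, [0.01, 0.01])

    def test_matches_statsmodels_when_family_complete(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(0.001, 1.0, 200)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(models.bh_fdr(p), q_ref, rtol=1e-12)

    def test_monotone_in_p(self):
        """q sorted by p is non-decreasing (step-up never reorders)."""
        rng = np.random.default_rng(6)
        p = rng.uniform(0.0001, 1.0, 500)
        q = models.bh_fdr(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= 0)
        assert np.all(q >= p)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            models.bh_fdr([0.0, 0.5])
        with pytest.raises(ValidationError):
            models.bh_fdr([0.5, 1.5])


class TestBestPerOutcome:
    def rec(self, outcome, predictor, r2, p):
        return AssociationRecord(
            outcome_id=outcome, predictor_id=predictor, beta=1.0,
            t_stat=1.0, p_value=p, df=10, r_squared=r2,
        )

    def test_argmax_r_squared(self):
        recs = [self.rec("c1", f"s{i}", r2, 0.01) for i, r2 in
                enumerate([0.1, 0.7, 0.3])]
        best = models.best_per_outcome(recs)
        assert len(best) == 1 and best[0].predictor_id == "s1"

    def test_tie_broken_by_smaller_p(self):
        recs = [self.rec("c1", "sA", 0.5, 0.02), self.rec("c1", "sB", 0.5, 0.01)]
        assert models.best_per_outcome(recs)[0].predictor_id == "sB"

    def test_full_tie_lexicographic(self):
        recs = [self.rec("c1", "sB", 0.5, 0.01), self.rec("c1", "sA", 0.5, 0.01)]
        assert models.best_per_outcome(recs)[0].predictor_id == "sA"

    def test_single_record_identity(self):
        recs = [self.rec("c1", "sA", 0.5, 0.01)]
        assert models.best_per_outcome(recs) == recs


class TestAttemptedModels:
    def test_counts_are_exact_products(self):
        assert models.attempted_models("emodel", 1423, n_envs=19) == 27_037
        assert models.attempted_models("gxemodel", 2, n_snps=3, n_envs=2) == 12

    def test_full_scale_gmodel_count(self):
        """1423 CpGs x 708,365 SNPs enumerates 1008 million models."""
        n = models.attempted_models("gmodel", 1423, n_snps=708_365)
        assert n == 1_008_003_395
        assert round(n / 1e6) == 1008


class TestRunEmodel:
    def test_model_count_bookkeeping(self, small_study):
        res = models.run_emodel(small_study.M, small_study.E, small_study.cvrt)
        assert res.summary.tests_attempted == 25 * 2
        assert res.summary.tests_computed == 25 * 2
        assert res.summary.records_emitted == len(res.records) == 50

    def test_self_association_saturates(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.uniform(0.2, 0.8, (3, 30)), kind="methylation")
        e = make_matrix(m.values[1][None, :], kind="environment",
                        feature_prefix="env")
        e.sample_ids = list(m.sample_ids)
        res = models.run_emodel(m, e, None)
        top = res.records[0]
        assert top.outcome_id == "f1" and top.saturated

    def test_planted_effects_rank_first(self):
        spec = simulate.SimulationSpec(
            n_samples=200, n_cpgs=50, n_snps=2, n_envs=1, seed=9,
            e_effects={(i, 0): 0.8 for i in range(5)}, noise_sd=0.2,
        )
        st = simulate.simulate_study(spec)
        res = models.run_emodel(st.M, st.E, st.cvrt)
        top5 = {r.outcome_id for r in res.records[:5]}
        assert top5 == {f"cg{i + 1:07d}" for i in range(5)}

    def test_fdr_is_per_environment_family(self, small_study):
        res = models.run_emodel(small_study.M, small_study.E, small_study.cvrt)
        for env_id in small_study.E.feature_ids:
            fam = [r for r in res.records if r.predictor_id == env_id]
            q_ref = models.bh_fdr([r.p_value for r in fam], m=len(fam))
            np.testing.assert_allclose([r.fdr for r in fam], q_ref)
            assert all(r.fdr >= r.p_value - 1e-15 for r in fam)

    def test_matches_oracle(self, small_study):
        res = models.run_emodel(small_study.M, small_study.E, small_study.cvrt)
        midx = {f: i for i, f in enumerate(small_study.M.feature_ids)}
        eidx = {f: i for i, f in enumerate(small_study.E.feature_ids)}
        for rec in res.records:
            fit = oracle.lm_single(
                small_study.M.values[midx[rec.outcome_id]],
                small_study.E.values[eidx[rec.predictor_id]],
                small_study.cvrt,
            )
            assert rec.t_stat == pytest.approx(fit.t, rel=1e-8)
            assert rec.p_value == pytest.approx(fit.p, rel=1e-8)
            assert rec.beta == pytest.approx(fit.beta, rel=1e-8)


class TestRunGmodel:
    def test_affine_pair_saturates_and_recovers_slope(self):
        rng = np.random.default_rng(1)
        g = make_matrix(rng.binomial(2, 0.4, (1, 40)).astype(float),
                        kind="genotype", feature_prefix="rs")
        m = make_matrix(0.1 + 0.2 * g.values, kind="methylation")
        m.sample_ids = list(g.sample_ids)
        res = models.run_gmodel(m, g, None, ScanConfig(p_output_threshold=1.0))
        top = res.records[0]
        assert top.saturated
        assert top.beta == pytest.approx(0.2, rel=1e-10)

    def test_planted_cis_pairs_recovered_at_fdr(self):
        planted = {(i, 10 * i): (0.6 if i % 2 == 0 else -0.6) for i in range(10)}
        spec = simulate.SimulationSpec(
            n_samples=300, n_cpgs=100, n_snps=500, n_envs=1, seed=17,
            g_effects=planted, noise_sd=0.1,
        )
        st = simulate.simulate_study(spec)
        res = models.run_gmodel(st.M, st.G, st.cvrt,
                                ScanConfig(p_output_threshold=1e-5),
                                cpg_ann=st.cpg_ann, snp_ann=st.snp_ann)
        hits = {(r.outcome_id, r.predictor_id): r for r in res.records}
        for t in st.ground_truth:
            key = (t.outcome_id, t.predictor_id)
            assert key in hits, f"planted pair {key} not emitted"
            assert hits[key].fdr < 0.05
            assert np.sign(hits[key].beta) == np.sign(t.latent_beta)
            assert hits[key].pair_class in ("cis", "disrupting")

    def test_block_invariance_bitwise(self, small_study):
        outs = []
        for bs in (1, 7, 1000):
            res = models.run_gmodel(
                small_study.M, small_study.G, small_study.cvrt,
                ScanConfig(p_output_threshold=1.0, block_size=bs),
            )
            outs.append([(r.outcome_id, r.predictor_id, r.beta, r.t_stat,
                          r.p_value, r.fdr) for r in res.records])
        assert outs[0] == outs[1] == outs[2]

    def test_matches_oracle(self, small_study):
        res = models.run_gmodel(small_study.M, small_study.G, small_study.cvrt,
                                ScanConfig(p_output_threshold=0.01))
        midx = {f: i for i, f in enumerate(small_study.M.feature_ids)}
        gidx = {f: i for i, f in enumerate(small_study.G.feature_ids)}
        assert res.records
        for rec in res.records:
            fit = oracle.lm_single(
                small_study.M.values[midx[rec.outcome_id]],
                small_study.G.values[gidx[rec.predictor_id]],
                small_study.cvrt,
            )
            assert rec.t_stat == pytest.approx(fit.t, rel=1e-8)
            assert rec.p_value == pytest.approx(fit.p, rel=1e-8)
            assert rec.beta == pytest.approx(fit.beta, rel=1e-8)

    def test_cis_window_restricts_tests(self, small_study):
        full = models.run_gmodel(small_study.M, small_study.G, small_study.cvrt,
                                 ScanConfig(p_output_threshold=1.0))
        cis = models.run_gmodel(
            small_study.M, small_study.G, small_study.cvrt,
            ScanConfig(p_output_threshold=1.0, cis_window_bp=10**6),
            cpg_ann=small_study.cpg_ann, snp_ann=small_study.snp_ann,
        )
        assert 0 < cis.summary.tests_computed < full.summary.tests_computed
        assert len(cis.records) == cis.summary.tests_computed


class TestRunGxemodel:
    def test_triplet_enumeration(self, small_study):
        res = models.run_gxemodel(small_study.M, small_study.G, small_study.E,
                                  small_study.cvrt,
                                  ScanConfig(p_output_threshold=1.0))
        assert res.summary.tests_attempted == 25 * 40 * 2
        assert res.summary.tests_computed == 25 * 40 * 2
        assert len(res.records) == 2000

    def test_planted_interaction_ranks_first(self):
        spec = simulate.SimulationSpec(
            n_samples=300, n_cpgs=30, n_snps=50, n_envs=2, seed=23,
            gxe_effects={(4, 7, 1): 0.6}, noise_sd=0.1,
        )
        st = simulate.simulate_study(spec)
        res = models.run_gxemodel(st.M, st.G, st.E, st.cvrt,
                                  ScanConfig(p_output_threshold=1.0))
        top = res.records[0]
        truth = st.ground_truth[0]
        assert (top.outcome_id, top.predictor_id, top.env_id) == (
            truth.outcome_id, truth.predictor_id, truth.env_id
        )

    def test_all_null_sweep_matches_oracle(self):
        """Complete 20 x 50 x 2 cross agrees with the full-model fits."""
        spec = simulate.SimulationSpec(
            n_samples=80, n_cpgs=20, n_snps=50, n_envs=2, seed=31, noise_sd=0.3
        )
        st = simulate.simulate_study(spec)
        res = models.run_gxemodel(st.M, st.G, st.E, st.cvrt,
                                  ScanConfig(p_output_threshold=1.0))
        assert len(res.records) == 20 * 50 * 2
        midx = {f: i for i, f in enumerate(st.M.feature_ids)}
        gidx = {f: i for i, f in enumerate(st.G.feature_ids)}
        eidx = {f: i for i, f in enumerate(st.E.feature_ids)}
        rng = np.random.default_rng(0)
        sample = rng.choice(len(res.records), size=300, replace=False)
        for k in sample:
            rec = res.records[k]
            fit = oracle.lm_interaction_single(
                st.M.values[midx[rec.outcome_id]],
                st.G.values[gidx[rec.predictor_id]],
                st.E.values[eidx[rec.env_id]],
                st.cvrt,
            )
            assert rec.p_value == pytest.approx(fit.p, rel=1e-8)
            assert rec.t_stat == pytest.approx(fit.t, rel=1e-8)

    def test_constant_environment_skipped_not_fatal(self, small_study):
        E = make_matrix(
            np.vstack([np.full(120, 3.0),
                       small_study.E.values[0]]),
            kind="environment", feature_prefix="env",
        )
        E.sample_ids = list(small_study.M.sample_ids)
        res = models.run_gxemodel(small_study.M, small_study.G, E,
                                  small_study.cvrt,
                                  ScanConfig(p_output_threshold=1.0))
        assert res.summary.excluded["skipped_envs"] == ["env0"]
        assert res.summary.tests_computed == 25 * 40


def test_unaligned_matrices_rejected(small_study):
    shuffled = small_study.E.subset_samples(
        list(reversed(small_study.E.sample_ids))
    )
    with pytest.raises(ValidationError, match="align"):
        models.run_emodel(small_study.M, shuffled, None)
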
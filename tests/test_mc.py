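"""Whole-genotype Monte Carlo resampling tests: per-SNP, table-wise,
and regression significance."""

import numpy as np
import pytest

from hostcline import ld, mc
from hostcline.genotypes import GenotypeData, allele_frequencies, posterior_dosages
from hostcline.simulate import SimConfig, simulate_genotypes_reads, simulate_truth

from conftest import certain_likelihoods


def null_dataset(seed, n_per_group=30, n_snps=300, depth=4.0):
    """One panmictic population split into two labelled groups."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        n_sites=1, n_per_pop=n_per_group,
        chrom_lengths={"1": n_snps}, blocks=[],
        alpha=np.log(1 / rng.uniform(0.2, 0.8, n_snps) - 1) * -1,
        beta=np.zeros(n_snps), gamma=np.zeros(n_snps),
        depth_mean=depth, base_error=0.01, seed=seed,
    )
    truth = simulate_truth(cfg)
    ds = simulate_genotypes_reads(truth, cfg)
    ids = ds.metadata["sample_id"].tolist()
    return ds.data, ids[:n_per_group], ids[n_per_group:]


class TestMcDifferenceTest:
    def test_argument_errors(self, small_survey):
        ids = small_survey.metadata["sample_id"].tolist()
        with pytest.raises(ValueError, match="n_reps"):
            mc.mc_difference_test(small_survey.data, ids[:5], ids[5:10], n_reps=0)
        with pytest.raises(ValueError, match="overlap"):
            mc.mc_difference_test(small_survey.data, ids[:5], ids[4:10], n_reps=10)

    def test_determinism(self, small_survey):
        ids = small_survey.metadata["sample_id"].tolist()
        a = mc.mc_difference_test(small_survey.data, ids[:15], ids[15:30],
                                  n_reps=100, seed=5)
        b = mc.mc_difference_test(small_survey.data, ids[:15], ids[15:30],
                                  n_reps=100, seed=5)
        np.testing.assert_array_equal(a.significant, b.significant)
        assert a.tablewise_p == b.tablewise_p

    def test_significance_monotone_in_observed_difference(self, small_survey):
        ids = small_survey.metadata["sample_id"].tolist()
        res = mc.mc_difference_test(small_survey.data, ids[:20], ids[20:40],
                                    n_reps=300, seed=1)
        ok = res.testable
        # flagged SNPs strictly exceed their critical value; others do not
        assert np.all(res.obs_abs[ok & res.significant] > res.crit[ok & res.significant])
        assert np.all(res.obs_abs[ok & ~res.significant] <= res.crit[ok & ~res.significant])

    def test_fixed_difference_is_significant(self):
        g1 = certain_likelihoods(np.full((30, 1), 2))
        g2 = certain_likelihoods(np.full((30, 1), 0))
        L = np.concatenate([g1, g2], axis=0)
        data = GenotypeData(L, np.zeros((60, 1), bool),
                            [f"s{i}" for i in range(60)], ["snp0"])
        ids = data.samples
        res = mc.mc_difference_test(data, ids[:30], ids[30:], n_reps=500, seed=0)
        assert res.significant[0]
        # one-SNP table: percentage is 0 or 100 and the procedure is defined
        assert res.observed_percent in (0.0, 100.0)
        assert 0.0 < res.tablewise_p <= 1.0

    def test_null_rejection_rate_near_alpha(self):
        data, g1, g2 = null_dataset(11, n_per_group=30, n_snps=500)
        res = mc.mc_difference_test(data, g1, g2, n_reps=800, seed=3)
        frac = res.significant[res.testable].mean()
        assert 0.02 <= frac <= 0.09

    def test_permutation_resampling_tablewise_p_spreads(self):
        # the without-replacement null makes the observed split exchangeable
        # with the replicates, so table-wise p covers the unit interval
        ps = []
        for k in range(30):
            data, g1, g2 = null_dataset(500 + k, n_per_group=25, n_snps=300)
            r = mc.mc_difference_test(data, g1, g2, n_reps=400, seed=k,
                                      resample="permutation")
            ps.append(r.tablewise_p)
        assert min(ps) < 0.2 and max(ps) > 0.8
        frac = r.significant[r.testable].mean()
        assert 0.0 <= frac <= 0.12

    def test_unknown_resample_mode_rejected(self, small_survey):
        ids = small_survey.metadata["sample_id"].tolist()
        with pytest.raises(ValueError, match="resample"):
            mc.mc_difference_test(small_survey.data, ids[:5], ids[5:10],
                                  n_reps=10, resample="jackknife")

    def test_tablewise_requires_retained_draws(self, small_survey):
        ids = small_survey.metadata["sample_id"].tolist()
        res = mc.mc_difference_test(small_survey.data, ids[:10], ids[10:20],
                                    n_reps=120, seed=2, keep_null=False)
        assert res.tablewise_p is None
        with pytest.raises(ValueError, match="not retained"):
            mc.tablewise_excess_test(res)


class TestResamplingPreservesLd:
    def test_null_interchromosomal_ld_matches_pooled_sample(self, rng):
        # resampling whole individuals keeps multi-locus structure: the mean
        # |delta| difference between pooled and resampled pairs stays small
        n, S = 120, 30
        block = rng.binomial(1, 0.5, (n, 1))
        D = np.where(rng.random((n, S)) < 0.8, block, rng.binomial(2, 0.5, (n, S))).astype(float)
        delta_pool, _, _ = ld.pairwise_composite_ld(D)
        diffs = []
        for _ in range(200):
            idx = rng.integers(0, n, n)
            delta_rep, _, _ = ld.pairwise_composite_ld(D[idx])
            diffs.append(np.nanmean(np.abs(delta_rep - delta_pool)))
        assert np.mean(diffs) < 0.02


class TestMcRegression:
    def test_self_regression_is_perfect_and_minimal_p(self, small_survey):
        ids = small_survey.metadata["sample_id"].tolist()
        g1, g2 = ids[:20], ids[20:40]
        pool = small_survey.data.subset(g1 + g2)
        dos = posterior_dosages(pool, allele_frequencies(pool))
        p1 = np.nanmean(dos[:20], axis=0) / 2
        p2 = np.nanmean(dos[20:], axis=0) / 2
        predictor = p1 - p2
        r2, p, null = mc.mc_regression_significance(
            small_survey.data, g1, g2, predictor, n_reps=200, seed=0
        )
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert p == pytest.approx(1.0 / 201.0)

    def test_too_few_snps_error(self, small_survey):
        ids = small_survey.metadata["sample_id"].tolist()
        predictor = np.full(small_survey.data.n_snps, np.nan)
        with pytest.raises(ValueError, match="fewer than 3"):
            mc.mc_regression_significance(small_survey.data, ids[:5], ids[5:10],
                                          predictor, n_reps=10, seed=0)

    def test_null_predictor_rejection_rate(self):
        # independent predictor: rejections at alpha=0.05 should be rare
        rejections = 0
        n_sets = 40
        for k in range(n_sets):
            data, g1, g2 = null_dataset(100 + k, n_per_group=25, n_snps=150)
            rng = np.random.default_rng(k)
            predictor = rng.normal(0, 1, 150)
            _, p, _ = mc.mc_regression_significance(data, g1, g2, predictor,
                                                    n_reps=200, seed=k)
            rejections += p < 0.05
        assert rejections <= 7  # ~5% expected; allow binomial slack

    def test_planted_shared_architecture_detected(self):
        # same SNPs carry the group shift and the predictor effect
        rng = np.random.default_rng(0)
        n_snps, n = 400, 50
        delta = np.zeros(n_snps)
        effect = rng.random(n_snps) < 0.5
        delta[effect] = 0.2 * np.where(rng.random(effect.sum()) < 0.5, 1, -1)
        p_base = rng.uniform(0.3, 0.7, n_snps)
        g1 = rng.binomial(2, np.clip(p_base + delta / 2, 0.01, 0.99), (n, n_snps))
        g2 = rng.binomial(2, np.clip(p_base - delta / 2, 0.01, 0.99), (n, n_snps))
        L = certain_likelihoods(np.concatenate([g1, g2]))
        data = GenotypeData(L, np.zeros((2 * n, n_snps), bool),
                            [f"s{i}" for i in range(2 * n)],
                            [f"snp{j}" for j in range(n_snps)])
        predictor = delta + rng.normal(0, 0.05, n_snps)
        _, p, _ = mc.mc_regression_significance(
            data, data.samples[:n], data.samples[n:], predictor, n_reps=300, seed=1
        )
        assert p < 0.05
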
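"""Kinship, PCA, the two genome scans, thresholds, and subsampling variance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polypar.poly_composition import GenotypeMatrix, base_phenotype
from polypar.structure_scan import (
    ThresholdConfig,
    allele_switch_threshold,
    bonferroni_threshold,
    compute_kinship,
    corr_phenotype_pc,
    flag_tas,
    linear_scan,
    mixed_scan,
    pca,
    subsample_variance,
)
from polypar.synthetic_data import PopSimConfig, simulate_populations


def _random_dosage(seed, n, m, missing=0.0):
    rng = np.random.default_rng(seed)
    d = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing:
        d[rng.random((n, m)) < missing] = -1
    return d


class TestKinship:
    def test_matches_double_loop_oracle(self):
        d = _random_dosage(0, 5, 20)
        K = compute_kinship(d)
        X = d.astype(float)
        p = X.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        Z = X[:, keep] - 2 * p[keep]
        denom = 2 * np.sum(p[keep] * (1 - p[keep]))
        expected = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                expected[i, j] = np.sum(Z[i] * Z[j]) / denom
        assert np.allclose(K, expected)

    def test_identical_samples_share_diagonal_value(self):
        d = _random_dosage(1, 3, 30)
        d = np.vstack([d, d[0]])  # sample 3 duplicates sample 0
        K = compute_kinship(d)
        assert K[0, 3] == pytest.approx(K[0, 0])
        assert K[3, 3] == pytest.approx(K[0, 0])

    def test_duplicated_sample_set_has_block_structure(self):
        d = _random_dosage(2, 4, 50)
        K = compute_kinship(np.vstack([d, d]))
        for i in range(4):
            assert K[i, i + 4] == pytest.approx(K[i, i])
            off = np.delete(K[i], [i, i + 4])
            assert K[i, i + 4] > off.max()

    def test_monomorphic_only_errors(self):
        with pytest.raises(ValueError):
            compute_kinship(np.zeros((4, 10), dtype=np.int8))

    def test_allele_sharing_option(self):
        d = _random_dosage(3, 4, 25)
        K = compute_kinship(d, method="allele_sharing")
        assert np.allclose(K, K.T)
        assert np.all(np.diag(K) == 1.0)


class TestPCA:
    def test_two_groups_separate_on_pc1(self):
        pop = simulate_populations(PopSimConfig(seed=0, n_basal=20, n_derived=30, n_snps=2000))
        res = pca(pop.genotypes, k=3)
        pc1 = res.pc(1)
        basal, derived = pc1[:20], pc1[20:]
        assert max(basal.min(), derived.min()) > min(basal.max(), derived.max()) or \
               min(basal.max(), derived.max()) < max(basal.min(), derived.min())
        # no overlap between group score ranges
        assert basal.max() < derived.min() or derived.max() < basal.min()

    def test_permuting_samples_permutes_scores(self):
        d = _random_dosage(4, 10, 60)
        res = pca(d, k=4)
        perm = np.random.default_rng(5).permutation(10)
        res_p = pca(d[perm], k=4)
        # scores may flip sign per component
        for j in range(4):
            col, colp = res.scores[perm, j], res_p.scores[:, j]
            assert np.allclose(col, colp, atol=1e-8) or np.allclose(col, -colp, atol=1e-8)

    def test_rank_one_structure_has_single_eigenvalue(self):
        u = np.array([0, 0, 0, 2, 2, 2], dtype=np.int8)
        d = np.tile(u[:, None], (1, 30))
        res = pca(d, k=3)
        assert res.eigenvalues[0] > 1e-6
        assert np.all(res.eigenvalues[1:] < 1e-8)

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError):
            pca(_random_dosage(6, 5, 50), k=6)

    def test_eigenvalues_non_increasing_and_scores_orthogonal(self):
        d = _random_dosage(7, 12, 80, missing=0.05)
        res = pca(d, k=5)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)
        G = res.scores.T @ res.scores
        assert np.allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-6)


class TestCorrPhenotypePC:
    def test_phenotype_equal_to_pc1_gives_unit_correlation(self):
        d = _random_dosage(8, 15, 100)
        res = pca(d, k=2)
        assert corr_phenotype_pc(res.pc(1), res, 1) == pytest.approx(1.0)

    def test_zero_variance_errors(self):
        d = _random_dosage(9, 8, 40)
        res = pca(d, k=2)
        with pytest.raises(ValueError):
            corr_phenotype_pc(np.ones(8), res, 1)

    def test_trait_tracks_pc1_and_shuffled_phenotype_is_null(self):
        # strong-divergence settings: enough sites that the within-group
        # site-sampling noise is small next to the group separation
        pop = simulate_populations(PopSimConfig(seed=1, n_basal=25, n_derived=50,
                                                n_snps=15_000))
        ph = base_phenotype(pop.variants, pop.genotypes)
        res = pca(pop.genotypes, k=1)
        y = ph["frac_a"].to_numpy()
        r_true = abs(corr_phenotype_pc(y, res, 1))
        rng = np.random.default_rng(0)
        r_null = [abs(corr_phenotype_pc(rng.permutation(y), res, 1)) for _ in range(50)]
        assert r_true > 0.9  # bottleneck + AT bias: trait tracks PC1
        assert np.quantile(r_null, 0.95) < 0.5


class TestLinearScan:
    def test_constant_phenotype_gives_zero_f(self):
        d = _random_dosage(10, 12, 20)
        scan = linear_scan(np.ones(12), d)
        assert np.allclose(scan["F"], 0.0)

    def test_group_fixed_snp_equals_anova_oracle(self):
        rng = np.random.default_rng(11)
        g = np.array([0] * 10 + [2] * 10, dtype=np.int8)
        y = np.where(g == 0, 0.0, 1.0) + rng.normal(0, 0.5, 20)
        scan = linear_scan(y, g[:, None])
        f_oracle, _ = stats.f_oneway(y[g == 0], y[g == 2])
        assert scan["F"][0] == pytest.approx(f_oracle)

    def test_affine_dosage_and_phenotype_invariance(self):
        rng = np.random.default_rng(12)
        d = _random_dosage(13, 15, 25)
        y = rng.normal(size=15)
        f1 = linear_scan(y, d)["F"]
        f2 = linear_scan(3.0 * y - 1.0, d.astype(float) / 2.0)["F"]
        assert np.allclose(f1, f2)

    def test_collinear_covariates_error_names_offender(self):
        d = _random_dosage(14, 10, 5)
        cov = np.ones((10, 2))
        cov[:, 0] = np.arange(10)
        cov[:, 1] = 2 * np.arange(10)
        with pytest.raises(ValueError, match="covariate 2"):
            linear_scan(np.random.default_rng(0).normal(size=10), d, covariates=cov)

    def test_p_suppression(self):
        d = _random_dosage(15, 10, 5)
        scan = linear_scan(np.random.default_rng(1).normal(size=10), d, report_p=False)
        assert scan["p"].isna().all()


class TestMixedScan:
    def test_identity_kinship_reduces_to_ols(self):
        rng = np.random.default_rng(16)
        d = _random_dosage(17, 20, 30)
        y = rng.normal(size=20)
        cov = rng.normal(size=(20, 2))
        lin = linear_scan(y, d, covariates=cov)
        mix, vc = mixed_scan(y, d, np.eye(20), covariates=cov)
        assert np.allclose(mix["F"], lin["F"], rtol=1e-8)

    def test_h2_zero_reproduces_linear_scan_exactly(self):
        rng = np.random.default_rng(18)
        d = _random_dosage(19, 15, 20)
        y = rng.normal(size=15)
        cov = rng.normal(size=(15, 2))
        K = compute_kinship(d)
        lin = linear_scan(y, d, covariates=cov)
        mix, vc = mixed_scan(y, d, K, covariates=cov, h2=0.0)
        assert np.allclose(mix["F"], lin["F"], rtol=1e-10)
        assert vc["h2"] == 0.0

    def test_variance_components_match_grid_search_oracle(self):
        """n = 12 toy data: REML h2 from the scan matches an independent
        dense-grid maximization of the restricted likelihood computed from
        first principles (explicit V, error-contrast density)."""
        rng = np.random.default_rng(20)
        n = 12
        d = _random_dosage(21, n, 40)
        K = compute_kinship(d)
        lam, U = np.linalg.eigh(K)
        lam = np.maximum(lam, 0)
        # simulate y with a genetic component so h2 is interior
        g = U @ (np.sqrt(lam) * rng.normal(size=n))
        y = 2.0 + 1.5 * g + rng.normal(size=n)
        X = np.ones((n, 1))

        def reml_loglik(h2):
            V = h2 * K + (1 - h2) * np.eye(n)
            Vi = np.linalg.inv(V)
            XtVX = X.T @ Vi @ X
            beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
            r = y - X @ beta
            q = float(r @ Vi @ r)
            s2 = q / (n - 1)
            _, ldV = np.linalg.slogdet(V)
            _, ldX = np.linalg.slogdet(XtVX)
            return -0.5 * ((n - 1) * np.log(s2) + ldV + ldX + (n - 1))

        grid = np.linspace(0, 0.999, 20_000)
        oracle_h2 = grid[int(np.argmax([reml_loglik(h) for h in grid]))]
        _, vc = mixed_scan(y, d, K)
        assert vc["h2"] == pytest.approx(oracle_h2, abs=1e-3)

    def test_asymmetric_kinship_rejected(self):
        d = _random_dosage(22, 8, 10)
        K = np.eye(8)
        K[0, 1] = 0.5
        with pytest.raises(ValueError):
            mixed_scan(np.zeros(8), d, K)


class TestThresholds:
    def test_bonferroni_reproduces_genomewide_values(self):
        thr, neglog = bonferroni_threshold(7_003_981, 0.05)
        assert float(f"{thr:.0e}") == pytest.approx(7e-9)
        assert round(neglog, 1) == 8.1

    @pytest.mark.parametrize("m, alpha, expected", [(1, 0.05, 0.05), (100, 0.05, 5e-4)])
    def test_bonferroni_direct_division(self, m, alpha, expected):
        assert bonferroni_threshold(m, alpha)[0] == pytest.approx(expected)

    def test_bonferroni_validation(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)
        with pytest.raises(ValueError):
            bonferroni_threshold(10, alpha=1.0)

    def _pheno_and_groups(self, seed=0, n_b=30, n_d=60):
        pop = simulate_populations(PopSimConfig(seed=seed, n_basal=n_b, n_derived=n_d,
                                                n_snps=3000))
        ph = base_phenotype(pop.variants, pop.genotypes)
        return ph["frac_a"].to_numpy(), pop.groups

    def test_zero_proportion_returns_unswitched_f_every_rep(self):
        y, groups = self._pheno_and_groups()
        cfg = ThresholdConfig(proportions=(0.0,), reps=20, seed=1)
        res = allele_switch_threshold(y, groups, cfg)
        Fs = res["distributions"][0.0]
        assert np.allclose(Fs, Fs[0])
        assert res["unswitched_F"] == pytest.approx(Fs[0])

    def test_mean_f_non_increasing_in_switching_proportion(self):
        y, groups = self._pheno_and_groups(seed=2)
        cfg = ThresholdConfig(proportions=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
                              reps=200, seed=3)
        res = allele_switch_threshold(y, groups, cfg)
        means = res["table"]["mean_F"].to_numpy()
        assert np.all(np.diff(means) <= 0.05 * means[0])  # sampling noise aside

    def test_half_switched_is_group_uninformative(self):
        """Flipping exactly half the samples makes the pseudo-SNP marginally
        independent of the group, so its F collapses to the central-F scale
        of a shuffled-genotype null. (Exact distributional equality with an
        unconstrained random SNP does not hold: drawing the flip set without
        replacement couples the pseudo-SNP's allele count to its residual
        group alignment, making it slightly more balanced than a free draw,
        so the comparison is on location, not by a two-sample KS test.)"""
        y, groups = self._pheno_and_groups(seed=4)
        cfg = ThresholdConfig(proportions=(0.0, 0.5), reps=400, seed=5)
        res = allele_switch_threshold(y, groups, cfg)
        half = res["distributions"][0.5]
        unswitched = res["unswitched_F"]
        rng = np.random.default_rng(6)
        n = len(y)
        g0 = np.where(np.asarray(groups) == "derived", 2.0, 0.0)
        null = []
        yc = y - y.mean()
        for _ in range(400):
            g = rng.permutation(g0)  # shuffled-genotype null
            gc = g - g.mean()
            expl = (gc @ yc) ** 2 / (gc @ gc)
            null.append(expl / (((yc @ yc) - expl) / (n - 2)))
        null = np.array(null)
        assert np.median(half) < np.quantile(null, 0.75)
        assert np.quantile(half, 0.975) < unswitched / 20

    def test_proportion_above_half_rejected(self):
        with pytest.raises(ValueError):
            ThresholdConfig(proportions=(0.6,))

    def test_flag_tas_rules(self):
        scan = pd.DataFrame({"F": [1.0, 10.0], "p": [0.5, 1e-9]})
        assert flag_tas(scan, 5.0, on="F")["is_tas"].tolist() == [False, True]
        assert flag_tas(scan, 1e-8, on="p")["is_tas"].tolist() == [False, True]


class TestSubsampleVariance:
    def _sim(self, seed=0, **kw):
        pop = simulate_populations(PopSimConfig(seed=seed, n_basal=25, n_derived=50,
                                                n_snps=2000, **kw))
        return pop.variants, pop.genotypes, pop.groups

    def test_full_set_equals_full_data_fraction(self):
        variants, genotypes, groups = self._sim()
        out = subsample_variance(variants, genotypes, groups, [genotypes.n_variants])
        ph = base_phenotype(variants, genotypes)
        from polypar.structure_scan import _variance_fraction

        full = _variance_fraction(ph["frac_a"].to_numpy(),
                                  groups.reindex(genotypes.samples).to_numpy())
        assert out["mean_fraction"].iloc[0] == pytest.approx(full)
        assert out["sd_fraction"].iloc[0] == 0.0

    def test_variance_fraction_grows_with_site_count_under_structure(self):
        variants, genotypes, groups = self._sim(seed=1)
        out = subsample_variance(variants, genotypes, groups,
                                 [10, 100, 1000], reps=15, seed=2)
        means = out["mean_fraction"].to_numpy()
        assert means[0] < means[1] < means[2]

    def test_unstructured_population_stays_near_null(self):
        variants, genotypes, groups = self._sim(seed=3, at_bias=1.0, bottleneck=None)
        out = subsample_variance(variants, genotypes, groups,
                                 [50, 500, 2000], reps=15, seed=4)
        assert np.all(out["mean_fraction"] < 0.2)

    def test_small_k_and_oversized_k_error(self):
        variants, genotypes, groups = self._sim(seed=5)
        with pytest.raises(ValueError):
            subsample_variance(variants, genotypes, groups, [1])
        with pytest.raises(ValueError):
            subsample_variance(variants, genotypes, groups, [genotypes.n_variants + 1])
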
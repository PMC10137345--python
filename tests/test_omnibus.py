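"""Combined-Z omnibus test, covariance estimation, Holm correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from genassoc import (
    PhenotypeSpec,
    SimulationConfig,
    SnpSpec,
    ValidationError,
    ZCovariance,
    ZVector,
    estimate_z_covariance,
    holm_bonferroni,
    omnibus_test,
    simulate_cohort,
    univariate_z,
    z_vector,
)
from genassoc.omnibus import score_contribution_covariance


def _null_cohort(seed, n=300, n_snps=2, mean_shift=0.0):
    """No genotype effect; optional group-level mean shift on every trait."""
    snps = [SnpSpec(f"rs{i}", "G", "T", "C", 0.4, 0.4) for i in range(n_snps)]
    phen = [
        PhenotypeSpec("SBP", 135, 15, 135 + mean_shift, 15),
        PhenotypeSpec("DBP", 85, 10, 85 + mean_shift * 10 / 15, 10),
        PhenotypeSpec("BMR", 1350, 120, 1350 + mean_shift * 120 / 15, 120),
    ]
    return simulate_cohort(
        SimulationConfig(n_lean=n, n_obese=n, snps=snps, phenotypes=phen, seed=seed)
    )


class TestUnivariateZ:
    def test_identical_groups_near_zero(self, rng):
        x = rng.normal(size=200)
        assert abs(univariate_z(x, x)) < 1e-12

    def test_antisymmetric_under_group_swap(self, rng):
        x, y = rng.normal(0.5, 1, 80), rng.normal(0, 1, 60)
        assert univariate_z(x, y) == pytest.approx(-univariate_z(y, x))

    def test_positive_when_cases_larger(self, rng):
        z = univariate_z(rng.normal(2, 1, 100), rng.normal(0, 1, 100))
        assert z > 3

    def test_approximately_standard_normal_under_null(self, rng):
        zs = [univariate_z(rng.normal(size=60), rng.normal(size=60)) for _ in range(500)]
        assert np.mean(zs) == pytest.approx(0.0, abs=0.15)
        assert np.std(zs) == pytest.approx(1.0, abs=0.12)


class TestZVector:
    def test_labels_cross_snps_and_phenotypes(self):
        cohort = _null_cohort(seed=1)
        zvec = z_vector(cohort.genotypes, cohort.phenotypes,
                        phenotype_names=["SBP", "DBP"])
        assert len(zvec.labels) == 4
        assert ("rs0", "SBP") in zvec.labels

    def test_undersized_comparison_excluded_with_reason(self):
        cohort = _null_cohort(seed=2, n=200)
        gm = cohort.genotypes
        # make rs0 carriers vanishingly rare
        gm.data["rs0"] = ["TT"] * (len(gm.data) - 2) + ["TC", "TC"]
        zvec = z_vector(gm, cohort.phenotypes, phenotype_names=["SBP"])
        excluded_labels = [lbl for lbl, _ in zvec.excluded]
        assert ("rs0", "SBP") in excluded_labels
        assert ("rs1", "SBP") in zvec.labels


class TestCovariance:
    def test_fixed_seed_reproducible(self):
        cohort = _null_cohort(seed=3, n=150)
        zvec = z_vector(cohort.genotypes, cohort.phenotypes, phenotype_names=["SBP", "DBP"])
        cov1 = estimate_z_covariance(cohort.genotypes, cohort.phenotypes, zvec.labels,
                                     n_resamples=150, seed=9)
        cov2 = estimate_z_covariance(cohort.genotypes, cohort.phenotypes, zvec.labels,
                                     n_resamples=150, seed=9)
        assert np.array_equal(cov1.matrix, cov2.matrix)

    def test_duplicated_label_perfectly_correlated(self):
        cohort = _null_cohort(seed=4, n=150)
        labels = [("rs0", "SBP"), ("rs0", "SBP")]
        cov = estimate_z_covariance(cohort.genotypes, cohort.phenotypes, labels,
                                    n_resamples=150, seed=1)
        assert cov.correlation[0, 1] == pytest.approx(1.0)

    def test_independent_snps_weakly_correlated(self):
        cohort = _null_cohort(seed=5, n=2000)
        labels = [("rs0", "SBP"), ("rs1", "DBP")]
        cov = estimate_z_covariance(cohort.genotypes, cohort.phenotypes, labels,
                                    n_resamples=500, seed=2)
        assert abs(cov.correlation[0, 1]) < 0.1

    def test_unit_diagonal_and_symmetry(self):
        cohort = _null_cohort(seed=6, n=150)
        zvec = z_vector(cohort.genotypes, cohort.phenotypes)
        cov = estimate_z_covariance(cohort.genotypes, cohort.phenotypes, zvec.labels,
                                    n_resamples=120, seed=3)
        assert np.allclose(np.diag(cov.correlation), 1.0)
        assert np.allclose(cov.matrix, cov.matrix.T, atol=1e-12)

    def test_too_few_resamples_rejected(self):
        cohort = _null_cohort(seed=7, n=100)
        with pytest.raises(ValidationError):
            estimate_z_covariance(cohort.genotypes, cohort.phenotypes,
                                  [("rs0", "SBP")], n_resamples=10)

    def test_score_contribution_estimator_close_to_bootstrap(self):
        """Shared-phenotype labels must correlate under both estimators."""
        cohort = _null_cohort(seed=8, n=800)
        labels = [("rs0", "SBP"), ("rs1", "SBP")]
        boot = estimate_z_covariance(cohort.genotypes, cohort.phenotypes, labels,
                                     n_resamples=400, seed=4)
        plug = score_contribution_covariance(cohort.genotypes, cohort.phenotypes, labels)
        assert plug.estimator == "score_contributions"
        assert plug.correlation[0, 1] == pytest.approx(boot.correlation[0, 1], abs=0.15)
        assert plug.correlation[0, 1] > 0.3  # shared subjects and trait


class TestOmnibusStatistic:
    def test_k1_reduces_to_univariate(self):
        z = ZVector(labels=[("rs0", "SBP")], z=[1.7], source=["mw"])
        cov = np.array([[1.0]])
        expected = 2 * stats.norm.sf(1.7)
        assert omnibus_test(z, cov, "sum").p_value == pytest.approx(expected, rel=1e-12)
        assert omnibus_test(z, cov, "quadratic").p_value == pytest.approx(expected, rel=1e-12)

    def test_closed_form_two_dimensional(self):
        z = ZVector(labels=[("a", "p"), ("b", "p")], z=[1.96, 1.96])
        res_sum = omnibus_test(z, np.eye(2), "sum")
        assert res_sum.statistic == pytest.approx(2 * 1.96 / np.sqrt(2), abs=1e-3)
        assert res_sum.p_value == pytest.approx(0.0056, abs=2e-4)
        res_q = omnibus_test(z, np.eye(2), "quadratic")
        assert res_q.statistic == pytest.approx(7.68, abs=0.01)
        assert res_q.p_value == pytest.approx(0.0215, abs=2e-4)

    def test_label_permutation_invariance(self, rng):
        k = 5
        z = rng.normal(size=k)
        a = rng.normal(size=(k, k))
        cov = a @ a.T + np.eye(k)
        perm = rng.permutation(k)
        zv = ZVector(labels=[("s", str(i)) for i in range(k)], z=z)
        zp = ZVector(labels=[("s", str(i)) for i in perm], z=z[perm])
        for method in ("sum", "quadratic"):
            r1 = omnibus_test(zv, cov, method)
            r2 = omnibus_test(zp, cov[np.ix_(perm, perm)], method)
            assert r2.statistic == pytest.approx(r1.statistic)

    def test_rank_deficient_covariance_flagged(self):
        z = ZVector(labels=[("a", "p"), ("b", "p")], z=[1.0, 1.0])
        cov = np.ones((2, 2))  # rank 1
        res = omnibus_test(z, cov, "quadratic")
        assert res.rank_deficient and res.df == 1

    def test_dimension_mismatch_rejected(self):
        z = ZVector(labels=[("a", "p")], z=[1.0])
        with pytest.raises(ValidationError):
            omnibus_test(z, np.eye(2), "sum")

    def test_non_psd_covariance_rejected(self):
        z = ZVector(labels=[("a", "p"), ("b", "p")], z=[1.0, 1.0])
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValidationError, match="resamples"):
            omnibus_test(z, bad, "sum")

    def test_cohort_null_rejection_rate(self):
        """Full pipeline (cohort -> z -> bootstrap cov -> test) near alpha."""
        rejections = {"sum": 0, "quadratic": 0}
        n_rep = 120
        for seed in range(n_rep):
            cohort = _null_cohort(seed=1000 + seed, n=80)
            zvec = z_vector(cohort.genotypes, cohort.phenotypes)
            cov = estimate_z_covariance(
                cohort.genotypes, cohort.phenotypes, zvec.labels,
                n_resamples=120, seed=seed,
            )
            for method in rejections:
                if omnibus_test(zvec, cov, method).p_value < 0.05:
                    rejections[method] += 1
        # binomial(120, 0.05): central 99.9% region is roughly [0, 15]
        for method, count in rejections.items():
            assert count <= 15, f"{method}: {count}/{n_rep} null rejections"


class TestHolm:
    def test_hand_computed_step_down(self):
        res = holm_bonferroni([0.001, 0.8, 0.9, 0.9])
        assert res.adjusted_p == pytest.approx([0.004, 1.0, 1.0, 1.0])
        res2 = holm_bonferroni([0.01, 0.04])
        assert res2.adjusted_p == pytest.approx([0.02, 0.04])

    def test_all_ones(self):
        res = holm_bonferroni([1.0, 1.0, 1.0])
        assert np.all(res.adjusted_p == 1.0) and not res.rejected.any()

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_dominates_bonferroni_and_is_monotone(self, ps):
        res = holm_bonferroni(ps)
        m = len(ps)
        bonf = np.minimum(1.0, m * np.asarray(ps))
        assert np.all(res.adjusted_p <= bonf + 1e-12)
        assert np.all(res.adjusted_p >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(res.adjusted_p[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            holm_bonferroni([0.5, 1.5])
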
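"""Mann-Whitney U, joint-genotype stratification, and stratified comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from genassoc import (
    JointEffectSpec,
    PhenotypeSpec,
    SimulationConfig,
    SnpSpec,
    ValidationError,
    compare_phenotypes_across_strata,
    mann_whitney_u,
    simulate_cohort,
    stratify_by_joint_genotype,
    whr_by_bmi_class_table,
)


def brute_force_u(x, y):
    """U as the count of (x_i > y_j) pairs plus half-ties."""
    x, y = np.asarray(x), np.asarray(y)
    return float(np.sum(x[:, None] > y[None, :]) + 0.5 * np.sum(x[:, None] == y[None, :]))


def exact_p_by_rank_splits(x, y):
    """Enumerate every assignment of the pooled ranks to the first sample."""
    pooled = sorted(list(x) + list(y))
    n1 = len(x)
    u_obs = brute_force_u(x, y)
    mu = n1 * len(y) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = brute_force_u(xs, ys)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_complete_separation_small_sample(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)

    def test_identical_multisets(self):
        x = [3.0, 1.0, 2.0, 2.0]
        res = mann_whitney_u(x, list(x))
        assert res.u == len(x) ** 2 / 2
        assert res.p_value == 1.0

    def test_u_plus_u_prime_is_n1_n2(self, rng):
        for _ in range(100):
            x = rng.normal(size=rng.integers(2, 12))
            y = rng.normal(size=rng.integers(2, 12))
            u1 = mann_whitney_u(x, y).u
            u2 = mann_whitney_u(y, x).u
            assert u1 + u2 == pytest.approx(len(x) * len(y))

    def test_u_matches_pair_count_with_ties(self, rng):
        for _ in range(200):
            x = rng.integers(0, 6, size=rng.integers(1, 10)).astype(float)
            y = rng.integers(0, 6, size=rng.integers(1, 10)).astype(float)
            assert mann_whitney_u(x, y).u == pytest.approx(brute_force_u(x, y))

    def test_exact_p_matches_rank_split_enumeration(self, rng):
        for n1, n2 in [(2, 3), (3, 3), (4, 5), (5, 2)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            res = mann_whitney_u(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(exact_p_by_rank_splits(x, y), abs=1e-12)

    def test_ties_fall_back_to_normal_approximation(self):
        res = mann_whitney_u([1.0, 2.0, 2.0], [2.0, 3.0])
        assert res.method == "normal_approx"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


def _two_snp_cohort(shift=0.0, seed=5, n=1000):
    cfg = SimulationConfig(
        n_lean=n, n_obese=n,
        snps=[
            SnpSpec("rsA", "G", "T", "C", 0.4, 0.4),
            SnpSpec("rsB", "G", "C", "T", 0.3, 0.3),
        ],
        phenotypes=[PhenotypeSpec("SBP", 135, 15, 135, 15)],
        joint_effects=(
            [JointEffectSpec("rsA", "TT", "rsB", "CT", "SBP", shift)] if shift else []
        ),
        seed=seed,
    )
    return simulate_cohort(cfg)


class TestStratification:
    def test_partition_of_complete_cases(self):
        cohort = _two_snp_cohort()
        strata = stratify_by_joint_genotype(cohort.genotypes, "rsA", "rsB")
        ids = [s for stratum in strata for s in stratum.sample_ids]
        assert len(ids) == len(set(ids)) == len(cohort.genotypes.data)
        assert len(strata) == 9

    def test_sample_missing_at_either_snp_in_no_stratum(self):
        cohort = _two_snp_cohort(n=50)
        gm = cohort.genotypes
        gm.data.iloc[0, gm.data.columns.get_loc("rsB")] = np.nan
        strata = stratify_by_joint_genotype(gm, "rsA", "rsB")
        dropped = gm.data.index[0]
        assert all(dropped not in s.sample_ids for s in strata)
        assert sum(s.n for s in strata) == len(gm.data) - 1

    def test_matches_simulator_effect_record(self):
        cohort = _two_snp_cohort(shift=10.0)
        strata = stratify_by_joint_genotype(cohort.genotypes, "rsA", "rsB")
        target = next(s for s in strata if (s.genotype_a, s.genotype_b) == ("TT", "CT"))
        assert set(target.sample_ids) == set(cohort.effect_members[0])

    def test_unknown_snp_rejected(self):
        cohort = _two_snp_cohort(n=20)
        with pytest.raises(ValidationError):
            stratify_by_joint_genotype(cohort.genotypes, "rsA", "rsZ")


class TestStratumComparison:
    def test_injected_shift_detected(self):
        cohort = _two_snp_cohort(shift=10.0, n=10_000)
        strata = stratify_by_joint_genotype(cohort.genotypes, "rsA", "rsB")
        labels = {(s.genotype_a, s.genotype_b): s.label for s in strata}
        _, comparisons = compare_phenotypes_across_strata(
            strata, cohort.phenotypes, ["SBP"],
            pairs=[(labels[("TT", "CT")], labels[("TT", "CC")])],
        )
        assert comparisons[0].p_value < 1e-6

    def test_identical_strata_p_one(self):
        from genassoc.compare import JointGenotypeStratum

        phen = pd.DataFrame({"SBP": [1.0, 2.0, 3.0, 4.0, 5.0] * 2},
                            index=[f"s{i}" for i in range(10)])
        s1 = JointGenotypeStratum("a", "TT", "b", "CC", [f"s{i}" for i in range(5)])
        s2 = JointGenotypeStratum("a", "TT", "b", "CT", [f"s{i}" for i in range(5, 10)])
        _, comps = compare_phenotypes_across_strata([s1, s2], phen, ["SBP"])
        assert comps[0].p_value == 1.0

    def test_small_stratum_flagged_and_untested(self):
        from genassoc.compare import JointGenotypeStratum

        phen = pd.DataFrame({"SBP": np.arange(8.0)}, index=[f"s{i}" for i in range(8)])
        small = JointGenotypeStratum("a", "TT", "b", "CC", ["s0", "s1", "s2"])
        big = JointGenotypeStratum("a", "TT", "b", "CT", [f"s{i}" for i in range(3, 8)])
        summaries, comps = compare_phenotypes_across_strata([small, big], phen, ["SBP"])
        assert any(s.low_n for s in summaries if s.stratum == small.label)
        assert comps == []  # fewer than two testable strata -> no comparison


class TestWhrTable:
    def test_empty_cell_rendered_missing(self):
        cohort = _whr_cohort(seed=2, n=400)
        gm = cohort.genotypes
        # wipe out one joint cell entirely
        mask = (gm.data["rsF"] == "TT") & (gm.data["rsP"] == "CT")
        gm.data.loc[mask, "rsP"] = "CC"
        table = whr_by_bmi_class_table(gm, cohort.phenotypes, "rsF", "rsP")
        cell = table[(table["fam_genotype"] == "TT") & (table["ppar_genotype"] == "CT")]
        assert (cell["label"] == "-").all()

    def test_injected_waist_shift_significant_in_target_cell(self):
        cohort = _whr_cohort(seed=3, n=4000, shift=12.0)
        table = whr_by_bmi_class_table(cohort.genotypes, cohort.phenotypes, "rsF", "rsP")
        cell = table[
            (table["bmi_class"] == "lean")
            & (table["fam_genotype"] == "TT")
            & (table["ppar_genotype"] == "CT")
        ]
        assert (cell["p_value"] < 0.05).all()


def _whr_cohort(seed, n, shift=0.0):
    cfg = SimulationConfig(
        n_lean=n, n_obese=n,
        snps=[
            SnpSpec("rsF", "G", "T", "C", 0.4, 0.4),
            SnpSpec("rsP", "G", "C", "T", 0.3, 0.3),
        ],
        phenotypes=[
            PhenotypeSpec("height", 161.8, 5.8, 160.3, 6.0),
            PhenotypeSpec("body_mass", 62.1, 3.0, 87.3, 3.0),
            PhenotypeSpec("waist", 77.7, 7.9, 100.2, 9.2),
            PhenotypeSpec("hip", 97.6, 5.4, 115.2, 8.5),
        ],
        joint_effects=(
            [JointEffectSpec("rsF", "TT", "rsP", "CT", "waist", shift)] if shift else []
        ),
        seed=seed,
    )
    return simulate_cohort(cfg)
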
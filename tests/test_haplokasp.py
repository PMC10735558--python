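"""Haplotype groups, LSD letters, allele profiling and KASP metrics."""

import numpy as np
import pandas as pd
import pytest

from durumwp import haplokasp


@pytest.fixture()
def inbred_calls():
    rng = np.random.default_rng(4)
    dosage = pd.DataFrame(rng.choice([0.0, 2.0], size=(60, 3)),
                          index=[f"g{i:03d}" for i in range(60)],
                          columns=["A", "B", "C"])
    return dosage


class TestBuildHaplotypes:
    def test_extreme_patterns_distinct_groups(self, inbred_calls):
        d = inbred_calls.copy()
        d.iloc[0] = [2.0, 2.0, 2.0]
        d.iloc[1] = [0.0, 0.0, 0.0]
        out = haplokasp.build_haplotypes(d, ["A", "B", "C"], {"A": 1, "B": 1, "C": 1})
        by = out.set_index("genotype_id")
        assert by.loc["g000", "pattern"] == "+++"
        assert by.loc["g001", "pattern"] == "---"
        assert by.loc["g000", "haplotype_id"] != by.loc["g001", "haplotype_id"]
        assert out["pattern"].nunique() <= 8

    def test_partition_is_disjoint_and_exhaustive(self, inbred_calls):
        out = haplokasp.build_haplotypes(inbred_calls, ["A", "B", "C"],
                                         {"A": 1, "B": 1, "C": 1})
        assert out["genotype_id"].is_unique
        assert len(out) == len(inbred_calls)  # all calls complete homozygous

    def test_het_and_missing_excluded(self, inbred_calls):
        d = inbred_calls.copy()
        d.iloc[0, 0] = 1.0
        d.iloc[1, 2] = np.nan
        out = haplokasp.build_haplotypes(d, ["A", "B", "C"], {"A": 1, "B": 1, "C": 1})
        assert "g000" not in set(out["genotype_id"])
        assert "g001" not in set(out["genotype_id"])

    def test_identical_calls_single_group(self):
        d = pd.DataFrame(2.0, index=[f"g{i}" for i in range(10)], columns=["A", "B"])
        out = haplokasp.build_haplotypes(d, ["A", "B"], {"A": 1, "B": 1})
        assert out["haplotype_id"].nunique() == 1

    def test_numbering_by_favorable_allele_count(self, inbred_calls):
        out = haplokasp.build_haplotypes(inbred_calls, ["A", "B", "C"],
                                         {"A": 1, "B": 1, "C": 1})
        ranks = out.groupby("haplotype_id")["n_positive_alleles"].first()
        ordered = ranks.loc[sorted(ranks.index, key=lambda h: int(h[3:]))]
        assert ordered.is_monotonic_decreasing


class TestLsd:
    def test_formula_hand_value(self):
        # MSE=1, n=5 per group, df=8 -> 2.306 * sqrt(0.4) = 1.458
        assert haplokasp.lsd_value(1.0, 8, 5, 5) == pytest.approx(1.458, abs=0.001)

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(0)
        groups = pd.DataFrame({
            "genotype_id": [f"g{i}" for i in range(20)],
            "haplotype_id": ["Hap1"] * 10 + ["Hap2"] * 10,
        })
        y = pd.Series(np.r_[rng.normal(0, 1, 10), rng.normal(10, 1, 10)],
                      index=groups["genotype_id"])
        out = haplokasp.haplotype_effect_test(groups, y)
        letters = out.set_index("haplotype_id")["lsd_letter"]
        assert set(letters["Hap1"]) & set(letters["Hap2"]) == set()

    def test_identical_groups_share_letter(self):
        groups = pd.DataFrame({
            "genotype_id": [f"g{i}" for i in range(12)],
            "haplotype_id": ["Hap1"] * 6 + ["Hap2"] * 6,
        })
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 1, 6)
        y = pd.Series(np.r_[noise, noise], index=groups["genotype_id"])
        out = haplokasp.haplotype_effect_test(groups, y)
        letters = out.set_index("haplotype_id")["lsd_letter"]
        assert set(letters["Hap1"]) & set(letters["Hap2"])

    def test_zero_error_df_raises(self):
        groups = pd.DataFrame({"genotype_id": ["a", "b", "c", "d"],
                               "haplotype_id": ["H1", "H1", "H2", "H2"]})
        y = pd.Series([1.0, 1.0, 2.0, 2.0], index=groups["genotype_id"])
        # zero residual but positive df: should run; force zero df via 1-member
        with pytest.raises(ValueError):
            haplokasp.haplotype_effect_test(groups.iloc[:3], y)


class TestAlleleProfile:
    def blues_for(self, gy_by_geno):
        return pd.DataFrame([dict(genotype_id=g, environment_id="E1", trait="GY", value=v)
                             for g, v in gy_by_geno.items()])

    def test_perfect_dosage_yield_correlation(self):
        d = pd.DataFrame({"A": [0.0, 1.0, 2.0]}, index=["g1", "g2", "g3"])
        blues = self.blues_for({"g1": 1.0, "g2": 2.0, "g3": 3.0})
        out = haplokasp.allele_gy_profile(d, blues, ["A"])
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["significant"].iloc[0]

    def test_sign_flips_with_favorable_designation(self):
        d = pd.DataFrame({"A": [0.0, 1.0, 2.0]}, index=["g1", "g2", "g3"])
        blues = self.blues_for({"g1": 1.0, "g2": 2.0, "g3": 3.0})
        plus = haplokasp.allele_gy_profile(d, blues, ["A"], {"A": +1})
        minus = haplokasp.allele_gy_profile(d, blues, ["A"], {"A": -1})
        assert plus["r"].iloc[0] == pytest.approx(-minus["r"].iloc[0])

    def test_monomorphic_marker_missing(self):
        d = pd.DataFrame({"A": [2.0, 2.0, 2.0]}, index=["g1", "g2", "g3"])
        blues = self.blues_for({"g1": 1.0, "g2": 2.0, "g3": 3.0})
        out = haplokasp.allele_gy_profile(d, blues, ["A"])
        assert np.isnan(out["r"].iloc[0])
        assert not out["significant"].iloc[0]

    def test_null_marker_calibration(self):
        # |r| should exceed the 0.01 critical value ~1% of the time
        rng = np.random.default_rng(2)
        n, reps = 120, 1000
        from scipy import stats
        tcrit = stats.t.ppf(1 - 0.01 / 2, n - 2)
        rcrit2 = tcrit ** 2 / (tcrit ** 2 + n - 2)
        X = rng.choice([0.0, 2.0], size=(n, reps))
        y = rng.normal(size=n)
        Xc = (X - X.mean(0)) / X.std(0)
        yc = (y - y.mean()) / y.std()
        r = Xc.T @ yc / n
        rate = (r ** 2 > rcrit2).mean()
        assert 0.002 < rate < 0.03


class TestKaspValidate:
    def constructed(self, n=100, top_carry=15, worst_carry_minus=18, seed=0):
        rng = np.random.default_rng(seed)
        gy = pd.Series(np.arange(n, dtype=float)[::-1],
                       index=[f"g{i:03d}" for i in range(n)])
        calls = pd.Series(rng.choice([0.0, 2.0], n), index=gy.index, name="M")
        top = gy.sort_values(ascending=False).index[:20]
        worst = gy.sort_values(ascending=False).index[-20:]
        calls.loc[top] = 0.0
        calls.loc[top[:top_carry]] = 2.0
        calls.loc[worst] = 2.0
        calls.loc[worst[:worst_carry_minus]] = 0.0
        return calls, gy

    def test_confusion_matrix_arithmetic(self):
        calls, gy = self.constructed()
        vm = haplokasp.kasp_validate(calls, gy, n_extreme=20)
        assert vm.accuracy == pytest.approx(0.825)
        assert vm.sensitivity == pytest.approx(0.75)
        assert vm.specificity == pytest.approx(0.90)

    def test_perfect_marker_all_ones(self):
        calls, gy = self.constructed(top_carry=20, worst_carry_minus=20)
        vm = haplokasp.kasp_validate(calls, gy, n_extreme=20)
        assert (vm.accuracy, vm.sensitivity, vm.specificity) == (1.0, 1.0, 1.0)

    def test_accuracy_is_mean_of_sens_spec_on_balanced_extremes(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = 60
            gy = pd.Series(rng.normal(size=n), index=[f"g{i:03d}" for i in range(n)])
            calls = pd.Series(rng.choice([0.0, 2.0], n), index=gy.index)
            vm = haplokasp.kasp_validate(calls, gy, n_extreme=20)
            assert vm.accuracy == pytest.approx((vm.sensitivity + vm.specificity) / 2)

    def test_random_calls_mean_accuracy_half(self):
        rng = np.random.default_rng(2)
        accs = []
        for _ in range(300):
            n = 50
            gy = pd.Series(rng.normal(size=n), index=[f"g{i:03d}" for i in range(n)])
            calls = pd.Series(rng.choice([0.0, 2.0], n), index=gy.index)
            accs.append(haplokasp.kasp_validate(calls, gy, n_extreme=20).accuracy)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.03)

    def test_too_few_genotypes_raise(self):
        gy = pd.Series(np.arange(30, dtype=float), index=[f"g{i}" for i in range(30)])
        calls = pd.Series(2.0, index=gy.index)
        with pytest.raises(ValueError):
            haplokasp.kasp_validate(calls, gy, n_extreme=20)

    def test_and_combination_monotonicity(self):
        # AND rule: sensitivity never above, specificity never below any member
        rng = np.random.default_rng(3)
        for rep in range(20):
            n = 60
            gy = pd.Series(rng.normal(size=n), index=[f"g{i:03d}" for i in range(n)])
            dosage = pd.DataFrame(rng.choice([0.0, 2.0], size=(n, 3)),
                                  index=gy.index, columns=["A", "B", "C"])
            out = haplokasp.kasp_validate_panel(dosage, gy, ["A", "B", "C"], n_extreme=20)
            singles = out[out["marker_id"] != "combined_AND"]
            combined = out[out["marker_id"] == "combined_AND"].iloc[0]
            assert combined["sensitivity"] <= singles["sensitivity"].min() + 1e-12
            assert combined["specificity"] >= singles["specificity"].max() - 1e-12

    def test_pooled_denominator_option(self):
        calls, gy = self.constructed()
        vm = haplokasp.kasp_validate(calls, gy, n_extreme=20,
                                     pooled_denominator=True)
        assert vm.sensitivity == pytest.approx(0.375)
        assert vm.specificity == pytest.approx(0.45)
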
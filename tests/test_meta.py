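"""Random-effects pooling, subgroup tests and target regions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumourgrade import meta, synth
from tumourgrade.meta import (
    DegenerateVarianceError,
    RowParseError,
    SchemaError,
    StudyRecord,
    SummaryEstimate,
    derive_target_region,
    dl_pool,
    load_study_table,
    pairwise_tukey,
    pool_by_group,
    subgroup_anova,
)


def rec(study="s", param="ADC_ROI_mean", subtype="pa", grade="I",
        n=10, mean=1.2e-3, sd=0.2e-3):
    return StudyRecord(study, param, subtype, grade, n, mean, sd)


class TestLoadStudyTable:
    def test_bundled_table_counts(self):
        records = load_study_table()
        assert meta.count_studies(records) == 14
        assert meta.count_patients(records, "ADC") == 290
        assert meta.count_patients(records, "CBF") == 252

    def test_header_only_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("study_id,parameter,subtype,who_grade,n,mean,sd\n")
        assert load_study_table(p) == []

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("study_id,parameter,subtype,who_grade,n,mean\nx,ADC_ROI_mean,s,I,1,1e-3\n")
        with pytest.raises(SchemaError, match="sd"):
            load_study_table(p)

    def test_non_numeric_row_reports_index(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "study_id,parameter,subtype,who_grade,n,mean,sd\n"
            "x,ADC_ROI_mean,s,I,1,1e-3,2e-4\n"
            "y,ADC_ROI_mean,s,I,oops,1e-3,2e-4\n"
        )
        with pytest.raises(RowParseError, match="row 1"):
            load_study_table(p)

    def test_unknown_parameter_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("study_id,parameter,subtype,who_grade,n,mean,sd\n"
                     "x,FA,s,I,1,1e-3,2e-4\n")
        with pytest.raises(RowParseError, match="parameter"):
            load_study_table(p)

    def test_adc_on_wrong_scale_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("study_id,parameter,subtype,who_grade,n,mean,sd\n"
                     "x,ADC_ROI_mean,s,I,5,1.2,0.2\n")
        with pytest.raises(RowParseError, match="mm"):
            load_study_table(p)


class TestDlPool:
    def test_single_study_returns_study_mean(self):
        e = dl_pool([rec(n=9, mean=1.2, sd=0.3)])
        assert e.pooled_mean == 1.2
        assert e.tau2 == 0.0
        assert e.ci95 == pytest.approx((1.004, 1.396), abs=1e-9)

    def test_two_study_hand_derived_values(self):
        # frozen from evaluating the moment formulas by hand:
        # v = 0.1^2/1 = 0.01, w = 100 each, Q = 8,
        # tau2 = (8-1)/(200-100) = 0.07, pooled = 1.2, se = 0.2
        records = [rec(study="a", n=1, mean=1.0, sd=0.1),
                   rec(study="b", n=1, mean=1.4, sd=0.1)]
        e = dl_pool(records)
        assert e.tau2 == pytest.approx(0.07, rel=1e-12)
        assert e.pooled_mean == pytest.approx(1.2, rel=1e-12)
        assert e.ci95 == pytest.approx((0.808, 1.592), rel=1e-12)

    def test_identical_studies_reduce_to_fixed_effect(self):
        records = [rec(study=s, n=4, mean=1.1, sd=0.2) for s in "abc"]
        e = dl_pool(records)
        v = 0.2**2 / 4
        assert e.tau2 == 0.0
        assert e.pooled_mean == pytest.approx(1.1)
        assert e.se_pooled == pytest.approx(math.sqrt(v / 3))

    def test_q_below_df_truncates_tau2_to_fixed_effect(self):
        # nearly identical means: Q < k-1, so tau2 = 0 and the pooled mean
        # equals the inverse-variance fixed-effect mean
        records = [rec(study="a", n=10, mean=1.00, sd=0.3),
                   rec(study="b", n=20, mean=1.01, sd=0.3),
                   rec(study="c", n=15, mean=1.005, sd=0.3)]
        e = dl_pool(records)
        w = np.array([10, 20, 15]) / 0.3**2
        m = np.array([1.00, 1.01, 1.005])
        assert e.tau2 == 0.0
        assert e.pooled_mean == pytest.approx(float(np.sum(w * m) / np.sum(w)))

    def test_zero_variance_study_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            dl_pool([rec(study="a", sd=0.0), rec(study="b")])

    def test_empty_and_mixed_parameter_inputs_rejected(self):
        with pytest.raises(ValueError):
            dl_pool([])
        with pytest.raises(ValueError, match="parameter"):
            dl_pool([rec(), rec(study="b", param="nCBF_ROI_max", mean=1.5, sd=0.4)])

    def test_se_scales_as_inverse_sqrt_k(self):
        """Equal variances, zero heterogeneity: se ~ 1/sqrt(k)."""
        def se(k):
            return dl_pool([rec(study=f"s{i}", n=10, mean=1.0, sd=0.3)
                            for i in range(k)]).se_pooled
        assert se(4) == pytest.approx(se(1) / 2)
        assert se(9) == pytest.approx(se(1) / 3)

    @given(st.lists(st.tuples(st.floats(0.5, 2.0), st.floats(0.05, 0.5),
                              st.integers(2, 50)),
                    min_size=1, max_size=8))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_pooled_mean_within_study_mean_range(self, specs):
        records = [rec(study=f"s{i}", mean=m, sd=s, n=n)
                   for i, (m, s, n) in enumerate(specs)]
        e = dl_pool(records)
        means = [r.mean for r in records]
        assert min(means) - 1e-12 <= e.pooled_mean <= max(means) + 1e-12
        lo, hi = e.ci95
        assert lo <= e.pooled_mean <= hi
        assert hi - lo == pytest.approx(2 * 1.96 * e.se_pooled)


class TestPoolByGroup:
    def test_two_singleton_subtypes(self):
        records = [rec(study="a", subtype="pa", mean=1.4e-3),
                   rec(study="b", subtype="mb", grade="IV", mean=0.7e-3)]
        ests = pool_by_group(records, "subtype")
        assert {e.group: e.pooled_mean for e in ests} == {
            "mb": 0.7e-3, "pa": 1.4e-3}
        assert all(e.k == 1 for e in ests)

    def test_group_below_min_patients_omitted(self):
        records = [rec(study="a", subtype="pa", n=10),
                   rec(study="b", subtype="rare", n=1, mean=1.0e-3)]
        groups = {e.group for e in pool_by_group(records, "subtype")}
        assert groups == {"pa"}

    def test_unknown_grade_excluded_not_error(self):
        records = [rec(study="a", grade="I"), rec(study="b", grade="unknown")]
        ests = pool_by_group(records, "binary_grade")
        assert len(ests) == 1 and ests[0].group == "low"

    def test_binary_mapping(self):
        records = [rec(study=s, grade=g, n=5)
                   for s, g in zip("abcd", ["I", "II", "III", "IV"])]
        ests = pool_by_group(records, "binary_grade")
        assert {e.group: e.N for e in ests} == {"low": 10, "high": 10}

    def test_order_invariance(self):
        records = [rec(study=f"s{i}", subtype="pa", mean=(1.0 + 0.1 * i) * 1e-3,
                       sd=0.2e-3, n=5 + i) for i in range(6)]
        a = pool_by_group(records, "subtype")
        b = pool_by_group(records[::-1], "subtype")
        assert a == b

    def test_recovers_known_subtype_means(self):
        """Pooled 95% CIs cover the generating truth in most replicates."""
        truth = {"pa": 1.4e-3, "mb": 0.7e-3}
        hits = total = 0
        for seed in range(200):
            # 9 studies per group: the scale of the pooled ADC literature
            table = synth.gen_study_table(truth, tau=0.08e-3, k_per_group=9,
                                          seed=seed)
            for e in pool_by_group(table, "subtype"):
                total += 1
                hits += e.ci95[0] <= truth[e.group] <= e.ci95[1]
        assert 0.90 <= hits / total <= 0.99

    def test_shared_tau2_mode(self):
        records = [rec(study=f"s{i}", subtype="pa",
                       mean=(1.2 + 0.2 * (i % 3)) * 1e-3, n=8)
                   for i in range(4)]
        records += [rec(study=f"t{i}", subtype="mb", grade="IV",
                        mean=(0.7 + 0.1 * i) * 1e-3, n=8) for i in range(3)]
        shared = pool_by_group(records, "subtype", tau2_share="modality")
        assert len({e.tau2 for e in shared}) == 1


class TestSubgroupAnova:
    def _est(self, group, mu, se):
        return SummaryEstimate(group=group, parameter="ADC_ROI_mean", k=2,
                               N=10, pooled_mean=mu, tau2=0.0, se_pooled=se,
                               ci95=(mu - 1.96 * se, mu + 1.96 * se))

    def test_identical_means_give_zero_q(self):
        q, df, p = subgroup_anova([self._est("a", 1.0, 0.1),
                                   self._est("b", 1.0, 0.2)])
        assert q == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_group_q(self):
        # mu_hat = 1.5, each term 100 * 0.25 -> Q = 50, df = 1
        q, df, p = subgroup_anova([self._est("a", 1.0, 0.1),
                                   self._est("b", 2.0, 0.1)])
        assert q == pytest.approx(50.0)
        assert df == 1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            subgroup_anova([self._est("a", 1.0, 0.1)])

    def test_zero_se_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            subgroup_anova([self._est("a", 1.0, 0.0), self._est("b", 2.0, 0.1)])


class TestPairwiseTukey:
    def _est(self, group, mu, se=0.1):
        return SummaryEstimate(group=group, parameter="ADC_ROI_mean", k=2,
                               N=10, pooled_mean=mu, tau2=0.0, se_pooled=se,
                               ci95=(mu - 1.96 * se, mu + 1.96 * se))

    def test_identical_groups_all_p_one(self):
        t = pairwise_tukey([self._est(g, 1.0) for g in "abc"])
        assert len(t) == 3
        assert (t["adjusted_p"] > 0.999).all()

    def test_two_groups_reduce_to_unadjusted_two_sided_p(self):
        from scipy.stats import norm
        t = pairwise_tukey([self._est("a", 1.0), self._est("b", 1.3)])
        z = 0.3 / math.hypot(0.1, 0.1)
        assert t["adjusted_p"].iloc[0] == pytest.approx(2 * norm.sf(z), rel=1e-6)

    def test_published_critical_value_k3(self):
        """At the tabulated 5% studentized-range critical value q(3, inf)=3.314
        the adjusted p is 0.05."""
        se = 0.1
        delta = 3.314 / math.sqrt(2) * math.hypot(se, se)
        t = pairwise_tukey([self._est("a", 1.0, se),
                            self._est("b", 1.0 + delta, se),
                            self._est("c", 1.0 + delta / 2, se)])
        pair = t[(t.group_a == "a") & (t.group_b == "b")]
        assert pair["adjusted_p"].iloc[0] == pytest.approx(0.05, abs=0.001)

    def test_outlier_group_has_smallest_adjusted_p(self):
        ests = [self._est("a", 1.0), self._est("b", 1.02),
                self._est("c", 0.98), self._est("out", 2.0)]
        t = pairwise_tukey(ests)
        assert len(t) == 6
        out_p = t[(t.group_a == "out") | (t.group_b == "out")]["adjusted_p"]
        rest_p = t[(t.group_a != "out") & (t.group_b != "out")]["adjusted_p"]
        assert out_p.max() < rest_p.min()
        # adjusted p monotone decreasing in |z|
        assert (t.sort_values("adjusted_p")["z"].abs().diff().dropna() <= 0).all()


class TestTargetRegion:
    def _est(self, group, lo, hi, parameter="ADC_ROI_mean"):
        mu = (lo + hi) / 2
        return SummaryEstimate(group=group, parameter=parameter, k=1, N=5,
                               pooled_mean=mu, tau2=0.0,
                               se_pooled=(hi - lo) / (2 * 1.96), ci95=(lo, hi))

    def test_adc_gap(self):
        r = derive_target_region(self._est("low", 1.1e-3, 1.3e-3),
                                 self._est("high", 0.6e-3, 0.9e-3))
        assert not r.empty
        assert (r.lower, r.upper) == pytest.approx((0.9e-3, 1.1e-3))

    def test_ncbf_gap(self):
        r = derive_target_region(
            self._est("low", 0.7, 1.1, "nCBF_ROI_max"),
            self._est("high", 1.8, 2.6, "nCBF_ROI_max"))
        assert (r.lower, r.upper) == pytest.approx((1.1, 1.8))

    def test_overlap_gives_empty_region(self):
        r = derive_target_region(self._est("low", 1.0e-3, 1.3e-3),
                                 self._est("high", 1.1e-3, 1.5e-3))
        assert r.empty and r.lower is None and r.upper is None

    def test_parameter_mismatch_rejected(self):
        with pytest.raises(ValueError):
            derive_target_region(self._est("low", 1.0, 1.2),
                                 self._est("high", 1.5, 2.0, "nCBF_ROI_max"))
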
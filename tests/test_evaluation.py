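import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ieegflow.evaluation import (EvaluationResult, bonferroni,
                                 classify_recording, cohens_d, ks_normality,
                                 roc_auc, seizure_auc, summarize_cohort,
                                 wilcoxon_ranksum)
from ieegflow.flows import FlowSeries
from ieegflow.recording import ValidationError


def brute_force_auc(scores, labels):
    """Concordant-pair counting with tie half-credit (independent oracle)."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [True, True, False, False]) == 1

    def test_all_tied_gives_half(self):
        assert roc_auc([0.5] * 5, [True, True, False, False, False]) == 0.5

    def test_hand_counted_example(self):
        scores = np.array([0.8, 0.3, 0.6, 0.2, 0.1])
        labels = np.array([True, True, False, False, False])
        assert roc_auc(scores, labels) == pytest.approx(5 / 6)

    def test_matches_brute_force_on_random_cases(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(3, 13))
            labels = np.zeros(n, dtype=bool)
            labels[:int(rng.integers(1, n))] = True
            rng.shuffle(labels)
            # discrete grid forces ties
            scores = rng.integers(0, 5, size=n) / 4.0
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_complement_symmetry_for_tie_free_scores(self):
        rng = np.random.default_rng(1)
        scores = rng.permutation(10) / 10.0
        labels = np.array([True] * 4 + [False] * 6)
        assert roc_auc(scores, labels) + roc_auc(1 - scores, labels) \
            == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="classes"):
            roc_auc([0.1, 0.2], [True, True])


class TestWilcoxonRankSum:
    def test_exact_fully_separated_small_sample(self):
        _, p = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_samples_p_one(self):
        _, p = wilcoxon_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_matches_scipy_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            _, p = wilcoxon_ranksum(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_asymptotic_close_to_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(size=10)
            y = rng.normal(0.3, size=10)
            _, p_asym = wilcoxon_ranksum(x, y)  # n=20 -> asymptotic branch
            p_exact = stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method="exact").pvalue
            assert abs(p_asym - p_exact) < 0.02

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError, match="nonempty"):
            wilcoxon_ranksum([], [1.0])


class TestKsNormality:
    def test_normal_sample_usually_passes(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(3, 2, size=500)
            if ks_normality(x)[1] > 0.05:
                hits += 1
        assert hits >= 18

    def test_uniform_sample_usually_rejected(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).uniform(0, 1, size=500)
            if ks_normality(x)[1] < 0.05:
                hits += 1
        assert hits >= 18

    def test_statistic_in_unit_interval(self):
        stat, _ = ks_normality(np.arange(10.0))
        assert 0 <= stat <= 1

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValidationError, match="5"):
            ks_normality([1.0, 2.0, 3.0])


class TestEffectSizeAndCorrection:
    def test_unit_shift_gives_d_near_one(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=5000)
        assert cohens_d(y + 1, y) == pytest.approx(1.0, abs=0.06)

    def test_antisymmetric(self):
        x = [1.0, 2.0, 4.0]
        y = [2.0, 3.0, 5.0]
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x))

    def test_bonferroni_definition_and_clipping(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.04]), [0.02, 0.08])
        assert bonferroni([0.9], m=5)[0] == 1.0
        np.testing.assert_allclose(bonferroni([0.3], m=1), [0.3])


def flow(values, soz, method="pdc", measure="inflow"):
    return FlowSeries(method=method, measure=measure, period="preictal",
                      values=np.asarray(values, dtype=float),
                      soz_mask=np.asarray(soz, dtype=bool))


def make_flows(soz_inflow_shift=0.0, soz_outflow_shift=0.0, n_ch=10,
               n_soz=3, seed=0):
    rng = np.random.default_rng(seed)
    soz = np.zeros(n_ch, dtype=bool)
    soz[:n_soz] = True
    flows = {}
    for method in ("pdc", "dtf"):
        for measure, shift in (("inflow", soz_inflow_shift),
                               ("outflow", soz_outflow_shift)):
            v = rng.uniform(0, 1, size=(7, n_ch))
            v[:, soz] = np.clip(v[:, soz] + shift, 0, 1)
            flows[(method, measure)] = flow(v, soz, method, measure)
    return flows


class TestClassification:
    def test_inflow_shift_classified_inflow_dominant(self):
        res = classify_recording(make_flows(soz_inflow_shift=0.6))
        assert res.group_label == "inflow_dominant"

    def test_outflow_shift_classified_outflow_dominant(self):
        res = classify_recording(make_flows(soz_outflow_shift=0.6))
        assert res.group_label == "outflow_dominant"

    def test_both_measures_shifted_is_unclassified(self):
        res = classify_recording(
            make_flows(soz_inflow_shift=0.6, soz_outflow_shift=0.6))
        assert res.group_label == "unclassified"

    def test_null_type_one_rate_conservative(self):
        dominant = 0
        for seed in range(40):
            res = classify_recording(make_flows(seed=seed))
            if res.group_label != "unclassified":
                dominant += 1
        assert dominant / 40 <= 0.10  # <= 2 * alpha

    def test_tests_table_has_adjusted_p(self):
        res = classify_recording(make_flows(soz_inflow_shift=0.6))
        assert (res.tests["p_adjusted"] >= res.tests["p_raw"] - 1e-15).all()
        assert len(res.tests) == 4


class TestSeizureAuc:
    def test_planted_channel_scores(self):
        v = np.tile([0.9, 0.8, 0.1, 0.2, 0.3], (7, 1))
        assert seizure_auc(flow(v, [1, 1, 0, 0, 0])) == 1.0

    def test_single_segment_degenerates_to_roc(self):
        v = np.array([[0.8, 0.3, 0.6, 0.2, 0.1]])
        f = flow(v, [1, 1, 0, 0, 0])
        assert seizure_auc(f) == roc_auc(v[0], f.soz_mask)


class TestCohortSummary:
    def _result(self, auc, group="inflow_dominant", **meta):
        table = pd.DataFrame([{
            "patient": "p", "seizure": meta.get("seizure_id", "s"),
            "method": "pdc", "measure": "inflow", "period": "preictal",
            "auc": auc}])
        return EvaluationResult(auc_table=table, group_label=group,
                                tests=pd.DataFrame(), meta=meta)

    def test_single_result_median_equals_auc(self):
        out = summarize_cohort([self._result(0.7)])
        assert out.table["median"].iloc[0] == 0.7
        assert out.table["iqr_low"].iloc[0] == out.table["iqr_high"].iloc[0]

    def test_unknown_stratify_key_rejected(self):
        with pytest.raises(ValidationError, match="metadata"):
            summarize_cohort([self._result(0.7)], stratify_by="nope")

    def test_effect_free_stratification_not_significant(self):
        rng = np.random.default_rng(0)
        hits = 0
        for rep in range(20):
            results = [self._result(rng.uniform(0.4, 0.6),
                                    seizure_id=f"s{i}",
                                    site="A" if i % 2 else "B")
                       for i in range(20)]
            out = summarize_cohort(results, stratify_by="site")
            if (out.strata_tests["p_adjusted"] > 0.05).all():
                hits += 1
        assert hits >= 18
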
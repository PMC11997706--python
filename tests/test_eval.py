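"""Diagnostic metrics, intervals, ROC/AUC, and secondary statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mirpair import (
    CohortSpec,
    ConfusionCounts,
    PairedFeatureDef,
    compute_paired_features,
    confusion_metrics,
    covariate_associations,
    delong_auc_ci,
    generate_cohort,
    generate_donor_series,
    roc_curve_auc,
    timepoint_correlation,
    two_sample_ttest,
    wilson_ci,
)
from mirpair.evaluate import chi_squared_table, diagnostic_report, percent


class TestConfusionMetrics:
    def test_unique_integer_counts_behind_printed_training_rates(self):
        # enumeration oracle: the only (tp, fn, tn, fp) with 34 positives and
        # 140 negatives whose rounded rates are 91.2 / 57.9 / 96.4
        hits = []
        for tp in range(35):
            for tn in range(141):
                fn, fp = 34 - tp, 140 - tn
                if tn + fn == 0:
                    continue
                m = confusion_metrics(ConfusionCounts(tp, fn, tn, fp))
                if (percent(m["sensitivity"]), percent(m["specificity"]),
                        percent(m["npv"])) == (91.2, 57.9, 96.4):
                    hits.append((tp, fn, tn, fp))
        assert hits == [(31, 3, 81, 59)]

    def test_unique_integer_counts_behind_printed_test_rates(self):
        hits = []
        for tp in range(25):
            for tn in range(68):
                fn, fp = 24 - tp, 67 - tn
                if tn + fn == 0:
                    continue
                m = confusion_metrics(ConfusionCounts(tp, fn, tn, fp))
                if (percent(m["sensitivity"]), percent(m["specificity"]),
                        percent(m["npv"])) == (95.8, 46.3, 96.9):
                    hits.append((tp, fn, tn, fp))
        assert hits == [(23, 1, 31, 36)]

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=10, fn=0, tn=20, fp=0))
        assert all(v == 1.0 for v in m.values())

    def test_zero_denominator_reported_as_undefined(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        assert m["sensitivity"] is None
        assert m["specificity"] == 0.5

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fn=0, tn=0, fp=0)


class TestWilsonCI:
    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [
            (31, 34, 77.0, 97.0),
            (81, 84, 90.0, 98.8),
            (81, 140, 49.6, 65.7),
            (23, 24, 79.8, 99.3),
            (31, 32, 84.3, 99.4),
            (31, 67, 34.9, 58.1),
        ],
    )
    def test_one_decimal_percent_bounds(self, k, n, lo, hi):
        ci = wilson_ci(k, n)
        assert (percent(ci.lower), percent(ci.upper)) == (lo, hi)

    def test_zero_successes_lower_bound_is_zero(self):
        ci = wilson_ci(0, 10)
        assert ci.lower == 0.0
        assert ci.point == 0.0

    def test_interval_contains_point_and_narrows_with_n(self):
        widths = []
        for n in (20, 80, 320):
            ci = wilson_ci(round(0.3 * n), n)
            assert ci.lower <= ci.point <= ci.upper
            assert 0.0 <= ci.lower and ci.upper <= 1.0
            widths.append(ci.upper - ci.lower)
        assert widths == sorted(widths, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_ci(1, 0)
        with pytest.raises(ValueError):
            wilson_ci(5, 4)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_curve_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_curve_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == 0.5

    def test_matches_pairwise_enumeration_oracle(self, rng):
        scores = rng.normal(size=12)
        labels = np.array([1, 0, 1, 0, 0, 1, 0, 0, 1, 0, 1, 0])
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        concordant = sum(
            1.0 if p > q else (0.5 if p == q else 0.0)
            for p, q in itertools.product(pos, neg)
        )
        _, auc = roc_curve_auc(scores, labels)
        assert auc == pytest.approx(concordant / (len(pos) * len(neg)))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.35).astype(int)
        _, auc = roc_curve_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.3).astype(int)
        _, auc0 = roc_curve_auc(scores, labels)
        _, auc1 = roc_curve_auc(np.exp(3 * scores) + 7, labels)
        assert auc1 == pytest.approx(auc0)

    def test_curve_spans_unit_square(self, rng):
        scores = rng.normal(size=30)
        labels = (rng.random(30) < 0.4).astype(int)
        curve, _ = roc_curve_auc(scores, labels)
        assert curve.iloc[0][["fpr", "tpr"]].tolist() == [0.0, 0.0]
        assert curve.iloc[-1][["fpr", "tpr"]].tolist() == [1.0, 1.0]

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_curve_auc([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_point_estimate_equals_mann_whitney_auc(self, rng):
        scores = rng.normal(size=50)
        labels = (rng.random(50) < 0.3).astype(int)
        _, auc = roc_curve_auc(scores, labels)
        ci = delong_auc_ci(scores, labels)
        assert ci.point == auc

    def test_variance_matches_placement_value_formula(self, rng):
        scores = rng.normal(size=14)
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 1, 0, 0, 1, 0, 0, 1])
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
        v01 = np.array([np.mean((pos > q) + 0.5 * (pos == q)) for q in neg])
        var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
        from scipy.stats import norm

        ci = delong_auc_ci(scores, labels)
        half = norm.ppf(0.975) * np.sqrt(var)
        assert ci.upper - ci.lower == pytest.approx(
            min(1, ci.point + half) - max(0, ci.point - half))

    def test_duplicated_data_same_auc_narrower_interval(self, rng):
        scores = rng.normal(size=30)
        labels = (rng.random(30) < 0.4).astype(int)
        ci1 = delong_auc_ci(scores, labels)
        ci2 = delong_auc_ci(np.tile(scores, 2), np.tile(labels, 2))
        assert ci2.point == pytest.approx(ci1.point)
        assert (ci2.upper - ci2.lower) < (ci1.upper - ci1.lower)

    def test_perfect_separation_degenerate_interval(self):
        ci = delong_auc_ci([1, 2, 3, 9, 10, 11], [0, 0, 0, 1, 1, 1])
        assert (ci.point, ci.lower, ci.upper) == (1.0, 1.0, 1.0)

    def test_too_few_per_class_raises(self):
        with pytest.raises(ValueError):
            delong_auc_ci([1, 2, 3], [1, 0, 0])


class TestTwoSampleTTest:
    def test_identical_groups(self):
        r = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r["t"] == 0.0
        assert r["p"] == 1.0

    def test_swap_symmetry(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        r1 = two_sample_ttest(a, b)
        r2 = two_sample_ttest(b, a)
        assert r1["t"] == pytest.approx(-r2["t"])
        assert r1["p"] == pytest.approx(r2["p"])

    def test_planted_effect_is_detected_across_seeds(self):
        # paired feature separated by 0.4 at low noise, 34 vs 140 subjects
        significant = 0
        for seed in range(100):
            spec = CohortSpec(n_benign=140, n_malignant=34, n_mirna=4,
                              planted_pairs=[("miR-0001", "miR-0002", 0.2)],
                              noise_sd=0.1, detection_dropout_rate=0.0,
                              detection_threshold=3, seed=seed)
            matrix, metadata = generate_cohort(spec)
            f = compute_paired_features(
                matrix, [PairedFeatureDef("miR-0001", "miR-0002")]
            ).iloc[:, 0]
            r = two_sample_ttest(f[metadata.label == "malignant"],
                                 f[metadata.label == "benign"])
            significant += r["p"] < 0.001
        assert significant >= 95

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [1.0, 2.0])


class TestCovariateAssociations:
    def test_chi_squared_diagonal_table(self):
        r = chi_squared_table([[10, 0], [0, 10]])
        assert r["chi2"] == pytest.approx(20.0)

    def test_null_age_association(self, rng):
        n = 200
        cov = pd.DataFrame({"age": rng.integers(35, 80, n)},
                           index=[f"S{i}" for i in range(n)])
        idx = rng.random(n)
        out = covariate_associations(idx, cov)
        assert out["age"]["defined"]
        assert abs(out["age"]["r"]) < 0.2

    def test_small_groups_dropped_from_anova(self, rng):
        n = 60
        levels = ["A"] * 29 + ["B"] * 29 + ["C"] * 1 + ["D"] * 1
        cov = pd.DataFrame({"group": levels},
                           index=[f"S{i}" for i in range(n)])
        out = covariate_associations(rng.random(n), cov)
        assert out["group"]["n_groups"] == 2
        assert set(out["group"]["dropped_levels"]) == {"C", "D"}

    def test_constant_covariate_flagged_undefined(self):
        cov = pd.DataFrame({"age": [50.0] * 10},
                           index=[f"S{i}" for i in range(10)])
        out = covariate_associations(np.linspace(0, 1, 10), cov)
        assert out["age"] == {"kind": "pearson", "defined": False}


class TestTimepointCorrelation:
    def _defs(self):
        return [PairedFeatureDef(f"miR-{i:02d}a", f"miR-{i:02d}b")
                for i in range(5)]

    def _mirnas(self):
        return [m for d in self._defs() for m in (d.mirna_i, d.mirna_j)]

    def test_identical_profiles_give_unit_correlation(self):
        matrix, meta = generate_donor_series(
            2, 3, 0.0, seed=0, mirna_ids=self._mirnas())
        out = timepoint_correlation(matrix, meta, self._defs())
        for mats in out.values():
            assert np.allclose(mats["signals"].to_numpy(), 1.0)
            assert np.allclose(mats["paired"].to_numpy(), 1.0)

    def test_symmetry_and_unit_diagonal(self):
        matrix, meta = generate_donor_series(
            3, 4, 0.3, seed=5, mirna_ids=self._mirnas())
        out = timepoint_correlation(matrix, meta, self._defs())
        for mats in out.values():
            for m in mats.values():
                a = m.to_numpy()
                assert np.allclose(a, a.T)
                assert np.allclose(np.diag(a), 1.0)

    def test_small_noise_keeps_correlations_high(self):
        matrix, meta = generate_donor_series(
            5, 6, 0.05, seed=9, mirna_ids=self._mirnas())
        out = timepoint_correlation(matrix, meta, self._defs())
        assert len(out) == 5
        for mats in out.values():
            assert mats["signals"].to_numpy().min() > 0.95

    def test_too_few_features_raises(self):
        matrix, meta = generate_donor_series(1, 2, 0.1, seed=0)
        with pytest.raises(ValueError, match="at least 2"):
            timepoint_correlation(matrix, meta, self._defs()[:1])


def test_diagnostic_report_bundles_counts_intervals_and_auc(rng):
    counts = ConfusionCounts(tp=31, fn=3, tn=81, fp=59)
    scores = np.r_[rng.normal(1.0, 1.0, 34), rng.normal(0.0, 1.0, 140)]
    labels = np.r_[np.ones(34), np.zeros(140)]
    report = diagnostic_report(counts, scores=scores, labels=labels)
    assert report["metrics"]["sensitivity"]["percent"] == 91.2
    assert report["metrics"]["npv"]["ci_lower_percent"] == 90.0
    assert report["auc"]["ci_lower"] <= report["auc"]["point"] \
        <= report["auc"]["ci_upper"]
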
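"""ROC/AUC, DeLong comparisons, threshold tables, descriptive statistics."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pedtriage.evaluation import (compare_auc, describe_cohort, roc_auc,
                                  sens_spec_at, threshold_table)
from pedtriage.exceptions import DegenerateGroupError, DegenerateLabelsError
from pedtriage.nfptcr import classify_nfptcr
from pedtriage.scores import derive_score_table

from conftest import auc_brute, make_record

FIX_A = [8.1, 6.5, 7.2, 5.0, 9.3, 4.4, 3.1, 5.2, 2.0, 4.8, 1.5, 6.0]
FIX_B = [7.0, 5.5, 8.0, 4.1, 6.2, 5.9, 4.0, 3.3, 2.8, 6.1, 1.0, 5.1]
FIX_Y = [True] * 6 + [False] * 6


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_all_ties(self):
        assert roc_auc([5, 5, 5, 5], [1, 0, 1, 0]).auc == 0.5

    def test_four_pair_example(self):
        # pos {0.4, 0.9} vs neg {0.2, 0.6}: 3 of 4 pairs concordant
        assert roc_auc([0.2, 0.6, 0.4, 0.9],
                       [False, False, True, True]).auc == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            roc_auc([1, 2, 3], [True, True, True])

    def test_ci_brackets_auc_within_unit_interval(self):
        res = roc_auc(FIX_A, FIX_Y)
        lo, hi = res.auc_ci
        assert 0.0 <= lo <= res.auc <= hi <= 1.0

    def test_points_monotone_with_sentinels(self):
        res = roc_auc(FIX_A, FIX_Y)
        pts = res.points
        assert pts.threshold.iloc[0] == -np.inf
        assert np.isinf(pts.threshold.iloc[-1])
        assert (pts.sensitivity.diff().dropna() <= 1e-12).all()
        assert (pts.specificity.diff().dropna() >= -1e-12).all()

    def test_matches_pair_counting_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                auc_brute(scores, labels), abs=1e-12)

    def test_label_inversion_complements_auc(self):
        res = roc_auc(FIX_A, FIX_Y)
        inv = roc_auc(FIX_A, [not y for y in FIX_Y])
        assert res.auc + inv.auc == pytest.approx(1.0)

    @given(st.floats(min_value=0.1, max_value=5.0),
           st.floats(min_value=-3.0, max_value=3.0))
    @settings(derandomize=True, max_examples=50)
    def test_auc_invariant_under_increasing_transforms(self, scale, shift):
        base = roc_auc(FIX_A, FIX_Y).auc
        transformed = [scale * x + shift for x in FIX_A]
        assert roc_auc(transformed, FIX_Y).auc == pytest.approx(base)
        assert roc_auc(np.exp(0.3 * np.asarray(FIX_A)),
                       FIX_Y).auc == pytest.approx(base)


class TestCompareAuc:
    def test_self_comparison_is_null(self):
        c = compare_auc(FIX_A, FIX_A, FIX_Y)
        assert c.auc_diff == 0.0
        assert c.p_value == 1.0
        assert np.isnan(c.statistic)

    def test_monotone_transform_gives_zero_difference(self):
        c = compare_auc(FIX_A, list(np.exp(np.asarray(FIX_A) / 2)), FIX_Y)
        assert c.auc_diff == pytest.approx(0.0, abs=1e-12)
        assert c.p_value == 1.0

    def test_variance_matches_paired_bootstrap_oracle(self):
        c = compare_auc(FIX_A, FIX_B, FIX_Y)
        rng = np.random.default_rng(2024)
        a, b, y = map(np.asarray, (FIX_A, FIX_B, FIX_Y))
        pos_idx, neg_idx = np.arange(6), np.arange(6, 12)
        diffs = []
        for _ in range(10_000):
            idx = np.concatenate([rng.choice(pos_idx, 6),
                                  rng.choice(neg_idx, 6)])
            diffs.append(auc_brute(a[idx], y[idx]) - auc_brute(b[idx], y[idx]))
        boot_var = np.var(diffs, ddof=1)
        assert c.var_diff == pytest.approx(boot_var, rel=0.2)

    def test_matches_r_proc_delong_oracle(self):
        """Statistic and p-value agree with pROC's paired DeLong test."""
        rcode = """
suppressMessages(library(pROC))
a <- c(%s); b <- c(%s); y <- c(%s)
ra <- roc(y, a, quiet=TRUE, direction="<")
rb <- roc(y, b, quiet=TRUE, direction="<")
tt <- roc.test(ra, rb, method="delong", paired=TRUE)
cat(sprintf("%%.12f %%.12f %%.12f %%.12f %%.12f",
    as.numeric(auc(ra)), as.numeric(auc(rb)),
    as.numeric(tt[["statistic"]]), tt[["p.value"]], as.numeric(var(ra))))
""" % (",".join(map(str, FIX_A)), ",".join(map(str, FIX_B)),
       ",".join("1" if y else "0" for y in FIX_Y))
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, check=True)
        r_auc_a, r_auc_b, r_z, r_p, r_var_a = map(float, out.stdout.split())
        mine = compare_auc(FIX_A, FIX_B, FIX_Y)
        roc_a = roc_auc(FIX_A, FIX_Y)
        assert mine.auc_a == pytest.approx(r_auc_a, abs=1e-10)
        assert mine.auc_b == pytest.approx(r_auc_b, abs=1e-10)
        assert mine.statistic == pytest.approx(r_z ** 2, abs=1e-10)
        assert mine.p_value == pytest.approx(r_p, abs=1e-10)
        assert roc_a.auc_se ** 2 == pytest.approx(r_var_a, abs=1e-10)


class TestThresholds:
    def test_threshold_below_all_scores(self):
        row = sens_spec_at([2, 3, 4, 5], [1, 0, 1, 0], threshold=1)
        assert (row.sensitivity, row.specificity) == (100.0, 0.0)

    def test_hand_counted_confusion_matrix(self):
        scores = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        labels = [0, 0, 0, 1, 0, 1, 0, 1, 1, 1]
        row = sens_spec_at(scores, labels, threshold=5)
        # pred+ = scores {6..10}: TP {6,8,9,10}=4, FP {7}=1; FN {4}=1, TN 4
        assert (row.tp, row.fn, row.tn, row.fp) == (4, 1, 4, 1)
        assert row.sensitivity == 80.0
        assert row.specificity == 80.0

    def test_geq_mode_includes_boundary(self):
        scores = [5, 6]
        labels = [1, 0]
        assert sens_spec_at(scores, labels, 5).sensitivity == 0.0
        assert sens_spec_at(scores, labels, 5, mode="geq").sensitivity == 100.0

    def test_sensitivity_monotone_decreasing_over_grid(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0, 30, size=300)
        labels = rng.random(300) < 0.4
        rows = [sens_spec_at(scores, labels, t) for t in (5, 10, 15, 20)]
        sens = [r.sensitivity for r in rows]
        spec = [r.specificity for r in rows]
        assert sens == sorted(sens, reverse=True)
        assert spec == sorted(spec)

    def test_threshold_table_composition(self):
        rng = np.random.default_rng(6)
        labels = rng.random(200) < 0.3
        sets = {"m1": rng.uniform(0, 30, 200), "m2": rng.uniform(0, 30, 200)}
        tab = threshold_table(sets, labels, thresholds=[5, 10, 15, 20])
        assert len(tab) == 8
        row = tab[(tab.metric == "m1") & (tab.threshold == 10)].iloc[0]
        direct = sens_spec_at(sets["m1"], labels, 10)
        assert row.sensitivity == direct.sensitivity
        assert row.auc == roc_auc(sets["m1"], labels).auc

    def test_empty_threshold_list_gives_empty_table(self):
        tab = threshold_table({"m": [1, 2, 3]}, [1, 0, 1], thresholds=[])
        assert len(tab) == 0


class TestDescriptives:
    @staticmethod
    def _cohort(n_pos=30, n_neg=50, seed=3):
        rng = np.random.default_rng(seed)
        cohort, nf = [], []
        for i in range(n_pos + n_neg):
            pos = i < n_pos
            rec = make_record(
                patient_id=f"P{i}", age_years=int(rng.integers(0, 16)),
                sex="F" if rng.random() < 0.6 else "M",
                mechanism="transport" if (pos and rng.random() < 0.5)
                else "other_blunt",
                icu_days=int(rng.integers(1, 6)) if pos else 0,
                hospital_hours=float(rng.uniform(10, 300)),
                transfusion_hours=1.0 if pos else None)
            cohort.append(rec)
            nf.append(classify_nfptcr(rec))
        scores = pd.DataFrame({
            "patient_id": [r.patient_id for r in cohort],
            "iss": rng.integers(1, 40, n_pos + n_neg),
            "iciss_scaled": rng.uniform(0, 80, n_pos + n_neg),
            "icass": rng.uniform(0, 80, n_pos + n_neg),
        })
        return cohort, nf, scores

    def test_table_structure_and_pvalues(self):
        cohort, nf, scores = self._cohort()
        tab = describe_cohort(cohort, nf, scores)
        assert tab.columns[0] == "variable"
        p = dict(zip(tab.variable, tab.p_value))
        assert 0 <= p["Age, years"] <= 1
        # mechanism mix was planted to differ between groups
        assert p["Injury mechanism"] < 0.05

    def test_degenerate_group_rejected(self):
        cohort, nf, scores = self._cohort(n_pos=0, n_neg=10)
        with pytest.raises(DegenerateGroupError):
            describe_cohort(cohort, nf, scores)

    def test_kruskal_wallis_hand_example(self):
        # groups {1,2,3} vs {4,5,6}: H = 12/(6*7) * (3*(2-3.5)^2 + 3*(5-3.5)^2)
        h, _ = stats.kruskal([1, 2, 3], [4, 5, 6])
        assert h == pytest.approx(3.857142857, abs=1e-9)

    def test_no_association_chi_square_is_zero(self):
        chi2, p, _, _ = stats.chi2_contingency([[10, 10], [10, 10]],
                                               correction=False)
        assert chi2 == 0.0 and p == 1.0


class TestDirectionalOrdering:
    def test_icass_beats_iss_for_resource_need_on_synthetic_cohort(self):
        """Resource need is mediated by code-level critical-care propensities,
        so the critical-care score should discriminate better than the
        anatomy-based ISS on a generated cohort (fixed seed, defaults)."""
        from pedtriage.synthetic import (CohortSpec, generate_cohort,
                                         generate_vocabulary)
        vocab = generate_vocabulary(300, seed=41)
        cohort = generate_cohort(
            CohortSpec(n_patients=8000, years=[2018, 2019], seed=42), vocab)
        deriv = [r for r in cohort if r.year == 2018]
        appl = [r for r in cohort if r.year == 2019]
        scores = derive_score_table(deriv).apply(appl)
        labels = np.array([classify_nfptcr(r).positive for r in appl])
        icass = scores["icass"].to_numpy(float)
        iss = scores["iss"].to_numpy(float)
        comparison = compare_auc(icass, iss, labels, "icass", "iss")
        assert comparison.auc_a > comparison.auc_b
        assert comparison.p_value < 0.05
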
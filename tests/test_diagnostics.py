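"""Diagnostic statistics: ROC/cutoff vs brute force, agreement, intervals."""

import math

import numpy as np
import pytest
from scipy import stats

import steatopipe as sp
from steatopipe.diagnostics import auc_p_value


def brute_force_auc(scores, labels):
    """All-pairs Mann-Whitney count: ties score 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_cutoff(scores, labels):
    """Exhaustive scan over all midpoint cutoffs, lowest Youden-tie wins."""
    uniq = np.unique(scores)
    cands = [uniq[0] - 1] + list((uniq[:-1] + uniq[1:]) / 2) + [uniq[-1] + 1]
    best = None
    for c in cands:
        pred = scores > c
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        if best is None or sens + spec > best[0] + 1e-12:
            best = (sens + spec, c, sens, spec)
    return best


class TestRocAuc:
    def test_perfect_separation(self):
        assert sp.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert sp.roc_auc([5.0] * 8, [0, 1, 0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            sp.roc_auc([1, 2, 3], [1, 1, 1])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 16)
        scores = rng.choice([0.1, 0.2, 0.3, 0.5, 0.7], size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.all() or not labels.any():
            labels[0] = 1 - labels[0]
        assert sp.roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        scores = rng.normal(size=200)
        labels = (scores + rng.normal(size=200)) > 0
        assert sp.roc_auc(scores, labels) == pytest.approx(
            sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0.01, 1, 50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        a = sp.roc_auc(scores, labels)
        assert sp.roc_auc(np.log(scores), labels) == pytest.approx(a)
        assert sp.roc_auc(scores**3, labels) == pytest.approx(a)

    def test_label_permutation_centres_on_half(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=40)
        labels = np.array([0] * 20 + [1] * 20)
        aucs = []
        for _ in range(500):
            rng.shuffle(labels)
            aucs.append(sp.roc_auc(scores, labels))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


class TestOptimalCutoff:
    def test_clean_separation(self):
        c, sens, spec = sp.optimal_cutoff([1, 2, 3, 4], [0, 0, 1, 1])
        assert 2 < c < 3
        assert sens == 100.0 and spec == 100.0

    def test_tie_takes_lowest_cutoff(self):
        # cutoffs 1.5 and 2.5 both give Youden sum 1.5; lowest favoured
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 1, 0, 1])
        c, sens, spec = sp.optimal_cutoff(scores, labels)
        assert c == pytest.approx(1.5)
        assert sens == 100.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = rng.integers(6, 16)
        scores = rng.choice(np.linspace(0, 1, 7), size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.all() or not labels.any():
            labels[0] = 1 - labels[0]
        c, sens, spec = sp.optimal_cutoff(scores, labels)
        youden, c_bf, sens_bf, spec_bf = brute_force_cutoff(scores, labels)
        assert sens + spec == pytest.approx(100 * youden, abs=1e-9)
        assert c == pytest.approx(c_bf)


class TestProportionCi:
    def test_all_successes_closed_form(self):
        lo, hi = sp.proportion_ci(30, 30)
        assert hi == 100.0
        assert lo == pytest.approx(100 * 0.025 ** (1 / 30), abs=1e-9)
        assert lo == pytest.approx(88.43, abs=0.01)

    def test_no_successes_closed_form(self):
        lo, hi = sp.proportion_ci(0, 20)
        assert lo == 0.0
        assert hi == pytest.approx(100 * (1 - 0.025 ** (1 / 20)), abs=1e-9)

    def test_reproduces_printed_sensitivity_interval(self):
        # 30 of 33 detected (90.91%): exact interval 75.67 to 98.08
        lo, hi = sp.proportion_ci(30, 33)
        assert lo == pytest.approx(75.67, abs=0.01)
        assert hi == pytest.approx(98.08, abs=0.01)
        # and 25 of 26 true negatives (96.15%): 80.36 to 99.90
        lo, hi = sp.proportion_ci(25, 26)
        assert lo == pytest.approx(80.36, abs=0.01)
        assert hi == pytest.approx(99.90, abs=0.01)

    def test_interval_contains_point_estimate(self):
        lo, hi = sp.proportion_ci(20, 22)
        assert lo < 100 * 20 / 22 < hi

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            sp.proportion_ci(5, 0)
        with pytest.raises(ValueError):
            sp.proportion_ci(10, 5)


class TestBlandAltmanLog:
    def test_identical_measurements(self):
        x = np.array([0.01, 0.05, 0.2, 0.4])
        res = sp.bland_altman_log(x, x)
        assert res.mean_diff_log == 0.0 and res.sd_diff_log == 0.0
        assert res.ratio_low == res.ratio_high == 1.0

    def test_nonpositive_value_named(self):
        with pytest.raises(ValueError, match="index 2"):
            sp.bland_altman_log([0.1, 0.2, 0.0, 0.3], [0.1, 0.2, 0.3, 0.4])

    def test_limits_symmetric_and_ratios_consistent(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(-3, 0.5, 40)
        y = x * rng.lognormal(0, 0.3, 40)
        res = sp.bland_altman_log(x, y)
        mid = 0.5 * (res.loa_low + res.loa_high)
        assert mid == pytest.approx(res.mean_diff_log, abs=1e-12)
        assert res.ratio_low * res.ratio_high == pytest.approx(
            math.exp(2 * res.mean_diff_log), rel=1e-12
        )

    def test_recovers_known_ratio_scatter(self):
        """Lognormal pairs with known log-ratio sd: the estimated limits
        converge on mean +/- 1.96 sd over many replicates."""
        rng = np.random.default_rng(7)
        sds = []
        for _ in range(300):
            x = rng.lognormal(-3.0, 0.6, 59)
            y = x * rng.lognormal(0.1, 0.45, 59)
            sds.append(sp.bland_altman_log(x, y).sd_diff_log)
        assert np.mean(sds) == pytest.approx(0.45, rel=0.02)


class TestPredictionIntervalLog:
    def test_constant_values_degenerate(self):
        res = sp.prediction_interval_log([0.03] * 10)
        assert res.low == pytest.approx(0.03)
        assert res.high == pytest.approx(0.03)

    def test_matches_hand_computed_formula(self):
        rng = np.random.default_rng(4)
        v = rng.lognormal(math.log(0.03), 0.5, 10)
        res = sp.prediction_interval_log(v)
        logs = np.log(v)
        half = stats.t.ppf(0.975, 9) * logs.std(ddof=1) * math.sqrt(1 + 1 / 10)
        assert res.low == pytest.approx(math.exp(logs.mean() - half), rel=1e-12)
        assert res.high == pytest.approx(math.exp(logs.mean() + half), rel=1e-12)

    def test_contains_geometric_mean(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            v = rng.lognormal(-3, rng.uniform(0.1, 1.0), rng.integers(3, 30))
            res = sp.prediction_interval_log(v)
            gm = math.exp(np.log(v).mean())
            assert res.low <= gm <= res.high

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sp.prediction_interval_log([0.1, -0.2, 0.3])


class TestDiagnosticReport:
    def test_strong_cohort_has_high_aucs(self, cohort_df):
        pat = cohort_df[cohort_df.group == "patient"]
        model = sp.fit_k(pat.alpha, pat.his_morph_frac)
        link = sp.fit_linear_link(pat.his_vis_pct, pat.his_morph_frac)
        rep = sp.diagnostic_report(cohort_df, calibration=model, link=link)
        assert len(rep.roc_visual) == 3
        assert all(r.auc > 0.9 for r in rep.roc_visual + rep.roc_morph)
        assert rep.agreement is not None and rep.agreement.n == 59
        assert rep.control_interval is not None
        assert 0 < rep.control_interval.low < rep.control_interval.high < 0.2

    def test_null_cohort_aucs_near_half(self, cohort_df):
        rng = np.random.default_rng(0)
        null = cohort_df.copy()
        noise = rng.uniform(0.01, 0.4, len(null))
        null["alpha"] = noise  # label-independent scores
        aucs = []
        for s in range(30):
            shuffled = null.copy()
            shuffled["alpha"] = rng.permutation(noise)
            rep = sp.diagnostic_report(shuffled)
            aucs.extend(r.auc for r in rep.roc_visual)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_missing_columns_reported(self, cohort_df):
        with pytest.raises(ValueError, match="alpha"):
            sp.diagnostic_report(cohort_df.drop(columns=["alpha"]))

    def test_roc_table_shape(self, cohort_df):
        rep = sp.diagnostic_report(cohort_df)
        tab = rep.roc_table()
        assert list(tab["reference"].unique()) == ["HIS-VIS"]
        assert {"auc", "alpha_cutoff", "sensitivity_pct"} <= set(tab.columns)


def test_auc_p_value_small_for_separated_groups():
    rng = np.random.default_rng(1)
    scores = np.concatenate([rng.normal(0, 1, 30), rng.normal(3, 1, 30)])
    labels = np.array([0] * 30 + [1] * 30)
    assert auc_p_value(scores, labels) < 1e-4
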
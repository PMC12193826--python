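"""Statistics layer: normality, group tests, correlation, ROC/Youden, ICC,
binormal AUC and the full study report."""

import itertools
import math

import numpy as np
import pytest

from uteqmt import synthetic_data as sd
from uteqmt.cohort_statistics import (
    binormal_auc,
    compare_groups,
    correlate,
    icc,
    ks_normality,
    plot_study,
    roc_auc,
    run_study,
    youden_threshold,
)
from uteqmt.exceptions import InvalidInputError


def pair_count_auc(scores, labels, direction="higher"):
    """Independent AUC oracle: exhaustive pair counting with half-credit ties."""
    s = np.asarray(scores, dtype=float)
    if direction == "lower":
        s = -s
    pos, neg = s[np.asarray(labels) == 1], s[np.asarray(labels) == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestNormality:
    def test_large_normal_sample_passes(self):
        x = np.random.default_rng(0).normal(size=500)
        assert ks_normality(x).p_value > 0.05

    def test_bimodal_sample_fails(self):
        x = np.concatenate([np.zeros(100), np.ones(100)]) + 0.0
        assert ks_normality(x).p_value < 0.01

    def test_permutation_invariant(self):
        x = np.random.default_rng(1).normal(size=60)
        shuffled = x[np.random.default_rng(2).permutation(60)]
        assert ks_normality(x) == ks_normality(shuffled)

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidInputError):
            ks_normality(np.full(10, 3.0))


class TestCompareGroups:
    def test_mann_whitney_exact_small_sample(self):
        """[1,2,3] vs [4,5,6]: U = 0 and exact two-sided p = 2/20 = 0.100."""
        rep = compare_groups([1, 2, 3], [4, 5, 6], normal=False)
        assert rep.test == "mann_whitney_u"
        assert rep.statistic == 0.0
        assert rep.p_value == pytest.approx(0.100, abs=1e-12)

    def test_exact_p_matches_full_enumeration(self):
        """Small-sample Mann–Whitney p agrees with enumerating all label
        arrangements of the pooled sample."""
        a, b = [1.2, 3.4, 2.2], [2.9, 4.1, 5.0, 3.3]
        rep = compare_groups(a, b, normal=False)
        pooled = np.array(a + b)
        na = len(a)

        def u_stat(idx):
            x = pooled[list(idx)]
            y = np.delete(pooled, list(idx))
            return sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in x for yi in y)

        u_obs = u_stat(range(na))
        us = [u_stat(c) for c in itertools.combinations(range(len(pooled)), na)]
        mu = len(a) * len(b) / 2
        p_exact = np.mean([abs(u - mu) >= abs(u_obs - mu) - 1e-12 for u in us])
        assert rep.p_value == pytest.approx(p_exact, abs=1e-9)

    def test_identical_groups_p_one(self):
        rep = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], normal=False)
        assert rep.p_value == pytest.approx(1.0, abs=1e-9)

    def test_welch_t_when_normal(self):
        rng = np.random.default_rng(3)
        rep = compare_groups(rng.normal(0, 1, 30), rng.normal(1, 2, 30), normal=True)
        assert rep.test == "welch_t"

    def test_degenerate_variance_falls_back_to_mann_whitney(self):
        with pytest.warns(UserWarning):
            rep = compare_groups([2.0, 2.0, 2.0], [3.0, 4.0, 5.0], normal=True)
        assert rep.test == "mann_whitney_u"


class TestCorrelate:
    def test_perfectly_decreasing_spearman(self):
        rep = correlate([20, 20, 15, 12, 10], [0, 0, 1, 2, 3], "spearman")
        assert rep.statistic == pytest.approx(-1.0)
        assert rep.effect_direction == "negative"

    def test_tied_spearman_matches_hand_ranking(self):
        """5-point set with one tie: matches Pearson on hand-assigned average
        ranks."""
        vals = [10.0, 9.0, 9.0, 7.0, 5.0]
        kl = [0, 1, 1, 2, 3]
        rep = correlate(vals, kl, "spearman")
        rank_vals = np.array([5.0, 3.5, 3.5, 2.0, 1.0])  # by hand
        rank_kl = np.array([1.0, 2.5, 2.5, 4.0, 5.0])
        oracle = np.corrcoef(rank_vals, rank_kl)[0, 1]
        assert rep.statistic == pytest.approx(oracle, abs=1e-12)

    def test_linear_pearson(self):
        rep = correlate([1.0, 2.0, 3.0, 4.0, 5.0], [0, 1, 2, 3, 4], "pearson")
        assert rep.statistic == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(InvalidInputError):
            correlate([2, 2, 2, 2, 2], [0, 1, 2, 3, 3], "spearman")


class TestRoc:
    def test_perfect_separation(self):
        rep = roc_auc([1, 2, 8, 9], [0, 0, 1, 1], "higher")
        assert rep.auc == 1.0
        assert rep.sensitivity_pct == 100.0 and rep.specificity_pct == 100.0

    def test_tied_scores_half_credit(self):
        """scores [1,2,2,3], labels [0,1,0,1]: 3.5 of 4 pairs -> AUC 0.875."""
        assert roc_auc([1, 2, 2, 3], [0, 1, 0, 1], "higher").auc == pytest.approx(0.875)

    def test_label_inversion_flips_auc(self):
        scores = [1.0, 3.0, 2.0, 5.0, 4.0, 2.5]
        labels = [0, 1, 0, 1, 1, 0]
        a = roc_auc(scores, labels, "higher").auc
        b = roc_auc(scores, [1 - l for l in labels], "higher").auc
        assert a + b == pytest.approx(1.0)

    def test_auc_equals_pair_count_identity_random_inputs(self):
        """Empirical AUC ≡ U/(n0·n1) on arbitrary (tied) inputs."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            scores = rng.integers(0, 10, size=30).astype(float)
            labels = rng.integers(0, 2, size=30)
            if labels.min() == labels.max():
                continue
            for direction in ("higher", "lower"):
                assert roc_auc(scores, labels, direction).auc == pytest.approx(
                    pair_count_auc(scores, labels, direction), abs=1e-12
                )

    def test_one_class_absent_rejected(self):
        with pytest.raises(InvalidInputError):
            roc_auc([1, 2, 3], [1, 1, 1], "higher")


class TestYouden:
    def brute_force(self, scores, labels, direction):
        s = np.asarray(scores, dtype=float)
        if direction == "lower":
            s = -s
        y = np.asarray(labels)
        best = None
        for c in np.concatenate([[-np.inf], np.sort(np.unique(s)), [np.inf]]):
            for cut in (c, c + 1e-9):
                sens = np.mean(s[y == 1] > cut)
                spec = np.mean(s[y == 0] <= cut)
                j = sens + spec - 1
                if best is None or j > best[0] + 1e-12:
                    best = (j, sens, spec)
        return best

    def test_overlapping_set_matches_brute_force(self):
        scores = [1.0, 2.0, 3.0, 3.5, 4.0, 6.0]
        labels = [0, 0, 1, 0, 1, 1]
        rep = youden_threshold(scores, labels, "higher")
        j_best, _, _ = self.brute_force(scores, labels, "higher")
        assert (rep.sensitivity_pct + rep.specificity_pct) / 100 - 1 == pytest.approx(j_best)

    def test_tie_prefers_higher_specificity(self):
        """neg [1,3], pos [2,4]: cuts at 1.5 and 3.5 share J = 0.5; the
        declared rule returns the higher-specificity cut (3.5)."""
        rep = youden_threshold([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1], "higher")
        assert rep.threshold == pytest.approx(3.5)
        assert rep.specificity_pct == 100.0

    def test_direction_lower_thresholds_on_original_scale(self):
        """MMF-like: diseased have the LOWER values; threshold is reported on
        the original scale between the classes."""
        rep = youden_threshold([15.5, 16.0, 13.0, 13.5], [0, 0, 1, 1], "lower")
        assert 13.5 < rep.threshold < 15.5
        assert rep.sensitivity_pct == 100.0 and rep.specificity_pct == 100.0


class TestIcc:
    def test_duplicated_column_gives_one(self):
        x = np.random.default_rng(0).normal(10, 2, size=20)
        assert icc(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_toy_table_matches_pingouin(self):
        """5x2 toy table agrees with an established ANOVA implementation for
        both ICC(2,1) and ICC(3,1)."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = np.array([[9.0, 10.0], [10.5, 10.0], [12.0, 12.5], [8.0, 8.5], [11.0, 10.0]])
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(5), 2),
                "rater": np.tile([0, 1], 5),
                "score": x.ravel(),
            }
        )
        res = pingouin.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        res = res.set_index("Type")["ICC"]
        assert icc(x, "icc2_1") == pytest.approx(float(res["ICC(A,1)"]), abs=1e-10)
        assert icc(x, "icc3_1") == pytest.approx(float(res["ICC(C,1)"]), abs=1e-10)

    def test_generator_calibration(self):
        """Mean estimated ICC over simulated cohorts recovers the 0.94 target
        within 0.02 (reader-noise generator calibration)."""
        vals = []
        for s in range(400):
            cohort = sd.draw_cohort(seed=s)
            noisy = sd.add_reader_noise(cohort, 0.94, seed=10_000 + s)
            vals.append(icc(noisy[["mmf_percent_reader1", "mmf_percent_reader2"]].to_numpy()))
        assert abs(np.mean(vals) - 0.94) < 0.02

    def test_zero_between_subject_variance_rejected(self):
        with pytest.raises(InvalidInputError):
            icc(np.ones((6, 2)))


class TestBinormalAuc:
    def test_equal_means_is_half(self):
        assert binormal_auc(10.0, 1.0, 10.0, 2.0) == pytest.approx(0.5)

    def test_closed_form_against_erf(self):
        """Group MMF parameters (15.8±1.4 vs 13.6±1.2) evaluated against an
        independent erf-based normal CDF; consistent with the observed
        discrimination (~0.88)."""
        d = abs(15.8 - 13.6) / math.sqrt(1.4**2 + 1.2**2)
        oracle = 0.5 * (1.0 + math.erf(d / math.sqrt(2.0)))
        val = binormal_auc(15.8, 1.4, 13.6, 1.2)
        assert val == pytest.approx(oracle, abs=1e-12)
        assert val == pytest.approx(0.88, abs=0.01)

    def test_symmetric_in_labels(self):
        assert binormal_auc(1.0, 0.5, 2.0, 0.7) == binormal_auc(2.0, 0.7, 1.0, 0.5)

    def test_agrees_with_empirical_auc_on_large_draws(self):
        rng = np.random.default_rng(5)
        n = 100_000
        for mu_h, sd_h, mu_d, sd_d, direction in [
            (15.8, 1.4, 13.6, 1.2, "lower"),
            (42.5, 2.5, 38.3, 2.9, "lower"),
            (19.7, 2.6, 21.6, 3.8, "higher"),
        ]:
            scores = np.concatenate([rng.normal(mu_h, sd_h, n), rng.normal(mu_d, sd_d, n)])
            labels = np.concatenate([np.zeros(n, int), np.ones(n, int)])
            emp = roc_auc(scores, labels, direction).auc
            assert emp == pytest.approx(binormal_auc(mu_h, sd_h, mu_d, sd_d), abs=0.005)

    def test_invalid_sd_rejected(self):
        with pytest.raises(InvalidInputError):
            binormal_auc(1.0, 0.0, 2.0, 1.0)


class TestRunStudy:
    def test_report_schema_and_determinism(self):
        cohort = sd.add_reader_noise(sd.draw_cohort(seed=4), 0.94, seed=4)
        rep1 = run_study(cohort)
        rep2 = run_study(cohort)
        assert rep1 == rep2
        for col in ("mmf_percent", "mtr_percent", "t2star_ms"):
            entry = rep1["biomarkers"][col]
            assert {"group_means", "normality", "comparison", "correlation_kl", "roc"} <= set(entry)
            assert {"mean", "sd"} <= set(entry["group_means"]["normal_subtle"])
            roc = entry["roc"]
            assert {"auc", "p_value", "threshold", "sensitivity_pct", "specificity_pct"} <= set(roc)
            assert 0.0 <= roc["auc"] <= 1.0
            assert "icc_inter_reader" in entry

    def test_group_means_near_population(self):
        """A drawn cohort's MMF group means sit within 3 SE of the population
        means 15.8 and 13.6."""
        cohort = sd.draw_cohort(seed=123)
        rep = run_study(cohort)
        gm = rep["biomarkers"]["mmf_percent"]["group_means"]
        assert abs(gm["normal_subtle"]["mean"] - 15.8) < 3 * 1.4 / math.sqrt(21)
        assert abs(gm["mild_moderate"]["mean"] - 13.6) < 3 * 1.2 / math.sqrt(24)

    def test_missing_biomarker_column_named(self):
        cohort = sd.draw_cohort(seed=1).drop(columns=["mtr_percent"])
        with pytest.raises(InvalidInputError, match="mtr_percent"):
            run_study(cohort)

    def test_plots_written(self, tmp_path):
        cohort = sd.draw_cohort(seed=2)
        paths = plot_study(cohort, tmp_path)
        assert len(paths) == 2
        for p in paths:
            assert (tmp_path / p.split("/")[-1]).stat().st_size > 0
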
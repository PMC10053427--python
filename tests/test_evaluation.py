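import numpy as np
import pytest
from scipy import stats

from paindraw import (
    BinaryScheme,
    ClassSpec,
    ConfusionMatrix,
    KDiseaseScheme,
    KernelNearestNeighborScheme,
    NearestNeighborScheme,
    SynthSpec,
    best_threshold_youden,
    build_profile,
    chi2_independence,
    classify_k,
    fisher_exact_2x2,
    generate_cohort,
    loocv,
    make_synthetic_template,
    roc_auc,
    summarize_confusion,
)
from paindraw.evaluation import _delong_variance
from conftest import random_binary_cohort


def mann_whitney_auc(pos, neg):
    """Brute-force pair-counting AUC with ties worth 1/2."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def delong_variance_naive(pos, neg):
    """Direct O(mn) evaluation of the DeLong structural components."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return psi.mean(), v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)


class TestSummarizeConfusion:
    def test_identity_matrix_is_perfect(self):
        cm = ConfusionMatrix(("A", "B", "C"), np.eye(3, dtype=int) * 4)
        s = summarize_confusion(cm)
        assert s.accuracy == 1.0
        assert all(v == 1.0 for v in s.sensitivity.values())
        assert all(v == 1.0 for v in s.specificity.values())

    def test_accuracy_complements_off_diagonal_mass(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, (4, 4))
        counts += np.eye(4, dtype=int)  # avoid zero rows
        cm = ConfusionMatrix(tuple("ABCD"), counts)
        s = summarize_confusion(cm)
        off = counts.sum() - np.trace(counts)
        assert s.accuracy == pytest.approx(1 - off / counts.sum())

    def test_zero_row_flagged_undefined(self):
        cm = ConfusionMatrix(("A", "B"), np.array([[0, 0], [1, 3]]))
        s = summarize_confusion(cm)
        assert "A" in s.undefined and np.isnan(s.sensitivity["A"])


class TestRocAuc:
    def test_perfect_separation(self):
        roc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert roc.auc == 1.0

    def test_all_tied_scores(self):
        roc = roc_auc(np.full(6, 0.5), np.array([1, 1, 1, 0, 0, 0]))
        assert roc.auc == 0.5

    def test_pair_counting_hand_example(self):
        scores = np.array([0.9, 0.8, 0.7, 0.85])
        truth = np.array([1, 1, 0, 0])
        roc = roc_auc(scores, truth)
        assert roc.auc == pytest.approx(0.75)  # 3 wins of 4 pairs

    def test_auc_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n_pos = rng.integers(2, 10)
            n_neg = rng.integers(2, 10)
            scores = rng.choice(np.linspace(0, 1, 7), n_pos + n_neg)
            truth = np.r_[np.ones(n_pos), np.zeros(n_neg)].astype(bool)
            roc = roc_auc(scores, truth)
            assert roc.auc == pytest.approx(
                mann_whitney_auc(scores[truth], scores[~truth])
            )

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(14)
        for _ in range(20):
            scores = rng.choice(np.linspace(0, 1, 6), 30)
            truth = rng.integers(0, 2, 30).astype(bool)
            truth[:2] = [True, False]
            assert roc_auc(scores, truth).auc == pytest.approx(
                roc_auc_score(truth, scores)
            )

    def test_delong_matches_naive_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            pos = rng.choice(np.linspace(0, 1, 9), rng.integers(3, 12))
            neg = rng.choice(np.linspace(0, 1, 9), rng.integers(3, 12))
            auc, var = _delong_variance(pos, neg)
            auc0, var0 = delong_variance_naive(pos, neg)
            assert auc == pytest.approx(auc0)
            assert var == pytest.approx(var0)

    def test_ci_contains_auc_and_shrinks_with_n(self):
        rng = np.random.default_rng(3)
        widths = []
        for n in (20, 80, 320):
            pos = rng.normal(1.0, 1.0, n)
            neg = rng.normal(0.0, 1.0, n)
            roc = roc_auc(np.r_[pos, neg], np.r_[np.ones(n), np.zeros(n)])
            lo, hi = roc.auc_ci
            assert lo <= roc.auc <= hi
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        scores = rng.random(40)
        truth = rng.integers(0, 2, 40).astype(bool)
        truth[:2] = [True, False]
        roc = roc_auc(scores, truth)
        assert (np.diff(roc.sens) <= 0).all()  # thresholds ascend

    def test_bootstrap_band_brackets_sensitivity(self):
        rng = np.random.default_rng(5)
        scores = np.r_[rng.normal(1, 1, 30), rng.normal(0, 1, 30)]
        truth = np.r_[np.ones(30), np.zeros(30)].astype(bool)
        roc = roc_auc(scores, truth, n_boot=300, seed=9)
        assert roc.sens_band.shape == (2, roc.thresholds.size)
        assert (roc.sens_band[0] <= roc.sens_band[1]).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestYouden:
    def test_perfect_separation_smallest_optimal_cutoff(self):
        roc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert best_threshold_youden(roc) == 0.8

    def test_exhaustive_scan_hand_example(self):
        roc = roc_auc(np.array([0.9, 0.6, 0.5, 0.55]), np.array([1, 1, 0, 0]))
        assert best_threshold_youden(roc) == 0.6  # sens 1, spec 1

    def test_all_tied_returns_smallest(self):
        roc = roc_auc(np.full(4, 0.3), np.array([1, 1, 0, 0]))
        assert best_threshold_youden(roc) == 0.3


class TestFisher:
    def test_unit_margins_uninformative(self):
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_diagonal_table_hypergeometric(self):
        from math import comb

        p = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_zero_margin_convention(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_matches_hypergeometric_enumeration(self):
        """Two-sided p = sum of hypergeometric probs <= observed prob."""
        table = np.array([[7, 2], [3, 8]])
        r1, r2 = table.sum(axis=1)
        c1 = table[:, 0].sum()
        n = table.sum()
        probs = [
            stats.hypergeom.pmf(a, n, r1, c1)
            for a in range(max(0, c1 - r2), min(r1, c1) + 1)
        ]
        obs = stats.hypergeom.pmf(table[0, 0], n, r1, c1)
        expected = sum(p for p in probs if p <= obs * (1 + 1e-9))
        assert fisher_exact_2x2(table) == pytest.approx(expected)


class TestChi2:
    def test_outer_product_table_is_independent(self):
        res = chi2_independence([[4, 6], [6, 9]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_scaled_identity_hand_computation(self):
        res = chi2_independence(np.eye(3, dtype=int) * 20)
        assert res.statistic == pytest.approx(120.0)
        assert res.df == 4
        assert res.pvalue == pytest.approx(
            stats.chi2.sf(120.0, 4), rel=1e-9
        )

    def test_zero_row_dropped_with_label(self):
        table = np.array([[5, 1, 0], [2, 7, 0], [0, 0, 0]])
        res = chi2_independence(table, labels=("A", "B", "C"))
        assert res.dropped == ("C",)

    def test_low_expected_flagged(self):
        res = chi2_independence([[2, 1], [1, 3]])
        assert res.low_expected


def two_class_spec(tpl, pa, pb, n=20, noise=0.0, seed=0):
    return SynthSpec(
        template=tpl,
        classes=(ClassSpec("A", n, pa), ClassSpec("B", n, pb)),
        background_noise=noise,
        seed=seed,
    )


@pytest.fixture(scope="module")
def tpl():
    return make_synthetic_template(32, 32, 4, seed=0)


class TestLoocv:
    def test_separable_classes_classified_perfectly(self, tpl):
        spec = two_class_spec(
            tpl, {"band_00": 1.0}, {"band_03": 1.0}, n=20, noise=0.0, seed=1
        )
        report = loocv(generate_cohort(spec), KDiseaseScheme())
        assert report.accuracy == 1.0
        assert np.array_equal(
            report.confusion.counts, np.diag(report.confusion.row_sums())
        )

    def test_row_sums_conserve_class_sizes(self, tpl):
        spec = two_class_spec(
            tpl, {"band_00": 0.8, "band_01": 0.3}, {"band_02": 0.7}, n=15,
            noise=0.05, seed=2,
        )
        cohort = generate_cohort(spec)
        report = loocv(cohort, KDiseaseScheme())
        sizes = cohort.class_sizes()
        assert report.confusion.row_sums().tolist() == [sizes["A"], sizes["B"]]

    def test_matches_naive_rebuild_oracle(self, tpl):
        """Vectorized LOOCV equals explicitly rebuilding the left-out profile.

        The naive oracle excludes the held-out drawing from its own class
        before building that class's profile, which also proves the
        protocol is leakage-free.
        """
        rng = np.random.default_rng(6)
        cohort = random_binary_cohort(rng, tpl, n_per_class=8)
        report = loocv(cohort, KDiseaseScheme())
        for _, row in report.predictions.iterrows():
            d = next(x for x in cohort.drawings if x.subject_id == row.subject_id)
            profiles = []
            for c in cohort.classes:
                members = [
                    x for x in cohort.by_class(c) if x.subject_id != d.subject_id
                ]
                assert len(members) == len(cohort.by_class(c)) - (
                    1 if c == d.label else 0
                )
                profiles.append(build_profile(members, c))
            assert classify_k(profiles, d).predicted == row.predicted

    def test_singleton_class_rejected_by_name(self, tpl):
        spec = SynthSpec(
            template=tpl,
            classes=(
                ClassSpec("big", 5, {"band_00": 1.0}),
                ClassSpec("lonely", 1, {"band_01": 1.0}),
            ),
            seed=0,
        )
        with pytest.raises(ValueError, match="lonely"):
            loocv(generate_cohort(spec), KDiseaseScheme())

    def test_identical_classes_hover_at_chance(self, tpl):
        """Mean LOOCV accuracy over seeded replicates stays near 1/2 when the
        two classes share one probability map."""
        probs = {"band_00": 0.6, "band_01": 0.4, "band_02": 0.3}
        accs = []
        for seed in range(60):
            spec = two_class_spec(tpl, probs, probs, n=30, noise=0.05, seed=seed)
            accs.append(loocv(generate_cohort(spec), KDiseaseScheme()).accuracy)
        accs = np.array(accs)
        se = accs.std(ddof=1) / np.sqrt(len(accs))
        assert abs(accs.mean() - 0.5) < 3 * se + 1e-12

    def test_binary_scheme_pools_and_scores(self, tpl):
        spec = SynthSpec(
            template=tpl,
            classes=(
                ClassSpec("A", 10, {"band_00": 0.9}),
                ClassSpec("B", 10, {"band_01": 0.9}),
                ClassSpec("C", 12, {"band_03": 0.8}),
            ),
            background_noise=0.02,
            seed=3,
        )
        cohort = generate_cohort(spec)
        scheme = BinaryScheme(
            positive_members=("A", "B"), negative_members=("C",),
            positive_label="AB", negative_label="C", threshold=0.5,
        )
        report = loocv(cohort, scheme, n_boot=50, seed=1)
        assert report.confusion.class_order == ("AB", "C")
        assert report.confusion.row_sums().tolist() == [20, 12]
        assert report.roc is not None and 0 <= report.roc.auc <= 1
        assert "fisher_p" in report.tests
        # normalized score and threshold rule agree with the recorded labels
        for _, row in report.predictions.iterrows():
            assert (row.predicted == "AB") == (row.score_positive >= 0.5)

    def test_binary_threshold_half_equals_argmax(self, tpl):
        rng = np.random.default_rng(8)
        cohort = random_binary_cohort(rng, tpl, n_per_class=10)
        b = loocv(
            cohort,
            BinaryScheme(("P",), ("Q",), positive_label="P", negative_label="Q"),
        )
        k = loocv(cohort, KDiseaseScheme())
        ties = b.predictions.tie_flag | k.predictions.tie_flag
        agree = (b.predictions.predicted == k.predictions.predicted) | ties
        assert agree.all()

    def test_uncovered_class_rejected(self, tpl):
        spec = SynthSpec(
            template=tpl,
            classes=(
                ClassSpec("A", 4, {"band_00": 1.0}),
                ClassSpec("B", 4, {"band_01": 1.0}),
                ClassSpec("C", 4, {"band_02": 1.0}),
            ),
            seed=0,
        )
        with pytest.raises(ValueError, match="no group"):
            loocv(
                generate_cohort(spec),
                BinaryScheme(("A",), ("B",)),
            )

    def test_nn_schemes_run_and_conserve(self, tpl):
        rng = np.random.default_rng(12)
        cohort = random_binary_cohort(rng, tpl, n_per_class=8)
        for scheme in (NearestNeighborScheme(), KernelNearestNeighborScheme()):
            report = loocv(cohort, scheme)
            assert report.confusion.row_sums().tolist() == [8, 8]
            assert (report.predictions.neighbor_id != report.predictions.subject_id).all()

    def test_nn_matches_per_query_classifier(self, tpl):
        from paindraw import Cohort, classify_nn

        rng = np.random.default_rng(13)
        cohort = random_binary_cohort(rng, tpl, n_per_class=6)
        report = loocv(cohort, NearestNeighborScheme())
        for i, d in enumerate(cohort.drawings):
            rest = Cohort(
                template=cohort.template,
                drawings=tuple(x for j, x in enumerate(cohort.drawings) if j != i),
                classes=cohort.classes,
            )
            assert classify_nn(rest, d).predicted == report.predictions.predicted[i]
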
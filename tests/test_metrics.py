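import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrnodseek.errors import ValidationError
from tcrnodseek.io import SubjectMetadata
from tcrnodseek.metrics import (
    auc_from_scores,
    confusion_metrics,
    evaluate_at_cutoff,
    expert_agreement_table,
    roc_auc,
    stratified_evaluation,
    youden_cutoff,
)


def brute_auc(scores, y01):
    """Exhaustive concordant-pair counting with half credit for ties."""
    pos = [s for s, y in zip(scores, y01) if y == 1]
    neg = [s for s, y in zip(scores, y01) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_youden(scores, y01):
    """Scan every unique score as a '>= cutoff' threshold."""
    pos = np.array([s for s, y in zip(scores, y01) if y == 1])
    neg = np.array([s for s, y in zip(scores, y01) if y == 0])
    best_c, best_j = None, -np.inf
    for c in sorted(set(scores)):
        j = (pos >= c).sum() / len(pos) - (neg >= c).sum() / len(neg)
        if j > best_j:
            best_c, best_j = c, j
    return best_c, best_j


class TestAUC:
    def test_perfect_separation(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = ["benign", "benign", "malignant", "malignant"]
        assert roc_auc(scores, labels).auc == 1.0

    def test_all_tied_scores(self):
        scores = [0.5, 0.5, 0.5, 0.5]
        labels = ["benign", "benign", "malignant", "malignant"]
        assert roc_auc(scores, labels).auc == pytest.approx(0.5)

    def test_hand_example_with_tie_matches_pair_counting(self):
        scores = [0.1, 0.4, 0.4, 0.35, 0.8, 0.65, 0.4, 0.9]
        y01 = [0, 0, 1, 0, 1, 1, 0, 1]
        labels = ["malignant" if y else "benign" for y in y01]
        assert roc_auc(scores, labels).auc == pytest.approx(
            brute_auc(scores, y01), abs=1e-12
        )
        assert auc_from_scores(scores, labels) == pytest.approx(
            brute_auc(scores, y01), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], ["benign", "benign"])

    def test_roc_points_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=30)
        labels = rng.choice(["benign", "malignant"], 30)
        while len(set(labels)) < 2:
            labels = rng.choice(["benign", "malignant"], 30)
        rep = roc_auc(scores, labels)
        pts = rep.roc_points
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()
        assert rep.auc == pytest.approx(
            np.trapezoid(pts[:, 1], pts[:, 0]), abs=1e-12
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_auc_complement_under_score_negation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.permutation(np.arange(n)).astype(float)  # tie-free
        y01 = np.zeros(n, int)
        y01[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if y01.all() or not y01.any():
            return
        a1 = auc_from_scores(scores, y01, positive=1)
        a2 = auc_from_scores(-scores, y01, positive=1)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)


class TestYouden:
    def test_separable_scores_take_lowest_gap_threshold(self):
        scores = [0.1, 0.2, 0.7, 0.9]
        labels = ["benign", "benign", "malignant", "malignant"]
        cutoff, j = youden_cutoff(scores, labels)
        assert j == 1.0
        assert cutoff == 0.7  # lowest threshold achieving J = 1

    def test_all_tied_scores_give_zero_j(self):
        cutoff, j = youden_cutoff([0.5] * 4, ["benign", "benign", "malignant", "malignant"])
        assert j == 0.0

    def test_ten_hand_scores_match_brute_scan(self):
        scores = [0.12, 0.3, 0.3, 0.44, 0.5, 0.51, 0.62, 0.62, 0.8, 0.97]
        y01 = [0, 0, 1, 0, 1, 0, 1, 1, 0, 1]
        labels = ["malignant" if y else "benign" for y in y01]
        cutoff, j = youden_cutoff(scores, labels)
        bc, bj = brute_youden(scores, y01)
        assert cutoff == bc and j == bj

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_matches_brute_scan_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = np.round(rng.normal(size=n), 1)  # induce ties
        y01 = rng.integers(0, 2, n)
        if y01.all() or not y01.any():
            return
        cutoff, j = youden_cutoff(scores, y01, positive=1)
        bc, bj = brute_youden(list(scores), list(y01))
        assert j == bj and cutoff == bc


class TestConfusion:
    LABELS = ["malignant"] * 12 + ["benign"] * 8

    def test_perfect_predictions(self):
        scores = [1.0] * 12 + [0.0] * 8
        m = confusion_metrics(scores, self.LABELS, cutoff=0.5)
        assert all(m[k] == 1.0 for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy"))

    def test_inverted_predictions(self):
        scores = [0.0] * 12 + [1.0] * 8
        m = confusion_metrics(scores, self.LABELS, cutoff=0.5)
        assert m["sensitivity"] == 0.0 and m["specificity"] == 0.0

    def test_hand_two_by_two_table(self):
        # TP=9, FN=3, FP=1, TN=7
        scores = [1.0] * 9 + [0.0] * 3 + [1.0] * 1 + [0.0] * 7
        m = confusion_metrics(scores, self.LABELS, cutoff=0.5)
        assert m["ppv"] == pytest.approx(0.9)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(0.875)
        assert m["npv"] == pytest.approx(0.7)
        assert m["accuracy"] == pytest.approx(0.8)

    def test_empty_denominator_reported_as_nan(self):
        scores = [0.0] * 12 + [0.0] * 8  # nothing called positive
        m = confusion_metrics(scores, self.LABELS, cutoff=0.5)
        assert np.isnan(m["ppv"]) and m["sensitivity"] == 0.0


class TestStratified:
    def metadata(self, n_b, n_m, **overrides):
        meta = []
        for i in range(n_b):
            meta.append(SubjectMetadata(f"B{i}", "benign", ggn=False, nodule_size_mm=12.0))
        for i in range(n_m):
            meta.append(
                SubjectMetadata(f"M{i}", "malignant", stage="I", ggn=False, nodule_size_mm=12.0)
            )
        for m in meta:
            for k, v in overrides.get(m.subject_id, {}).items():
                setattr(m, k, v)
        return meta

    def test_whole_cohort_stratum_equals_global_report(self):
        meta = self.metadata(5, 5)
        rng = np.random.default_rng(0)
        scores = np.r_[rng.uniform(0, 0.5, 5), rng.uniform(0.5, 1, 5)]
        labels = ["benign"] * 5 + ["malignant"] * 5
        report, waterfall = stratified_evaluation(
            scores, labels, meta, cutoff=0.5, strata=("size_le_20",)
        )
        sub = report.strata["size_le_20"]
        assert sub.auc == report.auc
        assert sub.at_cutoff == report.at_cutoff
        assert len(waterfall) == 10
        assert (np.diff(waterfall["predicted_value"]) >= 0).all()

    def test_single_class_stratum_flagged_insufficient(self):
        meta = self.metadata(5, 5, **{"M0": {"ggn": True}})
        scores = np.linspace(0, 1, 10)
        labels = ["benign"] * 5 + ["malignant"] * 5
        report, _ = stratified_evaluation(scores, labels, meta, 0.5, strata=("ggn",))
        assert report.strata["ggn"] == {"insufficient": True, "n": 1}
        assert report.strata["non_ggn"].auc == 1.0

    def test_effect_confined_to_non_ggn_stratum(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            meta = self.metadata(20, 20)
            for m in meta:
                m.ggn = rng.random() < 0.4
            labels = [m.label for m in meta]
            scores = np.empty(40)
            for i, m in enumerate(meta):
                if m.ggn:
                    scores[i] = rng.uniform()  # no signal among GGN
                else:
                    base = 0.7 if m.label == "malignant" else 0.3
                    scores[i] = np.clip(rng.normal(base, 0.15), 0, 1)
            report, _ = stratified_evaluation(scores, labels, meta, 0.5, strata=("ggn",))
            if (
                isinstance(report.strata["ggn"], dict)
                or report.strata["non_ggn"].auc > report.strata["ggn"].auc
            ):
                wins += 1
        assert wins >= 8

    def test_unknown_stratum_rejected(self):
        meta = self.metadata(2, 2)
        with pytest.raises(ValidationError, match="volume"):
            stratified_evaluation(
                [0.1, 0.2, 0.8, 0.9],
                ["benign", "benign", "malignant", "malignant"],
                meta,
                0.5,
                strata=("volume",),
            )

    def test_stage_strata_compare_against_all_benign(self):
        meta = self.metadata(4, 4, **{"M2": {"stage": "II"}, "M3": {"stage": "II"}})
        scores = [0.1, 0.2, 0.15, 0.25, 0.9, 0.8, 0.6, 0.7]
        labels = ["benign"] * 4 + ["malignant"] * 4
        report, _ = stratified_evaluation(scores, labels, meta, 0.5, strata=("stage",))
        assert set(report.strata) == {"stage_I", "stage_II"}
        assert report.strata["stage_I"].n_pos == 2
        assert report.strata["stage_I"].n_neg == 4


class TestExpertAgreement:
    def test_model_equal_truth_has_no_misclassification(self):
        truth = ["benign", "malignant", "benign"]
        counts, acc, mis = expert_agreement_table(
            truth, truth, {"radiologist": ["benign", "benign", "benign"]}, ["A", "B", "C"]
        )
        assert mis["model"] == []
        assert acc["model"] == 1.0
        assert mis["radiologist"] == ["B"]

    def test_expert_identical_to_model_gives_symmetric_table(self):
        truth = ["benign", "malignant", "malignant", "benign"]
        model = ["benign", "benign", "malignant", "malignant"]
        counts, acc, mis = expert_agreement_table(
            truth, model, {"doc": model}, ["A", "B", "C", "D"]
        )
        assert (counts["model"] == counts["doc"]).all()
        assert acc["model"] == acc["doc"]

    def test_six_subject_hand_tally(self):
        truth = ["benign", "benign", "benign", "malignant", "malignant", "malignant"]
        model = ["benign", "malignant", "benign", "malignant", "malignant", "benign"]
        doc = ["benign", "benign", "malignant", "malignant", "benign", "benign"]
        ids = list("ABCDEF")
        counts, acc, mis = expert_agreement_table(truth, model, {"doc": doc}, ids)
        assert int(counts["n"].sum()) == 6
        assert acc["model"] == pytest.approx(4 / 6)
        assert acc["doc"] == pytest.approx(3 / 6)
        assert mis["model"] == ["B", "F"]
        row = counts[
            (counts["truth"] == "benign")
            & (counts["model"] == "benign")
            & (counts["doc"] == "benign")
        ]
        assert int(row["n"].iloc[0]) == 1

    def test_misaligned_ids_rejected(self):
        with pytest.raises(ValidationError):
            expert_agreement_table(["benign"], ["benign", "malignant"], {}, ["A"])


def test_evaluate_at_cutoff_combines_roc_and_confusion():
    scores = [0.2, 0.3, 0.6, 0.9]
    labels = ["benign", "benign", "malignant", "malignant"]
    rep = evaluate_at_cutoff(scores, labels, cutoff=0.5)
    assert rep.auc == 1.0
    assert rep.at_cutoff["accuracy"] == 1.0
    assert rep.cutoff == 0.5
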
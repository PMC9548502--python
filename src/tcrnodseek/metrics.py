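"""ROC/AUC, Youden cutoff, confusion metrics and stratified evaluation.

AUC uses the rank (Mann–Whitney) formulation with half credit for ties,
which is identical to the trapezoidal integral of the ROC curve swept over
the unique observed scores.  The Youden cutoff is the lowest threshold
maximising J = sensitivity + specificity − 1 under the rule
"positive iff score >= cutoff".
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .errors import ValidationError

POSITIVE_LABEL = "malignant"


def _binarise(labels, positive) -> np.ndarray:
    y = np.asarray(labels)
    pos = y == positive
    if pos.all() or not pos.any():
        raise ValidationError("both classes must be present")
    return pos.astype(int)


def auc_from_scores(scores, labels, positive=POSITIVE_LABEL) -> float:
    """Mann–Whitney AUC with half credit for tied scores."""
    y = _binarise(labels, positive)
    s = np.asarray(scores, dtype=float)
    r = rankdata(s)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class EvaluationReport:
    """ROC summary plus confusion metrics at an operating cutoff."""

    auc: float
    roc_points: np.ndarray = field(repr=False)  # (fpr, tpr) rows
    cutoff: float | None = None
    at_cutoff: dict | None = None
    n_pos: int = 0
    n_neg: int = 0
    strata: dict | None = None

    def to_dict(self) -> dict:
        out = {
            "auc": self.auc,
            "roc_points": self.roc_points.tolist(),
            "cutoff": self.cutoff,
            "at_cutoff": self.at_cutoff,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }
        if self.strata is not None:
            out["strata"] = {
                k: (v.to_dict() if isinstance(v, EvaluationReport) else v)
                for k, v in self.strata.items()
            }
        return out


def roc_auc(scores, labels, positive=POSITIVE_LABEL) -> EvaluationReport:
    """ROC curve (threshold sweep over unique scores) and its AUC.

    The returned AUC is the trapezoidal integral of the ROC points, which
    for this sweep equals the rank-statistic AUC with half-credit ties.
    """
    y = _binarise(labels, positive)
    s = np.asarray(scores, dtype=float)
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return EvaluationReport(
        auc=auc, roc_points=points, n_pos=int(y.sum()), n_neg=int(y.size - y.sum())
    )


def youden_cutoff(scores, labels, positive=POSITIVE_LABEL) -> tuple[float, float]:
    """Lowest threshold maximising J = sensitivity + specificity − 1.

    Candidate thresholds are the unique observed scores; a subject is called
    positive when its score >= cutoff.
    """
    y = _binarise(labels, positive)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    candidates = np.unique(s)  # ascending
    order = np.argsort(s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # for cutoff c: positives called = those with s >= c
    pos_cum = np.cumsum(y_sorted[::-1])[::-1]  # pos with score >= s_sorted[i]
    neg_cum = np.cumsum((1 - y_sorted)[::-1])[::-1]
    idx = np.searchsorted(s_sorted, candidates, side="left")
    tp = pos_cum[idx]
    fp = neg_cum[idx]
    j = tp / n_pos - fp / n_neg
    best = int(np.argmax(j))  # argmax returns the first (lowest) maximiser
    return float(candidates[best]), float(j[best])


def confusion_metrics(scores, labels, cutoff, positive=POSITIVE_LABEL) -> dict:
    """Sensitivity/specificity/PPV/NPV/accuracy at a cutoff.

    Metrics with an empty denominator are reported as NaN rather than
    raising.
    """
    y = _binarise(labels, positive)
    pred = (np.asarray(scores, dtype=float) >= cutoff).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())

    def ratio(num, den):
        return float(num / den) if den else float("nan")

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "accuracy": ratio(tp + tn, tp + fp + tn + fn),
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }


def evaluate_at_cutoff(scores, labels, cutoff, positive=POSITIVE_LABEL) -> EvaluationReport:
    """ROC report augmented with confusion metrics at the given cutoff."""
    report = roc_auc(scores, labels, positive=positive)
    report.cutoff = float(cutoff)
    report.at_cutoff = confusion_metrics(scores, labels, cutoff, positive=positive)
    return report


DEFAULT_STRATA = ("ggn", "size_le_20", "size_le_10", "stage")


def _stratum_masks(metadata_by_id, subject_ids, strata):
    """Yield (name, boolean mask over subject_ids) for each requested stratum."""
    meta = [metadata_by_id[s] for s in subject_ids]
    for key in strata:
        if key == "ggn":
            yield "ggn", np.array([m.ggn for m in meta])
            yield "non_ggn", np.array([not m.ggn for m in meta])
        elif key in ("size_le_20", "size_le_10"):
            limit = 20.0 if key.endswith("20") else 10.0
            yield key, np.array(
                [m.nodule_size_mm is not None and m.nodule_size_mm <= limit for m in meta]
            )
        elif key == "stage":
            stages = sorted({m.stage for m in meta if m.stage is not None})
            for st in stages:
                # each malignant stage evaluated against all benign subjects
                yield f"stage_{st}", np.array(
                    [m.label == "benign" or m.stage == st for m in meta]
                )
        else:
            raise ValidationError(f"unknown stratum key {key!r}")


def stratified_evaluation(
    scores,
    labels,
    metadata,
    cutoff,
    subject_ids=None,
    strata=DEFAULT_STRATA,
    positive=POSITIVE_LABEL,
) -> tuple[EvaluationReport, pd.DataFrame]:
    """Global report plus per-stratum sub-reports at the global cutoff.

    Strata with a single class are flagged ``insufficient`` rather than
    failing the whole evaluation.  Also returns the waterfall table of
    predicted value − cutoff, sorted by predicted value.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if subject_ids is None:
        subject_ids = [m.subject_id for m in metadata]
    subject_ids = list(subject_ids)
    if len(subject_ids) != len(s):
        raise ValidationError("scores and subject ids are misaligned")
    by_id = {m.subject_id: m for m in metadata}
    missing = [sid for sid in subject_ids if sid not in by_id]
    if missing:
        raise ValidationError(f"subjects without metadata: {missing}")

    report = evaluate_at_cutoff(s, y, cutoff, positive=positive)
    report.strata = {}
    for name, mask in _stratum_masks(by_id, subject_ids, strata):
        if mask.sum() == 0 or len(np.unique(y[mask])) < 2:
            report.strata[name] = {"insufficient": True, "n": int(mask.sum())}
            continue
        report.strata[name] = evaluate_at_cutoff(
            s[mask], y[mask], cutoff, positive=positive
        )

    waterfall = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "predicted_value": s,
            "delta_from_cutoff": s - cutoff,
            "label": y,
        }
    ).sort_values(
        ["predicted_value", "subject_id"], kind="stable"
    ).reset_index(drop=True)
    return report, waterfall


def expert_agreement_table(truth, model_labels, expert_labels: dict, subject_ids):
    """Cross-tabulate pathology truth vs model and expert calls.

    ``expert_labels`` maps rater name → label sequence aligned with
    ``subject_ids``.  Returns (counts DataFrame over every observed
    (truth, model, rater...) combination, per-source accuracy dict,
    per-source misclassified subject lists).
    """
    subject_ids = list(subject_ids)
    n = len(subject_ids)
    cols = {"truth": list(truth), "model": list(model_labels)}
    for rater, labels in expert_labels.items():
        cols[rater] = list(labels)
    for name, vals in cols.items():
        if len(vals) != n:
            raise ValidationError(f"{name!r} labels misaligned with subject ids")
    df = pd.DataFrame(cols, index=subject_ids)
    counts = (
        df.groupby(list(cols.keys()), observed=True)
        .size()
        .rename("n")
        .reset_index()
        .sort_values(list(cols.keys()), kind="stable")
        .reset_index(drop=True)
    )
    accuracy = {
        source: float((df[source] == df["truth"]).mean())
        for source in cols
        if source != "truth"
    }
    misclassified = {
        source: sorted(df.index[df[source] != df["truth"]].tolist())
        for source in cols
        if source != "truth"
    }
    return counts, accuracy, misclassified
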
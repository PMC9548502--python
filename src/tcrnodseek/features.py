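"""Cohort feature assembly and RF-importance / information-gain selection.

The cohort feature table joins the per-subject diversity profile with the
clinical covariates (GGN flag, nodule size, age, sex) on subject id.
Features are ranked by two complementary criteria — mean-decrease-impurity
importance from a random forest, and information gain of the label given
the (quartile-discretised) feature — and fused by mean rank position.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .diversity import PROFILE_FEATURES, profiles_to_frame
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: feature columns derived from the TCR repertoire
TCR_FEATURES: tuple[str, ...] = PROFILE_FEATURES
#: clinical covariate columns
CLINICAL_FEATURES: tuple[str, ...] = ("ggn", "nodule_size_mm", "age_years", "sex")

LABEL_COLUMN = "label"
_SEX_CODES = {"M": 0.0, "F": 1.0}


def assemble_features(profiles, metadata) -> pd.DataFrame:
    """Inner-join diversity profiles with clinical covariates.

    Returns a subjects × (TCR features + clinical covariates + label)
    DataFrame.  Categorical covariates are encoded (sex M→0/F→1, ggn→0/1)
    and missing numeric covariates are median-imputed; every imputation is
    logged.
    """
    frame = profiles_to_frame(profiles)
    meta = {m.subject_id: m for m in metadata}
    unmatched = [s for s in frame.index if s not in meta]
    if unmatched:
        raise ValidationError(f"profiles without metadata: {unmatched}")
    clin = pd.DataFrame(
        {
            "ggn": {s: float(meta[s].ggn) for s in frame.index},
            "nodule_size_mm": {
                s: (np.nan if meta[s].nodule_size_mm is None else meta[s].nodule_size_mm)
                for s in frame.index
            },
            "age_years": {
                s: (np.nan if meta[s].age_years is None else meta[s].age_years)
                for s in frame.index
            },
            "sex": {
                s: _SEX_CODES.get(meta[s].sex, np.nan) for s in frame.index
            },
        }
    )
    table = frame.join(clin)
    for col in CLINICAL_FEATURES:
        n_missing = int(table[col].isna().sum())
        if n_missing:
            median = float(table[col].median())
            logger.info(
                "imputed %d missing %r value(s) with cohort median %r",
                n_missing, col, median,
            )
            table[col] = table[col].fillna(median)
    table[LABEL_COLUMN] = [meta[s].label for s in table.index]
    return table


def split_features_labels(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a cohort feature table into (features, labels)."""
    if LABEL_COLUMN not in table.columns:
        raise ValidationError(f"feature table lacks a {LABEL_COLUMN!r} column")
    return table.drop(columns=[LABEL_COLUMN]), table[LABEL_COLUMN].to_numpy()


def _entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(
    feature, labels, n_bins: int = 4, binning: str = "quantile"
) -> float:
    """Information gain (bits) of the class label given a discretised feature.

    Continuous features are discretised into ``n_bins`` quantile bins by
    default (``binning="width"`` uses equal-width bins); features with at
    most ``n_bins`` distinct values are used as-is.  IG is bounded by the
    label entropy and is 0 for a constant feature.
    """
    x = pd.Series(np.asarray(feature))
    y = np.asarray(labels)
    if x.size != y.size or x.size < 2:
        raise ValidationError("feature and labels must align with >= 2 subjects")
    if len(np.unique(y)) < 2:
        raise ValidationError("labels contain a single class")
    if x.nunique() <= 1:
        return 0.0
    if x.nunique() <= n_bins:
        groups = x.astype("category")
    elif binning == "quantile":
        groups = pd.qcut(x, n_bins, duplicates="drop")
    elif binning == "width":
        groups = pd.cut(x, n_bins, duplicates="drop")
    else:
        raise ValidationError(f"unknown binning {binning!r}")
    h = _entropy_bits(y)
    h_cond = 0.0
    for _, idx in pd.Series(np.arange(x.size)).groupby(groups.values, observed=True):
        h_cond += idx.size / x.size * _entropy_bits(y[idx.to_numpy()])
    return h - h_cond


def rf_importance(
    table: pd.DataFrame,
    labels,
    n_estimators: int = 500,
    random_state: int = 0,
) -> pd.Series:
    """Mean-decrease-impurity importances, normalised to sum to 1."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValidationError("need >= 2 subjects in each of two classes")
    rf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=random_state,
    ).fit(table.to_numpy(dtype=float), y)
    imp = pd.Series(rf.feature_importances_, index=table.columns)
    total = imp.sum()
    return imp / total if total > 0 else imp


def rank_features(
    table: pd.DataFrame,
    labels,
    n_estimators: int = 500,
    n_bins: int = 4,
    random_state: int = 0,
) -> pd.DataFrame:
    """Rank features by random-forest importance and information gain.

    Constant columns are dropped with a warning before ranking.  The
    combined order is the mean of the two per-method rank positions, with
    ties broken by higher information gain, then feature name.
    """
    const = [c for c in table.columns if table[c].nunique() <= 1]
    if const:
        warnings.warn(
            f"dropping constant feature column(s): {const}", RuntimeWarning,
            stacklevel=2,
        )
        table = table.drop(columns=const)
    if table.shape[1] == 0:
        raise ValidationError("no non-constant features to rank")
    imp = rf_importance(table, labels, n_estimators=n_estimators,
                        random_state=random_state)
    ig = pd.Series(
        {c: information_gain(table[c], labels, n_bins=n_bins) for c in table.columns}
    )
    return fuse_rankings(imp, ig)


def fuse_rankings(rf_imp: pd.Series, info_gain: pd.Series) -> pd.DataFrame:
    """Fuse the two criteria by mean rank position.

    Average-rank ties are broken by higher information gain, then feature
    name; ``combined_rank`` numbers the final order from 1.
    """
    rf_imp = rf_imp.astype(float)
    info_gain = info_gain.reindex(rf_imp.index).astype(float)
    rf_rank = rankdata(-rf_imp.to_numpy(), method="average")
    ig_rank = rankdata(-info_gain.to_numpy(), method="average")
    ranking = pd.DataFrame(
        {
            "rf_importance": rf_imp,
            "info_gain": info_gain,
            "rf_rank": rf_rank,
            "ig_rank": ig_rank,
            "mean_rank": (rf_rank + ig_rank) / 2.0,
        }
    )
    order = sorted(
        ranking.index,
        key=lambda c: (ranking.at[c, "mean_rank"], -ranking.at[c, "info_gain"], c),
    )
    ranking = ranking.loc[order]
    ranking["combined_rank"] = np.arange(1, len(order) + 1)
    return ranking


def select_top_features(ranking: pd.DataFrame, k: int = 3) -> list[str]:
    """The top-k features of a :func:`rank_features` ranking."""
    if k > len(ranking):
        raise ValidationError(
            f"k={k} exceeds the {len(ranking)} ranked features"
        )
    return list(ranking.index[:k])


class RankedFeatureSelector(SelectorMixin, BaseEstimator):
    """Scikit-learn transformer selecting the top-k features by RF + IG.

    Parameters
    ----------
    k : int
        Number of features to keep.
    n_estimators : int
        Trees in the random forest used for importance.
    n_bins : int
        Quantile bins for information-gain discretisation.
    random_state : int
        Seed for the random forest.

    Attributes
    ----------
    ranking_ : DataFrame with both criteria and the fused order.
    selected_features_ : list of the k retained feature names.
    """

    def __init__(self, k: int = 3, n_estimators: int = 500, n_bins: int = 4,
                 random_state: int = 0):
        self.k = k
        self.n_estimators = n_estimators
        self.n_bins = n_bins
        self.random_state = random_state

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            table = X
        else:
            X = np.asarray(X, dtype=float)
            table = pd.DataFrame(
                X, columns=[f"x{i}" for i in range(X.shape[1])]
            )
        self.feature_names_in_ = np.asarray(table.columns, dtype=object)
        self.n_features_in_ = table.shape[1]
        self.ranking_ = rank_features(
            table,
            y,
            n_estimators=self.n_estimators,
            n_bins=self.n_bins,
            random_state=self.random_state,
        )
        self.selected_features_ = select_top_features(self.ranking_, k=self.k)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "selected_features_")
        keep = set(self.selected_features_)
        return np.array([c in keep for c in self.feature_names_in_])
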
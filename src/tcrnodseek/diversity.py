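"""Repertoire diversity indices, clonal-homeostasis binning and group tests.

All entropies use natural logarithms.  Evenness is Pielou's J = H / ln S and
clonality is 1 − J; for a monoclonal repertoire (S = 1) the limiting
convention evenness = 0, clonality = 1 applies.  The Simpson index is the
Gini–Simpson form 1 − Σ pᵢ².

Clones are classified into the five standard clonal-homeostasis bins by
clonal fraction, using right-closed intervals:

    rare (0, 1e-5], small (1e-5, 1e-4], medium (1e-4, 1e-3],
    large (1e-3, 1e-2], hyperexpanded (1e-2, 1].
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InsufficientDataError, ValidationError
from .io import Repertoire

DEFAULT_CLONE_TYPE_BINS: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 1e-2)
CLONE_TYPE_NAMES: tuple[str, ...] = ("rare", "small", "medium", "large", "hyperexpanded")

#: diversity-profile feature columns, in canonical output order
PROFILE_FEATURES: tuple[str, ...] = (
    "richness",
    "shannon",
    "evenness",
    "simpson",
    "clonality",
    "clone_reads",
    "frac_rare",
    "frac_small",
    "frac_medium",
    "frac_large",
    "frac_hyperexpanded",
)


def _check_fractions(fractions) -> np.ndarray:
    p = np.asarray(fractions, dtype=float)
    if p.size == 0:
        raise ValidationError("empty clonal-fraction vector")
    if (p <= 0).any():
        raise ValidationError("clonal fractions must be strictly positive")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"clonal fractions must sum to 1 (got {p.sum()!r})"
        )
    return p


def shannon_index(fractions) -> float:
    """Shannon entropy H = −Σ pᵢ ln pᵢ of the clonal-fraction distribution."""
    p = _check_fractions(fractions)
    return float(-(p * np.log(p)).sum())


def evenness_clonality(fractions) -> tuple[float, float]:
    """Pielou evenness H/ln S and clonality 1 − evenness."""
    p = _check_fractions(fractions)
    if p.size == 1:
        return 0.0, 1.0
    evenness = shannon_index(p) / np.log(p.size)
    return float(evenness), float(1.0 - evenness)


def simpson_index(fractions) -> float:
    """Gini–Simpson index 1 − Σ pᵢ²."""
    p = _check_fractions(fractions)
    return float(1.0 - (p ** 2).sum())


def _check_bins(bins) -> np.ndarray:
    b = np.asarray(bins, dtype=float)
    if b.size != 4 or (b <= 0).any() or (b >= 1).any() or (np.diff(b) <= 0).any():
        raise ConfigError(
            "clone-type bins must be 4 strictly increasing thresholds in (0, 1)"
        )
    return b


def classify_clone_types(
    repertoire: Repertoire,
    bins=DEFAULT_CLONE_TYPE_BINS,
    weight_by: str = "reads",
) -> dict[str, float]:
    """Partition a repertoire's clones into the five homeostasis bins.

    Each clone falls into exactly one right-closed fraction interval.  With
    ``weight_by="reads"`` the returned map holds the read-mass per bin (the
    quantity used for group comparisons); ``weight_by="clones"`` returns the
    fraction of distinct clones per bin instead.
    """
    b = _check_bins(bins)
    if weight_by not in ("reads", "clones"):
        raise ConfigError(f"weight_by must be 'reads' or 'clones', got {weight_by!r}")
    f = repertoire.fractions
    idx = np.searchsorted(b, f, side="left")  # bin i: b[i-1] < f <= b[i]
    weights = f if weight_by == "reads" else np.full(f.size, 1.0 / f.size)
    mass = np.bincount(idx, weights=weights, minlength=5)
    return {name: float(mass[i]) for i, name in enumerate(CLONE_TYPE_NAMES)}


@dataclass
class DiversityProfile:
    """Per-subject repertoire feature vector."""

    subject_id: str
    richness: int
    shannon: float
    evenness: float
    simpson: float
    clonality: float
    clone_reads: int
    clone_type_fractions: dict[str, float]

    def as_row(self) -> dict[str, float]:
        row = {
            "richness": self.richness,
            "shannon": self.shannon,
            "evenness": self.evenness,
            "simpson": self.simpson,
            "clonality": self.clonality,
            "clone_reads": self.clone_reads,
        }
        for name in CLONE_TYPE_NAMES:
            row[f"frac_{name}"] = self.clone_type_fractions[name]
        return row


def diversity_profile(
    repertoire: Repertoire, bins=DEFAULT_CLONE_TYPE_BINS
) -> DiversityProfile:
    """Compute all diversity indices and bin masses for one repertoire."""
    f = repertoire.fractions
    h = shannon_index(f)
    evenness, clonality = evenness_clonality(f)
    return DiversityProfile(
        subject_id=repertoire.subject_id,
        richness=int(f.size),
        shannon=h,
        evenness=evenness,
        simpson=simpson_index(f),
        clonality=clonality,
        clone_reads=repertoire.total_count,
        clone_type_fractions=classify_clone_types(repertoire, bins=bins),
    )


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Stack diversity profiles into a subjects × features DataFrame."""
    rows = {p.subject_id: p.as_row() for p in profiles}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df[list(PROFILE_FEATURES)]


@dataclass
class GroupComparisonResult:
    """Two-sided Wilcoxon rank-sum comparison of one feature between groups."""

    feature: str
    group_a: str
    group_b: str
    statistic: float  # rank sum of group_a in the pooled ranking
    p_value: float
    direction: int  # sign of median(group_a) − median(group_b)
    n_a: int
    n_b: int
    stratum: str | None = None
    test: str = "wilcoxon-rank-sum"


def _rank_sum_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.ptp(np.concatenate([a, b])) == 0:
        # all observations identical: no evidence either way
        w = len(a) * (len(a) + len(b) + 1) / 2.0
        return w, 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    w = float(res.statistic) + len(a) * (len(a) + 1) / 2.0
    return w, float(res.pvalue)


def compare_groups(
    profiles,
    metadata,
    feature: str,
    stratify_by: str | None = None,
    group_a: str = "benign",
    group_b: str = "malignant",
):
    """Wilcoxon rank-sum test of a diversity feature between the two groups.

    With ``stratify_by`` (a boolean metadata attribute such as ``ggn``) the
    test is run separately within each stratum and a dict keyed by stratum
    name is returned; otherwise a single
    :class:`GroupComparisonResult` is returned.
    """
    frame = profiles_to_frame(profiles)
    if feature not in frame.columns:
        raise ValidationError(f"unknown feature {feature!r}")
    meta = {m.subject_id: m for m in metadata}
    missing = [s for s in frame.index if s not in meta]
    if missing:
        raise ValidationError(f"subjects without metadata: {missing}")

    def run(subject_ids, stratum=None) -> GroupComparisonResult:
        va = frame.loc[
            [s for s in subject_ids if meta[s].label == group_a], feature
        ].to_numpy(dtype=float)
        vb = frame.loc[
            [s for s in subject_ids if meta[s].label == group_b], feature
        ].to_numpy(dtype=float)
        where = f" in stratum {stratum!r}" if stratum else ""
        if len(va) < 2 or len(vb) < 2:
            raise InsufficientDataError(
                f"need >= 2 subjects per group{where}: "
                f"{group_a} n={len(va)}, {group_b} n={len(vb)}"
            )
        w, p = _rank_sum_test(va, vb)
        return GroupComparisonResult(
            feature=feature,
            group_a=group_a,
            group_b=group_b,
            statistic=w,
            p_value=p,
            direction=int(np.sign(np.median(va) - np.median(vb))),
            n_a=len(va),
            n_b=len(vb),
            stratum=stratum,
        )

    if stratify_by is None:
        return run(list(frame.index))
    strata: dict[str, list[str]] = {}
    for sid in frame.index:
        value = getattr(meta[sid], stratify_by)
        name = f"{stratify_by}={value}"
        strata.setdefault(name, []).append(sid)
    return {name: run(ids, stratum=name) for name, ids in sorted(strata.items())}


def correlate_features_clinical(
    profiles,
    metadata,
    features=None,
    covariates=("nodule_size_mm", "age_years"),
) -> pd.DataFrame:
    """Spearman correlation of each TCR feature with each clinical covariate.

    Rank correlation uses tie-corrected ranks (scipy); pairs with a missing
    covariate are dropped per pair (pairwise-complete).  A constant feature
    or covariate yields NaN with a warning rather than an error.
    """
    frame = profiles_to_frame(profiles)
    if features is None:
        features = list(PROFILE_FEATURES)
    meta = pd.DataFrame(
        {
            "nodule_size_mm": {m.subject_id: m.nodule_size_mm for m in metadata},
            "age_years": {m.subject_id: m.age_years for m in metadata},
        }
    ).astype(float)
    rows = []
    for feat in features:
        for cov in covariates:
            x = frame[feat]
            y = meta.reindex(frame.index)[cov]
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            if n < 3:
                raise InsufficientDataError(
                    f"need >= 3 complete pairs for {feat} vs {cov}, got {n}"
                )
            if x[ok].nunique() <= 1 or y[ok].nunique() <= 1:
                warnings.warn(
                    f"constant input for {feat} vs {cov}; rho undefined",
                    RuntimeWarning,
                    stacklevel=2,
                )
                rho, p = float("nan"), float("nan")
            else:
                rho, p = stats.spearmanr(x[ok], y[ok])
            rows.append(
                {"feature": feat, "covariate": cov, "rho": float(rho),
                 "p_value": float(p), "n": n}
            )
    return pd.DataFrame(rows)
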
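import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from tcrnodseek.diversity import (
    DEFAULT_CLONE_TYPE_BINS,
    CLONE_TYPE_NAMES,
    classify_clone_types,
    compare_groups,
    correlate_features_clinical,
    diversity_profile,
    evenness_clonality,
    profiles_to_frame,
    shannon_index,
    simpson_index,
)
from tcrnodseek.errors import ConfigError, InsufficientDataError, ValidationError
from tcrnodseek.io import SubjectMetadata

from conftest import repertoire_from_counts


def brute_shannon(p):
    return -sum(x * math.log(x) for x in p)


class TestIndices:
    def test_shannon_uniform_is_log_s(self):
        assert shannon_index([0.25] * 4) == pytest.approx(math.log(4), abs=1e-12)

    def test_shannon_single_clone_is_zero(self):
        assert shannon_index([1.0]) == 0.0

    def test_shannon_matches_term_by_term_oracle(self):
        p = [0.5, 0.3, 0.2]
        assert shannon_index(p) == pytest.approx(brute_shannon(p), abs=1e-15)

    def test_evenness_uniform_and_single(self):
        assert evenness_clonality([0.2] * 5) == pytest.approx((1.0, 0.0), abs=1e-12)
        assert evenness_clonality([1.0]) == (0.0, 1.0)

    def test_evenness_oracle(self):
        p = [0.5, 0.3, 0.2]
        e, c = evenness_clonality(p)
        assert e == pytest.approx(brute_shannon(p) / math.log(3), abs=1e-15)
        assert c == pytest.approx(1 - e, abs=0)

    def test_simpson_closed_forms_and_oracle(self):
        assert simpson_index([1.0]) == 0.0
        assert simpson_index([0.1] * 10) == pytest.approx(0.9, abs=1e-12)
        assert simpson_index([0.5, 0.3, 0.2]) == pytest.approx(0.62, abs=1e-12)

    @pytest.mark.parametrize("bad", [[0.5, 0.4], [], [0.5, 0.5, 0.5], [1.2, -0.2]])
    def test_invalid_fraction_vectors_rejected(self, bad):
        with pytest.raises(ValidationError):
            shannon_index(bad)

    def test_invariants_on_random_repertoires(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            rep = repertoire_from_counts(rng.integers(1, 200, rng.integers(1, 100)))
            f = rep.fractions
            h = shannon_index(f)
            e, c = evenness_clonality(f)
            s = simpson_index(f)
            assert 0 <= s < 1
            assert -1e-12 <= h <= math.log(len(f)) + 1e-12
            assert 0 <= e <= 1
            assert c == 1 - e  # exact complement

    @given(
        st.lists(st.floats(0.01, 10.0), min_size=3, max_size=20),
        st.data(),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_merging_two_clones_never_increases_entropy(self, weights, data):
        p = np.asarray(weights) / np.sum(weights)
        i, j = data.draw(
            st.tuples(
                st.integers(0, len(p) - 1), st.integers(0, len(p) - 1)
            ).filter(lambda t: t[0] != t[1])
        )
        merged = np.delete(p, [i, j])
        merged = np.append(merged, p[i] + p[j])
        assert shannon_index(merged / merged.sum()) <= shannon_index(p / p.sum()) + 1e-9


class TestCloneTypes:
    def test_single_clone_is_hyperexpanded(self):
        rep = repertoire_from_counts([5])
        masses = classify_clone_types(rep)
        assert masses["hyperexpanded"] == 1.0
        assert sum(masses.values()) == 1.0

    def test_default_threshold_edges(self):
        # a clone at fraction 1e-6 is rare ...
        rep = repertoire_from_counts([999_999, 1])
        masses = classify_clone_types(rep)
        assert masses["rare"] == pytest.approx(1e-6, abs=1e-15)
        # ... and one at 0.05 is hyperexpanded
        rep2 = repertoire_from_counts([5, 95])
        masses = classify_clone_types(rep2)
        assert masses["hyperexpanded"] == 1.0  # 0.05 and 0.95 both > 1e-2

    def test_masses_match_per_clone_loop(self):
        rng = np.random.default_rng(3)
        rep = repertoire_from_counts(rng.integers(1, 10_000, 50))
        masses = classify_clone_types(rep)
        bins = DEFAULT_CLONE_TYPE_BINS
        expected = dict.fromkeys(CLONE_TYPE_NAMES, 0.0)
        for frac in rep.fractions:
            for name, hi in zip(CLONE_TYPE_NAMES, (*bins, 1.0)):
                if frac <= hi:
                    expected[name] += frac
                    break
        for name in CLONE_TYPE_NAMES:
            assert masses[name] == pytest.approx(expected[name], abs=1e-12)

    def test_clone_count_weighting(self):
        rep = repertoire_from_counts([98, 1, 1])
        by_clones = classify_clone_types(rep, weight_by="clones")
        assert by_clones["hyperexpanded"] == pytest.approx(1 / 3)
        assert sum(by_clones.values()) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "bins", [(0.1, 0.05, 0.2, 0.3), (0.0, 0.1, 0.2, 0.3), (0.1, 0.2, 0.3)]
    )
    def test_malformed_thresholds_rejected(self, bins):
        rep = repertoire_from_counts([1, 1])
        with pytest.raises(ConfigError):
            classify_clone_types(rep, bins=bins)


def _profiles(values, prefix):
    """Diversity profiles whose shannon equals the given values."""
    out = []
    for i, v in enumerate(values):
        rep = repertoire_from_counts([1, 1, 1])
        p = diversity_profile(rep)
        p.subject_id = f"{prefix}{i}"
        p.shannon = float(v)
        out.append(p)
    return out


class TestCompareGroups:
    def metadata(self, n_a, n_b, **kw):
        return [SubjectMetadata(f"A{i}", "benign", **kw) for i in range(n_a)] + [
            SubjectMetadata(f"B{i}", "malignant", **kw) for i in range(n_b)
        ]

    def test_identical_groups_give_p_one(self):
        profiles = _profiles([1.0] * 5, "A") + _profiles([1.0] * 5, "B")
        res = compare_groups(profiles, self.metadata(5, 5), "shannon")
        assert res.p_value == 1.0
        assert res.direction == 0

    def test_full_separation_matches_exact_enumeration(self):
        profiles = _profiles([1, 2, 3, 4, 5], "A") + _profiles(
            [10, 11, 12, 13, 14], "B"
        )
        res = compare_groups(profiles, self.metadata(5, 5), "shannon")
        # group A occupies the 5 lowest ranks: statistic = 1+2+3+4+5
        assert res.statistic == 15
        # exactly 2 of the C(10,5) labelings are at least this extreme (two-sided)
        assert res.p_value == pytest.approx(2 / comb(10, 5, exact=True), abs=1e-12)
        assert res.direction == -1

    def test_insufficient_stratum_named(self):
        profiles = _profiles([1, 2, 3], "A") + _profiles([4, 5, 6], "B")
        meta = self.metadata(3, 3)
        for m in meta:
            m.ggn = m.subject_id != "A0"
        with pytest.raises(InsufficientDataError, match="ggn=False"):
            compare_groups(profiles, meta, "shannon", stratify_by="ggn")

    def test_effect_confined_to_non_ggn_stratum(self):
        """Planted effect only in non-GGN subjects: the stratified test finds
        it there and not in the GGN stratum (over seeded replicates)."""
        hits_non_ggn, misses_ggn = 0, 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            profiles, meta = [], []
            for grp, label in (("A", "benign"), ("B", "malignant")):
                for i in range(20):
                    ggn = i < 8
                    if ggn:
                        val = rng.normal(4.0, 0.3)  # no effect among GGN
                    else:
                        val = rng.normal(4.0 if label == "benign" else 2.5, 0.3)
                    p = _profiles([val], grp)[0]
                    p.subject_id = f"{grp}{i}"
                    profiles.append(p)
                    meta.append(SubjectMetadata(f"{grp}{i}", label, ggn=ggn))
            res = compare_groups(profiles, meta, "shannon", stratify_by="ggn")
            hits_non_ggn += res["ggn=False"].p_value < 0.05
            misses_ggn += res["ggn=True"].p_value > 0.05
        assert hits_non_ggn == 5
        assert misses_ggn >= 4


class TestSpearman:
    def make(self, feature_vals, cov_vals):
        profiles = _profiles(feature_vals, "S")
        meta = [
            SubjectMetadata(f"S{i}", "benign", nodule_size_mm=c, age_years=30 + i)
            for i, c in enumerate(cov_vals)
        ]
        return profiles, meta

    def test_perfect_monotone_correlations(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        profiles, meta = self.make(vals, vals)
        res = correlate_features_clinical(
            profiles, meta, features=["shannon"], covariates=["nodule_size_mm"]
        )
        assert res.iloc[0]["rho"] == pytest.approx(1.0)
        profiles, meta = self.make(vals, vals[::-1])
        res = correlate_features_clinical(
            profiles, meta, features=["shannon"], covariates=["nodule_size_mm"]
        )
        assert res.iloc[0]["rho"] == pytest.approx(-1.0)

    def test_tied_data_matches_rank_then_pearson_oracle(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]  # one tie
        y = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0]  # ties too
        profiles, meta = self.make(x, y)
        res = correlate_features_clinical(
            profiles, meta, features=["shannon"], covariates=["nodule_size_mm"]
        )
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.iloc[0]["rho"] == pytest.approx(oracle, abs=1e-12)

    def test_constant_feature_warns_not_raises(self):
        profiles, meta = self.make([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.warns(RuntimeWarning, match="constant"):
            res = correlate_features_clinical(
                profiles, meta, features=["shannon"], covariates=["nodule_size_mm"]
            )
        assert np.isnan(res.iloc[0]["rho"])

    def test_pairwise_complete_missing_handling(self):
        profiles, meta = self.make([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, None])
        res = correlate_features_clinical(
            profiles, meta, features=["shannon"], covariates=["nodule_size_mm"]
        )
        assert res.iloc[0]["n"] == 3
        assert res.iloc[0]["rho"] == pytest.approx(1.0)


def test_profiles_to_frame_has_canonical_columns(make_repertoire):
    reps = [repertoire_from_counts([3, 2, 1], subject_id=f"S{i}") for i in range(3)]
    frame = profiles_to_frame([diversity_profile(r) for r in reps])
    assert list(frame.columns)[:3] == ["richness", "shannon", "evenness"]
    assert frame.shape == (3, 11)
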
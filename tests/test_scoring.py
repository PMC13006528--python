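"""Score assembly, min/weighted scores, windowing, and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tagsite.scoring import (
    DEFAULT_WEIGHTS,
    FEATURE_ORDER,
    FeatureTrack,
    ScoringConfig,
    assemble_features,
    min_score,
    rank_sites,
    score_residues,
    weighted_score,
    window_average,
)


def brute_force_window(track, window):
    """Independent oracle: explicit double loop over clipped windows."""
    half = window // 2
    out = []
    for p in range(len(track)):
        lo, hi = max(0, p - half), min(len(track), p + half + 1)
        out.append(sum(track[lo:hi]) / (hi - lo))
    return out


def _tracks(length=10, fill=0.5):
    return [FeatureTrack(n, np.full(length, fill)) for n in FEATURE_ORDER]


class TestAssemble:
    def test_shape(self):
        assert assemble_features(*_tracks(10)).shape == (10, 4)

    def test_length_mismatch_rejected(self):
        e, s, r, d = _tracks(10)
        d = FeatureTrack("dbr", np.zeros(9))
        with pytest.raises(ValueError, match="mismatch"):
            assemble_features(e, s, r, d)

    def test_out_of_range_value_rejected(self):
        e, s, r, d = _tracks(10)
        r.values[3] = 1.2
        with pytest.raises(ValueError, match="outside"):
            assemble_features(e, s, r, d)


class TestMinScore:
    def test_one_bad_feature_vetoes(self):
        assert min_score((0.9, 0.9, 0.9, 0.0)) == 0.0

    def test_constant_vector(self):
        assert min_score((0.5, 0.5, 0.5, 0.5)) == 0.5

    def test_direct_minimum(self):
        assert min_score((0.23, 0.80, 0.95, 0.60)) == pytest.approx(0.23)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            min_score(())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.permutations(range(4)))
    def test_permuting_features_leaves_min_unchanged(self, perm):
        vec = np.array([0.1, 0.4, 0.7, 0.9])
        assert min_score(vec[list(perm)]) == min_score(vec)


class TestWeightedScore:
    def test_all_ones_with_default_weights(self):
        assert weighted_score((1.0, 1.0, 1.0, 1.0)) == pytest.approx(4.5)

    def test_all_zero(self):
        assert weighted_score((0.0, 0.0, 0.0, 0.0)) == 0.0

    def test_entropy_weight_is_one_point_five(self):
        assert weighted_score((1.0, 0.0, 0.0, 0.0)) == pytest.approx(1.5)

    def test_missing_weight_rejected(self):
        with pytest.raises(ValueError, match="missing weight"):
            weighted_score((1, 1, 1, 1), weights={"entropy": 1.5})


class TestWindowAverage:
    def test_constant_track_is_fixed_point(self):
        for window in (1, 3, 7):
            out = window_average(np.full(12, 0.37), window)
            assert np.allclose(out, 0.37)

    def test_centre_spike(self):
        track = np.array([0, 0, 0, 1, 0, 0, 0], dtype=float)
        out = window_average(track, 7)
        assert out[3] == pytest.approx(1 / 7)

    def test_clipped_terminal_counts(self):
        # with window 7 the three terminal positions average 4, 5, 6 residues
        track = np.array([0, 0, 0, 1, 0, 0, 0], dtype=float)
        out = window_average(track, 7)
        assert out[0] == pytest.approx(1 / 4)
        assert out[1] == pytest.approx(1 / 5)
        assert out[2] == pytest.approx(1 / 6)

    def test_terminal4_mode(self):
        track = np.array([0, 0, 0, 1, 0, 0, 0, 0, 0, 0], dtype=float)
        out = window_average(track, 7, terminal_mode="terminal4")
        assert np.allclose(out[:3], 1 / 4)
        assert np.allclose(out[-3:], 0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
           st.sampled_from([1, 3, 5, 7, 9]))
    def test_matches_brute_force_oracle(self, track, window):
        out = window_average(np.array(track), window)
        assert np.allclose(out, brute_force_window(track, window), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_windowed_value_bounded_by_track_extremes(self, track):
        out = window_average(np.array(track), 7)
        assert np.all(out >= min(track) - 1e-12)
        assert np.all(out <= max(track) + 1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            window_average(np.zeros(5), 4)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            window_average(np.array([]), 7)


class TestScoreResidues:
    def test_min_bounded_by_mean_and_max(self):
        rng = np.random.default_rng(0)
        matrix = rng.random((30, 4))
        scores = score_residues(matrix, "A" * 30)
        for i, r in enumerate(scores):
            vals = list(r.features.values())
            assert r.e_min <= np.mean(vals) + 1e-12 <= max(vals) + 1e-12

    def test_weighted_score_matches_elementwise(self):
        rng = np.random.default_rng(1)
        matrix = rng.random((10, 4))
        scores = score_residues(matrix, "A" * 10)
        for i, r in enumerate(scores):
            assert r.s_weighted == pytest.approx(
                weighted_score(matrix[i], DEFAULT_WEIGHTS))


class TestRankSites:
    def _scores(self, windowed):
        matrix = np.tile(np.array(windowed)[:, None], (1, 4))
        return score_residues(matrix, "A" * len(windowed),
                              ScoringConfig(window=1))

    def test_unique_maximum_ranks_first(self):
        track = [0.1] * 200
        track[180] = 0.9  # position 181
        report = rank_sites(self._scores(track), top_k=1)
        assert report.candidates[0][0] == 181

    def test_all_equal_track_reports_tie(self):
        report = rank_sites(self._scores([0.4] * 10), top_k=3)
        assert report.tie_warning
        assert [c[0] for c in report.candidates[:3]] == [1, 2, 3]
        assert len(report.candidates) == 10  # everything tied with the k-th

    def test_single_residue(self):
        report = rank_sites(self._scores([0.7]), top_k=5)
        assert report.candidates == [(1, 0.7, 0.7)]

    def test_terminals_always_reported(self):
        track = [0.0, 0.5, 0.9, 0.5, 0.0]
        report = rank_sites(self._scores(track), top_k=1)
        assert [t[0] for t in report.terminals] == [1, 5]

    def test_ties_ordered_by_ascending_position(self):
        track = [0.1, 0.8, 0.1, 0.8, 0.1]
        report = rank_sites(self._scores(track), top_k=2)
        assert [c[0] for c in report.candidates] == [2, 4]


class TestScoringConfig:
    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ScoringConfig(window=6)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ScoringConfig(weights={"entropy": -1, "secondary_structure": 1,
                                   "rsa": 1, "dbr": 1})

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ScoringConfig(weights=dict.fromkeys(FEATURE_ORDER, 0.0))
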
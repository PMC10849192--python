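import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doublechec.cleavage_profile import MeanCpmTrack, cpm_normalize, profile_from_arrays
from doublechec.io_formats import GenomeIndex
from doublechec.peak_core import (
    filter_and_find_maxima,
    genome_baseline,
    smooth,
)


def track_from(values, name="chrI"):
    vec = np.asarray(values, dtype=float)
    gi = GenomeIndex((name,), (len(vec),))
    return MeanCpmTrack(gi, {name: vec})


def brute_force_windows(values, w=3, s=2):
    """Oracle: loop over all full windows starting at 0, step s."""
    values = np.asarray(values, dtype=float)
    centers, means = [], []
    start = 0
    while start + w <= len(values):
        centers.append(start + w // 2)
        means.append(values[start : start + w].mean())
        start += s
    return np.asarray(centers), np.asarray(means)


def brute_force_maxima(centers, means, threshold):
    """Oracle: direct scan with -inf edge sentinels and strict inequality."""
    out = []
    for i, (c, m) in enumerate(zip(centers, means)):
        left = means[i - 1] if i > 0 else -np.inf
        right = means[i + 1] if i + 1 < len(means) else -np.inf
        if m >= threshold and m > left and m > right:
            out.append(c)
    return np.asarray(out, dtype=np.int64)


class TestSmooth:
    def test_three_term_means(self):
        smoothed = smooth(track_from([1, 2, 3, 0, 0]))
        np.testing.assert_array_equal(smoothed.centers["chrI"], [1, 3])
        np.testing.assert_allclose(smoothed.mean_cpm["chrI"], [2.0, 1.0])

    def test_raw_window_sums(self):
        gi = GenomeIndex(("chrI",), (5,))
        profile = profile_from_arrays(gi, {"chrI": np.array([1, 2, 3, 0, 0])})
        smoothed = smooth(MeanCpmTrack(gi, {"chrI": np.zeros(5)}), [profile])
        np.testing.assert_array_equal(smoothed.raw_sums["chrI"][:, 0], [6, 3])
        assert smoothed.raw_sums["chrI"].dtype == np.int64

    def test_constant_track_constant_means(self):
        smoothed = smooth(track_from([4.5] * 11))
        np.testing.assert_allclose(smoothed.mean_cpm["chrI"], 4.5)

    def test_trailing_partial_window_dropped(self):
        smoothed = smooth(track_from([1, 1, 1, 1]))  # only one full window fits at step 2
        np.testing.assert_array_equal(smoothed.centers["chrI"], [1])

    def test_short_contig_skipped_with_warning(self):
        gi = GenomeIndex(("tiny", "ok"), (2, 5))
        track = MeanCpmTrack(gi, {"tiny": np.ones(2), "ok": np.ones(5)})
        with pytest.warns(UserWarning, match="tiny"):
            smoothed = smooth(track)
        assert "tiny" not in smoothed.centers
        assert "ok" in smoothed.centers

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth(track_from([1, 2, 3, 4]), w=4)


class TestGenomeBaseline:
    def test_cpm_genome(self):
        gi = GenomeIndex(("chrI",), (12_000_000,))
        vec = np.zeros(12_000_000)
        vec[0] = 1e6
        assert genome_baseline(MeanCpmTrack(gi, {"chrI": vec})) == pytest.approx(0.25)

    def test_small_genome(self):
        gi = GenomeIndex(("chrI",), (1_000_000,))
        vec = np.zeros(1_000_000)
        vec[5] = 1e6
        assert genome_baseline(MeanCpmTrack(gi, {"chrI": vec})) == pytest.approx(3.0)

    def test_uses_actual_sum_not_1e6(self):
        # averaging unequal-depth replicates can leave the sum off 1e6
        gi = GenomeIndex(("chrI",), (4_000_000,))
        vec = np.zeros(4_000_000)
        vec[7] = 9.5e5
        expected = 3 * 9.5e5 / 4e6
        assert genome_baseline(MeanCpmTrack(gi, {"chrI": vec})) == pytest.approx(expected)


class TestFilterAndFindMaxima:
    def _maxima_of(self, window_means, threshold, **kw):
        # construct a smoothed track directly from window means
        gi = GenomeIndex(("chrI",), (2 * len(window_means) + 1,))
        centers = np.arange(len(window_means)) * 2 + 1
        from doublechec.peak_core import SmoothedTrack

        smoothed = SmoothedTrack(
            gi,
            {"chrI": centers},
            {"chrI": np.asarray(window_means, dtype=float)},
            {"chrI": np.zeros((len(window_means), 0), dtype=np.int64)},
            (),
        )
        return filter_and_find_maxima(smoothed, threshold, **kw).centers["chrI"]

    def test_strict_inequality_maxima(self):
        assert list(self._maxima_of([0, 5, 3, 8, 2], 1)) == [3, 7]

    def test_plateau_yields_no_maximum(self):
        assert list(self._maxima_of([0, 8, 8, 2], 1)) == []

    def test_plateau_keep_left(self):
        assert list(self._maxima_of([0, 8, 8, 2], 1, plateau="keep-left")) == [3]

    def test_left_edge_can_be_maximum(self):
        assert list(self._maxima_of([5, 1, 1], 1)) == [1]

    def test_threshold_filters(self):
        assert list(self._maxima_of([0, 5, 3, 8, 2], 6)) == [7]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            self._maxima_of([1, 2, 1], -1)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_random_tracks_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 10_000))
        values = rng.gamma(0.3, 5.0, n) * rng.integers(0, 2, n)
        threshold = float(rng.uniform(0, 2))
        track = track_from(values)
        smoothed = smooth(track)
        got = filter_and_find_maxima(smoothed, threshold)
        centers, means = brute_force_windows(values)
        np.testing.assert_array_equal(smoothed.centers["chrI"], centers)
        np.testing.assert_allclose(smoothed.mean_cpm["chrI"], means)
        np.testing.assert_array_equal(
            got.centers["chrI"], brute_force_maxima(centers, means, threshold)
        )

    @settings(max_examples=60, deadline=None)
    @given(
        values=st.lists(st.integers(0, 20), min_size=3, max_size=80),
        threshold=st.floats(0, 10),
    )
    def test_property_matches_brute_force(self, values, threshold):
        track = track_from(values)
        smoothed = smooth(track)
        got = filter_and_find_maxima(smoothed, threshold).centers["chrI"]
        centers, means = brute_force_windows(values)
        np.testing.assert_array_equal(got, brute_force_maxima(centers, means, threshold))


class TestProperties:
    def test_monotone_threshold(self):
        rng = np.random.default_rng(5)
        values = rng.gamma(0.5, 3.0, 2000)
        smoothed = smooth(track_from(values))
        prev = None
        for threshold in (0.0, 0.5, 1.0, 2.0, 4.0):
            got = set(filter_and_find_maxima(smoothed, threshold).centers["chrI"])
            if prev is not None:
                assert got <= prev
            prev = got

    def test_shift_equivariance_by_step(self):
        rng = np.random.default_rng(6)
        values = rng.gamma(0.5, 3.0, 500)
        shifted = np.concatenate([[0.0, 0.0], values])
        base = filter_and_find_maxima(smooth(track_from(values)), 0.5)
        moved = filter_and_find_maxima(smooth(track_from(shifted)), 0.5)
        got = moved.centers["chrI"]
        expected = base.centers["chrI"] + 2
        # ignore any maxima created at the padded left edge
        np.testing.assert_array_equal(got[np.isin(got, expected)], expected)
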
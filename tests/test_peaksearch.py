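"""Block extraction, per-block peak location, refractory error correction."""

import itertools

import numpy as np
import pytest

from triqrs.peaksearch import (
    CandidateBlock,
    PeakList,
    SearchParams,
    find_blocks,
    locate_peaks,
    refractory_correct,
)


class TestFindBlocks:
    def test_single_run_of_exceedance(self):
        blocks = find_blocks(np.array([0, 5, 5, 0.0]), np.ones(4))
        assert [(b.start, b.end) for b in blocks] == [(1, 2)]

    def test_no_exceedance_gives_empty_list(self):
        assert find_blocks(np.zeros(10), np.ones(10)) == []

    def test_two_single_sample_blocks(self):
        blocks = find_blocks(np.array([2, 0, 2.0]), np.ones(3))
        assert [(b.start, b.end) for b in blocks] == [(0, 0), (2, 2)]

    def test_strictness_at_equality(self):
        assert find_blocks(np.ones(5), np.ones(5)) == []

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            find_blocks(np.zeros(5), np.zeros(6))


def brute_force_tile_argmaxes(block, y, cap):
    out = []
    lo = block.start
    while lo <= block.end:
        hi = min(lo + cap - 1, block.end)
        seg = y[lo : hi + 1]
        out.append(lo + int(np.flatnonzero(seg == seg.max())[0]))
        lo = hi + 1
    return out


class TestLocatePeaks:
    params = SearchParams()  # cap = round(60 ms * 360 Hz) = 22 samples

    def test_single_block_argmax(self):
        y = np.array([1.0, 9.0, 3.0])
        peaks = locate_peaks([CandidateBlock(0, 2)], y, self.params, 360)
        assert list(peaks) == [1]

    def test_empty_block_list(self):
        assert locate_peaks([], np.ones(10), self.params, 360).size == 0

    def test_wide_block_is_tiled_one_candidate_per_tile(self):
        cap = self.params.search_cap_samples(360)
        y = np.zeros(3 * cap)
        y[5] = 2.0
        y[cap + 5] = 2.0  # equal maxima, one per tile
        blk = CandidateBlock(0, 2 * cap - 1)
        got = list(locate_peaks([blk], y, self.params, 360))
        assert got == brute_force_tile_argmaxes(blk, y, cap) == [5, cap + 5]

    def test_tie_breaks_to_earlier_index(self):
        y = np.array([0.0, 7.0, 7.0, 0.0])
        got = locate_peaks([CandidateBlock(0, 3)], y, self.params, 360)
        assert list(got) == [1]

    def test_block_outside_signal_raises(self):
        with pytest.raises(IndexError):
            locate_peaks([CandidateBlock(0, 50)], np.ones(10), self.params, 360)


def brute_force_outcomes(candidates, y, min_dist):
    """All reachable final sets under any order of pair elimination."""
    outcomes = set()

    def recurse(current):
        viol = [
            (a, b)
            for a, b in zip(current, current[1:])
            if b - a < min_dist
        ]
        if not viol:
            outcomes.add(tuple(current))
            return
        for a, b in viol:
            if y[a] < y[b] or (y[a] == y[b] and a > b):
                weaker = a
            else:
                weaker = b
            recurse([c for c in current if c != weaker])

    recurse(sorted(candidates))
    return outcomes


class TestRefractoryCorrect:
    params = SearchParams()  # refractory = round(272 ms * 360 Hz) = 98 samples

    def test_close_pair_keeps_larger_amplitude(self):
        y = np.zeros(200)
        y[100], y[150] = 5.0, 9.0
        kept = refractory_correct(np.array([100, 150]), y, self.params, 360)
        assert list(kept.indices) == [150]

    def test_single_candidate_unchanged(self):
        y = np.zeros(50)
        y[10] = 1.0
        kept = refractory_correct(np.array([10]), y, self.params, 360)
        assert list(kept.indices) == [10]

    def test_three_mutually_close_keep_strongest(self):
        y = np.zeros(300)
        idx = [100, 130, 160]
        for i, a in zip(idx, [1.0, 3.0, 2.0]):
            y[i] = a
        kept = refractory_correct(np.array(idx), y, self.params, 360)
        assert list(kept.indices) == [130]
        assert brute_force_outcomes(idx, y, 98) == {(130,)}

    def test_well_separated_candidates_all_kept(self):
        y = np.ones(1000)
        idx = np.array([0, 100, 250, 500])
        kept = refractory_correct(idx, y, self.params, 360)
        assert np.array_equal(kept.indices, idx)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_any_order_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 7)
        idx = np.unique(rng.integers(0, 400, size=n))
        y = np.zeros(500)
        y[idx] = rng.permutation(len(idx)) + 1.0  # distinct amplitudes
        kept = refractory_correct(idx, y, self.params, 360)
        assert tuple(kept.indices) in brute_force_outcomes(list(idx), y, 98)
        assert np.all(np.diff(kept.indices) >= 98)

    def test_unsorted_candidates_raise(self):
        with pytest.raises(ValueError):
            refractory_correct(np.array([50, 10]), np.ones(60), self.params, 360)


class TestTypes:
    def test_peaklist_requires_strictly_increasing(self):
        with pytest.raises(ValueError):
            PeakList(np.array([5, 5]), 360)

    def test_block_requires_nonempty_span(self):
        with pytest.raises(ValueError):
            CandidateBlock(3, 2)

    def test_search_params_sample_conversions(self):
        p = SearchParams()
        assert p.refractory_samples(360) == 98
        assert p.search_cap_samples(360) == 22
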
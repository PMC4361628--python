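"""NAWM masking, histogram summaries and lesion counting vs brute force."""

import numpy as np
import pytest

from nawmperf import (
    count_new_gd_lesions,
    histogram_mean,
    lesion_volume,
    make_nawm_mask,
)


# --- brute-force oracles ----------------------------------------------------

def bfs_dilate(mask, iterations):
    """6-connected dilation by breadth-first expansion (oracle)."""
    mask = mask.copy()
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
               (0, 0, 1), (0, 0, -1)]
    for _ in range(iterations):
        add = []
        for p in zip(*np.nonzero(mask)):
            for o in offsets:
                q = tuple(np.add(p, o))
                if all(0 <= q[d] < mask.shape[d] for d in range(3)):
                    add.append(q)
        for q in add:
            mask[q] = True
    return mask


def bfs_components(mask):
    """26-connected component labelling by flood fill (oracle)."""
    comps = []
    seen = np.zeros_like(mask, dtype=bool)
    offs = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
            for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        stack, comp = [start], set()
        seen[start] = True
        while stack:
            p = stack.pop()
            comp.add(p)
            for o in offs:
                q = tuple(np.add(p, o))
                if (all(0 <= q[d] < mask.shape[d] for d in range(3))
                        and mask[q] and not seen[q]):
                    seen[q] = True
                    stack.append(q)
        comps.append(comp)
    return comps


# --- NAWM mask --------------------------------------------------------------

def test_nawm_mask_without_lesions_is_thresholded_wm(phantom):
    empty = np.zeros(phantom.grid_shape, dtype=bool)
    got = make_nawm_mask(phantom.wm_prob, empty, 0.70, 2)
    assert np.array_equal(got, phantom.wm_prob >= 0.70)


def test_nawm_mask_empty_when_lesions_cover_wm(phantom):
    full = phantom.wm_prob >= 0.70
    assert not make_nawm_mask(phantom.wm_prob, full, 0.70, 0).any()


def test_single_voxel_dilation_ball_is_25_voxels():
    wm = np.ones((9, 9, 9))
    lesion = np.zeros((9, 9, 9), dtype=bool)
    lesion[4, 4, 4] = True
    nawm = make_nawm_mask(wm, lesion, 0.5, 2)
    excluded = ~nawm
    # 6-connectivity ball of radius 2 (L1 ball): 1 + 6 + 18 = 25 voxels
    assert excluded.sum() == 25
    assert np.array_equal(excluded, bfs_dilate(lesion, 2))


def test_dilation_matches_bfs_oracle(rng):
    for _ in range(5):
        lesion = rng.random((8, 8, 6)) < 0.08
        wm = np.ones(lesion.shape)
        for it in (0, 1, 2, 3):
            got = ~make_nawm_mask(wm, lesion, 0.5, it)
            assert np.array_equal(got, bfs_dilate(lesion, it))


def test_dilation_monotonicity(phantom, rng):
    lesion = np.zeros(phantom.grid_shape, dtype=bool)
    core = np.argwhere(phantom.wm_prob >= 0.9)
    lesion[tuple(core[rng.integers(0, len(core), 20)].T)] = True
    counts = [make_nawm_mask(phantom.wm_prob, lesion, 0.70, d).sum()
              for d in range(4)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_mask_grid_mismatch_rejected():
    with pytest.raises(ValueError):
        make_nawm_mask(np.ones((4, 4, 4)), np.zeros((5, 4, 4), dtype=bool))


# --- histogram summaries ----------------------------------------------------

def test_histogram_two_bins_hand_enumeration():
    s = histogram_mean([1.0, 2.0, 3.0, 4.0], n_bins=2)
    # bins [1, 2.5) and [2.5, 4]: centers 1.75 / 3.25, heights 0.5 / 0.5
    assert s.hist.sum() == pytest.approx(1.0, abs=1e-9)
    assert s.direct_mean == pytest.approx(2.5)
    half_bin = (4 - 1) / 2 / 2
    assert abs(s.mean - 2.5) <= half_bin
    assert s.mean == pytest.approx(2.5)  # symmetric sample: exact


def test_histogram_degenerate_sample():
    s = histogram_mean(np.full(10, 7.25), n_bins=256)
    assert s.mean == 7.25
    assert s.hist.sum() == pytest.approx(1.0, abs=1e-9)


def test_histogram_mean_close_to_direct_mean(rng):
    x = rng.normal(7.6, 0.5, 100_000)
    s = histogram_mean(x, n_bins=256)
    assert abs(s.mean - s.direct_mean) < 0.01
    bin_width = (x.max() - x.min()) / 256
    assert abs(s.mean - s.direct_mean) <= bin_width / 2


def test_histogram_rejects_empty_sample():
    with pytest.raises(ValueError):
        histogram_mean([])


# --- lesion volume and counting ---------------------------------------------

def test_lesion_volume_unit_conversion():
    assert lesion_volume(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1)) == 0.0
    m = np.zeros((10, 10, 10), dtype=bool)
    m.flat[:1000] = True
    assert lesion_volume(m, (1.0, 1.0, 1.0)) == pytest.approx(1.0)
    m = np.zeros((10, 10, 10), dtype=bool)
    m.flat[:69] = True
    assert lesion_volume(m, (1.9, 1.9, 4.0)) == pytest.approx(0.99636)


def test_count_new_simple_cases():
    empty = np.zeros((8, 8, 8), dtype=bool)
    assert count_new_gd_lesions(empty, None) == 0
    two = empty.copy()
    two[1, 1, 1] = True
    two[5, 5, 5] = True
    assert count_new_gd_lesions(two, None) == 2
    assert count_new_gd_lesions(two, empty) == 2


def test_one_of_three_components_overlaps_previous():
    cur = np.zeros((10, 10, 6), dtype=bool)
    cur[1:3, 1:3, 1] = True   # component 1
    cur[6:8, 6:8, 1] = True   # component 2
    cur[1:3, 7:9, 4] = True   # component 3
    prev = np.zeros_like(cur)
    prev[1, 1, 1] = True      # single-voxel overlap with component 1
    assert count_new_gd_lesions(cur, prev) == 2
    # brute-force: label components, check pairwise voxel overlap
    comps = bfs_components(cur)
    prev_set = set(zip(*np.nonzero(prev)))
    assert len(comps) == 3
    assert sum(1 for c in comps if not (c & prev_set)) == 2


def test_count_new_matches_bruteforce_on_random_masks(rng):
    for _ in range(10):
        cur = rng.random((9, 9, 7)) < 0.06
        prev = rng.random((9, 9, 7)) < 0.06
        comps = bfs_components(cur)
        prev_set = set(zip(*np.nonzero(prev)))
        expected = sum(1 for c in comps if not (c & prev_set))
        assert count_new_gd_lesions(cur, prev) == expected
        assert count_new_gd_lesions(cur, None) == len(comps)
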
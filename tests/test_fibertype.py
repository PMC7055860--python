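"""Intensity statistics, thresholding and the mask/modal typing procedure.

The defining check: the black-and-white-mask modal pipeline must agree
exactly with brute-force set algebra on random membership tables rendered to
disjoint (pre-expansion) ROI geometry.
"""

import numpy as np
import pytest

from myoseg.extract import FiberRecord
from myoseg.fibertype import (ChannelThreshold, bw_mask, choose_threshold,
                              classify_fibers, modal_select, positive_set,
                              roi_channel_stats)
from myoseg.io import FIBER_LABELS, MultiChannelImage, MyosegError


def grid_records(n=20, cell=6, size=3, width=None):
    """Disjoint size x size square ROIs laid out on a grid."""
    width = width or int(np.ceil(np.sqrt(n)))
    records = []
    for i in range(n):
        r0 = 1 + (i // width) * cell
        c0 = 1 + (i % width) * cell
        rr, cc = np.mgrid[r0:r0 + size, c0:c0 + size]
        records.append(FiberRecord(id=i + 1, pixels=(rr.ravel(), cc.ravel())))
    extent = 2 + cell * int(np.ceil(n / width)), 2 + cell * width
    return records, extent


def set_algebra_labels(ids, pos_I, pos_IIa, pos_IIb):
    """Independent oracle: direct set intersections/differences."""
    labels = {}
    for f in ids:
        on = frozenset(
            k for k, s in (("I", pos_I), ("IIa", pos_IIa), ("IIb", pos_IIb))
            if f in s
        )
        labels[f] = {
            frozenset(): "IIx",
            frozenset({"I"}): "I",
            frozenset({"IIa"}): "IIa",
            frozenset({"IIb"}): "IIb",
            frozenset({"I", "IIa"}): "I/IIa",
            frozenset({"I", "IIb"}): "I/IIb",
            frozenset({"IIa", "IIb"}): "IIa/IIb",
            frozenset({"I", "IIa", "IIb"}): "I/IIa/IIb",
        }[on]
    return labels


class TestChannelStats:
    def _image_with_plane(self, plane):
        return MultiChannelImage(
            channels={"laminin": np.zeros_like(plane), "type_I": plane},
            pixel_size_um=1.0, bit_depth=16,
        )

    def test_constant_region(self):
        plane = np.full((10, 10), 100, dtype=np.uint16)
        rec = FiberRecord(id=1, pixels=(np.array([2, 2]), np.array([3, 4])))
        roi_channel_stats([rec], self._image_with_plane(plane))
        st = rec.channel_stats["type_I"]
        assert st == dict(mean=100.0, sd=0.0, min=100.0, max=100.0, mode=100.0)

    def test_half_and_half_population_sd(self):
        plane = np.zeros((4, 4), dtype=np.uint16)
        plane[0, 1] = 200
        rec = FiberRecord(id=1, pixels=(np.array([0, 0]), np.array([0, 1])))
        roi_channel_stats([rec], self._image_with_plane(plane))
        st = rec.channel_stats["type_I"]
        assert st["mean"] == 100.0 and st["sd"] == 100.0
        assert st["mode"] == 0.0  # tie resolves to the smaller value

    def test_stats_invariant_to_pixel_order(self):
        rng = np.random.default_rng(0)
        plane = rng.integers(0, 1000, (12, 12)).astype(np.uint16)
        rr, cc = np.mgrid[2:8, 2:8]
        rec1 = FiberRecord(id=1, pixels=(rr.ravel(), cc.ravel()))
        perm = rng.permutation(rr.size)
        rec2 = FiberRecord(id=2, pixels=(rr.ravel()[perm], cc.ravel()[perm]))
        img = self._image_with_plane(plane)
        roi_channel_stats([rec1, rec2], img)
        assert rec1.channel_stats["type_I"] == rec2.channel_stats["type_I"]

    def test_missing_channel_raises(self):
        plane = np.zeros((4, 4), dtype=np.uint16)
        rec = FiberRecord(id=1, pixels=(np.array([0]), np.array([0])))
        with pytest.raises(MyosegError, match="missing"):
            roi_channel_stats([rec], self._image_with_plane(plane),
                              channels=["type_IIb"])


class TestChooseThreshold:
    def test_auto_splits_bimodal_values(self):
        thr = choose_threshold([10, 12, 11, 240, 250, 245], "auto")
        assert 12 < thr.value < 240

    def test_manual_returns_given_value(self):
        thr = choose_threshold([5.0, 50.0], "manual", manual_value=100.0)
        assert thr.value == 100.0 and thr.mode == "manual"

    def test_manual_without_value_and_degenerate_auto(self):
        with pytest.raises(MyosegError, match="requires a value"):
            choose_threshold([1.0, 2.0], "manual")
        with pytest.raises(MyosegError, match="auto threshold"):
            choose_threshold([7.0], "auto")

    def test_histogram_attached(self):
        thr = choose_threshold(list(range(100)), "manual", manual_value=50)
        edges, counts = thr.histogram
        assert counts.sum() == 100 and len(edges) == len(counts) + 1


class TestPositiveSet:
    def _records(self, means):
        records = []
        for i, m in enumerate(means, start=1):
            rec = FiberRecord(id=i, pixels=(np.array([i]), np.array([i])))
            rec.channel_stats["type_I"] = dict(mean=m, sd=0, min=m, max=m, mode=m)
            records.append(rec)
        return records

    def test_strict_inequality_excludes_exact_threshold(self):
        records = self._records([10.0, 100.0, 150.0])
        thr = ChannelThreshold(channel="type_I", mode="manual", value=100.0)
        assert positive_set(records, "type_I", thr) == {3}

    def test_all_below_is_empty(self):
        records = self._records([1.0, 2.0])
        thr = ChannelThreshold(channel="type_I", mode="manual", value=50.0)
        assert positive_set(records, "type_I", thr) == set()

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        records = self._records(rng.uniform(0, 255, 50))
        sizes = [
            len(positive_set(
                records, "type_I",
                ChannelThreshold(channel="type_I", mode="manual", value=v)))
            for v in np.linspace(0, 255, 20)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestBwMaskAndModal:
    def test_empty_selection_is_all_white(self):
        records, shape = grid_records(4)
        assert (bw_mask(set(), records, shape) == 255).all()

    def test_single_roi_pixel_count(self):
        records, shape = grid_records(4, size=3)
        mask = bw_mask({2}, records, shape)
        assert (mask == 0).sum() == 9

    def test_disjoint_masks_min_combine_to_union(self):
        records, shape = grid_records(9)
        a, b = {1, 3}, {5, 7}
        combined = np.minimum(bw_mask(a, records, shape),
                              bw_mask(b, records, shape))
        np.testing.assert_array_equal(combined, bw_mask(a | b, records, shape))

    def test_modal_select_full_overlap_cases(self):
        records, shape = grid_records(4)
        mask = bw_mask({1}, records, shape)
        assert modal_select(mask, {1, 2}, records, target=0) == {1}
        assert modal_select(mask, {1, 2}, records, target=255) == {2}

    def test_half_overlap_tie_resolves_to_black(self):
        rec = FiberRecord(id=1, pixels=(np.array([0, 0]), np.array([0, 1])))
        mask = np.full((2, 2), 255, dtype=np.uint8)
        mask[0, 0] = 0  # exactly half the ROI is black
        assert modal_select(mask, {1}, [rec], target=0) == {1}
        assert modal_select(mask, {1}, [rec], target=255) == set()


class TestClassifyFibers:
    def test_worked_membership_example(self):
        records, shape = grid_records(5)
        calls = classify_fibers(records, pos_I={4}, pos_IIa={1, 2, 4},
                                pos_IIb={2, 4, 5}, shape=shape)
        assert calls.labels == {1: "IIa", 2: "IIa/IIb", 3: "IIx",
                                4: "I/IIa/IIb", 5: "IIb"}

    def test_all_sets_empty_means_all_iix(self):
        records, shape = grid_records(6)
        calls = classify_fibers(records, set(), set(), set(), shape=shape)
        assert set(calls.labels.values()) == {"IIx"}

    def test_unknown_fiber_id_rejected(self):
        records, shape = grid_records(3)
        with pytest.raises(MyosegError, match="unknown fiber ids"):
            classify_fibers(records, {99}, set(), set(), shape=shape)

    def test_mask_modal_equals_set_algebra_on_random_tables(self):
        rng = np.random.default_rng(42)
        records, shape = grid_records(20)
        ids = [r.id for r in records]
        for _ in range(1000):
            pos = [
                {f for f in ids if rng.random() < p}
                for p in rng.uniform(0.1, 0.7, 3)
            ]
            calls = classify_fibers(records, *pos, shape=shape)
            assert calls.labels == set_algebra_labels(ids, *pos)

    def test_partition_invariant_on_every_run(self):
        rng = np.random.default_rng(7)
        records, shape = grid_records(30)
        ids = [r.id for r in records]
        for _ in range(50):
            pos = [set(rng.choice(ids, size=rng.integers(0, 25), replace=False))
                   for _ in range(3)]
            calls = classify_fibers(records, *pos, shape=shape)
            counts = calls.counts()
            assert sum(counts.values()) == len(ids)
            assert set(calls.labels) == set(ids)
            assert abs(sum(calls.proportions().values()) - 1.0) < 1e-9
            for fid, lab in calls.labels.items():
                assert lab in FIBER_LABELS
                m = calls.memberships[fid]
                assert (lab == "IIx") == (not any(m.values()))
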
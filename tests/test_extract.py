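"""Kapur thresholding, particle extraction, morphometry and gating.

Each numeric operation is checked against an independent oracle: an
exhaustive-scan entropy maximizer, a brute-force disk dilation, and a
0.1-degree projection sweep for the rotating-calipers minimum Feret.
"""

import numpy as np
import pytest
from skimage.draw import disk as skdisk

from myoseg.extract import (FiberRecord, apply_gates, binarize, expand_roi,
                            extract_particles, feret_diameters,
                            max_entropy_threshold, measure)
from myoseg.io import GateConfig, MyosegError
from myoseg.segment import ProbMap


# ---------------------------------------------------------------------------
# independent oracles


def kapur_brute_force(hist):
    """Naive exhaustive scan over all 255 splits; empty-side splits invalid."""
    p = np.asarray(hist, dtype=float)
    p = p / p.sum()

    def entropy(sub):
        s = sub.sum()
        if s <= 0:
            return None
        q = sub[sub > 0] / s
        return -(q * np.log(q)).sum()

    best_t, best_h = None, -np.inf
    for t in range(255):
        h0 = entropy(p[: t + 1])
        h1 = entropy(p[t + 1:])
        if h0 is None or h1 is None:
            continue
        if h0 + h1 > best_h + 1e-12:
            best_h, best_t = h0 + h1, t
    return best_t


def min_feret_sweep(points, step_deg=0.1):
    """Minimum projection width over a fine angle sweep."""
    pts = np.asarray(points, dtype=float)
    thetas = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
    proj = pts @ dirs.T
    return float((proj.max(axis=0) - proj.min(axis=0)).min())


def dilate_brute_force(roi, k, shape):
    rows, cols = roi
    out = set()
    for dr in range(-k, k + 1):
        for dc in range(-k, k + 1):
            if dr * dr + dc * dc <= k * k:
                for r, c in zip(rows, cols):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < shape[0] and 0 <= cc < shape[1]:
                        out.add((rr, cc))
    return out


# ---------------------------------------------------------------------------


class TestMaxEntropyThreshold:
    def test_uniform_histogram_closed_form(self):
        assert max_entropy_threshold(np.ones(256)) == 127

    def test_two_spike_histogram_smallest_tie(self):
        h = np.zeros(256)
        h[50] = h[200] = 10
        assert max_entropy_threshold(h) == 50

    def test_matches_exhaustive_scan_on_random_histograms(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            kind = rng.integers(3)
            if kind == 0:
                h = rng.integers(0, 1000, 256).astype(float)
            elif kind == 1:  # bimodal
                h = np.zeros(256)
                for mu in rng.integers(0, 256, 2):
                    x = np.arange(256)
                    h += rng.integers(50, 500) * np.exp(-0.5 * ((x - mu) / 8.0) ** 2)
            else:  # sparse
                h = np.zeros(256)
                bins = rng.choice(256, size=rng.integers(2, 8), replace=False)
                h[bins] = rng.integers(1, 100, bins.size)
            assert max_entropy_threshold(h) == kapur_brute_force(h)

    def test_degenerate_histogram_raises(self):
        h = np.zeros(256)
        h[10] = 5
        with pytest.raises(MyosegError, match="degenerate histogram"):
            max_entropy_threshold(h)


class TestBinarize:
    def test_bilevel_map_splits_classes(self):
        vals = np.full((10, 10), 255, dtype=np.uint8)
        vals[4:6, :] = 0
        out = binarize(ProbMap(values=vals), sigma=0, t=127)
        assert not out[4:6, :].any() and out[:4, :].all()

    def test_threshold_255_is_all_black(self):
        vals = np.random.default_rng(0).integers(0, 256, (16, 16), dtype=np.uint8)
        assert not binarize(ProbMap(values=vals), sigma=0, t=255).any()

    def test_blur_does_not_add_isolated_specks(self):
        rng = np.random.default_rng(1)
        vals = np.where(rng.random((128, 128)) < 0.05, 255, 0).astype(np.uint8)

        def speck_count(b):
            from scipy import ndimage

            lab, n = ndimage.label(b, structure=np.ones((3, 3)))
            sizes = ndimage.sum_labels(b, lab, range(1, n + 1))
            return int((sizes == 1).sum())

        pm = ProbMap(values=vals)
        assert speck_count(binarize(pm, 2.0, 127)) <= speck_count(binarize(pm, 0, 127))


class TestParticles:
    def test_separated_squares_are_two_rois(self):
        b = np.zeros((12, 25), dtype=bool)
        b[1:11, 1:11] = True
        b[1:11, 12:22] = True
        assert len(extract_particles(b, exclude_edges=False)) == 2

    def test_edge_exclusion_drops_border_component(self):
        b = np.zeros((12, 12), dtype=bool)
        b[0:5, 0:5] = True
        assert len(extract_particles(b, exclude_edges=True)) == 0
        assert len(extract_particles(b, exclude_edges=False)) == 1

    def test_corner_touching_pixels_join_under_8_connectivity(self):
        b = np.zeros((6, 6), dtype=bool)
        b[1, 1] = b[2, 2] = b[3, 3] = True
        rois = extract_particles(b, exclude_edges=False)
        assert len(rois) == 1 and rois[0][0].size == 3


class TestExpandRoi:
    def test_zero_expansion_is_identity(self):
        roi = (np.array([3, 4]), np.array([3, 3]))
        rr, cc = expand_roi(roi, 0, (10, 10))
        np.testing.assert_array_equal(rr, roi[0])
        np.testing.assert_array_equal(cc, roi[1])

    def test_square_reference_case(self):
        # 10x10 square dilated by the radius-1 disk (a cross): 4 sides x 10
        rr, cc = np.mgrid[5:15, 5:15]
        out = expand_roi((rr.ravel(), cc.ravel()), 1, (30, 30))
        assert out[0].size == 100 + 40

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_brute_force_disk_dilation(self, k):
        rng = np.random.default_rng(k)
        mask = rng.random((15, 15)) < 0.2
        if not mask.any():
            mask[7, 7] = True
        roi = tuple(np.nonzero(mask))
        rr, cc = expand_roi(roi, k, (15, 15))
        assert set(zip(rr, cc)) == dilate_brute_force(roi, k, (15, 15))

    def test_expansion_is_monotone(self):
        roi = (np.array([5, 6, 7]), np.array([5, 5, 6]))
        prev = set(zip(*roi))
        for k in (1, 2, 3):
            cur = set(zip(*expand_roi(roi, k, (20, 20))))
            assert prev <= cur
            prev = cur


class TestMeasure:
    def test_square_closed_forms(self):
        s = 60
        rr, cc = np.mgrid[0:s, 0:s]
        m = measure((rr.ravel(), cc.ravel()))
        assert m["circularity"] == pytest.approx(np.pi / 4, rel=0.05)
        assert m["feret_um"] == pytest.approx(s * np.sqrt(2), rel=0.05)
        assert m["min_feret_um"] == pytest.approx(s, rel=0.05)
        assert m["feret_ar"] == pytest.approx(np.sqrt(2), rel=0.05)
        assert m["solidity"] == pytest.approx(1.0, abs=0.02)

    def test_disk_closed_forms(self):
        rr, cc = skdisk((60, 60), 50)
        m = measure((rr, cc))
        assert 0.95 <= m["circularity"] <= 1.0
        assert 0.9 <= m["roundness"] <= 1.0

    def test_pixel_size_scales_lengths_and_areas(self):
        rr, cc = np.mgrid[0:20, 0:10]
        m1 = measure((rr.ravel(), cc.ravel()), 1.0)
        m2 = measure((rr.ravel(), cc.ravel()), 0.5)
        assert m2["area_um2"] == pytest.approx(m1["area_um2"] * 0.25)
        assert m2["feret_um"] == pytest.approx(m1["feret_um"] * 0.5)

    def test_min_feret_matches_angle_sweep_on_random_hulls(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            pts = rng.random((rng.integers(4, 40), 2)) * rng.uniform(5, 100)
            dmax, dmin, _ = feret_diameters(pts)
            assert dmin == pytest.approx(min_feret_sweep(pts), rel=0.005)
            assert dmin <= dmax + 1e-9

    def test_empty_roi_raises(self):
        with pytest.raises(MyosegError, match="empty"):
            measure((np.array([], dtype=int), np.array([], dtype=int)))

    def test_kept_fiber_invariants_on_random_blobs(self):
        rng = np.random.default_rng(12)
        from scipy import ndimage

        for _ in range(20):
            mask = ndimage.binary_closing(
                rng.random((40, 40)) < 0.45, structure=np.ones((3, 3))
            )
            lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
            for i in range(1, n + 1):
                roi = tuple(np.nonzero(lab == i))
                if roi[0].size < 5:
                    continue
                m = measure(roi)
                assert m["min_feret_um"] <= m["feret_um"] + 1e-9
                assert m["feret_ar"] >= 1.0
                assert 0 < m["circularity"] <= 1.0
                assert 0 < m["solidity"] <= 1.0
                assert 0.0 <= m["feret_angle_deg"] < 180.0


def _record(fid=1, **kw):
    rec = FiberRecord(id=fid, pixels=(np.array([0]), np.array([0])))
    defaults = dict(area_um2=1000.0, circularity=0.8, min_feret_um=30.0,
                    feret_ar=1.3)
    defaults.update(kw)
    for k, v in defaults.items():
        setattr(rec, k, v)
    return rec


class TestGates:
    def test_each_gate_rejects_with_correct_reason(self):
        g = GateConfig()
        cases = [
            (_record(1, area_um2=40.0), "area"),
            (_record(2, circularity=0.25), "circularity"),
            (_record(3, min_feret_um=3.0), "min_feret"),
            (_record(4, feret_ar=5.0), "feret_ar"),
        ]
        kept, rejected = apply_gates([r for r, _ in cases], g)
        assert kept == []
        assert [(r.id, why) for r, why in rejected] == [
            (rec.id, expected) for rec, expected in cases
        ]

    def test_in_range_record_passes(self):
        kept, rejected = apply_gates([_record()], GateConfig())
        assert len(kept) == 1 and rejected == []

    def test_constructed_shapes_fail_expected_gates(self):
        g = GateConfig()
        shapes = {}
        m = np.zeros((20, 20), bool); m[5:11, 5:12] = True          # 42 um2
        shapes["area"] = m
        m = np.zeros((40, 80), bool)
        m[5:25, 5:25] = True; m[5:25, 55:75] = True; m[13:17, 25:55] = True
        shapes["circularity"] = m                                     # dumbbell
        m = np.zeros((25, 25), bool); m[10:13, 4:21] = True           # thin strip
        shapes["min_feret"] = m
        m = np.zeros((20, 60), bool); m[5:13, 5:45] = True            # elongated
        shapes["feret_ar"] = m
        for expected, mask in shapes.items():
            roi = tuple(np.nonzero(mask))
            rec = FiberRecord(id=1, pixels=roi)
            for k, v in measure(roi).items():
                setattr(rec, k, v)
            kept, rejected = apply_gates([rec], g)
            assert kept == [] and rejected[0][1] == expected

    def test_gating_is_order_independent_and_idempotent(self):
        rng = np.random.default_rng(5)
        records = [
            _record(i, area_um2=rng.uniform(10, 8000),
                    circularity=rng.uniform(0.1, 1.0),
                    min_feret_um=rng.uniform(1, 80),
                    feret_ar=rng.uniform(1, 6))
            for i in range(40)
        ]
        g = GateConfig()
        kept1, _ = apply_gates(records, g)
        shuffled = list(records)
        rng.shuffle(shuffled)
        kept2, _ = apply_gates(shuffled, g)
        assert {r.id for r in kept1} == {r.id for r in kept2}
        kept3, rej3 = apply_gates(kept1, g)
        assert kept3 == kept1 and rej3 == []
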
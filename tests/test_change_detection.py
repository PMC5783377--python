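"""LCV construction, subtraction and the two-step threshold/cluster filter.

The cluster filter is checked against an independent brute-force
flood-fill oracle (explicit neighbour enumeration, no scipy) that is also
used by the acceptance suite.
"""

import numpy as np
import pytest

from bonediff import (
    BinaryMask,
    DensityVolume,
    FilterParams,
    RemodellingLabelVolume,
    RigidTransform3D,
    cluster_filter,
    compute_lcv,
    detect_remodelling,
    subtract,
    threshold_classify,
)
from bonediff.change_detection import DifferenceVolume
from bonediff.phantom import RemodellingEventSpec, apply_events

VOX = 0.082


def mask_of(data, voxel=VOX):
    return BinaryMask(np.asarray(data, dtype=bool), voxel)


# ---------------------------------------------------------------------------
# independent flood-fill oracle for the cluster filter
# ---------------------------------------------------------------------------

def _neighbour_offsets(connectivity):
    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                manhattan = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and manhattan > 1:
                    continue
                if connectivity == 18 and manhattan > 2:
                    continue
                offs.append((di, dj, dk))
    return offs


def flood_fill_cluster_oracle(labels: np.ndarray, min_cluster: int,
                              connectivity: int) -> np.ndarray:
    """Brute-force reference: per class, flood-fill each component with an
    explicit stack and reclassify small ones as unchanged."""
    out = labels.copy()
    offsets = _neighbour_offsets(connectivity)
    shape = labels.shape
    for cls in (2, 3):
        seen = np.zeros(shape, dtype=bool)
        for start in zip(*np.nonzero(labels == cls)):
            if seen[start]:
                continue
            stack = [start]
            seen[start] = True
            component = []
            while stack:
                p = stack.pop()
                component.append(p)
                for di, dj, dk in offsets:
                    q = (p[0] + di, p[1] + dj, p[2] + dk)
                    if not all(0 <= q[a] < shape[a] for a in range(3)):
                        continue
                    if labels[q] == cls and not seen[q]:
                        seen[q] = True
                        stack.append(q)
            if len(component) < min_cluster:
                for p in component:
                    out[p] = 1
    return out


# ---------------------------------------------------------------------------


class TestComputeLCV:
    def test_self_overlap_is_full(self, small_phantom):
        lcv, frac = compute_lcv(small_phantom.periosteal,
                                small_phantom.periosteal)
        assert frac == 100.0
        assert lcv.count == small_phantom.periosteal.count

    def test_shifted_box_overlap_fraction(self):
        box = np.zeros((8, 8, 110), dtype=bool)
        box[2:6, 2:6, 5:105] = True          # 100 voxels long
        shifted = np.roll(box, 10, axis=2)   # 10-voxel shift along long axis
        lcv, frac = compute_lcv(mask_of(box), mask_of(shifted))
        assert frac == pytest.approx(90.0)
        assert lcv.count == 4 * 4 * 90

    def test_disjoint_masks_error(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[0, 0, 0] = True
        b[7, 7, 7] = True
        with pytest.raises(ValueError, match="common volume"):
            compute_lcv(mask_of(a), mask_of(b))


class TestSubtract:
    def test_voxel_arithmetic(self):
        base = DensityVolume(np.full((8, 8, 8), 400.0))
        fup = DensityVolume(np.full((8, 8, 8), 650.0))
        lcv = mask_of(np.ones((8, 8, 8)), voxel=0.082)
        diff = subtract(base, fup, lcv)
        np.testing.assert_array_equal(diff.data[lcv.data], 250.0)

    def test_self_subtraction_is_zero(self, small_phantom):
        lcv, _ = compute_lcv(small_phantom.periosteal, small_phantom.periosteal)
        diff = subtract(small_phantom.density, small_phantom.density, lcv)
        assert np.all(diff.data[lcv.data] == 0.0)

    def test_outside_lcv_carries_no_value(self):
        base = DensityVolume(np.zeros((8, 8, 8)))
        fup = DensityVolume(np.full((8, 8, 8), 999.0))
        lcv_data = np.zeros((8, 8, 8), dtype=bool)
        lcv_data[4, 4, 4] = True
        diff = subtract(base, fup, mask_of(lcv_data))
        assert diff.data[0, 0, 0] == 0.0
        assert diff.data[4, 4, 4] == 999.0


class TestThresholdClassify:
    @pytest.mark.parametrize("delta,expected", [
        (300.0, 2),    # exceeds +T -> formation
        (-300.0, 3),   # exceeds -T -> resorption
        (225.0, 1),    # equal to T -> unchanged (strict inequality)
        (-225.0, 1),
        (0.0, 1),
    ])
    def test_classification_rule(self, delta, expected):
        data = np.full((8, 8, 8), delta)
        lcv = mask_of(np.ones((8, 8, 8)))
        labels = threshold_classify(DifferenceVolume(data, lcv), 225.0)
        assert labels.data[4, 4, 4] == expected

    def test_outside_lcv_is_class_zero(self):
        lcv_data = np.zeros((8, 8, 8), dtype=bool)
        lcv_data[1, 1, 1] = True
        labels = threshold_classify(
            DifferenceVolume(np.full((8, 8, 8), 500.0), mask_of(lcv_data)), 225.0)
        assert labels.data[0, 0, 0] == 0
        assert labels.data[1, 1, 1] == 2

    def test_monotone_in_threshold(self, rng):
        data = rng.normal(0, 150, (16, 16, 16))
        lcv = mask_of(np.ones((16, 16, 16)))
        diff = DifferenceVolume(data, lcv)
        prev = None
        for t in (200.0, 225.0, 250.0, 275.0):
            labels = threshold_classify(diff, t)
            n = ((labels.data == 2) | (labels.data == 3)).sum()
            if prev is not None:
                assert n <= prev
            prev = n


class TestClusterFilter:
    def _labels(self, data):
        return RemodellingLabelVolume(np.asarray(data, dtype=np.uint8))

    def test_four_voxel_component_removed(self):
        data = np.ones((8, 8, 8), dtype=np.uint8)
        data[2, 2, 2:6] = 2  # 4-voxel line
        out = cluster_filter(self._labels(data), min_cluster=5)
        assert (out.data == 2).sum() == 0
        assert np.all(out.data[2, 2, 2:6] == 1)

    def test_five_voxel_component_kept(self):
        data = np.ones((8, 8, 8), dtype=np.uint8)
        data[2, 2, 2:7] = 2  # 5 face-connected voxels
        out = cluster_filter(self._labels(data), min_cluster=5, connectivity=6)
        assert (out.data == 2).sum() == 5

    def test_classes_never_merge(self):
        # formation and resorption voxels adjacent: 3+3 voxels would only
        # survive min_cluster=5 if wrongly treated as one 6-voxel cluster
        data = np.ones((8, 8, 8), dtype=np.uint8)
        data[4, 4, 1:4] = 2
        data[4, 4, 4:7] = 3
        out = cluster_filter(self._labels(data), min_cluster=5)
        assert (out.data == 2).sum() == 0
        assert (out.data == 3).sum() == 0

    def test_idempotent(self, rng):
        data = rng.choice([0, 1, 2, 3], size=(14, 14, 14),
                          p=[0.1, 0.6, 0.15, 0.15])
        once = cluster_filter(self._labels(data), 5, 26)
        twice = cluster_filter(once, 5, 26)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_monotone_in_min_cluster(self, rng):
        data = rng.choice([1, 2, 3], size=(16, 16, 16), p=[0.8, 0.1, 0.1])
        labels = self._labels(data)
        prev = None
        for mc in (1, 3, 5, 7, 9):
            out = cluster_filter(labels, mc, 26)
            n = ((out.data == 2) | (out.data == 3)).sum()
            if prev is not None:
                assert n <= prev
            prev = n

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("min_cluster", [1, 5, 9])
    def test_matches_flood_fill_oracle(self, rng, connectivity, min_cluster):
        for _ in range(25):
            data = rng.choice([0, 1, 2, 3], size=(12, 12, 12),
                              p=[0.1, 0.55, 0.175, 0.175]).astype(np.uint8)
            expected = flood_fill_cluster_oracle(data, min_cluster, connectivity)
            out = cluster_filter(self._labels(data), min_cluster, connectivity)
            np.testing.assert_array_equal(out.data, expected)


class TestSignAntisymmetry:
    def test_swapping_scans_swaps_classes(self, small_phantom, rng):
        ph = small_phantom
        other = DensityVolume(
            ph.density.data + rng.normal(0, 120, ph.density.shape), VOX)
        ident = RigidTransform3D.identity()
        params = FilterParams(threshold=225.0, min_cluster=5)
        fwd = detect_remodelling(ph.density, ph.periosteal, other,
                                 ph.periosteal, params, transform=ident)
        rev = detect_remodelling(other, ph.periosteal, ph.density,
                                 ph.periosteal, params, transform=ident)
        np.testing.assert_array_equal(fwd.labels.data == 2, rev.labels.data == 3)
        np.testing.assert_array_equal(fwd.labels.data == 3, rev.labels.data == 2)


class TestDetectRemodelling:
    def test_identical_inputs_detect_nothing(self, small_phantom):
        ph = small_phantom
        for t in (200.0, 275.0):
            det = detect_remodelling(ph.density, ph.periosteal,
                                     ph.density.copy(), ph.periosteal,
                                     FilterParams(threshold=t))
            counts = det.labels.counts()
            assert counts[2] == 0 and counts[3] == 0

    def test_single_cavity_found_with_good_dice(self, small_phantom):
        ph = small_phantom
        events = [RemodellingEventSpec("resorption", 1, (20, 20), 500.0)]
        followup, truth = apply_events(ph, events, seed=3)
        det = detect_remodelling(ph.density, ph.periosteal, followup,
                                 ph.periosteal, FilterParams())
        from scipy import ndimage

        found = det.labels.data == 3
        _, n_comp = ndimage.label(found,
                                  ndimage.generate_binary_structure(3, 3))
        assert n_comp == 1
        true = truth.labels.data == 3
        dice = 2 * (found & true).sum() / (found.sum() + true.sum())
        assert dice >= 0.8

    def test_subminimum_event_is_filtered_out(self, small_phantom):
        ph = small_phantom
        events = [RemodellingEventSpec("formation", 1, (3, 3), 500.0)]
        followup, _ = apply_events(ph, events, seed=4)
        det = detect_remodelling(ph.density, ph.periosteal, followup,
                                 ph.periosteal, FilterParams(min_cluster=5))
        assert (det.labels.data == 2).sum() == 0
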
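import numpy as np
import pytest
from scipy import ndimage

from aprl.lesion_labelling import (
    assign_labels_nn,
    assign_prl_status,
    binarize,
    detect_centers,
    dice,
    dilate_one_voxel,
    exclude_tissue,
    flag_confluent,
    label_lesions,
    select_threshold,
)
from aprl.phantom import PhantomSpec, generate_case
from aprl.volume_io import BinaryMask, Grid, LesionLabelMap, ProbabilityMap

from oracles import local_maxima_count, nn_labels_oracle

G8 = Grid((8, 8, 8), 1.0)


def mask(shape, coords, grid=None):
    m = np.zeros(shape, np.uint8)
    for c in coords:
        m[c] = 1
    return BinaryMask(grid or Grid(shape, 1.0), m)


class TestDice:
    def test_identical_and_disjoint(self):
        a = mask((8, 8, 8), [(1, 1, 1), (1, 1, 2)])
        b = mask((8, 8, 8), [(5, 5, 5)])
        assert dice(a, a) == 1.0
        assert dice(a, b) == 0.0

    def test_forced_arithmetic(self):
        a = mask((8, 8, 8), [(0, 0, i) for i in range(8)])
        b = mask((8, 8, 8), [(0, 0, i) for i in range(4, 8)] + [(1, 1, i) for i in range(4)])
        assert dice(a, b) == pytest.approx(2 * 4 / 16)

    def test_both_empty_and_grid_mismatch(self):
        empty = mask((8, 8, 8), [])
        assert dice(empty, empty) == 0.0
        with pytest.raises(ValueError, match="grid mismatch"):
            dice(empty, mask((9, 8, 8), []))


class TestBinarizeAndThreshold:
    def test_binarize_boundary_inclusive(self):
        p = np.zeros((4, 4, 4), np.float32)
        p[0, 0, 0] = 0.5
        p[0, 0, 1] = 0.49
        b = binarize(ProbabilityMap(Grid((4, 4, 4), 1.0), p), 0.5)
        assert b.values.sum() == 1 and b.values[0, 0, 0] == 1

    def test_binarize_empty(self):
        p = ProbabilityMap(G8, np.zeros((8, 8, 8), np.float32))
        assert not binarize(p, 0.3).values.any()

    def test_tie_breaks_toward_smallest(self):
        vals = np.zeros((8, 8, 8), np.float32)
        vals[2:4, 2:4, 2:4] = 1.0
        prob = ProbabilityMap(G8, vals)
        gold = BinaryMask(G8, (vals > 0).astype(np.uint8))
        assert select_threshold(prob, gold, [0.25, 0.5, 0.75]) == 0.25

    def test_empty_gold_returns_smallest(self):
        prob = ProbabilityMap(G8, np.random.default_rng(0).random((8, 8, 8)).astype(np.float32))
        gold = mask((8, 8, 8), [])
        assert select_threshold(prob, gold, [0.2, 0.4, 0.6]) == 0.2

    def test_invalid_grids(self):
        prob = ProbabilityMap(G8, np.zeros((8, 8, 8), np.float32))
        gold = mask((8, 8, 8), [])
        with pytest.raises(ValueError, match="empty"):
            select_threshold(prob, gold, [])
        with pytest.raises(ValueError, match="increasing"):
            select_threshold(prob, gold, [0.5, 0.5])

    def test_matches_exhaustive_sweep_on_phantom(self):
        spec = PhantomSpec(grid=Grid((48, 48, 48), 0.65), n_lesions=6,
                           prob_blur_sigma_vox=1.0, seed=4)
        case = generate_case(spec)
        ts = list(np.round(np.arange(0.05, 0.951, 0.05), 2))
        chosen = select_threshold(case.prob_map, case.gold_mask, ts)
        dices = [dice(binarize(case.prob_map, t), case.gold_mask) for t in ts]
        best = max(range(len(ts)), key=lambda i: (dices[i], -i))
        assert chosen == ts[best]


class TestDilation:
    def test_single_interior_voxel_gives_box(self):
        d = dilate_one_voxel(mask((8, 8, 8), [(4, 4, 4)]))
        assert d.values.sum() == 27

    def test_empty(self):
        assert not dilate_one_voxel(mask((8, 8, 8), [])).values.any()

    def test_corner_clipped(self):
        d = dilate_one_voxel(mask((8, 8, 8), [(0, 0, 0)]))
        assert d.values.sum() == 8

    def test_superset(self, rng):
        m = BinaryMask(G8, (rng.random((8, 8, 8)) > 0.7).astype(np.uint8))
        d = dilate_one_voxel(m)
        assert np.all(d.values >= m.values)


class TestExcludeTissue:
    def setup_method(self):
        self.orig = mask((8, 8, 8), [(4, 4, 4)])
        self.dil = dilate_one_voxel(self.orig)
        self.ring = self.dil.as_bool() & ~self.orig.as_bool()

    def test_no_tissue_keeps_dilated(self):
        empty = mask((8, 8, 8), [])
        out = exclude_tissue(self.dil, self.orig, empty, empty)
        assert np.array_equal(out.values, self.dil.values)

    def test_tissue_covering_ring_restores_original(self):
        csf = BinaryMask(G8, self.ring.astype(np.uint8))
        out = exclude_tissue(self.dil, self.orig, csf, mask((8, 8, 8), []))
        assert np.array_equal(out.values, self.orig.values)

    def test_original_voxels_protected(self):
        csf = mask((8, 8, 8), [(4, 4, 4)])  # overlaps original only
        out = exclude_tissue(self.dil, self.orig, csf, mask((8, 8, 8), []))
        assert np.array_equal(out.values, self.dil.values)

    def test_subset_precondition(self):
        with pytest.raises(ValueError, match="subset"):
            exclude_tissue(self.orig, self.dil, mask((8, 8, 8), []), mask((8, 8, 8), []))


def gaussian_blob_prob(shape, centers, sigma=2.0):
    f = np.zeros(shape)
    for c, a in centers:
        grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        f += a * np.exp(-d2 / (2 * sigma**2))
    return ProbabilityMap(Grid(shape, 1.0), np.clip(f, 0, 1).astype(np.float32))


class TestDetectCenters:
    def test_single_blob_single_center_contains_peak(self):
        prob = gaussian_blob_prob((24, 24, 24), [((12, 12, 12), 0.9)])
        m = BinaryMask(Grid((24, 24, 24), 1.0), (prob.values > 0.1).astype(np.uint8))
        centers = detect_centers(prob, m)
        assert centers.n_lesions == 1
        assert centers.values[12, 12, 12] == 1

    def test_two_separated_blobs(self):
        prob = gaussian_blob_prob((32, 32, 32), [((8, 8, 8), 0.9), ((24, 24, 24), 0.9)])
        m = BinaryMask(Grid((32, 32, 32), 1.0), (prob.values > 0.05).astype(np.uint8))
        assert detect_centers(prob, m).n_lesions == 2

    def test_touching_blobs_match_local_maxima_oracle(self):
        """Peaks >= 6 sigma apart but with touching supports resolve into
        exactly as many centres as the exhaustive local-maxima scan finds."""
        sigma = 2.0
        prob = gaussian_blob_prob((32, 16, 16), [((9, 8, 8), 0.9), ((22, 8, 8), 0.9)],
                                  sigma=sigma)
        m = BinaryMask(Grid((32, 16, 16), 1.0), (prob.values > 0.005).astype(np.uint8))
        _, n_components = ndimage.label(m.as_bool(), np.ones((3, 3, 3)))
        assert n_components == 1  # supports touch
        sm = ndimage.gaussian_filter(prob.values.astype(np.float64), 1.0)
        expected = local_maxima_count(sm, m.as_bool())
        assert expected == 2
        assert detect_centers(prob, m).n_lesions == expected

    def test_fallback_single_center(self):
        # a linear ramp has no interior maximum: fallback picks the argmax voxel
        vals = np.tile(np.linspace(0, 0.9, 16), (16, 16, 1)).astype(np.float32)
        prob = ProbabilityMap(Grid((16, 16, 16), 1.0), vals)
        m = BinaryMask(Grid((16, 16, 16), 1.0), np.ones((16, 16, 16), np.uint8))
        centers = detect_centers(prob, m)
        assert centers.n_lesions == 1
        assert centers.values.sum() == 1

    def test_empty_mask_rejected(self):
        prob = gaussian_blob_prob((8, 8, 8), [((4, 4, 4), 0.5)])
        with pytest.raises(ValueError, match="empty"):
            detect_centers(prob, mask((8, 8, 8), []))


class TestAssignLabelsNN:
    def test_identity(self):
        m = mask((8, 8, 8), [(2, 2, 2), (2, 2, 3)])
        centers = LesionLabelMap(G8, m.values.astype(np.uint16))
        out = assign_labels_nn(m, centers)
        assert np.array_equal(out.values > 0, m.as_bool())
        assert set(np.unique(out.values)) == {0, 1}

    def test_equidistant_tie_goes_to_smaller_label(self):
        c = np.zeros((9, 3, 3), np.uint16)
        c[1, 1, 1] = 1
        c[5, 1, 1] = 2
        centers = LesionLabelMap(Grid((9, 3, 3), 1.0), c)
        m = mask((9, 3, 3), [(1, 1, 1), (5, 1, 1), (3, 1, 1)])  # distance 2 to both
        out = assign_labels_nn(m, centers)
        assert out.values[3, 1, 1] == 1

    def test_matches_exhaustive_oracle(self, rng):
        shape = (12, 12, 12)
        m = (rng.random(shape) > 0.6).astype(np.uint8)
        c = np.zeros(shape, np.uint16)
        placed = 0
        for x, y, z in np.argwhere(m):
            if placed < 3 and (x + y + z) % 5 == 0:
                placed += 1
                c[x, y, z] = placed
        assert placed == 3
        centers = LesionLabelMap(Grid(shape, 1.0), c)
        got = assign_labels_nn(BinaryMask(Grid(shape, 1.0), m), centers)
        coords = [tuple(v) for v in np.argwhere(m)]
        by_label = {k: [tuple(v) for v in np.argwhere(c == k)] for k in (1, 2, 3)}
        expected = nn_labels_oracle(coords, by_label)
        for (x, y, z), e in zip(coords, expected):
            assert got.values[x, y, z] == e

    def test_support_equals_mask_exactly(self, small_case, small_labelled):
        labels, _ = small_labelled
        # recompute the final mask independently
        from aprl.lesion_labelling import DEFAULT_THRESHOLDS

        t = select_threshold(small_case.prob_map, small_case.gold_mask, DEFAULT_THRESHOLDS)
        seg = binarize(small_case.prob_map, t)
        dil = dilate_one_voxel(seg)
        fm = exclude_tissue(dil, seg, small_case.csf_mask, small_case.gm_mask)
        assert np.array_equal(labels.values > 0, fm.as_bool())


class TestConfluenceAndPrl:
    def _labelmap(self, assignments, shape=(10, 10, 10)):
        lab = np.zeros(shape, np.uint16)
        for coord, k in assignments:
            lab[coord] = k
        return LesionLabelMap(Grid(shape, 1.0), lab)

    def test_disjoint_not_confluent(self):
        lab = self._labelmap([((1, 1, 1), 1), ((7, 7, 7), 2)])
        assert flag_confluent(lab) == {1: False, 2: False}

    def test_touching_pair_confluent(self):
        lab = self._labelmap([((1, 1, 1), 1), ((1, 1, 2), 2)])
        assert flag_confluent(lab) == {1: True, 2: True}

    def test_mixed_three_lesions(self):
        lab = self._labelmap([((1, 1, 1), 1), ((1, 1, 2), 2), ((7, 7, 7), 3)])
        assert flag_confluent(lab) == {1: True, 2: True, 3: False}

    def test_prl_status_rules(self):
        lab = self._labelmap([((1, 1, 1), 1), ((3, 3, 3), 2), ((5, 5, 5), 3)])
        empty = mask((10, 10, 10), [])
        assert assign_prl_status(lab, empty) == {1: False, 2: False, 3: False}
        inside_3 = mask((10, 10, 10), [(5, 5, 5)])
        assert assign_prl_status(lab, inside_3) == {1: False, 2: False, 3: True}
        straddle = mask((10, 10, 10), [(1, 1, 1), (3, 3, 3)])
        assert assign_prl_status(lab, straddle) == {1: True, 2: True, 3: False}


class TestLabelLesionsEndToEnd:
    def test_disjoint_phantom_counts(self):
        spec = PhantomSpec(grid=Grid((64, 64, 64), 0.65), n_lesions=5,
                           rim_fraction=0.0, confluence_rate=0.0, seed=61)
        case = generate_case(spec)
        # mark exactly one lesion as rim by hand-drawing an annotation line
        ann = np.zeros(case.gold_mask.values.shape, np.uint8)
        supp = case.lesion_supports[2]
        c = tuple(int(round(v)) for v in case.truth[2].center)
        ann[c] = 1
        annotation = BinaryMask(case.gold_mask.grid, ann)
        labels, records = label_lesions(case.prob_map, case.gold_mask,
                                        case.csf_mask, case.gm_mask, annotation)
        assert len(records) == 5
        assert sum(r.is_prl_truth for r in records) == 1
        assert not any(r.is_confluent for r in records)

    def test_confluent_pair_flagged(self):
        spec = PhantomSpec(grid=Grid((48, 48, 48), 0.65), n_lesions=2,
                           confluence_rate=1.0, rim_fraction=0.0,
                           lesion_radius_range_vox=(3.0, 4.0), seed=8)
        case = generate_case(spec)
        labels, records = label_lesions(case.prob_map, case.gold_mask,
                                        case.csf_mask, case.gm_mask,
                                        case.prl_annotation)
        assert len(records) == 2
        assert all(r.is_confluent for r in records)

    def test_partition_and_size_identity(self, small_labelled):
        labels, records = small_labelled
        counts = np.bincount(labels.values.ravel())
        assert sum(r.size_vox for r in records) == int((labels.values > 0).sum())
        for r in records:
            assert r.size_vox == counts[r.lesion_id]
        ids = sorted(r.lesion_id for r in records)
        assert ids == list(range(1, len(ids) + 1))

    def test_adding_disjoint_lesion_preserves_labels(self):
        """Monotonicity: a far-away extra lesion must not re-partition the
        existing ones (up to renumbering)."""
        shape = (40, 40, 40)
        base = gaussian_blob_prob(shape, [((10, 10, 10), 0.95), ((10, 28, 10), 0.95)])
        extra = gaussian_blob_prob(shape, [((10, 10, 10), 0.95), ((10, 28, 10), 0.95),
                                           ((30, 20, 30), 0.95)])
        m1 = BinaryMask(Grid(shape, 1.0), (base.values > 0.2).astype(np.uint8))
        m2 = BinaryMask(Grid(shape, 1.0), (extra.values > 0.2).astype(np.uint8))
        l1 = assign_labels_nn(m1, detect_centers(base, m1))
        l2 = assign_labels_nn(m2, detect_centers(extra, m2))
        old = m1.as_bool()
        # mapping from old labels to new must be a bijection on old support
        pairs = set(zip(l1.values[old].tolist(), l2.values[old].tolist()))
        assert len(pairs) == len({a for a, _ in pairs}) == len({b for _, b in pairs})
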
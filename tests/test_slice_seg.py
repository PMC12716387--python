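"""Single-slice segmentation: thresholding, contour hierarchy, closure."""

import numpy as np
import pytest
from skimage.draw import disk

import cuticlevol as cv
from cuticlevol import slice_seg as ss
from cuticlevol.phantoms import BACKGROUND_LEVEL, INTERIOR_LEVEL, SHELL_LEVEL


def annulus_slice(shape=(96, 96), r_out=30, r_in=24, center=None):
    """A hollow ring: shell between r_in and r_out, tissue inside r_in."""
    img = np.full(shape, BACKGROUND_LEVEL, dtype=np.uint16)
    c = center or ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    rr, cc = disk(c, r_out, shape=shape)
    img[rr, cc] = SHELL_LEVEL
    rr, cc = disk(c, r_in, shape=shape)
    img[rr, cc] = INTERIOR_LEVEL
    shell = img == SHELL_LEVEL
    body = img != BACKGROUND_LEVEL
    return img, int(shell.sum()), int(body.sum())


class TestConfigAndTypes:
    def test_band_requires_ordered_thresholds(self):
        with pytest.raises(ValueError, match="t_lo < t_hi"):
            cv.SegConfig(t_lo=10.0, t_hi=5.0)

    def test_negative_perimeter_rejected(self):
        with pytest.raises(ValueError):
            cv.SegConfig(min_perimeter=-1)

    def test_slice_image_validation(self):
        with pytest.raises(ValueError):
            ss.SliceImage(np.zeros(5))
        with pytest.raises(ValueError):
            ss.SliceImage(np.zeros((4, 4)), pixel_size_um=0)

    def test_result_invariant(self):
        with pytest.raises(ValueError, match="invariant"):
            ss.SliceResult(cuticle_px=10, body_px=5)


class TestThreshold:
    def test_band_lower_threshold_separates_tissue_from_cuticle(self):
        rng = np.random.default_rng(0)
        sample = np.concatenate(
            [
                rng.normal(BACKGROUND_LEVEL, 300, 4000),
                rng.normal(INTERIOR_LEVEL, 300, 2000),
                rng.normal(SHELL_LEVEL, 300, 1000),
            ]
        )
        t = ss.band_lower_threshold(sample, t_hi=65535.0)
        assert INTERIOR_LEVEL < t < SHELL_LEVEL

    def test_constant_slice_yields_empty_band(self):
        img = ss.SliceImage(np.full((32, 32), 100, dtype=np.uint16))
        mask = ss.threshold_band(img, cv.SegConfig(enhance=False, vial_detect=False))
        assert not mask.any()

    def test_explicit_band(self):
        img, shell_px, _ = annulus_slice()
        mask = ss.threshold_band(
            ss.SliceImage(img),
            cv.SegConfig(t_lo=20000.0, t_hi=65535.0, enhance=False, vial_detect=False),
        )
        assert int(mask.sum()) == shell_px


class TestContourTree:
    def test_annulus_has_external_with_hole(self):
        img, shell_px, body_px = annulus_slice()
        tree = ss.extract_contour_tree(img == SHELL_LEVEL)
        kinds = [n.kind for n in tree.nodes]
        assert kinds.count("external") == 1
        assert kinds.count("hole") == 1
        ext = tree.nodes[tree.externals()[0]]
        hole = tree.nodes[[i for i, n in enumerate(tree.nodes) if n.kind == "hole"][0]]
        assert hole.parent == tree.externals()[0]
        assert int(ext.filled.sum()) == body_px
        assert int(ext.filled.sum()) - int(hole.mask.sum()) == shell_px

    def test_filter_removes_speckle_and_is_idempotent(self):
        img, _, _ = annulus_slice()
        mask = img == SHELL_LEVEL
        mask[2, 2] = True  # 1-px speckle, perimeter << 40
        tree = ss.extract_contour_tree(mask)
        cfg = cv.SegConfig()
        f1 = ss.filter_hierarchy(tree, cfg)
        assert len(f1.externals()) == 1
        f2 = ss.filter_hierarchy(f1, cfg)
        assert len(f2.nodes) == len(f1.nodes)

    def test_perimeter_filter_is_strict_less_than(self):
        # A contour of perimeter exactly min_perimeter must be kept.
        mask = np.zeros((32, 32), dtype=bool)
        mask[10:15, 10:15] = True  # 5x5 square
        tree = ss.extract_contour_tree(mask)
        p = tree.nodes[tree.externals()[0]].perimeter
        kept = ss.filter_hierarchy(tree, cv.SegConfig(min_perimeter=p))
        assert len(kept.externals()) == 1
        removed = ss.filter_hierarchy(
            tree, cv.SegConfig(min_perimeter=p + 0.001)
        )
        assert len(removed.externals()) == 0


class TestClosure:
    @staticmethod
    def open_arc(shape=(96, 96), r_out=30, r_in=24, gap_deg=40):
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
        r = np.hypot(yy - cy, xx - cx)
        theta = np.degrees(np.arctan2(yy - cy, xx - cx))
        ring = (r <= r_out) & (r > r_in)
        return ring & ~(np.abs(theta) <= gap_deg / 2.0)

    def test_solid_disk_is_not_an_orphan(self):
        mask = np.zeros((64, 64), dtype=bool)
        rr, cc = disk((32, 32), 8)
        mask[rr, cc] = True
        tree = ss.extract_contour_tree(mask)
        assert ss._orphan_candidates(tree, cv.SegConfig()) == []

    def test_open_arc_is_an_orphan_and_hull_closed(self):
        mask = self.open_arc()
        tree = ss.extract_contour_tree(mask)
        assert len(ss._orphan_candidates(tree, cv.SegConfig())) == 1
        closed = ss.close_orphans(tree, cv.SegConfig())
        ext = closed.nodes[closed.externals()[0]]
        assert "orphan_closed" in ext.flags
        # Hull closure recovers at least the arc's own footprint.
        assert ext.filled.sum() >= mask.sum()

    def test_linking_bridges_narrow_gaps(self):
        # A ring broken into two arcs by two narrow gaps: linking should
        # rebuild a closed shape whose filled area is close to the full disk.
        yy, xx = np.mgrid[:96, :96]
        cy = cx = 47.5
        r = np.hypot(yy - cy, xx - cx)
        theta = np.degrees(np.arctan2(yy - cy, xx - cx))
        ring = (r <= 30) & (r > 24)
        gaps = (np.abs(theta) <= 4) | (np.abs(np.abs(theta) - 180) <= 4)
        mask = ring & ~gaps
        tree = ss.extract_contour_tree(mask)
        linked = ss.link_open_contours(tree, cv.SegConfig())
        filled = sum(
            int(linked.nodes[i].filled.sum()) for i in linked.externals()
        )
        full_disk = np.pi * 30**2
        assert filled > 0.9 * full_disk


class TestSegmentSlice:
    def test_annulus_counts_exact(self):
        img, shell_px, body_px = annulus_slice()
        res = ss.segment_slice(ss.SliceImage(img), cv.SegConfig(min_perimeter=0))
        assert res.cuticle_px == shell_px
        assert res.body_px == body_px

    def test_label_mask_tallies_counts(self):
        img, _, _ = annulus_slice()
        res = ss.segment_slice(
            ss.SliceImage(img), cv.SegConfig(min_perimeter=0), keep_mask=True
        )
        assert int((res.label_mask == 1).sum()) == res.cuticle_px
        assert int((res.label_mask != 0).sum()) == res.body_px

    def test_invariant_cuticle_le_body(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 65535, size=(64, 64), dtype=np.uint16)
        res = ss.segment_slice(ss.SliceImage(img), cv.SegConfig())
        assert res.cuticle_px <= res.body_px

    def test_background_only_slice_is_empty(self):
        img = np.full((64, 64), BACKGROUND_LEVEL, dtype=np.uint16)
        res = ss.segment_slice(ss.SliceImage(img), cv.SegConfig())
        assert res.cuticle_px == 0 and res.body_px == 0

    def test_vial_rim_excluded(self):
        img, shell_px, body_px = annulus_slice()
        yy, xx = np.mgrid[:96, :96]
        r = np.hypot(yy - 47.5, xx - 47.5)
        rim = (r <= 44) & (r > 41)
        img2 = img.copy()
        img2[rim] = 55000
        res = ss.segment_slice(ss.SliceImage(img2), cv.SegConfig(min_perimeter=0))
        assert res.vial_detected
        assert res.cuticle_px == shell_px
        assert res.body_px == body_px
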
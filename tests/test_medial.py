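"""Medial-line extraction (skeleton longest path) and straightening."""

from __future__ import annotations

import heapq
import math

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

import roothairsizer as rhs

from conftest import small_run_config


def _mask(px, px_size=1.0, role="root_body"):
    return rhs.BinaryMask(np.asarray(px, dtype=bool), px_size, role)


def _brute_force_longest_geodesic(mask):
    """All-endpoint-pairs geodesic maximum on the skeleton graph, via a
    hand-rolled Dijkstra (1 orthogonal / sqrt(2) diagonal steps)."""
    skel = skeletonize(np.asarray(mask, dtype=bool))
    pix = {tuple(p) for p in np.argwhere(skel)}

    def neighbours(p):
        r, c = p
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q in pix:
                    yield q, math.sqrt(2) if dr and dc else 1.0

    ends = [p for p in pix if sum(1 for _ in neighbours(p)) == 1]
    best = -1.0
    for src in ends:
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            d, p = heapq.heappop(heap)
            if d > dist.get(p, np.inf):
                continue
            for q, w in neighbours(p):
                nd = d + w
                if nd < dist.get(q, np.inf):
                    dist[q] = nd
                    heapq.heappush(heap, (nd, q))
        best = max(best, max(dist.get(e, -1.0) for e in ends))
    return best


def _random_tree_mask(rng, shape=(120, 120), n_branches=5):
    """A connected, thick, tree-ish blob grown from random strokes."""
    px = np.zeros(shape, dtype=bool)
    pts = [np.array([shape[0] // 2, shape[1] // 2])]
    for _ in range(n_branches):
        start = pts[rng.integers(len(pts))].astype(float)
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.integers(20, 45)
        for t in range(length):
            r = int(round(start[0] + t * math.sin(ang)))
            c = int(round(start[1] + t * math.cos(ang)))
            if not (5 <= r < shape[0] - 5 and 5 <= c < shape[1] - 5):
                break
            px[r, c] = True
            if t == length - 1:
                pts.append(np.array([r, c]))
    px = ndi.binary_dilation(px, iterations=2)
    return px


class TestExtractRML:
    def test_horizontal_bar_gives_straight_axis(self):
        px = np.zeros((60, 260), dtype=bool)
        px[20:40, 30:230] = True
        rml = rhs.extract_rml(_mask(px), simplify_stride=20, tip_rule="end:left")
        assert rml.vertices[0, 0] < rml.vertices[-1, 0]
        assert abs(rml.length_um - 200) <= 3  # bar length, tip extension included
        assert np.ptp(rml.vertices[:, 1]) <= 2

    def test_longest_path_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            px = _random_tree_mask(rng)
            if px.sum() < 100:
                continue
            rml = rhs.extract_rml(_mask(px), simplify_stride=10, tip_rule="end:left")
            expected = _brute_force_longest_geodesic(px)
            assert rml.geodesic_length_px == pytest.approx(expected, abs=1e-9)

    def test_quarter_annulus_arc_length(self):
        R, half_w = 150.0, 10.0
        yy, xx = np.mgrid[0:200, 0:200]
        rr = np.hypot(xx - 20, yy - 20)
        ang = np.arctan2(yy - 20, xx - 20)
        px = (np.abs(rr - R) <= half_w) & (ang >= 0) & (ang <= np.pi / 2)
        rml = rhs.extract_rml(_mask(px), simplify_stride=20, tip_rule="end:top")
        assert rml.length_um == pytest.approx(np.pi * R / 2, rel=0.03)

    def test_translation_and_rotation_invariance(self, rng):
        px = _random_tree_mask(rng, shape=(140, 140))
        base = rhs.extract_rml(_mask(px), simplify_stride=10, tip_rule="end:left")
        shifted = np.roll(px, (7, -9), axis=(0, 1))
        rot = np.rot90(px)
        for variant in (shifted, rot):
            rml = rhs.extract_rml(_mask(variant), simplify_stride=10, tip_rule="end:left")
            assert rml.geodesic_length_px == pytest.approx(
                base.geodesic_length_px, rel=0.02
            )

    def test_auto_tip_picks_the_bald_end(self, small_masks):
        _, body, hairs = small_masks
        rml = rhs.extract_rml(body, tip_rule="auto", hairs_only=hairs)
        # the synthetic tip cap sits at the left margin
        assert rml.vertices[0, 0] < rml.vertices[-1, 0]

    def test_auto_tip_requires_hairs_mask(self, small_masks):
        _, body, _ = small_masks
        with pytest.raises(ValueError, match="hairs_only"):
            rhs.extract_rml(body, tip_rule="auto")

    def test_multiple_components_rejected(self):
        px = np.zeros((80, 80), dtype=bool)
        px[10:20, 10:60] = True
        px[50:60, 10:60] = True
        with pytest.raises(ValueError, match="components"):
            rhs.extract_rml(_mask(px))

    def test_tiny_mask_rejected(self):
        px = np.zeros((40, 40), dtype=bool)
        px[20, 15:25] = True
        with pytest.raises(ValueError, match="100 px"):
            rhs.extract_rml(_mask(px))


def _straight_rml(y, x0, x1, px_size=1.0):
    xs = np.array([[x0, y], [(x0 + x1) / 2, y], [x1, y]], dtype=float)
    arc = np.array([0.0, (x1 - x0) / 2, float(x1 - x0)]) * px_size
    return rhs.MedialLine(xs, arc, px_size, geodesic_length_px=float(x1 - x0))


class TestStraighten:
    def test_straight_axis_is_an_axis_aligned_crop(self, rng):
        px = rng.random((80, 120)) < 0.2
        mask = _mask(px, role="hairs_only")
        rml = _straight_rml(40, 10, 110)
        out = rhs.straighten(mask, rml, band_halfwidth_px=20)
        # column j samples x = 10 + j, rows 20..60 top-to-bottom
        expected = px[20:61, 10:111]
        np.testing.assert_array_equal(out.pixels, expected)

    def test_empty_mask_straightens_to_empty(self):
        mask = _mask(np.zeros((60, 100), dtype=bool), role="hairs_only")
        out = rhs.straighten(mask, _straight_rml(30, 5, 95), band_halfwidth_px=10)
        assert not out.pixels.any()
        assert out.n_cols == pytest.approx(90, abs=1)

    def test_radial_hair_on_curved_root_stays_vertical(self):
        # quarter annulus root with one radial hair at 45 degrees
        cy = cx = 20.0
        R, half_w, hair_len = 120.0, 10.0, 40.0
        yy, xx = np.mgrid[0:200, 0:200]
        rr = np.hypot(xx - cx, yy - cy)
        ang = np.arctan2(yy - cy, xx - cx)
        body = (np.abs(rr - R) <= half_w) & (ang >= 0) & (ang <= np.pi / 2)
        hair = (
            (rr > R + half_w)
            & (rr <= R + half_w + hair_len)
            & (np.abs(ang - np.pi / 4) < 0.012)
        )
        rml = rhs.extract_rml(_mask(body), simplify_stride=15, tip_rule="end:top")
        out = rhs.straighten(_mask(hair, role="hairs_only"), rml, band_halfwidth_px=60)
        cols = np.nonzero(out.pixels.any(axis=0))[0]
        s_hair = R * np.pi / 4  # arc position of the hair
        assert abs(cols.mean() - s_hair) < 12
        heights = out.pixels[:, cols].sum(axis=0)
        assert abs(heights.max() - hair_len) <= 0.1 * hair_len

    def test_area_roughly_conserved_for_in_band_hairs(self, small_masks, small_profile):
        _, body, hairs = small_masks
        _, diag = small_profile
        sm = diag["straightened"]
        in_band = hairs.pixels.sum()
        assert sm.pixels.sum() == pytest.approx(in_band, rel=0.15)

    def test_short_rml_rejected(self):
        mask = _mask(np.zeros((60, 60), dtype=bool), role="hairs_only")
        rml = rhs.MedialLine(
            np.array([[5.0, 5.0], [5.0, 6.0]]),
            np.array([0.0, 1.0]),
            1.0,
            geodesic_length_px=1.0,
        )
        with pytest.raises(ValueError, match="2 px"):
            rhs.straighten(mask, rml, band_halfwidth_px=5)

    def test_band_edge_warning_when_hairs_clipped(self):
        px = np.zeros((60, 120), dtype=bool)
        px[10:50, 40:44] = True  # tall structure crossing the band edge
        with pytest.warns(UserWarning, match="band"):
            rhs.straighten(_mask(px, role="hairs_only"), _straight_rml(30, 5, 115), 10)
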
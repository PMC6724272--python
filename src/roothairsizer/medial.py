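"""Root median line extraction and image straightening.

The root median line (RML) is the longest geodesic path through the
skeleton of the root-body mask, simplified to a polyline and oriented so
that vertex 0 is the root tip. The hairs-only mask is then resampled along
the RML so that columns of the straightened image correspond to arc-length
distance from the tip and rows to signed normal offset — the geometry in
which a sliding rectangular window measures hair length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize

from .segment import BinaryMask

__all__ = ["MedialLine", "StraightenedMask", "extract_rml", "straighten"]

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class MedialLine:
    """Ordered polyline along the root axis, tip at vertex 0.

    ``vertices`` are (x, y) pixel coordinates; ``arc_length_um`` is the
    cumulative polyline length from the tip, in µm. ``geodesic_length_px``
    is the length of the underlying skeleton longest path (orthogonal steps
    weighted 1, diagonal steps sqrt(2)) before simplification or boundary
    extension.
    """

    vertices: np.ndarray
    arc_length_um: np.ndarray
    px_size_um: float
    geodesic_length_px: float
    tip_index: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.arc_length_um = np.asarray(self.arc_length_um, dtype=float)
        if len(self.vertices) < 2:
            raise ValueError("medial line needs >= 2 vertices")
        if np.any(np.diff(self.arc_length_um) <= 0):
            raise ValueError("arc length must increase strictly from the tip")

    @property
    def length_um(self) -> float:
        return float(self.arc_length_um[-1])


@dataclass
class StraightenedMask:
    """Binary mask resampled along the RML.

    Column ``j`` corresponds to arc length ``j`` pixels from the tip; row
    ``band_halfwidth_px`` is the RML itself, smaller row indices are the
    left side of the tip-to-end direction, larger the right side.
    """

    pixels: np.ndarray
    band_halfwidth_px: int
    px_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)

    @property
    def center_row(self) -> int:
        return self.band_halfwidth_px

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]


def _skeleton_graph(skel: np.ndarray):
    """Sparse weighted adjacency over skeleton pixels (8-connectivity)."""
    coords = np.argwhere(skel)  # (row, col)
    n = len(coords)
    node_of = -np.ones(skel.shape, dtype=np.int64)
    node_of[coords[:, 0], coords[:, 1]] = np.arange(n)
    rows_i, rows_j, wts = [], [], []
    h, w = skel.shape
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r, c = coords[:, 0], coords[:, 1]
        r2, c2 = r + dr, c + dc
        ok = (r2 >= 0) & (r2 < h) & (c2 >= 0) & (c2 < w)
        ok[ok] &= skel[r2[ok], c2[ok]]
        i = node_of[r[ok], c[ok]]
        j = node_of[r2[ok], c2[ok]]
        rows_i.append(i)
        rows_j.append(j)
        wts.append(np.full(len(i), _SQRT2 if dr and dc else 1.0))
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    wt = np.concatenate(wts)
    graph = coo_matrix((wt, (i, j)), shape=(n, n)).tocsr()
    return coords, node_of, graph


def _longest_skeleton_path(skel: np.ndarray) -> tuple[np.ndarray, float]:
    """Pixel path (row, col) and weighted length of the longest endpoint-to-
    endpoint geodesic through a 1-px skeleton."""
    coords, node_of, graph = _skeleton_graph(skel)
    # endpoints: skeleton pixels with exactly one 8-neighbour
    nbrs = ndi.convolve(skel.astype(np.int32), np.ones((3, 3), dtype=np.int32), mode="constant")
    ends = np.argwhere(skel & (nbrs == 2))  # self + one neighbour
    if len(ends) < 2:
        raise ValueError(f"skeleton has {len(ends)} endpoint(s); need >= 2")
    end_nodes = node_of[ends[:, 0], ends[:, 1]]
    dist, pred = dijkstra(
        graph, directed=False, indices=end_nodes, return_predecessors=True
    )
    d_ends = dist[:, end_nodes]
    d_ends[~np.isfinite(d_ends)] = -1.0
    a, b = np.unravel_index(np.argmax(d_ends), d_ends.shape)
    best = float(d_ends[a, b])
    if best < 0:
        raise ValueError("skeleton endpoints are disconnected")
    # walk back from endpoint b to source endpoint a
    path_nodes = [end_nodes[b]]
    while path_nodes[-1] != end_nodes[a]:
        path_nodes.append(pred[a, path_nodes[-1]])
    path = coords[np.asarray(path_nodes[::-1])]
    return path, best


def _extend_to_boundary(path: np.ndarray, mask: np.ndarray, at_start: bool) -> np.ndarray:
    """March from one end of the pixel path along its local tangent until the
    mask boundary, returning the appended/prepended boundary point (if any)."""
    k = min(20, len(path) - 1)
    if at_start:
        p0, pk = path[0].astype(float), path[k].astype(float)
    else:
        p0, pk = path[-1].astype(float), path[-1 - k].astype(float)
    direction = p0 - pk
    norm = np.hypot(*direction)
    if norm == 0:
        return path
    direction /= norm
    h, w = mask.shape
    last_inside = None
    pt = p0.copy()
    for _ in range(max(h, w)):
        pt = pt + direction
        r, c = int(round(pt[0])), int(round(pt[1]))
        if not (0 <= r < h and 0 <= c < w) or not mask[r, c]:
            break
        last_inside = (r, c)
    if last_inside is None:
        return path
    ext = np.asarray([last_inside])
    return np.vstack([ext, path]) if at_start else np.vstack([path, ext])


def extract_rml(
    root_body: BinaryMask,
    simplify_stride: int = 200,
    tip_rule: str = "auto",
    hairs_only: BinaryMask | None = None,
    extend_to_boundary: bool = True,
    tip_search_radius_px: int = 150,
) -> MedialLine:
    """Extract the root median line from the root-body mask.

    The mask is skeletonised, the longest geodesic path between skeleton
    endpoints is taken, the path is subsampled keeping one pixel out of
    ``simplify_stride`` (plus both ends, with the stride clamped so at least
    4 vertices survive), and the tip end is designated.

    ``tip_rule``: ``"auto"`` picks the end whose surroundings contain the
    least hairs-only area (the tip region is bald; requires ``hairs_only``);
    ``"end:left"`` / ``"end:right"`` / ``"end:top"`` / ``"end:bottom"`` pick
    the end nearest the named image border.

    With ``extend_to_boundary`` the path is prolonged along its local
    tangent from each end to the mask boundary, compensating for the
    skeleton stopping about half a root-width short of the actual tip.
    """
    mask = root_body.pixels
    lab, n_comp = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n_comp != 1:
        raise ValueError(f"root body mask has {n_comp} connected components; expected 1")
    if mask.sum() < 100:
        raise ValueError("root body mask too small (< 100 px)")

    skel = skeletonize(mask)
    path, geo_len = _longest_skeleton_path(skel)
    if extend_to_boundary:
        path = _extend_to_boundary(path, mask, at_start=True)
        path = _extend_to_boundary(path, mask, at_start=False)

    # subsample to a polyline
    stride = max(1, int(simplify_stride))
    while len(range(0, len(path), stride)) + 1 < 4 and stride > 1:
        stride = max(1, stride // 2)
    keep = list(range(0, len(path) - 1, stride)) + [len(path) - 1]
    poly = path[np.asarray(keep)]  # (row, col)

    # designate the tip
    ends_rc = [poly[0], poly[-1]]
    if tip_rule == "auto":
        if hairs_only is None:
            raise ValueError("tip_rule='auto' requires the hairs_only mask")
        areas = []
        for r, c in ends_rc:
            r, c = int(r), int(c)
            rad = tip_search_radius_px
            win = hairs_only.pixels[
                max(0, r - rad) : r + rad + 1, max(0, c - rad) : c + rad + 1
            ]
            areas.append(int(win.sum()))
        tip_first = areas[0] <= areas[1]
    elif tip_rule.startswith("end:"):
        border = tip_rule.split(":", 1)[1]
        h, w = mask.shape
        key = {
            "left": lambda rc: rc[1],
            "right": lambda rc: w - 1 - rc[1],
            "top": lambda rc: rc[0],
            "bottom": lambda rc: h - 1 - rc[0],
        }
        if border not in key:
            raise ValueError(f"unknown tip_rule {tip_rule!r}")
        tip_first = key[border](ends_rc[0]) <= key[border](ends_rc[1])
    else:
        raise ValueError(f"unknown tip_rule {tip_rule!r}")
    if not tip_first:
        poly = poly[::-1]

    xy = poly[:, ::-1].astype(float)  # (x, y)
    seg = np.hypot(*np.diff(xy, axis=0).T)
    if np.any(seg == 0):  # drop duplicate vertices
        keep_v = np.concatenate([[True], seg > 0])
        xy = xy[keep_v]
        seg = np.hypot(*np.diff(xy, axis=0).T)
    arc_um = np.concatenate([[0.0], np.cumsum(seg)]) * root_body.px_size_um
    return MedialLine(xy, arc_um, root_body.px_size_um, geodesic_length_px=geo_len)


def straighten(
    hairs_only: BinaryMask, rml: MedialLine, band_halfwidth_px: int
) -> StraightenedMask:
    """Resample a binary mask along the RML into tip-aligned coordinates.

    For every 1-px step of arc length from the tip, the mask is sampled
    (nearest neighbour) along the local normal out to +/-
    ``band_halfwidth_px``; samples falling outside the image are background.
    Positive offsets (upper rows) are the left-hand side of the tip-to-end
    direction. A warning is issued if any foreground touches the band edge,
    i.e. the band may be clipping hairs.
    """
    xy = rml.vertices
    if len(xy) < 2:
        raise ValueError("RML must have >= 2 vertices")
    seg = np.hypot(*np.diff(xy, axis=0).T)
    s_vert = np.concatenate([[0.0], np.cumsum(seg)])  # px units
    total = s_vert[-1]
    if total < 2:
        raise ValueError("RML shorter than 2 px")

    s = np.arange(0.0, np.floor(total) + 1.0)  # 1-px arc steps
    xs = np.interp(s, s_vert, xy[:, 0])
    ys = np.interp(s, s_vert, xy[:, 1])
    tx = np.gradient(xs)
    ty = np.gradient(ys)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    tx, ty = tx / norm, ty / norm
    # left of heading (x right, y down): rotate tangent by -90 deg
    nx, ny = ty, -tx

    b = int(band_halfwidth_px)
    offsets = (b - np.arange(2 * b + 1))[:, None]  # +b at row 0 ... -b at last row
    sample_x = xs[None, :] + offsets * nx[None, :]
    sample_y = ys[None, :] + offsets * ny[None, :]
    ix = np.rint(sample_x).astype(np.int64)
    iy = np.rint(sample_y).astype(np.int64)
    h, w = hairs_only.pixels.shape
    inside = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
    out = np.zeros(inside.shape, dtype=bool)
    out[inside] = hairs_only.pixels[iy[inside], ix[inside]]

    if out[0].any() or out[-1].any():
        warnings.warn(
            "foreground touches the straightening band edge; increase band_halfwidth_px",
            stacklevel=2,
        )
    return StraightenedMask(out, b, hairs_only.px_size_um)
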
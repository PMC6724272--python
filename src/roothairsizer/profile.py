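"""Root-hair length profiling by sliding-window area measurement.

A rectangular window of width w slides (in steps of its own width) along
the straightened hairs-only mask. On each side of the root axis the hair
area A inside the window gives a length estimate L = A / w: for a straight
hair spanning the window this is exactly the hair length, and for bent
hairs it measures total hair material rather than extent. A block max
filter over k consecutive windows then keeps only the longest local
estimate, which makes the profile robust to bald spots and obliquely
growing hairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point

from .io import AnnotationRegion
from .medial import MedialLine, StraightenedMask

__all__ = [
    "ProfilePoint",
    "RHProfile",
    "RawWindow",
    "scan_windows",
    "max_filter",
    "project_annotations",
    "flag_profile",
    "compute_profile",
]

_SIDES = ("left", "right")


@dataclass
class RawWindow:
    """One un-filtered window measurement."""

    d_um: float
    L_um: float
    side: str


@dataclass
class ProfilePoint:
    """A max-filtered length measurement at a distance from the root tip."""

    d_um: float
    L_um: float
    side: str
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.d_um < 0 or self.L_um < 0:
            raise ValueError("distance and length must be >= 0")
        if self.side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}, got {self.side!r}")


@dataclass
class RHProfile:
    """The root-hair length profile of one image.

    Points are ordered by distance within each side; ``w_um`` is the
    scanning-window width, ``interval_k`` the max-filter block size and
    ``scan_range_um`` the requested scan range along the root axis.
    """

    points: list
    w_um: float
    interval_k: int
    scan_range_um: tuple

    def __post_init__(self) -> None:
        if self.w_um <= 0:
            raise ValueError("w_um must be > 0")
        if self.interval_k < 1:
            raise ValueError("interval_k must be >= 1")
        for side in _SIDES:
            ds = [p.d_um for p in self.points if p.side == side]
            if any(b < a for a, b in zip(ds, ds[1:])):
                raise ValueError(f"points not sorted by distance on side {side!r}")

    def distances(self) -> np.ndarray:
        return np.asarray([p.d_um for p in self.points])

    def lengths(self) -> np.ndarray:
        return np.asarray([p.L_um for p in self.points])

    def __len__(self) -> int:
        return len(self.points)


def scan_windows(
    sm: StraightenedMask,
    w_um: float,
    range_um: tuple[float, float],
    px_size_um: float | None = None,
) -> list[RawWindow]:
    """Slide the measuring window along the straightened mask.

    The window is ``w_um`` wide, stepped by exactly its own width, and is
    evaluated separately on the rows above (left side) and below (right
    side) the root axis row. Each window yields L = A / w with A the
    foreground area (pixel count times pixel area); the distance d is the
    arc length of the window centre from the tip.
    """
    px = px_size_um if px_size_um is not None else sm.px_size_um
    start_um, end_um = range_um
    if end_um <= start_um:
        raise ValueError(f"scan range end {end_um} not after start {start_um}")
    w_px = int(round(w_um / px))
    if w_px < 1:
        raise ValueError(f"window width {w_um} um is < 1 px at {px} um/px")
    start_px = max(0, int(round(start_um / px)))
    end_px = min(sm.n_cols, int(round(end_um / px)))

    c = sm.center_row
    top = sm.pixels[:c, :]
    bottom = sm.pixels[c + 1 :, :]
    out: list[RawWindow] = []
    area_per_px = px * px
    for side, half in (("left", top), ("right", bottom)):
        counts = half.sum(axis=0)
        for i in range(start_px, end_px - w_px + 1, w_px):
            a_um2 = float(counts[i : i + w_px].sum()) * area_per_px
            d_um = (i + w_px / 2.0) * px
            out.append(RawWindow(d_um=d_um, L_um=a_um2 / w_um, side=side))
    return out


def max_filter(raw: list[RawWindow], k: int) -> list[ProfilePoint]:
    """Block max filter: per side, keep the largest L of every ``k``
    consecutive windows, at the distance where that maximum occurred
    (ties broken toward the smaller distance). The trailing block may be
    shorter than ``k``."""
    if k < 1:
        raise ValueError("max-filter interval k must be >= 1")
    points: list[ProfilePoint] = []
    for side in _SIDES:
        seq = [r for r in raw if r.side == side]
        for i in range(0, len(seq), k):
            block = seq[i : i + k]
            best = max(block, key=lambda r: (r.L_um, -r.d_um))
            points.append(ProfilePoint(d_um=best.d_um, L_um=best.L_um, side=side))
    return points


def project_annotations(
    regions: list[AnnotationRegion], rml: MedialLine
) -> list[tuple[str, float, float]]:
    """Project polygon annotations onto the root axis.

    Every polygon vertex is mapped to its nearest point on the RML polyline
    (perpendicular projection onto each segment, clamped to the segment
    ends) and converted to arc-length distance from the tip; the region's
    interval is the [min, max] over its vertices. Returns
    ``(label, d_min_um, d_max_um)`` per region.
    """
    line = LineString(rml.vertices)
    out = []
    for reg in regions:
        if len(reg.vertices) < 3:
            raise ValueError("annotation polygon needs >= 3 vertices")
        d_px = [line.project(Point(x, y)) for x, y in reg.vertices]
        out.append(
            (reg.label, float(min(d_px)) * rml.px_size_um, float(max(d_px)) * rml.px_size_um)
        )
    return out


def flag_profile(
    points: list[ProfilePoint], intervals: list[tuple[str, float, float]]
) -> list[ProfilePoint]:
    """Set each point's flag for label ℓ to 1 iff its distance lies inside a
    closed interval of label ℓ. Returns new points; measurements unchanged."""
    labels = sorted({lab for lab, _, _ in intervals})
    out = []
    for p in points:
        flags = {
            lab: int(
                any(lo <= p.d_um <= hi for lab2, lo, hi in intervals if lab2 == lab)
            )
            for lab in labels
        }
        out.append(ProfilePoint(p.d_um, p.L_um, p.side, flags))
    return out


def compute_profile(
    sm: StraightenedMask,
    w_um: float,
    range_um: tuple[float, float],
    interval_k: int,
    intervals: list[tuple[str, float, float]] | None = None,
) -> RHProfile:
    """Scan, max-filter and flag in one call, returning the RHProfile."""
    raw = scan_windows(sm, w_um, range_um)
    points = max_filter(raw, interval_k)
    points = flag_profile(points, intervals or [])
    return RHProfile(points=points, w_um=w_um, interval_k=interval_k, scan_range_um=range_um)
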
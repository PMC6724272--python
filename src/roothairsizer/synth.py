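"""Synthetic root-tip image generator with known ground truth.

Renders a brightfield-like image of a gently curved root body carrying
perpendicular hairs whose lengths follow a known sigmoid of the distance
from the tip, with bald spots, occasionally kinked hairs, multiplicative
length jitter, Gaussian blur and additive intensity noise. Because the
true hair lengths, the true medial line and the rendered hair pixels are
all returned alongside the image, the full measurement pipeline can be
validated end to end without real micrographs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import LineString
from skimage.draw import polygon as draw_polygon

from .io import IntensityImage

__all__ = ["SynthSpec", "GroundTruth", "generate", "truth_sigmoid"]

# multiplicative length jitter is truncated here so the tallest possible
# hair still fits the pre-checked geometry (cuts ~0.1% of draws at sd 0.1)
_JITTER_CAP = 1.35


def truth_sigmoid(d_um, L_max, d50, delta):
    """Ground-truth hair length at distance d (lower asymptote 0)."""
    return L_max / (1.0 + np.exp((d50 - np.asarray(d_um, dtype=float)) / delta))


@dataclass
class SynthSpec:
    """Conditions of a synthetic root-tip image.

    The defaults describe a Medicago-like root: hairs reaching
    L_max = 600 µm with the half-length point d50 = 2500 µm from the tip
    and slope factor delta = 500 µm; hair sites every 25 µm per side with a
    20% chance of a bald site and 20% of hairs kinked mid-length; hair
    lengths carry 10% multiplicative lognormal jitter. The root body is
    300 µm wide and bends gently (curvature radius 20 mm). Rendering is
    brightfield-like (structures ~60/255 on a ~225/255 background) with
    1 px Gaussian blur and additive sensor noise of sd 1.5, the level left
    by a five-plane sum projection rescaled to 8 bits.
    """

    L_max: float = 600.0
    d50: float = 2500.0
    delta: float = 500.0
    root_width_um: float = 300.0
    root_curvature_radius_um: float = 20000.0  # inf = straight
    hair_spacing_um: float = 25.0
    hair_width_um: float = 12.0
    bald_prob: float = 0.2
    bent_frac: float = 0.2
    length_jitter_sd: float = 0.10
    noise_sd: float = 1.5
    blur_sigma_px: float = 1.0
    px_size_um: float = 2.0
    shape_px: tuple = (1100, 2900)
    margin_px: int = 50
    background: int = 225
    foreground: int = 60
    dark_structures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("L_max", "d50", "delta", "root_width_um", "hair_spacing_um",
                     "hair_width_um", "px_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("bald_prob", "bent_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def truth(self, d_um):
        return truth_sigmoid(d_um, self.L_max, self.d50, self.delta)


@dataclass
class GroundTruth:
    """What was actually rendered: per-hair (distance, true length, side),
    the true medial line as an (N, 2) x/y pixel polyline, and the exact
    pre-blur pixel masks of hairs and root body."""

    hairs: list  # (d_um, length_um, side)
    rml_xy: np.ndarray
    hair_mask: np.ndarray
    body_mask: np.ndarray


def _sagitta_px(spec: SynthSpec) -> float:
    """Bow depth of the symmetric centerline arc, in pixels (0 if straight)."""
    if math.isinf(spec.root_curvature_radius_um):
        return 0.0
    h, w = spec.shape_px
    px = spec.px_size_um
    half_w_px = spec.root_width_um / (2.0 * px)
    r_px = spec.root_curvature_radius_um / px
    chord = w - 2 * spec.margin_px - 2 * half_w_px
    if chord >= 2 * r_px:
        raise ValueError("root curvature too strong for the image width")
    half_theta = math.asin(chord / (2 * r_px))
    return r_px * (1.0 - math.cos(half_theta))


def _centerline(spec: SynthSpec):
    """True medial line sampled at 1 px arc steps, plus unit tangents.

    The line starts half a root width in from the margin so that the round
    tip cap of the buffered body lands exactly at the margin; the tip apex
    is therefore half a root width before the first sample, along the
    initial tangent. A finite curvature radius bends the line as a circular
    arc, symmetric about the image mid-width so the bow stays centred.
    """
    h, w = spec.shape_px
    m = spec.margin_px
    half_w_px = spec.root_width_um / (2.0 * spec.px_size_um)
    x0 = float(m) + half_w_px
    sag = _sagitta_px(spec)
    y_end = h / 2.0 + sag / 2.0  # centreline ends; the bow rises above them
    r_px = spec.root_curvature_radius_um / spec.px_size_um
    n_max = int(4 * w)
    s = np.arange(n_max, dtype=float)  # arc length, px
    if math.isinf(r_px):
        xs = x0 + s
        ys = np.full_like(s, y_end)
        tx = np.ones_like(s)
        ty = np.zeros_like(s)
    else:
        s_span = w - 2 * m - 2 * half_w_px  # nominal arc extent
        phi = (s - s_span / 2.0) / r_px
        phi0 = -s_span / 2.0 / r_px
        xs = x0 + r_px * (np.sin(phi) - math.sin(phi0))
        ys = y_end - r_px * (np.cos(phi) - math.cos(phi0))  # bows upward
        tx = np.cos(phi)
        ty = np.sin(phi)
    ok = xs <= w - m - half_w_px
    xs, ys, tx, ty = xs[ok], ys[ok], tx[ok], ty[ok]
    if len(xs) < 10:
        raise ValueError("image too small for the requested geometry")
    return xs, ys, tx, ty


def _stamp_polygon(canvas: np.ndarray, poly_xy: np.ndarray) -> None:
    rr, cc = draw_polygon(poly_xy[:, 1], poly_xy[:, 0], shape=canvas.shape)
    canvas[rr, cc] = True


def generate(spec: SynthSpec) -> tuple[IntensityImage, GroundTruth]:
    """Render a synthetic root-tip image.

    Deterministic for a given spec (all randomness from ``spec.seed``).
    Raises before rendering if the longest possible hair cannot fit inside
    the image for the requested geometry.
    """
    h, w = spec.shape_px
    px = spec.px_size_um
    half_w_px = spec.root_width_um / (2.0 * px)
    reach_px = half_w_px + spec.L_max * _JITTER_CAP / px
    sag_px = _sagitta_px(spec)
    y_end = h / 2.0 + sag_px / 2.0
    if y_end - sag_px - reach_px < 0 or y_end + reach_px > h:
        raise ValueError(
            "geometry overflow: hairs of L_max "
            f"{spec.L_max} um do not fit in a {spec.shape_px} image at {px} um/px"
        )

    rng = np.random.default_rng(spec.seed)
    xs, ys, tx, ty = _centerline(spec)
    n = len(xs)

    # root body: buffered centerline polygon
    body = np.zeros((h, w), dtype=bool)
    line = LineString(np.column_stack([xs[::5], ys[::5]]))
    poly = line.buffer(half_w_px, quad_segs=8)
    _stamp_polygon(body, np.asarray(poly.exterior.coords))

    # hairs, perpendicular to the root surface on both sides
    hair_mask = np.zeros((h, w), dtype=bool)
    hairs: list[tuple[float, float, str]] = []
    hw_px = spec.hair_width_um / px
    spacing_px = spec.hair_spacing_um / px
    sites = np.arange(spacing_px, n - 1, spacing_px)
    for s_px in sites:
        i = int(round(s_px))
        # left of travel direction = upper rows in the straightened frame
        normals = {"left": (ty[i], -tx[i]), "right": (-ty[i], tx[i])}
        # distances are measured from the tip apex, half a root width
        # before the centerline start
        d_um = (s_px + half_w_px) * px
        for side, (nx, ny) in normals.items():
            if rng.random() < spec.bald_prob:
                continue
            jitter = min(rng.lognormal(mean=0.0, sigma=spec.length_jitter_sd), _JITTER_CAP)
            length_um = float(spec.truth(d_um) * jitter)
            len_px = length_um / px
            if len_px < 1.0:
                continue
            base = np.array([xs[i] + nx * half_w_px, ys[i] + ny * half_w_px])
            if rng.random() < spec.bent_frac:
                ang = rng.uniform(0.35, 0.8) * rng.choice([-1.0, 1.0])
                ca, sa = math.cos(ang), math.sin(ang)
                n2 = (nx * ca - ny * sa, nx * sa + ny * ca)
                mid = base + np.array([nx, ny]) * (len_px / 2.0)
                tip = mid + np.array(n2) * (len_px / 2.0)
                pts = [base, mid, tip]
            else:
                pts = [base, base + np.array([nx, ny]) * len_px]
            # flat caps: the rendered extent equals the nominal length exactly
            shape = LineString(pts).buffer(hw_px / 2.0, quad_segs=4, cap_style="flat")
            _stamp_polygon(hair_mask, np.asarray(shape.exterior.coords))
            hairs.append((d_um, length_um, side))

    # render intensities
    img = np.full((h, w), float(spec.background))
    structure = body | hair_mask
    fg, bg = (spec.foreground, spec.background)
    if not spec.dark_structures:
        fg, bg = bg, fg
        img[:] = float(bg)
    img[structure] = float(fg)
    if spec.blur_sigma_px > 0:
        img = ndi.gaussian_filter(img, spec.blur_sigma_px)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    apex = np.array([xs[0] - tx[0] * half_w_px, ys[0] - ty[0] * half_w_px])
    truth = GroundTruth(
        hairs=hairs,
        rml_xy=np.vstack([apex, np.column_stack([xs, ys])]),
        hair_mask=hair_mask,
        body_mask=body,
    )
    return IntensityImage(img, 8, px), truth
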
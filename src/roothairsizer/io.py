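"""Image and table input/output.

Reads single- or multi-page TIFF root-tip images (multi-page stacks are
sum-projected to a single 8-bit plane), and serialises root-hair length
profiles (CSV), fitted parameters (JSON) and polygonal annotation regions
(JSON sidecar).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "IntensityImage",
    "AnnotationRegion",
    "load_image",
    "write_profile",
    "read_profile",
    "read_annotations",
    "write_annotations",
]


class CalibrationError(ValueError):
    """Raised when no pixel-size calibration can be determined."""


@dataclass
class IntensityImage:
    """A 2-D grayscale image with physical pixel-size calibration.

    Parameters
    ----------
    pixels : ndarray
        2-D array of non-negative intensities.
    bit_depth : int
        8 or 16; intensities must lie in ``[0, 2**bit_depth - 1]``.
    px_size_um : float
        Physical size of one pixel edge in micrometres (> 0).
    """

    pixels: np.ndarray
    bit_depth: int
    px_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={self.pixels.ndim}")
        if min(self.pixels.shape) < 32:
            raise ValueError(f"image too small: {self.pixels.shape} (minimum 32x32)")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not (np.isfinite(self.px_size_um) and self.px_size_um > 0):
            raise CalibrationError(f"px_size_um must be finite and > 0, got {self.px_size_um}")
        lo = self.pixels.min()
        hi = self.pixels.max()
        if lo < 0 or hi > 2**self.bit_depth - 1:
            raise ValueError(
                f"intensities [{lo}, {hi}] outside the {self.bit_depth}-bit range"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class AnnotationRegion:
    """A labelled polygon marking a region to flag (e.g. an artefact).

    Vertices are (x, y) pixel coordinates; the polygon must have at least
    three vertices and non-zero area.
    """

    vertices: np.ndarray
    label: str

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("annotation polygon needs >= 3 (x, y) vertices")
        x, y = v[:, 0], v[:, 1]
        # shoelace
        area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        if area <= 0:
            raise ValueError(f"annotation polygon {self.label!r} has zero area")
        self.vertices = v

    def clamped(self, shape: tuple[int, int]) -> "AnnotationRegion":
        """Return a copy with vertices clamped into the image bounds."""
        h, w = shape
        v = self.vertices.copy()
        v[:, 0] = np.clip(v[:, 0], 0, w - 1)
        v[:, 1] = np.clip(v[:, 1], 0, h - 1)
        return AnnotationRegion(v, self.label)


def _px_size_from_tiff(tf: tifffile.TiffFile) -> float | None:
    """Pixel size in µm from TIFF resolution tags, if present and sane."""
    page = tf.pages[0]
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
    unit = int(unit)
    per_unit = num / den  # pixels per unit
    if unit == 3:  # centimetre
        um_per_unit = 1e4
    elif unit == 2:  # inch
        um_per_unit = 25400.0
    else:
        return None
    return um_per_unit / per_unit


def load_image(
    path: str | Path,
    plane_policy: str = "sum",
    px_size_um: float | None = None,
) -> IntensityImage:
    """Load a TIFF image, sum-projecting multi-page stacks.

    Parameters
    ----------
    path : path-like
        Single- or multi-page grayscale TIFF.
    plane_policy : str
        ``"sum"`` sum-projects all pages and linearly rescales (min-max) the
        result to the 8-bit range; ``"single:IDX"`` keeps page ``IDX``
        unchanged. Single-page files are always returned unchanged.
    px_size_um : float, optional
        Pixel size in µm. Takes precedence over the file's resolution tags;
        required when the file carries none.

    Returns
    -------
    IntensityImage
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        if px_size_um is None:
            px_size_um = _px_size_from_tiff(tf)
    if px_size_um is None:
        raise CalibrationError(
            f"{path}: no pixel-size calibration: the TIFF has no resolution tags "
            "and no px_size_um was supplied"
        )
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D image or a stack, got shape {arr.shape}")
    if arr.shape[1] < 1 or arr.shape[2] < 1:
        raise ValueError(f"{path}: zero-size image")

    if plane_policy.startswith("single:"):
        idx = int(plane_policy.split(":", 1)[1])
        plane = arr[idx]
        bit_depth = 16 if plane.dtype.itemsize > 1 else 8
        return IntensityImage(plane, bit_depth, px_size_um)
    if plane_policy != "sum":
        raise ValueError(f"unknown plane_policy {plane_policy!r}")

    if arr.shape[0] == 1:
        plane = arr[0]
        bit_depth = 16 if plane.dtype.itemsize > 1 else 8
        return IntensityImage(plane, bit_depth, px_size_um)

    total = arr.astype(np.float64).sum(axis=0)
    lo, hi = total.min(), total.max()
    if hi > lo:
        scaled = (total - lo) * (255.0 / (hi - lo))
    else:
        scaled = np.clip(total, 0, 255)  # constant stack: clip, nothing to stretch
    return IntensityImage(np.rint(scaled).astype(np.uint8), 8, px_size_um)


# ---------------------------------------------------------------------------
# profile CSV

_META_PREFIX = "# rhs "


def write_profile(profile, path: str | Path) -> None:
    """Write an RHProfile to CSV.

    Columns: distance_um, length_um, side, then one 0/1 column
    ``flag_<label>`` per annotation label. Profile-level metadata (window
    width, max-filter interval, scan range) goes in ``# rhs key=value``
    comment lines before the header so that :func:`read_profile` can
    reconstruct the profile exactly.
    """
    from .profile import RHProfile  # local import to avoid a cycle

    if not isinstance(profile, RHProfile):
        raise TypeError("write_profile expects an RHProfile")
    if not profile.points:
        raise ValueError("refusing to write an empty profile")

    labels = sorted({lab for p in profile.points for lab in p.flags})
    rows = [
        {
            "distance_um": p.d_um,
            "length_um": p.L_um,
            "side": p.side,
            **{f"flag_{lab}": int(p.flags.get(lab, 0)) for lab in labels},
        }
        for p in profile.points
    ]
    df = pd.DataFrame(rows)
    meta = {
        "w_um": profile.w_um,
        "interval_k": profile.interval_k,
        "scan_start_um": profile.scan_range_um[0],
        "scan_end_um": profile.scan_range_um[1],
    }
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"{_META_PREFIX}{k}={v!r}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def read_profile(path: str | Path):
    """Read an RHProfile written by :func:`write_profile`."""
    from .profile import ProfilePoint, RHProfile

    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            if line.startswith(_META_PREFIX):
                try:
                    key, val = line[len(_META_PREFIX):].strip().split("=", 1)
                    meta[key] = float(val)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed metadata line") from exc
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed profile CSV: {exc}") from exc
    required = {"distance_um", "length_um", "side"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    flag_cols = [c for c in df.columns if c.startswith("flag_")]
    points = [
        ProfilePoint(
            d_um=float(r.distance_um),
            L_um=float(r.length_um),
            side=str(r.side),
            flags={c[len("flag_"):]: int(getattr(r, c)) for c in flag_cols},
        )
        for r in df.itertuples()
    ]
    return RHProfile(
        points=points,
        w_um=meta.get("w_um", float("nan")),
        interval_k=int(meta.get("interval_k", 1)),
        scan_range_um=(meta.get("scan_start_um", 0.0), meta.get("scan_end_um", float("nan"))),
    )


# ---------------------------------------------------------------------------
# annotation JSON


def read_annotations(path: str | Path) -> list[AnnotationRegion]:
    """Read labelled polygons from a JSON sidecar.

    Format: ``[{"label": "artefact", "vertices": [[x, y], ...]}, ...]``.
    """
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise ValueError(f"{path}: expected a JSON list of regions")
    return [AnnotationRegion(np.asarray(r["vertices"], dtype=float), r["label"]) for r in data]


def write_annotations(regions: list[AnnotationRegion], path: str | Path) -> None:
    data = [{"label": r.label, "vertices": r.vertices.tolist()} for r in regions]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
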
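"""Shared fixtures: a small, fast synthetic root and its measured profile."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import roothairsizer as rhs

SMALL_TRUTH = {"L_max": 240.0, "d50": 900.0, "delta": 200.0}


def small_spec(**overrides) -> rhs.SynthSpec:
    """A compact straight root (500x1100 px at 2 µm/px) for fast tests."""
    kw = dict(
        L_max=SMALL_TRUTH["L_max"],
        d50=SMALL_TRUTH["d50"],
        delta=SMALL_TRUTH["delta"],
        root_width_um=150.0,
        root_curvature_radius_um=float("inf"),
        shape_px=(500, 1100),
        px_size_um=2.0,
        seed=7,
    )
    kw.update(overrides)
    return rhs.SynthSpec(**kw)


def small_run_config(**overrides) -> rhs.RunConfig:
    kw = dict(
        band_halfwidth_px=260,
        first_fit_range_um=(0.0, 2100.0),
        scan_end_um=2100.0,
    )
    kw.update(overrides)
    return rhs.RunConfig.for_synthetic(**kw)


@pytest.fixture(scope="session")
def small_image():
    img, truth = rhs.generate(small_spec())
    return img, truth


@pytest.fixture(scope="session")
def small_masks(small_image):
    img, _ = small_image
    return rhs.build_masks(img, small_run_config().segmentation())


@pytest.fixture(scope="session")
def small_profile(small_image):
    img, _ = small_image
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profile, diag = rhs.run_measure(img, small_run_config())
    return profile, diag


@pytest.fixture
def rng():
    return np.random.default_rng(123)
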
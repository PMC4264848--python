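"""Shared fixtures: small phantoms, pipeline inputs on disk, and the
brute-force morphology oracle used to validate every morphological step."""

from __future__ import annotations

import numpy as np
import pytest

from scaffoldmri import AcquisitionModel, ScaffoldGeometry, generate_phantom
from scaffoldmri.io import write_stack
from scaffoldmri.phantom import generate_bare_phantom


# --------------------------------------------------------------------------
# brute-force oracle: erosion-then-dilation with explicit loops over the
# disk offsets and symmetric (reflective) padding; independent of scipy's
# morphology path used by the implementation


def oracle_disk_offsets(radius: int) -> list[tuple[int, int]]:
    r = int(radius)
    return [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= r * r
    ]


def _oracle_shifts(image: np.ndarray, radius: int) -> np.ndarray:
    """Stack of the image translated to every disk offset, with symmetric
    (reflective) padding; reductions over axis 0 give erosion/dilation/median."""
    r = int(radius)
    pad = np.pad(image, r, mode="symmetric")
    ny, nx = image.shape
    return np.stack(
        [pad[r + dy : r + dy + ny, r + dx : r + dx + nx] for dy, dx in oracle_disk_offsets(r)]
    )


def oracle_erosion(image: np.ndarray, radius: int) -> np.ndarray:
    return _oracle_shifts(image, radius).min(axis=0)


def oracle_dilation(image: np.ndarray, radius: int) -> np.ndarray:
    return _oracle_shifts(image, radius).max(axis=0)


def oracle_opening(image: np.ndarray, radius: int) -> np.ndarray:
    return oracle_dilation(oracle_erosion(image, radius), radius)


def oracle_median(image: np.ndarray, radius: int) -> np.ndarray:
    return np.median(_oracle_shifts(image, radius), axis=0)


@pytest.fixture(scope="session")
def oracle():
    class Oracle:
        erosion = staticmethod(oracle_erosion)
        dilation = staticmethod(oracle_dilation)
        opening = staticmethod(oracle_opening)
        median = staticmethod(oracle_median)
        disk_offsets = staticmethod(oracle_disk_offsets)

    return Oracle


# --------------------------------------------------------------------------
# phantoms (session-scoped: generation is deterministic, consumers must not
# mutate)


@pytest.fixture(scope="session")
def small_geometry() -> ScaffoldGeometry:
    """A reduced scaffold that keeps unit tests fast: 5 mm cylinder,
    1.5 mm tall, on a 64-px grid."""
    return ScaffoldGeometry(cylinder_diameter=5.0, cylinder_height=1.5)


@pytest.fixture(scope="session")
def small_acquisition() -> AcquisitionModel:
    return AcquisitionModel(
        matrix_size=64, n_slices=20, slice_thickness=0.1, tube_diameter=6.0, seed=7
    )


@pytest.fixture(scope="session")
def small_phantom(small_geometry, small_acquisition):
    return generate_phantom(geometry=small_geometry, acquisition=small_acquisition)


@pytest.fixture(scope="session")
def default_phantom():
    """Full-size (128 x 128 x 45) phantom at the default study conditions."""
    return generate_phantom()


@pytest.fixture(scope="session")
def bare_phantom():
    return generate_bare_phantom()


@pytest.fixture(scope="session")
def clean_acquisition() -> AcquisitionModel:
    """Noise- and bias-free acquisition with well-separated levels."""
    return AcquisitionModel(
        bias_amplitude=0.0,
        noise_sigma=0.0,
        intensity_levels={"scaffold": 10.0, "liquid": 100.0, "tissue": 150.0},
    )


@pytest.fixture(scope="session")
def clean_phantom(clean_acquisition):
    return generate_phantom(acquisition=clean_acquisition)


@pytest.fixture(scope="session")
def pipeline_paths(tmp_path_factory, default_phantom, bare_phantom):
    """Default phantom + bare control written as TIFF for pipeline runs."""
    d = tmp_path_factory.mktemp("stacks")
    sample = write_stack(default_phantom.stack, d / "sample.tif")
    bare = write_stack(bare_phantom.stack, d / "bare.tif")
    return {"sample": sample, "bare": bare}
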
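"""Shared fixtures: phantoms are rendered once per session (they are the
expensive inputs) and small helper scenes keep property tests fast."""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pytest

import mwiphase as mw
from mwiphase.phantom import PhantomScene, TumorRegion


def pytest_configure(config):
    # degenerate-line warnings from flat reference strips are expected
    warnings.filterwarnings("ignore", message=".*constant line.*")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cube():
    """A tiny deterministic cube for I/O tests (8 x 9 x 3)."""
    data = np.arange(8 * 9 * 3, dtype=np.float32).reshape(8, 9, 3)
    return mw.SpectralCube(
        data=data, wavelengths_nm=[446.6, 550.0, 632.0], meta={"origin": "test"}
    )


def two_band_scene(**overrides) -> PhantomScene:
    """A compact two-band scene (445 / 630 nm) for fast end-to-end tests."""
    base = dict(
        rows=176,
        cols=192,
        wavelengths_nm=(445.0, 630.0),
        reference_strip=(0, 32),
        tumor_regions=(TumorRegion(104, 96, 30.0, 24.0, 16.0),),
        seed=7,
    )
    base.update(overrides)
    return PhantomScene(**base)


@pytest.fixture(scope="session")
def noiseless_phantom():
    return mw.render_phantom(mw.default_scene(seed=42, noise_sigma=0.0))


@pytest.fixture(scope="session")
def default_phantom():
    return mw.render_phantom(mw.default_scene(seed=42))


@pytest.fixture(scope="session")
def deep_phantom_noiseless():
    return mw.render_phantom(mw.deep_tumor_scene(noise_sigma=0.0))


def pipeline_result(phantom_output):
    return mw.run_pipeline(
        phantom_output.cube,
        reference_strip=phantom_output.scene.reference_strip,
        truth=phantom_output.truth,
    )


@pytest.fixture(scope="session")
def noiseless_result(noiseless_phantom):
    return pipeline_result(noiseless_phantom)


@pytest.fixture(scope="session")
def default_result(default_phantom):
    return pipeline_result(default_phantom)


def injected_shift(phantom_output, blue_nm=446.6, red_nm=632.0):
    """Ground-truth |wrap(phi_blue - phi_red)| at the selected bands."""
    wl = phantom_output.cube.wavelengths_nm
    ib = int(np.argmin(np.abs(wl - blue_nm)))
    ir = int(np.argmin(np.abs(wl - red_nm)))
    return np.abs(
        mw.wrap_phase(
            phantom_output.phase_truth[:, :, ib]
            - phantom_output.phase_truth[:, :, ir]
        )
    )
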
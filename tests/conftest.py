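"""Shared fixtures: compact phantoms and a fitted segmenter.

The heavy recovery phantom (generation + two control volumes + tubeness
calibration) is built once per session and reused by the segmentation,
network, clearance, pipeline and acceptance tests.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pytest

from perivasc.core import ImageVolume
from perivasc.phantom import PhantomSpec, TubeSpec, demo_spec, generate_naive, generate_phantom
from perivasc.tubeness import PVSSegmenter


def spec_with(spec: PhantomSpec, **overrides) -> PhantomSpec:
    """Copy of a phantom spec with fields replaced."""
    fields = {k: getattr(spec, k) for k in spec.__dataclass_fields__}
    fields.update(overrides)
    return PhantomSpec(**fields)


@pytest.fixture(scope="session")
def recovery_phantom():
    """Demo phantom + truth + two matched naive controls."""
    spec = demo_spec(seed=7)
    volume, truth = generate_phantom(spec)
    naives = [generate_naive(spec_with(spec, seed=s)) for s in (108, 109)]
    return {"spec": spec, "volume": volume, "truth": truth, "naives": naives}


@pytest.fixture(scope="session")
def fitted_segmenter(recovery_phantom):
    truth = recovery_phantom["truth"]
    seg = PVSSegmenter(reference_peak=100.0)
    seg.fit(recovery_phantom["naives"], [truth.brain_mask] * 2)
    return seg


@pytest.fixture(scope="session")
def recovery_segmentation(recovery_phantom, fitted_segmenter):
    truth = recovery_phantom["truth"]
    return fitted_segmenter.predict(
        recovery_phantom["volume"], truth.brain_mask, truth.ventricle_mask
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def straight_tube_spec(n_layers: int = 50, grid: int = 60, radius: float = 0.02,
                       noise_sd: float = 0.0) -> PhantomSpec:
    """Axis-aligned single-voxel-wide tube through ``n_layers`` voxel layers."""
    c = grid * 0.04 / 2
    y = c + 0.02  # off lattice planes so exactly one voxel center per layer is hit
    x0 = c - n_layers * 0.04 / 2
    tube = TubeSpec(
        polyline=[[x0 + 0.001, y, y], [x0 + n_layers * 0.04 - 0.001, y, y]],
        radius=radius,
    )
    return PhantomSpec(
        grid_shape=(grid, grid, grid),
        spacing=(0.04, 0.04, 0.04),
        brain_center=(c, c, c),
        brain_semiaxes=(c * 0.95, c * 0.95, c * 0.95),
        ventricle=[],
        tubes=[tube],
        noise_sd=noise_sd,
        bias_amplitude=0.0,
    )
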
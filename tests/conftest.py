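"""Shared fixtures: reference geometry, meshes, and simulated datasets.

Expensive artifacts (reference layout, meshes, full virtual-heart runs) are
session-scoped so the suite builds each of them once.
"""
from __future__ import annotations

import numpy as np
import pytest

from panomap import (
    EllipsoidSpec,
    FiberTrace,
    Modality,
    SimulationConfig,
    build_mesh,
    generate_layout,
    simulate,
)
from panomap.simulate import INDICATORS


REFERENCE_AXES = (2.75, 3.5, 6.0)  # semi-axes of the 5.5 x 7 x 12 mm cup
REFERENCE_TRUNCATION = 0.25
REFERENCE_PITCH = 0.7
REFERENCE_COUNTS = (64, 294)  # electrodes, optical fibers


@pytest.fixture(scope="session")
def reference_ellipsoid() -> EllipsoidSpec:
    return EllipsoidSpec(*REFERENCE_AXES, truncation_fraction=REFERENCE_TRUNCATION)


@pytest.fixture(scope="session")
def reference_layout(reference_ellipsoid):
    return generate_layout(reference_ellipsoid, REFERENCE_PITCH, *REFERENCE_COUNTS, seed=1)


@pytest.fixture(scope="session")
def reference_mesh(reference_ellipsoid):
    return build_mesh(reference_ellipsoid, 0.35)


@pytest.fixture(scope="session")
def unit_sphere_mesh():
    return build_mesh(EllipsoidSpec(1, 1, 1), 0.05)


@pytest.fixture(scope="session")
def virtual_heart(reference_layout, reference_mesh):
    """Fast-indicator virtual heart at SNR 15 (the headline concordance run).

    The stimulated electrode sits mid-flank (free-wall pacing); the apex is a
    poor origin because the circumferential fiber field degenerates there.
    """
    eids = reference_layout.site_ids(Modality.ELECTRICAL)
    epos = reference_layout.positions(Modality.ELECTRICAL)
    origin = eids[int(np.argmin(np.abs(epos[:, 2] + 1.5) + np.abs(epos[:, 0] - 2.0)))]
    cfg = SimulationConfig(
        layout=reference_layout,
        mesh=reference_mesh,
        origin_site=origin,
        theta_long=600.0,
        theta_trans=300.0,
        indicator=INDICATORS["fast_dye"],
        seed=7,
    ).with_target_snr(15)
    return simulate(cfg)


def logistic(t: np.ndarray, t0: float, k: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip((t - t0) * k, -500, 500)))


def make_ap_trace(
    fs: float = 10000.0,
    duration_ms: float = 150.0,
    lat_ms: float = 50.0,
    rise_k: float = 2.0,
    amplitude: float = 100.0,
    baseline: float = 500.0,
    apd_ms: float = 40.0,
    noise_sd: float = 1e-7,
    seed: int = 0,
    fiber_id: int = 0,
) -> FiberTrace:
    """Single logistic-upstroke AP with a logistic repolarization."""
    t = np.arange(0, duration_ms, 1000.0 / fs)
    rng = np.random.default_rng(seed)
    sig = logistic(t, lat_ms, rise_k) * (1 - logistic(t, lat_ms + apd_ms, 0.5))
    return FiberTrace(fiber_id, baseline + amplitude * sig + rng.normal(0, noise_sd, len(t)), fs)
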
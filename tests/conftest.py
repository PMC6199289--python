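"""Shared fixtures: phantoms are generated once per session where reused."""

from __future__ import annotations

import numpy as np
import pytest

from sarcomech.phantom import FiberPhantomSpec, TraceSpec, generate_fiber_stack, generate_force_trace


@pytest.fixture(scope="session")
def parallel_stack():
    """Perfectly parallel, dislocation-free, noise-free fiber phantom."""
    spec = FiberPhantomSpec(
        orientation_dispersion_deg=0.0,
        n_dislocations=0,
        field_size_um=(80.0, 80.0),
        seed=11,
    )
    return generate_fiber_stack(spec)


@pytest.fixture(scope="session")
def dislocation_slice():
    """One 200x200 um slice with 8 inserted dislocations (full acquisition size)."""
    spec = FiberPhantomSpec(
        field_size_um=(200.0, 200.0),
        pixel_size_um=0.195,
        fiber_diameter_um=60.0,
        n_dislocations=8,
        orientation_dispersion_deg=5.0,
        seed=21,
    )
    return generate_fiber_stack(spec)


@pytest.fixture(scope="session")
def multislice_stack():
    """Multi-slice 40 um fiber for geometry tests (z spans the full chord)."""
    spec = FiberPhantomSpec(
        fiber_diameter_um=40.0,
        field_size_um=(80.0, 120.0),
        n_slices=31,
        z_step_um=2.0,
        orientation_dispersion_deg=0.0,
        seed=31,
    )
    return generate_fiber_stack(spec)


@pytest.fixture()
def pca_trace():
    """Noise-free pCa staircase with exchange spikes."""
    return generate_force_trace(TraceSpec(kind="pca_series", noise_sigma_un=0.0, seed=5))


@pytest.fixture()
def stretch_trace():
    """Noise-free single 50 um stretch step (F_eq 200, A1 100, A2 50)."""
    spec = TraceSpec(
        kind="stretch_series",
        step_sizes_um=[50.0],
        feq_per_step_un=[200.0],
        a1_un=100.0,
        a2_un=50.0,
        tau1_s=0.5,
        tau2_s=5.0,
        noise_sigma_un=0.0,
        step_duration_s=60.0,
    )
    return generate_force_trace(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
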
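"""Shared fixtures: small geometries for unit tests, one full moving-case
pipeline reused across modules, and a numerical ray-marching projection
oracle independent of the analytic projector."""

from __future__ import annotations

import numpy as np
import pytest

from parmoco import ReconGrid, SystemGeometry
from parmoco.fixtures import gated_timeline, run_case
from parmoco.phantom import rasterize


@pytest.fixture(scope="session")
def small_geometry() -> SystemGeometry:
    """Desk-scale geometry for fast unit tests."""
    return SystemGeometry(n_channels=256, views_per_rotation=360)


@pytest.fixture(scope="session")
def small_grid() -> ReconGrid:
    return ReconGrid(n=128, pixel_size=250.0 / 128)


@pytest.fixture(scope="session")
def full_grid() -> ReconGrid:
    return ReconGrid(n=256, pixel_size=250.0 / 256)


@pytest.fixture(scope="session")
def moving_case_80bpm():
    """One full pipeline run (80 bpm, R-R 70%) shared by several tests."""
    return run_case(80.0, 0.7)


def ray_march_projection(frozen, geometry, beta, step=0.25, raster_n=1024,
                         fov=250.0):
    """Numerical line integrals by marching through a rasterized snapshot.

    Independent oracle for the analytic projector: nearest-neighbor
    sampling of a fine rasterization, summed along each ray with a
    fixed step (mm).
    """
    grid = ReconGrid(n=raster_n, pixel_size=fov / raster_n)
    img = rasterize(frozen, grid).values
    origin = geometry.source_position(beta)
    theta = beta + geometry.gamma
    out = np.empty(theta.size)
    # march from source across the FOV
    t0 = geometry.source_to_iso - fov
    t1 = geometry.source_to_iso + fov
    ts = np.arange(t0, t1, step)
    half = fov / 2.0
    for k, th in enumerate(theta):
        x = origin[0] + ts * np.sin(th)
        y = origin[1] - ts * np.cos(th)
        inside = (np.abs(x) < half) & (np.abs(y) < half)
        col = np.clip((x[inside] / grid.pixel_size - 0.5 + raster_n / 2.0)
                      .round().astype(int), 0, raster_n - 1)
        row = np.clip((y[inside] / grid.pixel_size - 0.5 + raster_n / 2.0)
                      .round().astype(int), 0, raster_n - 1)
        out[k] = img[row, col].sum() * step
    return out
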
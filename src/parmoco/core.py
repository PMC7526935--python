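"""Reconstruction grids, images and attenuation/HU conversion.

All images live on a square metric grid centered on the scanner
isocenter.  Pixel (i, j) has its center at

    x = (j + 0.5 - n/2) * pixel_size,   y = (i + 0.5 - n/2) * pixel_size

with x pointing to the patient right and y up.  Array axis 0 is y,
axis 1 is x, so ``values[i, j]`` samples the point ``(x_j, y_i)``.

Attenuation is stored as linear attenuation mu in 1/mm; the Hounsfield
view uses the reference value ``MU_WATER`` (water = 0 HU, air = -1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Linear attenuation of water used for HU conversion, 1/mm.
MU_WATER = 0.02


def hu_to_mu(hu: float | np.ndarray) -> float | np.ndarray:
    """Convert Hounsfield units to linear attenuation (1/mm)."""
    return MU_WATER * (1.0 + np.asarray(hu, dtype=float) / 1000.0)


def mu_to_hu(mu: float | np.ndarray) -> float | np.ndarray:
    """Convert linear attenuation (1/mm) to Hounsfield units."""
    return 1000.0 * (np.asarray(mu, dtype=float) - MU_WATER) / MU_WATER


@dataclass(frozen=True)
class ReconGrid:
    """Square pixel grid centered at the isocenter.

    Parameters
    ----------
    n : int
        Pixels per side.
    pixel_size : float
        Pixel edge length in mm.  The field of view is ``n * pixel_size``.
    """

    n: int
    pixel_size: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("grid size must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def fov(self) -> float:
        """Field-of-view edge length in mm."""
        return self.n * self.pixel_size

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D pixel-center coordinates ``(x, y)`` in mm."""
        c = (np.arange(self.n) + 0.5 - self.n / 2.0) * self.pixel_size
        return c, c.copy()

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """2-D pixel-center coordinate arrays ``(X, Y)``, shape (n, n)."""
        x, y = self.coords()
        return np.meshgrid(x, y)

    def mm_to_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map mm coordinates to fractional array indices (row, col)."""
        col = np.asarray(x) / self.pixel_size - 0.5 + self.n / 2.0
        row = np.asarray(y) / self.pixel_size - 0.5 + self.n / 2.0
        return row, col


@dataclass
class ReconImage:
    """Attenuation image on a :class:`ReconGrid`.

    ``values`` are linear attenuation coefficients in 1/mm;
    ``target_time`` records the time (s) the image nominally represents
    (None for static ground truth).
    """

    values: np.ndarray
    grid: ReconGrid
    target_time: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n, self.grid.n):
            raise ValueError(
                f"image shape {self.values.shape} does not match grid n={self.grid.n}"
            )

    def hu(self) -> np.ndarray:
        """Image values in Hounsfield units."""
        return mu_to_hu(self.values)

    def copy_with(self, values: np.ndarray) -> "ReconImage":
        return ReconImage(values=values, grid=self.grid,
                          target_time=self.target_time, meta=dict(self.meta))
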
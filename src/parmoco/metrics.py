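"""Evaluation suite: ROI-wise MSSIM, masked RMSE, HU line-profile
stability across cardiac phases, and one-sided paired comparisons.

Conventions: MSSIM follows the standard luminance/contrast/structure
formulation (11x11 Gaussian window, sigma 1.5, K1=0.01, K2=0.03) with
the dynamic range taken from the reference ROI, since HU images are not
8-bit.  RMSE and profile statistics are reported in HU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy import stats
from skimage.metrics import structural_similarity

from .core import ReconImage


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned square region of interest, in mm."""

    center: tuple[float, float]
    half_extent: float = 10.0
    label: str = ""

    def mask(self, image: ReconImage) -> np.ndarray:
        X, Y = image.grid.meshgrid()
        return ((np.abs(X - self.center[0]) <= self.half_extent)
                & (np.abs(Y - self.center[1]) <= self.half_extent))

    def crop(self, image: ReconImage) -> np.ndarray:
        """Rectangular HU crop of the ROI."""
        g = image.grid
        r0, c0 = g.mm_to_index(self.center[0] - self.half_extent,
                               self.center[1] - self.half_extent)
        r1, c1 = g.mm_to_index(self.center[0] + self.half_extent,
                               self.center[1] + self.half_extent)
        r0, c0 = int(np.ceil(r0)), int(np.ceil(c0))
        r1, c1 = int(np.floor(r1)) + 1, int(np.floor(c1)) + 1
        if r0 < 0 or c0 < 0 or r1 > g.n or c1 > g.n:
            raise ValueError(f"ROI {self.label!r} exceeds the image FOV")
        return image.hu()[r0:r1, c0:c1]


@dataclass(frozen=True)
class LineProfile:
    """Straight sampling line between two mm endpoints."""

    start: tuple[float, float]
    stop: tuple[float, float]
    n_samples: int = 100

    def sample(self, image: ReconImage) -> np.ndarray:
        """HU values along the line (linear interpolation)."""
        g = image.grid
        t = np.linspace(0.0, 1.0, self.n_samples)
        x = self.start[0] + t * (self.stop[0] - self.start[0])
        y = self.start[1] + t * (self.stop[1] - self.start[1])
        half = g.fov / 2.0
        if np.any(np.abs(x) > half) or np.any(np.abs(y) > half):
            raise ValueError("line profile leaves the image FOV")
        rows, cols = g.mm_to_index(x, y)
        return map_coordinates(image.hu(), [rows, cols], order=1)


def mssim(img: ReconImage, ref: ReconImage, roi: ROISpec,
          k1: float = 0.01, k2: float = 0.03, sigma: float = 1.5,
          win_size: int = 11, data_range: float | None = None) -> float:
    """Mean structural similarity over one ROI against a reference.

    ``data_range`` defaults to max - min of the *reference* ROI.
    """
    if img.grid != ref.grid:
        raise ValueError("images must share a grid")
    a = roi.crop(img)
    b = roi.crop(ref)
    if min(a.shape) < win_size:
        raise ValueError(f"ROI smaller than the {win_size}x{win_size} window")
    if data_range is None:
        data_range = float(b.max() - b.min())
        if data_range == 0.0:
            data_range = 1.0
    return float(structural_similarity(
        a, b, win_size=win_size, gaussian_weights=True, sigma=sigma,
        use_sample_covariance=False, K1=k1, K2=k2, data_range=data_range))


def rmse(img: ReconImage, ref: ReconImage, mask: np.ndarray | None = None
         ) -> float:
    """Root mean square error in HU over ``mask`` (whole image if None)."""
    if img.grid != ref.grid:
        raise ValueError("images must share a grid")
    d = img.hu() - ref.hu()
    if mask is not None:
        if not np.any(mask):
            raise ValueError("empty RMSE mask")
        d = d[mask]
    return float(np.sqrt(np.mean(d ** 2)))


def profile_stability(images: list[ReconImage], line: LineProfile
                      ) -> tuple[float, np.ndarray]:
    """Pooled HU standard deviation along a line across phases.

    Returns ``(pooled_std, profiles)`` where ``profiles`` has one row
    per phase (for plotting).  The pooled value is the population
    standard deviation of all samples of all phases.
    """
    if len(images) < 2:
        raise ValueError("need at least two phases")
    profiles = np.stack([line.sample(im) for im in images])
    return float(np.std(profiles)), profiles


def paired_compare(values_a, values_b, alternative: str = "less") -> float:
    """One-sided paired t-test p-value comparing ``a`` against ``b``.

    ``alternative='less'`` tests mean(a - b) < 0.  Degenerate cases:
    all differences zero gives p = 0.5 (t = 0); zero-variance nonzero
    differences give p = 0.0 or 1.0 by the sign of the mean.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D samples, n >= 2")
    d = a - b
    if np.std(d) == 0.0:
        m = float(np.mean(d))
        if m == 0.0:
            return 0.5
        favored = (m < 0) if alternative == "less" else (m > 0)
        return 0.0 if favored else 1.0
    res = stats.ttest_rel(a, b, alternative=alternative)
    return float(res.pvalue)
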
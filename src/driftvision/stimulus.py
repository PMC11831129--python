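"""Snellen-E optotype rasterization and optional optical blur.

The stimulus is a Snellen E on the canonical 5x5 bar-unit square: a full
spine of 5 units plus three limbs of length 4 units, all of thickness 1
unit with 1-unit gaps, so the ink area is exactly 17 bar_size^2 and the
overall letter size is 5 * bar_size.  ``bar_size`` (arcmin) is the bar
thickness, equal to the gap width; the orientation names the direction
the limbs point (the opening side).

Rasterization is exact: the letter is a union of four disjoint
axis-aligned rectangles, and each grid cell receives its exact area
coverage fraction, which yields area-weighted anti-aliasing without any
supersampling error.  The four orientations are produced by quarter-turn
rotations of one rendered raster and are therefore bit-exact rotations of
one another.

Array convention: ``intensities[i, j]`` has x (horizontal, arcmin) along
axis 0 and y (vertical) along axis 1, both increasing with index and
centered on the middle cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as _ndi

ORIENTATIONS = ("up", "down", "left", "right")

#: number of quarter-turn (counter-clockwise) rotations from the canonical
#: limbs-point-right letter to each orientation
_ROTATIONS = {"right": 0, "up": 1, "left": 2, "down": 3}


@dataclass
class StimulusRaster:
    """A discretized light-intensity image of one Snellen-E stimulus."""

    intensities: np.ndarray    # (n, n) in [0, 1]
    grid_spacing: float        # arcmin per cell
    orientation: str
    bar_size: float            # arcmin (bar thickness = gap width)

    @property
    def overall_size(self) -> float:
        """Letter extent (arcmin): 5 bar units."""
        return 5.0 * self.bar_size

    @property
    def total_intensity(self) -> float:
        return float(self.intensities.sum())

    def ink_area(self) -> float:
        """Summed intensity times cell area, arcmin^2 (= 17 bar_size^2 unblurred)."""
        return self.total_intensity * self.grid_spacing**2


def _interval_overlap(lo: np.ndarray, hi: np.ndarray, a: float, b: float) -> np.ndarray:
    return np.clip(np.minimum(hi, b) - np.maximum(lo, a), 0.0, None)


def _render_canonical(bar_size: float, grid_spacing: float, n: int) -> np.ndarray:
    """Exact-coverage raster of the limbs-point-right E on an n x n grid."""
    b, s = bar_size, grid_spacing
    half = n // 2
    lo = (np.arange(n) - half - 0.5) * s
    hi = lo + s
    # disjoint rectangles (x0, x1, y0, y1) of the canonical letter
    rects = [(-2.5 * b, -1.5 * b, -2.5 * b, 2.5 * b)]           # spine
    for y0 in (-2.5 * b, -0.5 * b, 1.5 * b):                    # three limbs
        rects.append((-1.5 * b, 2.5 * b, y0, y0 + b))
    img = np.zeros((n, n))
    for x0, x1, y0, y1 in rects:
        wx = _interval_overlap(lo, hi, x0, x1)
        wy = _interval_overlap(lo, hi, y0, y1)
        img += np.outer(wx, wy) / s**2
    return img


def render_E(orientation: str, bar_size: float, grid_spacing: float) -> StimulusRaster:
    """Rasterize a Snellen E with exact area-weighted anti-aliasing.

    Raises
    ------
    ValueError
        If ``bar_size`` is smaller than ``grid_spacing / 4`` (the grid
        cannot meaningfully resolve the bars; use a finer grid).
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    if bar_size <= 0:
        raise ValueError("bar_size must be positive")
    if bar_size < grid_spacing / 4.0:
        raise ValueError(
            f"bar_size {bar_size} arcmin is below grid_spacing/4 "
            f"({grid_spacing / 4.0} arcmin); rasterize on a finer grid"
        )
    n = int(np.ceil(5.0 * bar_size / grid_spacing))
    if n % 2 == 0:
        n += 1  # odd extent so the letter is centered on a cell
    img = _render_canonical(bar_size, grid_spacing, n)
    img = np.rot90(img, _ROTATIONS[orientation])
    return StimulusRaster(intensities=np.ascontiguousarray(img),
                          grid_spacing=grid_spacing,
                          orientation=orientation, bar_size=bar_size)


def apply_optical_blur(raster: StimulusRaster, blur_fwhm: float) -> StimulusRaster:
    """Convolve with an isotropic 2-D Gaussian of the given FWHM (arcmin).

    Emulates optical blurring by the eye's point-spread function (the
    adaptive-optics experiments bypass it; natural viewing does not).  The
    raster is zero-padded so that the total intensity is preserved;
    ``blur_fwhm = 0`` is the identity.
    """
    if blur_fwhm < 0:
        raise ValueError("blur_fwhm must be >= 0")
    if blur_fwhm == 0:
        return StimulusRaster(intensities=raster.intensities.copy(),
                              grid_spacing=raster.grid_spacing,
                              orientation=raster.orientation,
                              bar_size=raster.bar_size)
    sigma_px = blur_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / raster.grid_spacing
    pad = int(np.ceil(4 * sigma_px)) + 1
    img = np.pad(raster.intensities, pad)
    out = _ndi.gaussian_filter(img, sigma=sigma_px, mode="constant")
    # renormalize away residual kernel truncation so total intensity is exact
    out *= raster.intensities.sum() / out.sum()
    return StimulusRaster(intensities=out, grid_spacing=raster.grid_spacing,
                          orientation=raster.orientation, bar_size=raster.bar_size)
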
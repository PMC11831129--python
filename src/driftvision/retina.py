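"""Retinal ganglion cell (RGC) population model.

Each model RGC has a circular Gaussian spatial receptive field (RF) and a
one-lag differencing temporal kernel that makes its response transient:
the firing rate in bin t is

    r(t) = max(0, r0 + contrast_scale * dr * (O(t) - w * O(t-1)))

where ``O(t)`` is the inner product of the cell's unit-mass RF with the
stimulus at its current grid position, ``r0`` (20 Hz) the baseline rate in
darkness, ``dr`` (120 Hz) the gain, and ``w`` in [0, 1] the temporal
kernel weight (``w = 1``: fully transient, a static stimulus drives the
cell back to baseline after one bin; ``w = 0``: unimodal filter, the cell
responds to intensity rather than intensity change).  Spike counts per
50 ms bin are Poisson with mean ``r(t) * dt``.  Cells are conditionally
independent: any correlation between their spike trains comes from the
shared stimulus and trajectory.

RFs are arranged in a jittered square lattice at foveal density (one RGC
per cone); the ``heterogeneous`` variant increases the jitter to open
gaps in the mosaic coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffusion import DiffusionParams, Trajectory, grid_indices
from .stimulus import ORIENTATIONS, StimulusRaster, render_E

#: jitter fraction used when ``heterogeneous=True`` and none is given
HETEROGENEOUS_JITTER = 0.45


@dataclass(frozen=True)
class RGCParams:
    """Shared RGC rate parameters (rates in Hz, dt in seconds)."""

    r0: float = 20.0
    dr: float = 120.0
    w: float = 0.8
    dt: float = 0.05
    contrast_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.r0 < 0 or self.dr < 0:
            raise ValueError("r0 and dr must be >= 0")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must be in [0, 1], got {self.w}")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass
class RGCMosaic:
    """RGC population: centers (arcmin, relative to the grid center) and RF widths."""

    centers: np.ndarray            # (N, 2)
    sigmas: np.ndarray             # (N,)
    params: RGCParams
    jitter_frac: float = 0.0

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.sigmas = np.atleast_1d(np.asarray(self.sigmas, dtype=float))
        if len(self.centers) < 1:
            raise ValueError("mosaic needs at least one cell")
        if np.any(self.sigmas <= 0):
            raise ValueError("all RF sigmas must be positive")
        if len(self.sigmas) != len(self.centers):
            raise ValueError("centers and sigmas must have equal lengths")

    @property
    def n_cells(self) -> int:
        return len(self.centers)


@dataclass
class SpikeTrain:
    """Per-cell, per-bin nonnegative spike counts."""

    counts: np.ndarray             # (n_bins, n_cells) integers
    dt: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def duration(self) -> float:
        return self.n_bins * self.dt

    def mean_rate(self) -> float:
        """Population mean firing rate in Hz."""
        return float(self.counts.mean() / self.dt)


def build_mosaic(n_per_side: int = 11, spacing: float = 0.5, sigma: float = 0.25,
                 jitter_frac: float = 0.1, seed: int | np.random.Generator | None = None,
                 heterogeneous: bool = False, params: RGCParams | None = None) -> RGCMosaic:
    """Build a jittered square lattice of RGC receptive fields.

    Centers sit on an ``n_per_side`` x ``n_per_side`` lattice (spacing in
    arcmin, centered on the origin) with i.i.d. uniform jitter of
    +/- ``jitter_frac * spacing`` per axis; RF widths are
    ``sigma * (1 + U(-jitter_frac, jitter_frac))``.  ``heterogeneous=True``
    raises the jitter to ``HETEROGENEOUS_JITTER`` to create coverage gaps.
    """
    if n_per_side < 1:
        raise ValueError("n_per_side must be >= 1")
    if heterogeneous:
        jitter_frac = max(jitter_frac, HETEROGENEOUS_JITTER)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = (np.arange(n_per_side) - (n_per_side - 1) / 2.0) * spacing
    cx, cy = np.meshgrid(idx, idx, indexing="ij")
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    centers = centers + rng.uniform(-jitter_frac * spacing, jitter_frac * spacing,
                                    centers.shape)
    sigmas = sigma * (1.0 + rng.uniform(-jitter_frac, jitter_frac, len(centers)))
    return RGCMosaic(centers=centers, sigmas=sigmas,
                     params=params or RGCParams(), jitter_frac=jitter_frac)


# ---------------------------------------------------------------------------
# receptive-field / stimulus overlaps
# ---------------------------------------------------------------------------

def rf_maps(mosaic: RGCMosaic, grid_extent: int, grid_spacing: float) -> np.ndarray:
    """Unit-mass RF weight maps on the cyclic grid, shape (N, G, G).

    Distances are minimal-image distances on the torus so that RFs, like
    stimulus positions, respect the cyclic boundary conditions.
    """
    g = (np.arange(grid_extent) - grid_extent // 2) * grid_spacing
    X, Y = np.meshgrid(g, g, indexing="ij")
    L = grid_extent * grid_spacing
    maps = np.empty((mosaic.n_cells, grid_extent, grid_extent))
    for i, ((cx, cy), s) in enumerate(zip(mosaic.centers, mosaic.sigmas)):
        dx = (X - cx + L / 2) % L - L / 2
        dy = (Y - cy + L / 2) % L - L / 2
        m = np.exp(-(dx**2 + dy**2) / (2.0 * s**2))
        maps[i] = m / m.sum()
    return maps


def _embed_raster(raster: StimulusRaster, grid_extent: int) -> np.ndarray:
    n = raster.intensities.shape[0]
    if n > grid_extent:
        raise ValueError(
            f"stimulus support ({n} cells) exceeds the grid ({grid_extent}); "
            "use a larger grid_extent"
        )
    canvas = np.zeros((grid_extent, grid_extent))
    s0 = grid_extent // 2 - n // 2
    canvas[s0:s0 + n, s0:s0 + n] = raster.intensities
    return canvas


def overlap_table(mosaic: RGCMosaic, raster: StimulusRaster,
                  grid_extent: int, maps: np.ndarray | None = None) -> np.ndarray:
    """Per-cell RF/stimulus overlaps O_i(x, y) for one raster, shape (N, G, G).

    ``O[i, x, y]`` is the inner product of cell i's unit-mass RF with the
    raster centered at grid position (x, y); positions wrap cyclically, so
    translating the raster by one grid unit shifts the table by one index.
    Computed with FFT cross-correlation on the torus.
    """
    if maps is None:
        maps = rf_maps(mosaic, grid_extent, raster.grid_spacing)
    canvas = _embed_raster(raster, grid_extent)
    c = grid_extent // 2
    corr = np.real(np.fft.ifft2(np.fft.fft2(maps) * np.conj(np.fft.fft2(canvas))))
    table = np.roll(corr, (c, c), axis=(1, 2))
    return np.clip(table, 0.0, None)


def orientation_overlap_tables(mosaic: RGCMosaic, bar_size: float,
                               grid_extent: int, grid_spacing: float,
                               blur_fwhm: float = 0.0) -> np.ndarray:
    """Overlap tables for all four letter orientations, shape (4, N, G, G).

    Orientation order follows :data:`driftvision.stimulus.ORIENTATIONS`.
    These tables are the single expensive geometric computation shared by
    the encoder and the decoder; compute once per configuration.
    """
    from .stimulus import apply_optical_blur

    maps = rf_maps(mosaic, grid_extent, grid_spacing)
    tables = []
    for orient in ORIENTATIONS:
        raster = render_E(orient, bar_size, grid_spacing)
        if blur_fwhm > 0:
            raster = apply_optical_blur(raster, blur_fwhm)
        tables.append(overlap_table(mosaic, raster, grid_extent, maps=maps))
    return np.stack(tables)


# ---------------------------------------------------------------------------
# rates and spiking
# ---------------------------------------------------------------------------

def firing_rate(params: RGCParams, O_now, O_prev):
    """Rectified linear-nonlinear rate, Hz (vectorized over cells)."""
    drive = params.contrast_scale * params.dr * (np.asarray(O_now) - params.w * np.asarray(O_prev))
    return np.clip(params.r0 + drive, 0.0, None)


def sample_spikes(rate, params: RGCParams,
                  seed: int | np.random.Generator | None = None):
    """Poisson spike counts for one bin; mean = rate [Hz] * dt [s]."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(np.asarray(rate) * params.dt)


def encode(O_lambda: np.ndarray, positions: np.ndarray, params: RGCParams,
           rng: np.random.Generator) -> SpikeTrain:
    """Generate spikes for one trial from a precomputed overlap table.

    ``O_lambda`` is the (N, G, G) overlap table of the true orientation and
    ``positions`` the (n_bins, 2) cyclic grid indices of the stimulus
    center in each bin.  The first bin's previous-frame overlap is 0 (blank
    screen before stimulus onset).
    """
    n_bins = len(positions)
    counts = np.empty((n_bins, O_lambda.shape[0]), dtype=np.int64)
    O_prev = np.zeros(O_lambda.shape[0])
    for t, (px, py) in enumerate(positions):
        O_now = O_lambda[:, px, py]
        counts[t] = rng.poisson(firing_rate(params, O_now, O_prev) * params.dt)
        O_prev = O_now
    return SpikeTrain(counts=counts, dt=params.dt)


def simulate_trial(mosaic: RGCMosaic, raster: StimulusRaster, traj: Trajectory,
                   duration: float, seed: int | np.random.Generator | None = None,
                   grid_extent: int = 31) -> SpikeTrain:
    """Simulate RGC population spiking to a stimulus moving along ``traj``.

    The trajectory must be binned at the model ``dt`` and span at least
    ``duration``; the stimulus position in bin t is the trajectory sample
    at t * dt (cyclically wrapped onto the grid).
    """
    params = mosaic.params
    n_bins = int(round(duration / params.dt))
    steps = np.diff(traj.times)
    if not np.allclose(steps, params.dt, rtol=1e-6):
        raise ValueError("trajectory must be sampled at the model dt")
    if traj.duration + params.dt < duration - 1e-9:
        raise ValueError("trajectory shorter than requested duration")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dparams = DiffusionParams(D=0.0, dt=params.dt,
                              grid_spacing=raster.grid_spacing,
                              grid_extent=grid_extent)
    positions = grid_indices(traj, dparams)[:n_bins]
    O = overlap_table(mosaic, raster, grid_extent)
    return encode(O, positions, params, rng)


# ---------------------------------------------------------------------------
# spike-train serialization (sparse CSV: cell, bin, count)
# ---------------------------------------------------------------------------

def write_spikes(train: SpikeTrain, path) -> None:
    bins, cells = np.nonzero(train.counts)
    pd.DataFrame({
        "cell": cells, "bin": bins, "count": train.counts[bins, cells],
        "n_bins": train.n_bins, "n_cells": train.n_cells, "dt_s": train.dt,
    }).to_csv(path, index=False)


def read_spikes(path) -> SpikeTrain:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"spike file {path} is empty")
    counts = np.zeros((int(df["n_bins"].iloc[0]), int(df["n_cells"].iloc[0])),
                      dtype=np.int64)
    counts[df["bin"], df["cell"]] = df["count"]
    return SpikeTrain(counts=counts, dt=float(df["dt_s"].iloc[0]))
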
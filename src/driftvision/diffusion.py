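"""Fixational-eye-movement (FEM) trajectories as grid diffusion.

Ocular drift is modelled as an isotropic two-dimensional random walk on a
discrete square grid.  In every time bin of width ``dt`` each axis takes an
integer step distributed as the difference of two independent Poisson counts
with equal means (a Skellam step), so the per-axis step variance is ``mu``
grid units squared.  ``mu`` is chosen such that the two-dimensional mean
square displacement grows as ``D * t``::

    MSD_2D(t) = D * t      =>      per-axis variance per bin = D * dt / 2

with the diffusion coefficient ``D`` in arcmin^2/s.  The same construction
supplies the position transition kernel used by the Bayesian decoder, so the
generator and the decoder share one diffusion model.

Generated trajectories are stored in unwrapped (free-diffusion) arcmin
coordinates; the cyclic boundary condition of the grid is applied only when
positions are looked up as grid indices (see :func:`grid_indices`), which
leaves displacement statistics untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as _sps

logger = logging.getLogger(__name__)

#: maximum fraction of probability mass the truncated transition kernel may
#: discard before it is considered too small for the requested D
MAX_TRUNCATION_LOSS = 0.01

#: columns of the trajectory CSV dialect, in file order
TRAJECTORY_COLUMNS = [
    "subject_eye",
    "trial",
    "t_s",
    "x_arcmin",
    "y_arcmin",
    "stim_size_arcmin",
    "stim_orientation",
    "correct",
]

_REQUIRED_COLUMNS = ["subject_eye", "trial", "t_s", "x_arcmin", "y_arcmin"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffusionParams:
    """Parameters of the grid diffusion model of ocular drift.

    Parameters
    ----------
    D
        Diffusion coefficient, arcmin^2/s (slope of the 2-D MSD vs time).
    dt
        Time-bin width in seconds (50 ms by default, the scale of the
        retinal temporal kernel).
    grid_spacing
        Arcmin per grid unit (order of the foveal cone spacing).
    grid_extent
        Number of grid positions per axis; boundary conditions are cyclic.
    kernel_radius
        Maximum per-axis step magnitude retained in the truncated
        transition kernel, in grid units.
    """

    D: float
    dt: float = 0.05
    grid_spacing: float = 0.5
    grid_extent: int = 31
    kernel_radius: int = 4

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"D must be >= 0, got {self.D}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.grid_spacing <= 0:
            raise ValueError(f"grid_spacing must be > 0, got {self.grid_spacing}")
        if self.grid_extent < 3:
            raise ValueError(f"grid_extent must be >= 3, got {self.grid_extent}")
        if self.kernel_radius < 1:
            raise ValueError(f"kernel_radius must be >= 1, got {self.kernel_radius}")

    @property
    def step_mean(self) -> float:
        """Skellam parameter mu: per-axis step variance per bin, grid units^2."""
        return self.D * self.dt / (2.0 * self.grid_spacing**2)


@dataclass
class Trajectory:
    """A time-ordered sequence of 2-D gaze/stimulus positions in arcmin."""

    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        if not (len(self.times) == len(self.xs) == len(self.ys)):
            raise ValueError("times, xs and ys must have equal lengths")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def positions(self) -> np.ndarray:
        """(n, 2) array of x/y positions in arcmin."""
        return np.column_stack([self.xs, self.ys])


@dataclass(frozen=True)
class TransitionKernel:
    """Truncated, renormalized per-bin position transition kernel.

    ``probs[i, j]`` is the probability of a displacement of
    ``(offsets[i], offsets[j])`` grid units in one time bin.
    """

    offsets: np.ndarray        # (2R+1,) per-axis integer displacements
    probs: np.ndarray          # (2R+1, 2R+1), sums to 1
    retained_mass: float       # mass before renormalization

    @property
    def radius(self) -> int:
        return int(self.offsets[-1])

    def axis_variance(self, grid_spacing: float = 1.0) -> float:
        """Per-axis displacement variance (in ``grid_spacing`` units squared)."""
        marg = self.probs.sum(axis=1)
        return float(np.sum(marg * self.offsets**2) * grid_spacing**2)

    def flat_offsets(self) -> np.ndarray:
        """(K, 2) integer offsets matching :meth:`flat_probs`."""
        dx, dy = np.meshgrid(self.offsets, self.offsets, indexing="ij")
        return np.column_stack([dx.ravel(), dy.ravel()])

    def flat_probs(self) -> np.ndarray:
        return self.probs.ravel()


# ---------------------------------------------------------------------------
# transition kernel
# ---------------------------------------------------------------------------

def _axis_pmf(mu: float, radius: int) -> tuple[np.ndarray, np.ndarray]:
    offsets = np.arange(-radius, radius + 1)
    if mu == 0.0:
        pmf = (offsets == 0).astype(float)
    else:
        pmf = _sps.skellam.pmf(offsets, mu / 2.0, mu / 2.0)
    return offsets, pmf


def make_transition_kernel(params: DiffusionParams) -> TransitionKernel:
    """Build the per-bin position transition kernel for the decoder.

    The two-dimensional kernel is the outer product of two identical
    per-axis Skellam distributions truncated at ``kernel_radius`` and
    renormalized.

    Raises
    ------
    ValueError
        If the truncation would discard more than 1% of the probability
        mass, which signals that ``kernel_radius`` is too small for ``D``.
    """
    offsets, pmf = _axis_pmf(params.step_mean, params.kernel_radius)
    probs = np.outer(pmf, pmf)
    mass = float(probs.sum())
    if mass < 1.0 - MAX_TRUNCATION_LOSS:
        raise ValueError(
            f"truncated kernel retains only {mass:.4f} of the probability "
            f"mass; kernel_radius={params.kernel_radius} is too small for "
            f"D={params.D} (increase kernel_radius or grid_spacing)"
        )
    return TransitionKernel(offsets=offsets, probs=probs / mass, retained_mass=mass)


def min_kernel_radius(params: DiffusionParams, max_loss: float = MAX_TRUNCATION_LOSS) -> int:
    """Smallest kernel radius that retains ``1 - max_loss`` of the step mass."""
    mu = params.step_mean
    radius = 1
    while True:
        _, pmf = _axis_pmf(mu, radius)
        if pmf.sum() ** 2 >= 1.0 - max_loss:
            return radius
        radius += 1


def with_min_radius(params: DiffusionParams) -> DiffusionParams:
    """Copy of ``params`` with the kernel radius set adaptively for its D."""
    return replace(params, kernel_radius=min_kernel_radius(params))


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

def sample_steps(params: DiffusionParams, n_bins: int,
                 rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw untruncated Skellam steps, shape (size, n_bins, 2), grid units."""
    half = params.step_mean / 2.0
    shape = (size, n_bins, 2)
    return rng.poisson(half, shape) - rng.poisson(half, shape)


def generate_trajectory(params: DiffusionParams, duration: float,
                        seed: int | np.random.Generator | None = None,
                        meta: dict | None = None) -> Trajectory:
    """Generate one drift trajectory of ``duration`` seconds.

    Positions start at the grid center (0 arcmin by convention) and are
    sampled every ``dt``; each bin's displacement is an independent
    Skellam draw per axis.  Coordinates are stored unwrapped; use
    :func:`grid_indices` to obtain cyclic grid indices.
    """
    if duration < params.dt:
        raise ValueError(f"duration {duration} shorter than one bin ({params.dt} s)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_bins = int(round(duration / params.dt))
    steps = sample_steps(params, n_bins, rng)[0]
    pos = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)]) * params.grid_spacing
    times = np.arange(n_bins + 1) * params.dt
    return Trajectory(times=times, xs=pos[:, 0], ys=pos[:, 1], meta=dict(meta or {}))


def generate_trajectories(params: DiffusionParams, duration: float, n: int,
                          seed: int | np.random.Generator | None = None) -> list[Trajectory]:
    """Generate ``n`` independent trajectories from one RNG stream."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return [generate_trajectory(params, duration, rng, meta={"trial": i}) for i in range(n)]


def grid_indices(traj: Trajectory, params: DiffusionParams) -> np.ndarray:
    """Map arcmin positions to cyclic grid indices, shape (n, 2).

    The grid center index ``grid_extent // 2`` corresponds to 0 arcmin.
    """
    center = params.grid_extent // 2
    idx = np.rint(traj.positions() / params.grid_spacing).astype(int) + center
    return np.mod(idx, params.grid_extent)


def upsample_trajectory(traj: Trajectory, rate: float) -> Trajectory:
    """Linearly interpolate positions onto a finer uniform time base.

    Intended for plumbing (matching the ~960 Hz eye-tracker format); note
    that interpolation attenuates spectral power above the source Nyquist
    frequency, so spectral analyses should use natively fine-sampled
    trajectories instead (see :mod:`driftvision.stats`).
    """
    if len(traj) < 2:
        raise ValueError("need at least two samples to upsample")
    dt_in = float(np.min(np.diff(traj.times)))
    if rate * dt_in < 1.0 - 1e-9:
        raise ValueError(f"rate {rate} Hz would downsample (input step {dt_in} s)")
    if np.any(np.diff(traj.times) <= 0):
        raise ValueError("times must be strictly increasing")
    t0, t1 = traj.times[0], traj.times[-1]
    n = int(np.floor((t1 - t0) * rate + 1e-9))
    times = t0 + np.arange(n + 1) / rate
    times[-1] = min(times[-1], t1)
    if times[-1] < t1 - 1e-12:
        times = np.append(times, t1)
    xs = np.interp(times, traj.times, traj.xs)
    ys = np.interp(times, traj.times, traj.ys)
    return Trajectory(times=times, xs=xs, ys=ys, meta=dict(traj.meta))


# ---------------------------------------------------------------------------
# trajectory file I/O
# ---------------------------------------------------------------------------

_META_FIELDS = {
    "subject_eye": "subject_eye",
    "trial": "trial",
    "stim_size_arcmin": "stim_size_arcmin",
    "stim_orientation": "stim_orientation",
    "correct": "correct",
}


def write_trajectories(trajs: list[Trajectory], path) -> None:
    """Write trajectories to the documented CSV dialect (one row per sample)."""
    frames = []
    for k, traj in enumerate(trajs):
        df = pd.DataFrame({
            "subject_eye": traj.meta.get("subject_eye", "S0"),
            "trial": traj.meta.get("trial", k),
            "t_s": traj.times,
            "x_arcmin": traj.xs,
            "y_arcmin": traj.ys,
            "stim_size_arcmin": traj.meta.get("stim_size_arcmin", np.nan),
            "stim_orientation": traj.meta.get("stim_orientation", ""),
            "correct": traj.meta.get("correct", np.nan),
        })
        frames.append(df)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    out.to_csv(path, index=False)


def read_trajectories(path) -> list[Trajectory]:
    """Read trajectories from the CSV dialect written by :func:`write_trajectories`.

    Trials containing non-finite coordinates are excluded with a warning
    naming the offending file lines; an empty file yields an empty list.
    """
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("trajectory file %s is empty", path)
        return []
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file {path} is missing required columns: {missing}")
    for col in ("t_s", "x_arcmin", "y_arcmin"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-indexing
            raise ValueError(f"non-numeric values in column {col!r} of {path}, lines {lines}")

    trajs: list[Trajectory] = []
    for (eye, trial), grp in df.groupby(["subject_eye", "trial"], sort=False):
        coords = grp[["t_s", "x_arcmin", "y_arcmin"]].to_numpy()
        bad = ~np.isfinite(coords).all(axis=1)
        if bad.any():
            lines = [int(i) + 2 for i in grp.index[bad]]
            logger.warning(
                "trial %s/%s excluded: non-finite coordinates on lines %s",
                eye, trial, lines,
            )
            continue
        meta = {"subject_eye": eye, "trial": trial}
        for col in ("stim_size_arcmin", "stim_orientation", "correct"):
            if col in grp.columns:
                val = grp[col].iloc[0]
                if not (isinstance(val, float) and np.isnan(val)):
                    meta[col] = val
        trajs.append(Trajectory(times=coords[:, 0], xs=coords[:, 1],
                                ys=coords[:, 2], meta=meta))
    return trajs
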
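"""Drift-trajectory statistics and size/path-length comparisons.

Implements the descriptive statistics used to characterise ocular drift —
diffusion-coefficient estimation from mean square displacement (MSD),
position power spectra (drift power falls as 1/f^2 with frequency),
MSD curves, path lengths, displacement autocorrelation — and the
nonparametric comparisons of trajectory amplitude across stimulus sizes.

Diffusion-coefficient convention: ``D`` is the slope of the
two-dimensional MSD versus time, so each axis contributes ``D/2`` and the
per-axis components satisfy ``D_x + D_y = D`` exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _sps

from .diffusion import Trajectory

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# diffusion coefficient estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DEstimate:
    """Diffusion coefficient estimate (arcmin^2/s), 2-D and per-axis."""

    D: float
    D_x: float
    D_y: float
    n_trajectories: int
    lag: float


def _lag_pairs(traj: Trajectory, lag: float) -> tuple[np.ndarray, np.ndarray]:
    """All overlapping per-axis displacements across time pairs ~``lag`` apart."""
    dts = np.diff(traj.times)
    step = float(np.median(dts))
    k = int(round(lag / step))
    if k < 1 or k >= len(traj):
        return np.empty(0), np.empty(0)
    if abs(k * step - lag) > 0.05 * lag:
        return np.empty(0), np.empty(0)
    dx = traj.xs[k:] - traj.xs[:-k]
    dy = traj.ys[k:] - traj.ys[:-k]
    return dx, dy


def estimate_D(trajs: list[Trajectory], lag: float = 0.05) -> DEstimate:
    """Estimate D as the mean square 2-D displacement over ``lag``, divided by ``lag``.

    Uses all overlapping sample pairs separated by ``lag`` in every
    trajectory.  Per-axis components are ``mean(dx^2)/lag`` so that
    ``D_x + D_y = D``; under isotropic diffusion ``D_x ~= D_y ~= D/2``.
    """
    sx, sy, n = 0.0, 0.0, 0
    for traj in trajs:
        dx, dy = _lag_pairs(traj, lag)
        if dx.size == 0:
            raise ValueError(
                f"trajectory {traj.meta.get('trial', '?')} has no sample pairs "
                f"at lag {lag} s"
            )
        sx += float(np.sum(dx**2))
        sy += float(np.sum(dy**2))
        n += dx.size
    return DEstimate(D=(sx + sy) / (n * lag), D_x=sx / (n * lag),
                     D_y=sy / (n * lag), n_trajectories=len(trajs), lag=lag)


# ---------------------------------------------------------------------------
# power spectrum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumResult:
    """Trial-averaged position power spectrum and its log-log slope."""

    frequencies: np.ndarray
    power: np.ndarray
    loglog_slope: float
    fit_band: tuple[float, float]


def power_spectrum(trajs: list[Trajectory], axis: str = "x",
                   fit_band: tuple[float, float] = (2.0, 100.0),
                   window: str | None = None) -> SpectrumResult:
    """Trial-averaged periodogram of the position signal along one axis.

    Each trajectory must be uniformly sampled; periodograms (mean-detrended,
    optionally Hann-windowed) are averaged across trajectories and the
    log-log slope is fitted by least squares inside ``fit_band`` after
    excluding the band's lowest and highest octave.  For pure diffusion the
    slope is -2; note that linearly interpolated (upsampled) trajectories
    only follow the -2 law below the Nyquist frequency of the source
    sampling, so slope estimation should use natively fine-sampled data.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    spectra = []
    freqs = None
    for traj in trajs:
        if len(traj) < 8:
            raise ValueError("need at least 8 samples per trajectory for a spectrum")
        dts = np.diff(traj.times)
        if not np.allclose(dts, dts[0], rtol=1e-3):
            raise ValueError("trajectory is not uniformly sampled")
        fs = 1.0 / float(dts[0])
        sig = traj.xs if axis == "x" else traj.ys
        f, p = _signal.periodogram(sig, fs=fs, detrend="constant",
                                   window=window or "boxcar")
        if freqs is None:
            freqs = f
        elif len(f) != len(freqs) or not np.allclose(f, freqs):
            raise ValueError("trajectories must share one time base")
        spectra.append(p)
    power = np.mean(spectra, axis=0)

    lo, hi = fit_band
    lo_fit, hi_fit = 2.0 * lo, hi / 2.0  # drop lowest and highest octave
    mask = (freqs >= lo_fit) & (freqs <= hi_fit) & (power > 0) & (freqs > 0)
    if mask.sum() < 2:
        raise ValueError(
            f"fewer than 2 spectral points in fit band [{lo_fit}, {hi_fit}] Hz"
        )
    slope = np.polyfit(np.log10(freqs[mask]), np.log10(power[mask]), 1)[0]
    return SpectrumResult(frequencies=freqs[1:], power=power[1:],
                          loglog_slope=float(slope), fit_band=(lo_fit, hi_fit))


# ---------------------------------------------------------------------------
# MSD curve
# ---------------------------------------------------------------------------

def msd_curve(trajs: list[Trajectory], max_lag: float | None = None) -> pd.DataFrame:
    """Mean square end-to-end displacement versus lag, per axis and 2-D.

    Returns a DataFrame with columns ``lag``, ``msd_x``, ``msd_y``,
    ``msd_2d`` and ``n_pairs``; the linear fit of ``msd_2d`` through lags
    is reported in ``df.attrs['slope']`` / ``df.attrs['intercept']`` (the
    slope estimates D).
    """
    step = float(np.median(np.diff(trajs[0].times)))
    n_max = max(len(t) for t in trajs) - 1
    if max_lag is not None:
        n_max = min(n_max, int(round(max_lag / step)))
    rows = [{"lag": 0.0, "msd_x": 0.0, "msd_y": 0.0, "msd_2d": 0.0,
             "n_pairs": sum(len(t) for t in trajs)}]
    for k in range(1, n_max + 1):
        sx = sy = 0.0
        n = 0
        for traj in trajs:
            if k >= len(traj):
                continue
            dx = traj.xs[k:] - traj.xs[:-k]
            dy = traj.ys[k:] - traj.ys[:-k]
            sx += float(np.sum(dx**2))
            sy += float(np.sum(dy**2))
            n += dx.size
        if n == 0:
            break
        rows.append({"lag": k * step, "msd_x": sx / n, "msd_y": sy / n,
                     "msd_2d": (sx + sy) / n, "n_pairs": n})
    df = pd.DataFrame(rows)
    slope, intercept = np.polyfit(df["lag"], df["msd_2d"], 1)
    df.attrs["slope"] = float(slope)
    df.attrs["intercept"] = float(intercept)
    return df


# ---------------------------------------------------------------------------
# path length and autocorrelation
# ---------------------------------------------------------------------------

def path_length(traj: Trajectory, bin_dt: float = 0.05) -> float:
    """Total drift amplitude: summed Euclidean steps on the decoder time base.

    The trajectory is sampled at multiples of ``bin_dt`` (linear
    interpolation if recorded at a finer rate) before the step lengths are
    summed, because 50 ms is the scale at which the retinal model consumes
    motion and finer sampling inflates path length with tracker noise.
    """
    if len(traj) < 2:
        raise ValueError("path length requires at least 2 samples")
    t0, t1 = traj.times[0], traj.times[-1]
    n = int(np.floor((t1 - t0) / bin_dt + 1e-9))
    if n < 1:
        return 0.0
    tt = t0 + np.arange(n + 1) * bin_dt
    xs = np.interp(tt, traj.times, traj.xs)
    ys = np.interp(tt, traj.times, traj.ys)
    return float(np.sum(np.hypot(np.diff(xs), np.diff(ys))))


def end_to_end_length(traj: Trajectory) -> float:
    """Euclidean distance between the first and last position, arcmin."""
    return float(np.hypot(traj.xs[-1] - traj.xs[0], traj.ys[-1] - traj.ys[0]))


def displacement_autocorrelation(trajs: list[Trajectory], max_lag: int = 5) -> pd.DataFrame:
    """Autocorrelation of per-bin displacements at integer-bin lags.

    Correlations are computed per axis per trajectory (lag 0 normalized
    to 1) and averaged across axes and trajectories; for independent-step
    diffusion every lag >= 1 is ~0.
    """
    acc = np.zeros(max_lag + 1)
    n = 0
    for traj in trajs:
        for sig in (np.diff(traj.xs), np.diff(traj.ys)):
            if len(sig) <= max_lag:
                raise ValueError("trajectory too short for requested max_lag")
            sig = sig - sig.mean()
            var = float(np.dot(sig, sig))
            if var == 0:
                continue
            for k in range(max_lag + 1):
                acc[k] += float(np.dot(sig[: len(sig) - k], sig[k:])) / var
            n += 1
    if n == 0:
        # all-static ensemble: autocorrelation undefined except lag 0
        acc[:] = np.nan
        acc[0] = 1.0
        n = 1
    return pd.DataFrame({"lag_bins": np.arange(max_lag + 1),
                         "autocorrelation": acc / n})


# ---------------------------------------------------------------------------
# comparisons across stimulus sizes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KruskalResult:
    """Rank-based k-sample comparison of path lengths across size bins."""

    H: float
    p_value: float
    medians: pd.Series
    n_per_bin: pd.Series
    per_subject_eye: pd.DataFrame | None = None


def compare_path_lengths_across_sizes(
    trial_table: pd.DataFrame,
    value_col: str = "path_length_arcmin",
    size_col: str = "stim_size_arcmin",
    per_subject_eye: bool = False,
) -> KruskalResult:
    """Kruskal-Wallis test of ``value_col`` across stimulus-size bins.

    Size bins with fewer than 2 trials are dropped with a warning.  With
    ``per_subject_eye=True`` the same test is additionally run within each
    subject eye (requires a ``subject_eye`` column) and returned as a
    DataFrame with one row per eye.
    """
    groups, medians, counts = [], {}, {}
    for size, grp in trial_table.groupby(size_col):
        vals = grp[value_col].dropna().to_numpy()
        if len(vals) < 2:
            warnings.warn(f"size bin {size} dropped: fewer than 2 trials")
            continue
        groups.append(vals)
        medians[size] = float(np.median(vals))
        counts[size] = len(vals)
    if len(groups) < 2:
        raise ValueError("need at least 2 size bins with >= 2 trials")
    H, p = _sps.kruskal(*groups)

    per_eye = None
    if per_subject_eye:
        rows = []
        for eye, sub in trial_table.groupby("subject_eye"):
            try:
                res = compare_path_lengths_across_sizes(sub, value_col, size_col)
            except ValueError:
                continue
            rows.append({"subject_eye": eye, "H": res.H, "p_value": res.p_value})
        per_eye = pd.DataFrame(rows)
    return KruskalResult(H=float(H), p_value=float(p),
                         medians=pd.Series(medians).sort_index(),
                         n_per_bin=pd.Series(counts).sort_index(),
                         per_subject_eye=per_eye)


@dataclass(frozen=True)
class ConsecutiveTrialResult:
    """Paired comparison of trajectory amplitude before/after size increases."""

    n_pairs: int
    mean_difference: float | None   # after - before, arcmin
    p_value: float | None           # Wilcoxon signed-rank
    differences: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0


def compare_consecutive_trials(
    trial_table: pd.DataFrame,
    value_col: str = "end_to_end_arcmin",
    size_col: str = "stim_size_arcmin",
    order_col: str = "trial",
) -> ConsecutiveTrialResult:
    """Compare trajectory amplitude before vs after stimulus-size increases.

    Within each subject eye, trials are ordered by ``order_col``; every
    consecutive pair in which the stimulus size increased contributes the
    amplitude difference (after - before).  The sign and a Wilcoxon
    signed-rank p-value are reported; with no qualifying pairs an
    explicitly empty result is returned.  A positive mean difference rules
    out the confound of drift amplitude simply shrinking over the session.
    """
    diffs = []
    for _, sub in trial_table.groupby("subject_eye"):
        sub = sub.sort_values(order_col)
        sizes = sub[size_col].to_numpy()
        vals = sub[value_col].to_numpy()
        inc = np.flatnonzero(np.diff(sizes) > 0)
        diffs.extend(vals[inc + 1] - vals[inc])
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size == 0:
        return ConsecutiveTrialResult(n_pairs=0, mean_difference=None, p_value=None)
    if np.allclose(diffs, 0):
        p = 1.0
    else:
        p = float(_sps.wilcoxon(diffs).pvalue)
    return ConsecutiveTrialResult(n_pairs=int(diffs.size),
                                  mean_difference=float(diffs.mean()),
                                  p_value=p, differences=diffs)
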
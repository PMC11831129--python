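"""End-to-end simulated psychophysics: 4AFC sweeps over drift amplitude and size.

Each trial draws a random Snellen-E orientation, generates a drift
trajectory at diffusion coefficient D, simulates RGC population spiking,
and decodes the orientation with the matched-model Bayesian observer;
the fraction of correct discrimination after 500 ms is aggregated with
binomial standard errors.  On top of single conditions this module
provides the accuracy sweeps over (D, stimulus size), path-length x size
heatmaps, the subject-weighted accuracy average, and the comparison of
empirical stimulus-dependent D against fixed-D observers, emulated with
synthetic subject-eye profiles.

Scales are desk scale by default: a 25-position grid, an 11 x 11 mosaic
and 20 trials per condition (see docs/methods.md for the rationale); all
randomness derives from one master seed through counter-based
SeedSequence keys, so any subset of conditions can be re-run bit
identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from .decoder import DecoderConfig, run_decoder
from .diffusion import (DiffusionParams, Trajectory, generate_trajectory,
                        grid_indices, make_transition_kernel, min_kernel_radius)
from .retina import (RGCMosaic, RGCParams, build_mosaic, encode,
                     orientation_overlap_tables)
from .stats import end_to_end_length, path_length
from .stimulus import ORIENTATIONS

logger = logging.getLogger(__name__)

MODEL_VARIANTS = ("default", "w0", "heterogeneous", "blurred")

#: default sweep grid of diffusion coefficients, arcmin^2/s.  The interior
#: values span the emulated across-subject range (~3x spread, max ~40);
#: 200 = 5x the maximum is the larger-than-empirical control and 0 the
#: no-drift control.
DEFAULT_D_GRID = (0.0, 15.0, 25.0, 40.0, 200.0)

#: emulated across-subject range of D, arcmin^2/s
EMPIRICAL_D_RANGE = (15.0, 40.0)

#: default bar sizes, arcmin (overall letter sizes 1.5 to 4 arcmin)
DEFAULT_BAR_SIZES = (0.3, 0.4, 0.5, 0.6, 0.8)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Desk-scale simulation configuration shared by all experiment runners."""

    # grid (shared by diffusion, stimulus and decoder)
    grid_extent: int = 25
    grid_spacing: float = 0.5          # arcmin per grid unit
    dt: float = 0.05                   # s
    duration: float = 0.5              # s of stimulus presentation
    # mosaic
    n_per_side: int = 11
    mosaic_spacing: float = 0.5        # arcmin
    sigma: float = 0.25                # RF width, arcmin
    jitter_frac: float = 0.1
    # RGC rates
    r0: float = 20.0                   # Hz
    dr: float = 120.0                  # Hz
    w: float = 0.8
    contrast_scale: float = 1.0
    # optics (used by the 'blurred' variant)
    blur_fwhm: float = 1.0             # arcmin
    rate_floor: float = 1e-6

    def rgc_params(self, variant: str = "default") -> RGCParams:
        w = 0.0 if variant == "w0" else self.w
        return RGCParams(r0=self.r0, dr=self.dr, w=w, dt=self.dt,
                         contrast_scale=self.contrast_scale)

    def diffusion_params(self, D: float) -> DiffusionParams:
        base = DiffusionParams(D=D, dt=self.dt, grid_spacing=self.grid_spacing,
                               grid_extent=self.grid_extent, kernel_radius=1)
        return replace(base, kernel_radius=min_kernel_radius(base))

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.dt))


def load_config(path) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML document with per-module blocks.

    Recognized blocks and keys (all optional): ``diffusion:`` dt,
    grid_spacing, grid_extent; ``stimulus:`` blur_fwhm_arcmin; ``retina:``
    r0_hz, dr_hz, w, n_per_side, spacing_arcmin, sigma_arcmin, jitter_frac,
    contrast_scale; ``decoder:`` rate_floor; ``experiment:`` duration_s.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    kw = {}
    diff = doc.get("diffusion", {})
    for src, dst in (("dt", "dt"), ("grid_spacing", "grid_spacing"),
                     ("grid_extent", "grid_extent")):
        if src in diff:
            kw[dst] = diff[src]
    stim = doc.get("stimulus", {})
    if "blur_fwhm_arcmin" in stim:
        kw["blur_fwhm"] = stim["blur_fwhm_arcmin"]
    ret = doc.get("retina", {})
    for src, dst in (("r0_hz", "r0"), ("dr_hz", "dr"), ("w", "w"),
                     ("n_per_side", "n_per_side"), ("spacing_arcmin", "mosaic_spacing"),
                     ("sigma_arcmin", "sigma"), ("jitter_frac", "jitter_frac"),
                     ("contrast_scale", "contrast_scale")):
        if src in ret:
            kw[dst] = ret[src]
    dec = doc.get("decoder", {})
    if "rate_floor" in dec:
        kw["rate_floor"] = dec["rate_floor"]
    exp = doc.get("experiment", {})
    if "duration_s" in exp:
        kw["duration"] = exp["duration_s"]
    return SimConfig(**kw)


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    """Counter-based child RNG: reproducible regardless of execution order."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=tuple(key)))


# ---------------------------------------------------------------------------
# single condition
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    """One simulated 4AFC trial."""

    seed_key: tuple
    D: float
    bar_size: float
    true_orientation: str
    decisions: list[str]            # decoded orientation at each decision time
    decision_times: np.ndarray
    correct: bool                   # at the final decision time (500 ms)
    path_length_arcmin: float
    end_to_end_arcmin: float


@dataclass
class ConditionResult:
    """Aggregate of one (D, bar_size) condition."""

    D: float
    bar_size: float
    model_variant: str
    n_trials: int
    fraction_correct: float
    se: float                       # binomial standard error (nan if n == 1)
    accuracy_curve: pd.DataFrame    # columns: time_s, fraction_correct, se
    records: list[TrialRecord]
    degenerate_se: bool = False


class ConditionRunner:
    """Precomputed encoder/decoder for one (D, bar_size, variant) condition.

    Building the overlap tables and the decoder's likelihood tensors is the
    expensive part; one runner amortizes it across trials.
    """

    def __init__(self, D: float, bar_size: float, sim: SimConfig,
                 model_variant: str = "default", mosaic_seed: int | np.random.Generator = 0):
        if model_variant not in MODEL_VARIANTS:
            raise ValueError(f"model_variant must be one of {MODEL_VARIANTS}")
        self.D, self.bar_size, self.sim = D, bar_size, sim
        self.model_variant = model_variant
        self.dparams = sim.diffusion_params(D)
        self.rgc = sim.rgc_params(model_variant)
        self.mosaic: RGCMosaic = build_mosaic(
            n_per_side=sim.n_per_side, spacing=sim.mosaic_spacing, sigma=sim.sigma,
            jitter_frac=sim.jitter_frac, seed=mosaic_seed,
            heterogeneous=(model_variant == "heterogeneous"), params=self.rgc)
        blur = sim.blur_fwhm if model_variant == "blurred" else 0.0
        self.overlap_tables = orientation_overlap_tables(
            self.mosaic, bar_size, sim.grid_extent, sim.grid_spacing, blur_fwhm=blur)
        self.decoder_config = DecoderConfig(
            transition=make_transition_kernel(self.dparams),
            overlap_tables=self.overlap_tables, rgc=self.rgc,
            rate_floor=sim.rate_floor)

    def run_trial(self, rng: np.random.Generator, seed_key: tuple = ()) -> TrialRecord:
        lam_idx = int(rng.integers(len(ORIENTATIONS)))
        traj: Trajectory = generate_trajectory(self.dparams, self.sim.duration, rng)
        positions = grid_indices(traj, self.dparams)[: self.sim.n_bins]
        spikes = encode(self.overlap_tables[lam_idx], positions, self.rgc, rng)
        result = run_decoder(spikes, self.decoder_config, seed=rng)
        return TrialRecord(
            seed_key=seed_key, D=self.D, bar_size=self.bar_size,
            true_orientation=ORIENTATIONS[lam_idx],
            decisions=result.decisions, decision_times=result.times,
            correct=(result.decisions[-1] == ORIENTATIONS[lam_idx]),
            path_length_arcmin=path_length(traj, bin_dt=self.sim.dt),
            end_to_end_arcmin=end_to_end_length(traj),
        )


def _binomial_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n)) if n > 1 else float("nan")


def _aggregate(records: list[TrialRecord], D: float, bar_size: float,
               variant: str) -> ConditionResult:
    n = len(records)
    frac = sum(r.correct for r in records) / n
    times = records[0].decision_times
    curve = []
    for j, t in enumerate(times):
        pc = sum(r.decisions[j] == r.true_orientation for r in records) / n
        curve.append({"time_s": float(t), "fraction_correct": pc,
                      "se": _binomial_se(pc, n)})
    if n == 1:
        logger.warning("condition D=%s bar=%s has a single trial; SE is degenerate",
                       D, bar_size)
    return ConditionResult(D=D, bar_size=bar_size, model_variant=variant,
                           n_trials=n, fraction_correct=frac,
                           se=_binomial_se(frac, n),
                           accuracy_curve=pd.DataFrame(curve), records=records,
                           degenerate_se=(n == 1))


def run_condition(D: float, bar_size: float, n_trials: int, seed: int,
                  model_variant: str = "default",
                  sim: SimConfig | None = None,
                  cell_key: tuple = ()) -> ConditionResult:
    """Simulate ``n_trials`` 4AFC trials of one (D, bar_size) condition.

    The mosaic is drawn once per condition; trial randomness is derived
    from ``seed`` with counter-based keys so individual trials are
    reproducible in isolation.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    sim = sim or SimConfig()
    runner = ConditionRunner(D, bar_size, sim, model_variant,
                             mosaic_seed=_rng(seed, *cell_key, 0))
    records = []
    for t in range(n_trials):
        key = cell_key + (1, t)
        records.append(runner.run_trial(_rng(seed, *key), seed_key=(seed,) + key))
    return _aggregate(records, D, bar_size, model_variant)


# ---------------------------------------------------------------------------
# sweeps (accuracy vs D vs size)
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Grid of conditions over (D, bar_size)."""

    cells: dict                     # (D, bar_size) -> ConditionResult
    seed: int
    model_variant: str

    @property
    def table(self) -> pd.DataFrame:
        rows = [{"D": c.D, "bar_size": c.bar_size,
                 "overall_size": 5.0 * c.bar_size,
                 "fraction_correct": c.fraction_correct, "se": c.se,
                 "n_trials": c.n_trials}
                for c in self.cells.values()]
        return pd.DataFrame(rows).sort_values(["D", "bar_size"]).reset_index(drop=True)

    def all_records(self) -> list[TrialRecord]:
        return [r for c in self.cells.values() for r in c.records]

    def min_fraction_correct(self) -> float:
        return min(c.fraction_correct for c in self.cells.values())


def sweep_accuracy(D_list=DEFAULT_D_GRID, size_list=DEFAULT_BAR_SIZES,
                   n_trials: int = 20, seed: int = 0,
                   model_variant: str = "default",
                   sim: SimConfig | None = None) -> SweepResult:
    """Full accuracy sweep over the (D, bar_size) grid.

    Deterministic given ``seed``; per-time accuracy curves are retained in
    each cell.
    """
    if not len(D_list) or not len(size_list):
        raise ValueError("D_list and size_list must be nonempty")
    cells = {}
    for i, D in enumerate(D_list):
        for j, bar in enumerate(size_list):
            cells[(D, bar)] = run_condition(D, bar, n_trials, seed, model_variant,
                                            sim=sim, cell_key=(i, j))
            logger.info("sweep cell D=%g bar=%g: %.2f +/- %.2f", D, bar,
                        cells[(D, bar)].fraction_correct, cells[(D, bar)].se)
    return SweepResult(cells=cells, seed=seed, model_variant=model_variant)


def records_table(records: list[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records to a trial-table DataFrame."""
    return pd.DataFrame([{
        "D": r.D, "bar_size": r.bar_size, "overall_size": 5.0 * r.bar_size,
        "true_orientation": r.true_orientation,
        "decoded_orientation": r.decisions[-1], "correct": r.correct,
        "path_length_arcmin": r.path_length_arcmin,
        "end_to_end_arcmin": r.end_to_end_arcmin,
    } for r in records])


def path_length_heatmap(records: list[TrialRecord] | pd.DataFrame,
                        size_bins=None, length_bins: int | np.ndarray = 4) -> pd.DataFrame:
    """Fraction correct binned by realized path length and stimulus size.

    Path-length bin edges default to quantiles of the realized path
    lengths; sizes keep their discrete grid unless explicit bin edges are
    given.  Returns one row per (size bin, length bin) with the fraction
    correct and the trial count (empty bins are absent).
    """
    df = records if isinstance(records, pd.DataFrame) else records_table(records)
    if df.empty:
        raise ValueError("no trial records to bin")
    if isinstance(length_bins, int):
        qs = np.linspace(0, 1, length_bins + 1)
        edges = np.unique(np.quantile(df["path_length_arcmin"], qs))
        if len(edges) < 2:
            edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    else:
        edges = np.asarray(length_bins, dtype=float)
    df = df.copy()
    df["length_bin"] = pd.cut(df["path_length_arcmin"], edges, include_lowest=True)
    size_key = df["bar_size"] if size_bins is None else pd.cut(df["bar_size"], size_bins)
    out = (df.groupby([size_key, "length_bin"], observed=True)
             .agg(fraction_correct=("correct", "mean"), n=("correct", "size"))
             .reset_index())
    return out


def weighted_accuracy_over_D(sweep: SweepResult, D_weights: dict) -> pd.DataFrame:
    """Convex combination of per-D accuracies with subject-representation weights.

    ``D_weights`` maps each D of the sweep to its weight (how heavily that
    drift amplitude is represented across subjects); weights must be
    nonnegative and sum to 1.  Returns the weighted fraction correct per
    stimulus size.
    """
    w = pd.Series(D_weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    tab = sweep.table
    out = []
    for bar, grp in tab.groupby("bar_size"):
        grp = grp.set_index("D")
        missing = [d for d in w.index if d not in grp.index]
        if missing:
            raise ValueError(f"sweep lacks conditions for D={missing}")
        acc = float((grp.loc[w.index, "fraction_correct"] * w.to_numpy()).sum())
        out.append({"bar_size": bar, "overall_size": 5.0 * bar,
                    "weighted_fraction_correct": acc})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# synthetic subject-eye profiles and the stimulus-dependent-D comparison
# ---------------------------------------------------------------------------

@dataclass
class SubjectProfile:
    """Synthetic per-subject-eye drift profile (emulation, not recorded data)."""

    subject_eye: str
    bar_sizes: np.ndarray           # arcmin
    D_values: np.ndarray            # fitted D per size, arcmin^2/s
    n_trials: np.ndarray            # trial count per size

    @property
    def mean_D(self) -> float:
        return float(np.mean(self.D_values))


def generate_subject_profiles(bar_sizes=DEFAULT_BAR_SIZES, n_eyes: int = 33,
                              seed: int = 0, d_range=EMPIRICAL_D_RANGE,
                              frac_modulated: float = 0.36,
                              modulation: float = 0.5,
                              n_trials_per_size: int = 10) -> list[SubjectProfile]:
    """Emulate the across-subject drift statistics of the acuity experiment.

    Each of ``n_eyes`` subject eyes (17 participants, two eyes each except
    one) gets a base D drawn uniformly from ``d_range`` (about a 3x spread
    from the smallest to the largest).  In ``frac_modulated`` of the eyes
    the per-size D increases with stimulus size by up to
    +/- ``modulation``/2 of the base value; the rest keep a flat profile.
    """
    rng = _rng(seed, 97)
    bar_sizes = np.asarray(bar_sizes, dtype=float)
    span = bar_sizes.max() - bar_sizes.min()
    rel = (bar_sizes - bar_sizes.mean()) / (span if span > 0 else 1.0)
    n_mod = int(round(frac_modulated * n_eyes))
    modulated = np.zeros(n_eyes, dtype=bool)
    modulated[rng.choice(n_eyes, size=n_mod, replace=False)] = True
    profiles = []
    for e in range(n_eyes):
        base = rng.uniform(*d_range)
        Ds = base * (1.0 + modulation * rel) if modulated[e] else np.full_like(rel, base)
        profiles.append(SubjectProfile(
            subject_eye=f"S{e // 2:02d}-{'LR'[e % 2]}", bar_sizes=bar_sizes,
            D_values=np.asarray(Ds, dtype=float),
            n_trials=np.full(len(bar_sizes), n_trials_per_size, dtype=int)))
    return profiles


def default_fixed_D_list(profiles: list[SubjectProfile]) -> list[float]:
    """Min, quartiles, median, max of the profile D distribution, plus 5x max."""
    all_D = np.concatenate([p.D_values for p in profiles])
    qs = np.quantile(all_D, [0.0, 0.25, 0.5, 0.75, 1.0])
    return [float(q) for q in qs] + [float(5.0 * qs[-1])]


def stimulus_dependent_D_experiment(profiles: list[SubjectProfile],
                                    n_trials_per_cell: int | None = None,
                                    seed: int = 0,
                                    fixed_D_list: list[float] | None = None,
                                    sim: SimConfig | None = None,
                                    model_variant: str = "default") -> pd.DataFrame:
    """Accuracy vs size for stimulus-dependent vs fixed drift amplitudes.

    Conditions: per-(eye, size) empirical D, per-eye averaged D, per-eye
    shuffled-across-sizes D, and each fixed D in ``fixed_D_list`` (default:
    min, quartiles, median and max of the profile distribution plus five
    times the maximum).  For each condition and size, every eye contributes
    ``n_trials_per_cell`` trials (default: the profile's per-size count),
    mirroring the trials-per-eye bookkeeping of the empirical comparison.

    Returns a DataFrame with one row per (condition, bar_size):
    fraction correct, binomial SE and trial count.
    """
    if not profiles:
        raise ValueError("profiles must be nonempty")
    sim = sim or SimConfig()
    bar_sizes = profiles[0].bar_sizes
    if fixed_D_list is None:
        fixed_D_list = default_fixed_D_list(profiles)

    rng_shuffle = _rng(seed, 11)
    conditions: dict[str, dict] = {}
    for name in ("empirical", "averaged", "shuffled"):
        conditions[name] = {}
    for e, prof in enumerate(profiles):
        perm = rng_shuffle.permutation(len(prof.bar_sizes))
        for j, bar in enumerate(prof.bar_sizes):
            conditions["empirical"][(e, bar)] = float(prof.D_values[j])
            conditions["averaged"][(e, bar)] = prof.mean_D
            conditions["shuffled"][(e, bar)] = float(prof.D_values[perm[j]])
    for D in fixed_D_list:
        conditions[f"fixed:{D:g}"] = {
            (e, bar): float(D)
            for e in range(len(profiles)) for bar in bar_sizes}

    runners: dict[tuple, ConditionRunner] = {}
    rows = []
    for ci, (cond, cell_D) in enumerate(conditions.items()):
        for j, bar in enumerate(bar_sizes):
            correct = total = 0
            for e, prof in enumerate(profiles):
                D = cell_D[(e, float(bar))]
                n = n_trials_per_cell if n_trials_per_cell is not None else int(prof.n_trials[j])
                rk = (round(D, 6), float(bar))
                if rk not in runners:
                    runners[rk] = ConditionRunner(D, float(bar), sim, model_variant,
                                                  mosaic_seed=_rng(seed, 5, 0))
                runner = runners[rk]
                for t in range(n):
                    rec = runner.run_trial(_rng(seed, ci, j, e, t))
                    correct += rec.correct
                    total += 1
            frac = correct / total
            rows.append({"condition": cond, "bar_size": float(bar),
                         "overall_size": 5.0 * float(bar),
                         "fraction_correct": frac, "se": _binomial_se(frac, total),
                         "n_trials": total})
    return pd.DataFrame(rows)
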
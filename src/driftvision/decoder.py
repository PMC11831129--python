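"""Recursive Bayesian ideal-observer decoding of orientation from spikes.

The decoder maintains a joint posterior over the stimulus orientation
(4 alternatives) and its latent grid position, updated each 50 ms bin in a
forward-algorithm recursion:

    P(lam, x, y | spikes_{<=t}) = 1/Z_t * sum_{x', y'}
        P(sigma_t | lam, x, y, x', y') * P(x, y | x', y')
        * P(lam, x', y' | spikes_{<=t-1})

The likelihood is a product of per-cell Poisson terms whose rates come
from the retinal model; it depends on the previous position (x', y')
because of the temporal differencing kernel.  The transition matrix is
the truncated diffusion kernel, so the observer knows the drift
statistics (D) but not the realized trajectory, and receives no efference
copy.  Starting from a flat prior, the classifier reports the orientation
with the largest position-marginal posterior — with a flat orientation
prior this argmax coincides with the maximum-likelihood rule.

All recursions run in the log domain with max-shift normalization.  The
per-cell log-rates for every (orientation, position, previous-position)
hypothesis are precomputed once per configuration and cached on the
:class:`DecoderConfig`, which reduces each bin's update to one
matrix-vector product against the spike-count vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .diffusion import TransitionKernel
from .retina import RGCParams, SpikeTrain, firing_rate
from .stimulus import ORIENTATIONS

#: rate floor in Hz, keeps log-likelihoods finite when a rectified rate is 0
RATE_FLOOR = 1e-6


@dataclass
class PosteriorState:
    """Joint posterior over orientation and grid position (log domain)."""

    log_probs: np.ndarray          # (4, G, G), normalized: logsumexp == 0
    log_norm: float = 0.0          # accumulated log of the per-step constants Z_t

    @property
    def probs(self) -> np.ndarray:
        return np.exp(self.log_probs)

    @property
    def grid_extent(self) -> int:
        return self.log_probs.shape[-1]

    def orientation_marginal(self) -> np.ndarray:
        """Position-marginal posterior over the four orientations."""
        return np.exp(logsumexp(self.log_probs.reshape(len(ORIENTATIONS), -1), axis=1))


@dataclass
class DecoderConfig:
    """Everything the ideal observer knows: likelihood model and drift statistics.

    ``transition`` must be built with the same D convention as the
    trajectory generator for matched-model decoding.  ``overlap_tables``
    has shape (4, N, G, G) in the orientation order of
    :data:`driftvision.stimulus.ORIENTATIONS`.
    """

    transition: TransitionKernel
    overlap_tables: np.ndarray
    rgc: RGCParams
    rate_floor: float = RATE_FLOOR
    first_bin_blank: bool = True   # first bin's previous frame is a blank screen

    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def grid_extent(self) -> int:
        return self.overlap_tables.shape[-1]

    @property
    def n_cells(self) -> int:
        return self.overlap_tables.shape[1]

    # -- precomputed likelihood tensors ------------------------------------
    def _tensors(self):
        """Cache per-hypothesis log-rates and rate sums.

        LR has shape (4 * K * G * G, N) float32 (log of rate*dt per cell),
        B (4, K, G, G) float64 (sum over cells of rate*dt); LR1/B1 are the
        blank-previous-frame analogues used in the first bin.
        """
        if "LR" in self._cache:
            return self._cache
        O = self.overlap_tables
        p = self.rgc
        G = self.grid_extent
        offs = self.transition.offsets
        shifts = [(int(dx), int(dy)) for dx in offs for dy in offs]
        K = len(shifts)

        rates1 = np.maximum(firing_rate(p, O, 0.0), self.rate_floor)
        self._cache["LR1"] = np.log(rates1 * p.dt).astype(np.float32)   # (4,N,G,G)
        self._cache["B1"] = (rates1 * p.dt).sum(axis=1)                 # (4,G,G)

        LR = np.empty((len(ORIENTATIONS), K, G, G, O.shape[1]), dtype=np.float32)
        B = np.empty((len(ORIENTATIONS), K, G, G))
        for k, (dx, dy) in enumerate(shifts):
            O_prev = np.roll(O, (dx, dy), axis=(2, 3))
            r = np.maximum(firing_rate(p, O, O_prev), self.rate_floor)
            LR[:, k] = np.moveaxis(np.log(r * p.dt), 1, -1)
            B[:, k] = (r * p.dt).sum(axis=1)
        self._cache["LR"] = np.ascontiguousarray(LR.reshape(-1, O.shape[1]))
        self._cache["B"] = B
        self._cache["shifts"] = shifts
        self._cache["logT"] = np.log(self.transition.flat_probs() + 1e-300)
        return self._cache


def init_posterior(grid_extent: int, n_orientations: int = 4) -> PosteriorState:
    """Flat prior over all (orientation, x, y) hypotheses."""
    n = n_orientations * grid_extent * grid_extent
    lp = np.full((n_orientations, grid_extent, grid_extent), -np.log(n))
    return PosteriorState(log_probs=lp, log_norm=0.0)


def pair_log_likelihood(spikes_t: np.ndarray, O_tables: np.ndarray,
                        params: RGCParams, lam: int,
                        pos: tuple[int, int], prev_pos: tuple[int, int] | None,
                        rate_floor: float = RATE_FLOOR) -> float:
    """Log-probability of one bin's population spike vector for one hypothesis.

    Sums the Poisson log-pmf over cells, with rates from the retinal model
    evaluated at overlaps ``O_i(lam, pos)`` and ``O_i(lam, prev_pos)``
    (``prev_pos=None`` means a blank previous frame).  Rates are floored at
    ``rate_floor`` so that a zero rectified rate with a nonzero count gives
    a very negative but finite value.
    """
    spikes_t = np.asarray(spikes_t)
    O_now = O_tables[lam, :, pos[0], pos[1]]
    O_prev = 0.0 if prev_pos is None else O_tables[lam, :, prev_pos[0], prev_pos[1]]
    mean = np.maximum(firing_rate(params, O_now, O_prev), rate_floor) * params.dt
    return float(np.sum(spikes_t * np.log(mean) - mean - gammaln(spikes_t + 1)))


def update_posterior(state: PosteriorState, spikes_t: np.ndarray,
                     config: DecoderConfig, first_bin: bool = False) -> PosteriorState:
    """One recursive Bayes update (diffuse prior, multiply likelihood, normalize).

    With ``first_bin=True`` (and ``config.first_bin_blank``) the likelihood
    conditions on a blank previous frame and is therefore independent of
    the previous position.  Raises if the unnormalized posterior mass
    underflows to zero, which signals a misconfigured rate floor.
    """
    c = config._tensors()
    s = np.asarray(spikes_t, dtype=np.float64)
    G = config.grid_extent
    shifts, logT = c["shifts"], c["logT"]
    K = len(shifts)

    # diffuse the prior through the (truncated, renormalized) transition kernel
    acc = np.empty((K,) + state.log_probs.shape)
    for k, (dx, dy) in enumerate(shifts):
        acc[k] = logT[k] + np.roll(state.log_probs, (dx, dy), axis=(1, 2))

    if first_bin and config.first_bin_blank:
        ll = np.tensordot(c["LR1"], s, axes=([1], [0])) - c["B1"]   # (4,G,G)
        log_post = ll + logsumexp(acc, axis=0)
    else:
        S = (c["LR"] @ s.astype(np.float32)).astype(np.float64)
        S = S.reshape(len(ORIENTATIONS), K, G, G) - c["B"]          # (4,K,G,G)
        log_post = logsumexp(acc + np.moveaxis(S, 1, 0), axis=0)

    # normalization constant of this step (restore the count-dependent term
    # dropped from the cached tensors so log_norm is a true log-probability)
    const = -float(np.sum(gammaln(s + 1)))
    log_z = float(logsumexp(log_post)) + const
    if not np.isfinite(log_z):
        raise FloatingPointError(
            "posterior mass vanished; rate_floor is misconfigured for these spikes"
        )
    return PosteriorState(log_probs=log_post - logsumexp(log_post),
                          log_norm=state.log_norm + log_z)


def classify(state: PosteriorState,
             rng: np.random.Generator | None = None,
             tie_tol: float = 1e-12) -> str:
    """Orientation with the largest position-marginal posterior.

    Ties (e.g. under a zero-gain retina, where the posterior stays flat)
    are broken uniformly at random with the provided RNG.
    """
    marg = logsumexp(state.log_probs.reshape(len(ORIENTATIONS), -1), axis=1)
    cand = np.flatnonzero(marg >= marg.max() - tie_tol)
    if len(cand) == 1:
        return ORIENTATIONS[cand[0]]
    rng = rng if rng is not None else np.random.default_rng()
    return ORIENTATIONS[rng.choice(cand)]


@dataclass
class DecodeResult:
    """Per-decision-time classifications and orientation marginals."""

    times: np.ndarray              # decision times, s
    decisions: list[str]           # classifier outcome at each decision time
    marginals: np.ndarray          # (n_times, 4) orientation marginals
    log_evidence: float            # accumulated log normalization constant

    def decision_at(self, t: float) -> str:
        idx = int(np.argmin(np.abs(self.times - t)))
        return self.decisions[idx]


def run_decoder(spike_train: SpikeTrain, config: DecoderConfig,
                seed: int | np.random.Generator | None = None,
                decision_times: np.ndarray | None = None) -> DecodeResult:
    """Decode a full trial, reporting the classification at each decision time.

    By default a decision is recorded after every bin (the 50 ms
    simulation step); ``decision_times`` may select a subset.  The result
    is deterministic given the spike train and the seed (which only feeds
    tie-breaking).
    """
    if abs(spike_train.dt - config.rgc.dt) > 1e-9:
        raise ValueError(
            f"spike train dt={spike_train.dt} does not match decoder dt={config.rgc.dt}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    all_times = (np.arange(spike_train.n_bins) + 1) * spike_train.dt
    if decision_times is None:
        wanted = set(range(spike_train.n_bins))
    else:
        wanted = {int(round(t / spike_train.dt)) - 1 for t in decision_times}

    state = init_posterior(config.grid_extent)
    times, decisions, marginals = [], [], []
    for t in range(spike_train.n_bins):
        state = update_posterior(state, spike_train.counts[t], config,
                                 first_bin=(t == 0))
        if t in wanted:
            times.append(all_times[t])
            decisions.append(classify(state, rng))
            marginals.append(state.orientation_marginal())
    return DecodeResult(times=np.array(times), decisions=decisions,
                        marginals=np.array(marginals),
                        log_evidence=state.log_norm)
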
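"""Exact stochastic simulation (Gillespie direct method) of relay networks.

The simulator is the classic direct method: at each step the total propensity
a0 is accumulated over all reactions (zeroth order: c; first order: c*x;
second order, distinct species: c*x1*x2), the waiting time is drawn as an
Exponential(a0), and the firing reaction is chosen proportionally to its
propensity.  States are recorded on a fixed time grid so that temporal means
are unweighted averages.  The inner loop is a numba kernel; a fixed seed
gives bit-identical trajectories.

:func:`staircase_protocol` implements the equilibrium-sampling protocol used
for noise analysis: the signal-molecule count is stepped through a
non-decreasing ladder (0..200), at each level a burn-in is discarded and the
relay is sampled on a regular grid, with the molecular state carried over
between levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .model import ReactionNetwork
from .metrics import LevelStats, snr

__all__ = ["Trajectory", "ssa_run", "staircase_protocol", "subseeds"]


@njit(cache=True)
def _ssa_kernel(x, react_i, react_j, stoich, rates, record_times, out, seed):  # pragma: no cover
    np.random.seed(seed)
    t = 0.0
    rec = 0
    n_rec = record_times.shape[0]
    n_rx = rates.shape[0]
    a = np.empty(n_rx)
    while rec < n_rec:
        a0 = 0.0
        for r in range(n_rx):
            i = react_i[r]
            j = react_j[r]
            if i < 0:
                ar = rates[r]
            elif j < 0:
                ar = rates[r] * x[i]
            else:
                ar = rates[r] * x[i] * x[j]
            a[r] = ar
            a0 += ar
        if a0 <= 0.0:
            # no reaction can fire: the state is frozen for the rest of the grid
            while rec < n_rec:
                out[rec, :] = x
                rec += 1
            break
        tau = -np.log(np.random.random()) / a0
        t_next = t + tau
        while rec < n_rec and record_times[rec] <= t_next:
            out[rec, :] = x
            rec += 1
        t = t_next
        u = np.random.random() * a0
        chosen = n_rx - 1
        acc = 0.0
        for r in range(n_rx):
            acc += a[r]
            if u < acc:
                chosen = r
                break
        x += stoich[chosen]


def _compile_arrays(network: ReactionNetwork):
    names = network.species_names
    index = {s: k for k, s in enumerate(names)}
    n_rx = len(network.reactions)
    react_i = np.full(n_rx, -1, dtype=np.int64)
    react_j = np.full(n_rx, -1, dtype=np.int64)
    stoich = np.zeros((n_rx, len(names)), dtype=np.int64)
    rates = np.empty(n_rx)
    for r, rx in enumerate(network.reactions):
        flat: list[str] = []
        for name, count in rx.reactants:
            flat.extend([name] * count)
        if len(flat) > 2:
            raise ValueError(f"reaction order > 2 not supported: {rx.format()}")
        if len(flat) == 2 and flat[0] == flat[1]:
            raise ValueError(f"identical-reactant bimolecular reaction not supported: {rx.format()}")
        if len(flat) >= 1:
            react_i[r] = index[flat[0]]
        if len(flat) == 2:
            react_j[r] = index[flat[1]]
        for name, count in rx.reactants:
            stoich[r, index[name]] -= count
        for name, count in rx.products:
            stoich[r, index[name]] += count
        rates[r] = rx.rate
    return react_i, react_j, stoich, rates


@dataclass
class Trajectory:
    """SSA sample path recorded on a fixed time grid."""

    times: np.ndarray
    counts: np.ndarray
    species: list[str]
    seed: int

    def species_counts(self, name: str) -> np.ndarray:
        return self.counts[:, self.species.index(name)]

    def phospho_counts(self, n_layers: int) -> np.ndarray:
        """Columns L1p..LNp as an (n_times, n_layers) array."""
        cols = [self.species.index(f"L{i}p") for i in range(1, n_layers + 1)]
        return self.counts[:, cols]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.species)
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


def subseeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-stage sub-seeds (< 2**31) derived from a master seed."""
    ss = np.random.SeedSequence(int(seed))
    return (ss.generate_state(n, dtype=np.uint64) % np.uint64(2**31)).astype(np.int64)


def ssa_run(
    network: ReactionNetwork,
    t_end: float,
    record_interval: float,
    seed: int,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """One exact SSA trajectory, recorded every ``record_interval`` seconds.

    The recorded state at grid time t is the state just before the first
    reaction firing after t.  If every propensity vanishes before ``t_end``
    the frozen state fills the remaining grid.  Identical (network, seed, x0)
    give identical trajectories.
    """
    if t_end <= 0 or record_interval <= 0:
        raise ValueError("t_end and record_interval must be positive")
    react_i, react_j, stoich, rates = _compile_arrays(network)
    x = network.initial_counts() if x0 is None else np.asarray(x0, dtype=np.int64).copy()
    if x.shape != (len(network.species),):
        raise ValueError("x0 shape does not match the species list")
    n_rec = int(np.floor(t_end / record_interval)) + 1
    times = np.arange(n_rec) * record_interval
    out = np.empty((n_rec, x.size), dtype=np.int64)
    _ssa_kernel(x, react_i, react_j, stoich, rates, times, out, int(seed) % 2**31)
    return Trajectory(times=times, counts=out, species=network.species_names, seed=int(seed))


def staircase_protocol(
    network: ReactionNetwork,
    input_levels: Sequence[int],
    burn_in: float = 50.0,
    sample_time: float = 200.0,
    record_interval: float = 0.1,
    seed: int = 0,
    return_samples: bool = False,
):
    """Progressive staircase of signal levels with per-level equilibrium sampling.

    At each level the signal-species count is set (the relay state carries
    over from the previous level), ``burn_in`` seconds are discarded, and the
    state is then sampled every ``record_interval`` for ``sample_time``
    seconds.  Per-level, per-layer temporal statistics (mean, std, SNR of
    phosphorylated counts) are returned as :class:`~phosphorelay.metrics.LevelStats`.

    Per-level RNG seeds are derived deterministically from ``seed``.
    """
    levels = [int(v) for v in input_levels]
    if not levels:
        raise ValueError("input_levels must be non-empty")
    if any(v < 0 for v in levels):
        raise ValueError("input levels must be non-negative")
    if any(b < a for a, b in zip(levels, levels[1:])):
        raise ValueError("input levels must be non-decreasing (progressive increase)")
    if burn_in <= 0 or sample_time <= 0 or record_interval <= 0:
        raise ValueError("burn_in, sample_time and record_interval must be positive")

    react_i, react_j, stoich, rates = _compile_arrays(network)
    sig = network.index(network.signal_species)
    x = network.initial_counts()
    n_samp = int(round(sample_time / record_interval))
    times = burn_in + np.arange(n_samp) * record_interval
    layer_cols = [network.index(f"L{i}p") for i in range(1, network.n_layers + 1)]
    seeds = subseeds(seed, len(levels))

    stats: list[LevelStats] = []
    samples: list[np.ndarray] = []
    out = np.empty((n_samp, x.size), dtype=np.int64)
    for level, sub in zip(levels, seeds):
        x[sig] = level
        _ssa_kernel(x, react_i, react_j, stoich, rates, times, out, int(sub))
        phos = out[:, layer_cols].astype(float)
        stats.append(snr(phos, input_level=level))
        if return_samples:
            samples.append(out.copy())
    if return_samples:
        return stats, samples
    return stats
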
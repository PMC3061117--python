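"""Synthetic input regimes driving the relay.

Three kinds of input are used throughout the analyses:

* constant inputs — a fixed k1 (deterministic) or fixed signal count
  (stochastic); these are plain arguments elsewhere;
* step programs — piecewise-constant schedules of input changes, runnable
  through both the deterministic (time-varying k1) and the stochastic
  (signal-count resets) drivers; stochastic counts are 100x the
  deterministic values, matching the count scale of the discrete model;
* the noisy two-step cascade — a first signal species S1 induces release of
  a second, degradable species S2 (S1 -> S1 + S2, S2 -> 0) which drives L1;
  the stationary S2 count is Poisson with mean S1 * release/degradation, so
  stepping S1 through 0..200 produces Poisson-distributed input noise with
  matching mean (the extrinsic-noise configuration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import RelaySpec, RelayState, ReactionNetwork, _rhs_vector, compile_reactions
from .ssa import Trajectory, _compile_arrays, _ssa_kernel, subseeds

__all__ = [
    "InputProgram",
    "step_program",
    "noisy_input_cascade",
    "run_timecourse",
    "run_timecourse_ssa",
]

#: Stochastic signal counts are this factor times the deterministic k1 values.
COUNT_FACTOR = 100.0


@dataclass(frozen=True)
class InputProgram:
    """Piecewise-constant input schedule.

    ``times[j]`` is when ``values[j]`` takes effect; the first time must be 0
    and times are strictly increasing.  Values are deterministic inputs k1;
    the stochastic driver uses ``round(100 * value)`` signal molecules.
    """

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) == 0:
            raise ValueError("input program must have at least one step")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if self.times[0] != 0:
            raise ValueError("program must start at time 0")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("step times must be strictly increasing")
        if any(v < 0 for v in self.values):
            raise ValueError("input values must be non-negative")

    def value_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return self.values[max(idx, 0)]

    def signal_counts(self) -> tuple[int, ...]:
        """Stochastic-driver signal counts: 100x the deterministic values."""
        return tuple(int(round(COUNT_FACTOR * v)) for v in self.values)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time": self.times, "value": self.values}).to_csv(
            path, index=False, float_format="%.12g"
        )

    @classmethod
    def from_csv(cls, path) -> "InputProgram":
        df = pd.read_csv(path)
        return cls(tuple(df["time"]), tuple(df["value"]))


def step_program(schedule: Sequence[Sequence[float]]) -> InputProgram:
    """Build an InputProgram from (start_time, value) pairs."""
    schedule = list(schedule)
    if not schedule:
        raise ValueError("schedule must be non-empty")
    times, values = zip(*((float(t), float(v)) for t, v in schedule))
    return InputProgram(times, values)


def noisy_input_cascade(
    spec: RelaySpec,
    mean_level: int = 0,
    release_rate: float = 1.0,
    degradation_rate: float = 1.0,
    count_scale: int = 100,
) -> ReactionNetwork:
    """Relay network driven by the Poisson-noisy two-step input cascade.

    S1 (count ``mean_level``) catalyses release of S2 at ``release_rate`` per
    S1 molecule; S2 degrades at ``degradation_rate`` and drives L1
    activation.  With the default equal rates the stationary S2 count is
    Poisson with mean equal to the S1 count, so S1 plays the role of the
    (noise-free) staircase signal while S2 delivers it noisily.
    """
    if release_rate <= 0 or degradation_rate <= 0:
        raise ValueError("cascade release and degradation rates must be positive")
    return compile_reactions(
        spec,
        count_scale=count_scale,
        signal_mode="noisy-cascade",
        signal_count=mean_level,
        release_rate=release_rate,
        degradation_rate=degradation_rate,
    )


def run_timecourse(
    spec: RelaySpec,
    program: InputProgram,
    t_end: float,
    record_interval: float = 0.1,
    state0: RelayState | None = None,
):
    """Deterministic time course under a piecewise-constant input program.

    Integrates the mass-action ODEs segment by segment (k1 constant within a
    segment) and samples on a regular grid.  Returns ``(times, phospho)``
    with one row per grid time and one column per layer.
    """
    if t_end <= 0 or record_interval <= 0:
        raise ValueError("t_end and record_interval must be positive")
    y = (state0 or RelayState.zeros(spec)).to_vector(spec)
    grid = np.arange(0.0, t_end + 0.5 * record_interval, record_interval)
    out = np.empty((grid.size, y.size))
    bounds = [t for t in program.times if 0 < t < t_end] + [t_end]
    t0 = 0.0
    done = 0
    for t1 in bounds:
        k1 = program.value_at(t0)
        sol = solve_ivp(
            lambda t, yy: _rhs_vector(spec, yy, k1),
            (t0, t1),
            y,
            dense_output=True,
            method="LSODA",
            rtol=1e-9,
            atol=1e-11,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed on [{t0}, {t1}]: {sol.message}")
        seg = grid[(grid >= t0 - 1e-12) & (grid < t1 - 1e-12)]
        if seg.size:
            out[done : done + seg.size] = sol.sol(seg).T
            done += seg.size
        y = sol.y[:, -1]
        t0 = t1
    if done < grid.size:  # grid points at t_end itself
        out[done:] = y
        done = grid.size
    n = spec.n_layers
    return grid, out[:, :n]


def run_timecourse_ssa(
    network: ReactionNetwork,
    program: InputProgram,
    t_end: float,
    record_interval: float = 0.1,
    seed: int = 0,
) -> Trajectory:
    """Stochastic time course under a step program (signal-count resets).

    At each program step the signal-species count is reset to 100x the
    deterministic value; the molecular state carries over across steps.
    """
    if t_end <= 0 or record_interval <= 0:
        raise ValueError("t_end and record_interval must be positive")
    react_i, react_j, stoich, rates = _compile_arrays(network)
    sig = network.index(network.signal_species)
    x = network.initial_counts()
    counts = program.signal_counts()
    bounds = [t for t in program.times if 0 < t < t_end] + [t_end]
    seeds = subseeds(seed, len(bounds))
    all_times: list[np.ndarray] = []
    all_counts: list[np.ndarray] = []
    t0 = 0.0
    for (t1, sub) in zip(bounds, seeds):
        idx = int(np.searchsorted(program.times, t0, side="right")) - 1
        x[sig] = counts[max(idx, 0)]
        seg = np.arange(0.0, t1 - t0 + 1e-12, record_interval)
        out = np.empty((seg.size, x.size), dtype=np.int64)
        _ssa_kernel(x, react_i, react_j, stoich, rates, seg, out, int(sub))
        all_times.append(seg + t0)
        all_counts.append(out)
        t0 = t1
    return Trajectory(
        times=np.concatenate(all_times),
        counts=np.vstack(all_counts),
        species=network.species_names,
        seed=int(seed),
    )
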
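"""Steady states and input-response curves.

Two independent routes to the steady state are provided:

* :func:`solve_steady` / :func:`sweep_input` — numerical: long-time adaptive
  integration of the mass-action ODEs polished by Newton root-finding, with
  continuation along the input axis for whole curves;
* :func:`analytic_curve` — the closed-form parametric solution available when
  cross-talk and the bifunctional enzyme are off.  At steady state a single
  phosphate flux J runs through every reaction of the chain:

      J = k1 * L1 = k2 * L1p * L2 = ... = kN * L(N-1)p * LN = k_hyd * LNp,

  so LNp = J / k_hyd, then backwards L(i)p = J / (k_{i+1} * (L(i+1)_tot -
  L(i+1)p)), and finally k1 = J / (L1_tot - L1p).  The curve is parameterized
  by J on [0, J_max), J_max being the supremum keeping every layer below its
  total.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import RelaySpec, RelayState, _rhs_vector

__all__ = [
    "ResponseCurve",
    "SteadyStateError",
    "solve_steady",
    "sweep_input",
    "analytic_curve",
    "analytic_state",
    "max_flux",
]


class SteadyStateError(RuntimeError):
    """Raised when a steady state cannot be found or does not exist."""


@dataclass
class ResponseCurve:
    """Input grid x per-layer steady-state phosphorylated levels.

    ``response[j, i]`` is the steady phosphorylated concentration of layer
    i+1 at input ``inputs[j]``.
    """

    inputs: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.response = np.atleast_2d(np.asarray(self.response, dtype=float))
        if self.response.shape[0] != self.inputs.shape[0]:
            raise ValueError("inputs and response row counts differ")
        if self.inputs.size > 1 and np.any(np.diff(self.inputs) <= 0):
            raise ValueError("input grid must be strictly increasing")

    @property
    def n_layers(self) -> int:
        return self.response.shape[1]

    def layer(self, layer: int) -> np.ndarray:
        """Response column of a 1-based layer index."""
        if not 1 <= layer <= self.n_layers:
            raise ValueError(f"layer must be in 1..{self.n_layers}, got {layer}")
        return self.response[:, layer - 1]

    def to_frame(self) -> pd.DataFrame:
        cols = {"input": self.inputs}
        for i in range(self.n_layers):
            cols[f"L{i + 1}p"] = self.response[:, i]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "ResponseCurve":
        df = pd.read_csv(path)
        layers = [c for c in df.columns if c != "input"]
        return cls(df["input"].to_numpy(), df[layers].to_numpy())


def _in_bounds(spec: RelaySpec, y: np.ndarray, slack: float = 1e-7) -> bool:
    n = spec.n_layers
    totals = np.asarray(spec.totals)
    p = y[:n]
    c = y[n] if spec.bifunctional else 0.0
    if np.any(p < -slack) or c < -slack:
        return False
    if np.any(p > totals + slack):
        return False
    if p[0] + c > totals[0] + slack or p[-1] + c > totals[-1] + slack:
        return False
    return True


def _clip(spec: RelaySpec, y: np.ndarray) -> np.ndarray:
    n = spec.n_layers
    totals = np.asarray(spec.totals)
    out = y.copy()
    out[:n] = np.clip(out[:n], 0.0, totals)
    if spec.bifunctional:
        out[n] = max(out[n], 0.0)
    return out


def _polish(spec: RelaySpec, y0: np.ndarray, k1: float, tol: float):
    """Newton polish of the algebraic steady-state system; None on failure."""
    sol = root(lambda y: _rhs_vector(spec, y, k1), y0, method="hybr", tol=1e-13)
    y = sol.x
    resid = np.max(np.abs(_rhs_vector(spec, y, k1)))
    if resid < tol and _in_bounds(spec, y):
        return _clip(spec, y)
    return None


def solve_steady(
    spec: RelaySpec,
    k1: float,
    initial_guess: RelayState | None = None,
    tol: float = 1e-9,
    t_max: float = 1e4,
) -> RelayState:
    """Steady state of the relay at fixed input ``k1``.

    Adaptive long-time integration from ``initial_guess`` (default: the fully
    unphosphorylated state) followed by a Newton polish of the algebraic
    system; the returned state satisfies ``max |dy/dt| < tol``.

    Raises
    ------
    SteadyStateError
        If no steady state exists (e.g. zero phosphate outflux with positive
        input) or convergence fails within the integration budget; the error
        message carries the input level and the residual reached.
    """
    if k1 < 0:
        raise ValueError("input k1 must be non-negative")
    outflux = spec.hydrolysis_rate + spec.deact_rates[-1] + (spec.k_on if spec.bifunctional else 0)
    if k1 > 0 and outflux == 0:
        raise SteadyStateError(
            f"no steady state at k1={k1}: the last layer has no dephosphorylation "
            "route (hydrolysis, self-dephosphorylation and bifunctional rates all zero), "
            "so phosphate accumulates without bound"
        )
    if initial_guess is None:
        initial_guess = RelayState.zeros(spec)
    y = initial_guess.to_vector(spec)

    t_stage = 100.0
    t_total = 0.0
    resid = np.inf
    while t_total < t_max:
        sol = solve_ivp(
            lambda t, y: _rhs_vector(spec, y, k1),
            (0.0, t_stage),
            y,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise SteadyStateError(f"integration failed at k1={k1}: {sol.message}")
        y = sol.y[:, -1]
        t_total += t_stage
        t_stage *= 10.0
        polished = _polish(spec, y, k1, tol)
        if polished is not None:
            return RelayState.from_vector(spec, polished)
        resid = np.max(np.abs(_rhs_vector(spec, y, k1)))
        if resid < tol:
            return RelayState.from_vector(spec, _clip(spec, y))
    raise SteadyStateError(
        f"no convergence at k1={k1} after t={t_total:g}: residual max|dy/dt|={resid:.3e} "
        f"(tol={tol:g})"
    )


def sweep_input(
    spec: RelaySpec,
    k1_grid: Sequence[float],
    tol: float = 1e-9,
) -> ResponseCurve:
    """Input-response curve by continuation along a strictly increasing grid.

    Each solve is seeded with the previous steady state (a Newton step from
    the neighbouring solution, falling back to full integration), which for
    this monostable system is equivalent to solving each input level
    independently from the unphosphorylated state.
    """
    k1_grid = np.asarray(k1_grid, dtype=float)
    if k1_grid.ndim != 1 or k1_grid.size == 0:
        raise ValueError("k1_grid must be a non-empty 1-D array")
    if k1_grid.size > 1 and np.any(np.diff(k1_grid) <= 0):
        raise ValueError("k1_grid must be strictly increasing")
    if k1_grid[0] < 0:
        raise ValueError("inputs must be non-negative")

    rows = np.empty((k1_grid.size, spec.n_layers))
    seed = RelayState.zeros(spec)
    for j, k1 in enumerate(k1_grid):
        y = None
        if j > 0:
            y = _polish(spec, seed.to_vector(spec), k1, tol)  # continuation fast path
        if y is not None:
            state = RelayState.from_vector(spec, y)
        else:
            try:
                state = solve_steady(spec, k1, initial_guess=seed, tol=tol)
            except SteadyStateError as err:
                raise SteadyStateError(f"sweep failed at k1={k1}: {err}") from err
        rows[j] = state.phospho
        seed = state
    return ResponseCurve(k1_grid, rows)


def _phospho_from_flux(spec: RelaySpec, flux: float) -> np.ndarray | None:
    """Backwards parametric solution at phosphate flux J; None if infeasible."""
    n = spec.n_layers
    totals = spec.totals
    p = np.zeros(n)
    if spec.hydrolysis_rate <= 0:
        return p if flux == 0 else None
    p[-1] = flux / spec.hydrolysis_rate
    if p[-1] >= totals[-1] and flux > 0:
        return None
    for i in range(n - 2, -1, -1):
        denom = spec.transfer_rates[i] * (totals[i + 1] - p[i + 1])
        if denom <= 0:
            return None
        p[i] = flux / denom
        if p[i] >= totals[i] and flux > 0:
            return None
    return p


def _check_analytic_ok(spec: RelaySpec) -> None:
    if spec.bifunctional:
        raise ValueError("analytic solution requires the bifunctional enzyme off")
    if any(r != 0 for r in spec.act_rates) or any(r != 0 for r in spec.deact_rates):
        raise ValueError("analytic solution requires all cross-talk rates zero")
    if spec.hydrolysis_rate <= 0:
        raise SteadyStateError(
            "no steady state: last-layer hydrolysis rate is zero, phosphate "
            "accumulates without bound for any positive input"
        )


def max_flux(spec: RelaySpec, rel_tol: float = 1e-12) -> float:
    """Supremum J_max of the steady-state phosphate flux.

    Found by bisection on feasibility of the parametric solution: beyond
    J_max some layer's phosphorylated level would exceed its total.
    """
    _check_analytic_ok(spec)
    hi = spec.hydrolysis_rate * spec.totals[-1]
    lo = 0.0
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if _phospho_from_flux(spec, mid) is not None:
            lo = mid
        else:
            hi = mid
    return lo


def analytic_state(spec: RelaySpec, k1: float, rel_tol: float = 1e-14) -> RelayState:
    """Closed-form steady state at input ``k1`` (cross-talk-free relays).

    Inverts the strictly increasing map J -> k1(J) = J / (L1_tot - L1p(J))
    by bisection, then evaluates the parametric solution exactly.
    """
    _check_analytic_ok(spec)
    if k1 < 0:
        raise ValueError("input k1 must be non-negative")
    if k1 == 0:
        return RelayState.zeros(spec)
    jmax = max_flux(spec)

    def k1_of(flux: float) -> float:
        p = _phospho_from_flux(spec, flux)
        if p is None:
            return np.inf
        denom = spec.totals[0] - p[0]
        return flux / denom if denom > 0 else np.inf

    lo, hi = 0.0, jmax
    while hi - lo > rel_tol * jmax:
        mid = 0.5 * (lo + hi)
        if k1_of(mid) <= k1:
            lo = mid
        else:
            hi = mid
    return RelayState(_phospho_from_flux(spec, lo), 0.0)


def analytic_curve(
    spec: RelaySpec,
    flux_grid: Sequence[float] | None = None,
    n_points: int = 512,
    sat_frac: float = 1.0 - 1e-9,
) -> ResponseCurve:
    """Input-response curve from the closed-form parametric solution.

    If ``flux_grid`` is not given, a default grid of ``n_points`` flux values
    on [0, sat_frac * J_max] is used, placed log-densely near J_max to
    resolve the sharp threshold region.  Explicit flux values at or beyond
    J_max are rejected.
    """
    _check_analytic_ok(spec)
    jmax = max_flux(spec)
    if flux_grid is None:
        # half linear over the bulk, half geometrically crowding the saturation point
        lin = np.linspace(0.0, 0.9 * jmax, n_points - n_points // 2, endpoint=False)
        crowd = jmax * (1.0 - np.geomspace(0.1, 1.0 - sat_frac, n_points // 2))
        flux_grid = np.unique(np.concatenate([lin, crowd]))
    flux_grid = np.asarray(flux_grid, dtype=float)
    if np.any(flux_grid < 0):
        raise ValueError("flux values must be non-negative")

    rows = np.empty((flux_grid.size, spec.n_layers))
    k1s = np.empty(flux_grid.size)
    for j, J in enumerate(flux_grid):
        p = _phospho_from_flux(spec, J)
        if p is None:
            raise SteadyStateError(
                f"flux J={J:g} is at or beyond saturation (J_max={jmax:.12g}): some "
                "layer would exceed its total protein concentration"
            )
        denom = spec.totals[0] - p[0]
        if denom <= 0:
            raise SteadyStateError(
                f"flux J={J:g} saturates layer 1 (J_max={jmax:.12g}); no finite input "
                "achieves this flux"
            )
        rows[j] = p
        k1s[j] = J / denom
    order = np.argsort(k1s)
    return ResponseCurve(k1s[order], rows[order])
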
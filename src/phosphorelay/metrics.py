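"""Quantitative summaries of response curves and stochastic trajectories.

Curve metrics
    * response coefficient — input needed for 90% of a layer's maximal
      response divided by input needed for 10%; 81 for a Michaelis
      hyperbola, approaching 1 (maximal ultrasensitivity) for a step.
    * sensitivity — average slope of a layer's response per unit input over
      a stated input window.

Noise metrics
    * per-level temporal mean, standard deviation and signal-to-noise ratio
      (mean/std) of phosphorylated counts, with the Poisson baseline
      SNR = sqrt(mean);
    * the noise-scaling exponent, the log-log slope of std against mean
      across input levels (1/2 for Poisson-like intrinsic noise).

Robustness
    * acr_deviation — maximal relative change of the final-layer steady
      state under fold perturbations of the layer totals; near zero in the
      absolute-concentration-robustness regime of the bifunctional relay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import RelaySpec
from .steady import ResponseCurve, solve_steady

__all__ = [
    "CurveRangeError",
    "CurveMetrics",
    "LevelStats",
    "response_coefficient",
    "sensitivity",
    "curve_metrics",
    "snr",
    "poisson_snr",
    "batched_statistic_se",
    "noise_scaling_exponent",
    "acr_deviation",
]


class CurveRangeError(ValueError):
    """The curve does not span the range needed for the requested metric."""


def _crossing_input(inputs: np.ndarray, r: np.ndarray, threshold: float) -> float:
    """Input at the first upward crossing of ``threshold``, by linear interpolation."""
    idx = np.flatnonzero(r >= threshold)
    if idx.size == 0:
        raise CurveRangeError(
            f"response never reaches {threshold:g} on the grid (max {r.max():g}); "
            "extend the input range"
        )
    j = idx[0]
    if j == 0:
        return float(inputs[0])
    x0, x1 = inputs[j - 1], inputs[j]
    y0, y1 = r[j - 1], r[j]
    return float(x0 + (threshold - y0) * (x1 - x0) / (y1 - y0))


def response_coefficient(curve: ResponseCurve, layer: int) -> float:
    """Ratio I90/I10 of inputs reaching 90% and 10% of the layer's maximum.

    The maximum is the curve's own maximum on the evaluated grid (final-layer
    curves generally saturate below the layer total).  Crossing inputs are
    found by monotone linear interpolation.  The ratio is >= 1 for monotone
    non-decreasing curves and equals 81 for a Michaelis hyperbola sampled to
    saturation.
    """
    r = curve.layer(layer)
    m = float(r.max())
    if m <= 0:
        raise CurveRangeError(f"layer {layer} response is identically zero")
    i10 = _crossing_input(curve.inputs, r, 0.1 * m)
    i90 = _crossing_input(curve.inputs, r, 0.9 * m)
    if i10 <= 0:
        raise CurveRangeError(
            f"layer {layer} response is already above 10% of maximum at zero input"
        )
    return i90 / i10


def sensitivity(curve: ResponseCurve, layer: int, window: Sequence[float] = (0.0, 2.0)) -> float:
    """Average response change per unit input over ``window``.

    Computed as (r(b) - r(a)) / (b - a) with endpoint responses interpolated
    on the grid; this equals the per-bin slope summed over the window and
    normalized by the number of bins, so it is independent of grid density.
    Additive over adjacent windows when weighted by window width.
    """
    a, b = float(window[0]), float(window[1])
    if not a < b:
        raise ValueError("window must be an increasing pair")
    if a < curve.inputs[0] - 1e-12 or b > curve.inputs[-1] + 1e-12:
        raise ValueError(
            f"window [{a:g}, {b:g}] outside curve grid "
            f"[{curve.inputs[0]:g}, {curve.inputs[-1]:g}]"
        )
    r = curve.layer(layer)
    ra, rb = np.interp([a, b], curve.inputs, r)
    return float((rb - ra) / (b - a))


@dataclass
class CurveMetrics:
    """Per-layer response coefficients plus final-layer window sensitivity.

    Layers whose curve does not span the 10%/90% range hold NaN.
    """

    response_coefficient: np.ndarray
    sensitivity: float
    window: tuple[float, float]

    def most_ultrasensitive_layer(self) -> int:
        """1-based layer with the smallest (finite) response coefficient."""
        rc = self.response_coefficient
        if np.all(np.isnan(rc)):
            raise CurveRangeError("no layer has a defined response coefficient")
        return int(np.nanargmin(rc)) + 1


def curve_metrics(curve: ResponseCurve, window: Sequence[float] = (0.0, 2.0)) -> CurveMetrics:
    """Response coefficient of every layer and final-layer sensitivity."""
    rc = np.full(curve.n_layers, np.nan)
    for layer in range(1, curve.n_layers + 1):
        try:
            rc[layer - 1] = response_coefficient(curve, layer)
        except CurveRangeError:
            pass
    sens = sensitivity(curve, curve.n_layers, window)
    return CurveMetrics(rc, sens, (float(window[0]), float(window[1])))


@dataclass
class LevelStats:
    """Temporal statistics of phosphorylated counts at one input level.

    ``mean``, ``std`` and ``snr`` are per-layer arrays; ``snr`` is NaN where
    the standard deviation is zero (undefined, not infinite), with the
    ``snr_defined`` mask marking usable entries.  ``std`` uses the population
    (1/n) convention.
    """

    input_level: int
    mean: np.ndarray
    std: np.ndarray
    snr: np.ndarray
    snr_defined: np.ndarray
    n_samples: int


def snr(samples: np.ndarray, input_level: int = 0) -> LevelStats:
    """Per-layer mean, standard deviation and SNR of post-burn-in samples.

    ``samples`` has one row per time sample and one column per layer (a 1-D
    array is treated as a single layer).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    if samples.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    mean = samples.mean(axis=0)
    std = samples.std(axis=0)  # population convention
    defined = std > 0
    ratio = np.full(mean.shape, np.nan)
    ratio[defined] = mean[defined] / std[defined]
    return LevelStats(
        input_level=int(input_level),
        mean=mean,
        std=std,
        snr=ratio,
        snr_defined=defined,
        n_samples=samples.shape[0],
    )


def batched_statistic_se(samples: np.ndarray, statistic, n_batches: int = 20):
    """Batch-means estimate of a temporal statistic and its standard error.

    SSA samples on a fine time grid are autocorrelated, so the naive
    std/sqrt(n) standard error is far too small.  The samples are split into
    ``n_batches`` contiguous batches (each longer than the relaxation time of
    the relay, ~1/k_hyd); the statistic is computed per batch and its
    standard error taken as the spread of batch values over sqrt(n_batches).

    Returns ``(value_on_full_sample, standard_error)``.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] < 2 * n_batches:
        raise ValueError("too few samples for the requested number of batches")
    usable = (samples.shape[0] // n_batches) * n_batches
    batches = samples[:usable].reshape(n_batches, -1, *samples.shape[1:])
    vals = np.array([statistic(b) for b in batches], dtype=float)
    return float(statistic(samples)), float(vals.std(ddof=1) / np.sqrt(n_batches))


def poisson_snr(mean) -> np.ndarray | float:
    """SNR of a Poisson-distributed count with the given mean: sqrt(mean)."""
    return np.sqrt(mean)


def noise_scaling_exponent(means: Sequence[float], stds: Sequence[float]) -> float:
    """Least-squares slope of log(std) against log(mean).

    Requires at least 5 usable (positive mean and std) pairs from a single
    layer across input levels; callers should restrict to the pre-saturation
    regime, where sqrt-scaling (slope 1/2) is the Poisson-like expectation.
    """
    means = np.asarray(means, dtype=float)
    stds = np.asarray(stds, dtype=float)
    ok = (means > 0) & (stds > 0)
    if ok.sum() < 5:
        raise ValueError(f"need at least 5 usable (mean, std) pairs, got {int(ok.sum())}")
    slope, _ = np.polyfit(np.log(means[ok]), np.log(stds[ok]), 1)
    return float(slope)


def acr_deviation(
    spec: RelaySpec,
    factors: Sequence[float] = (0.5, 2.0),
    k1: float = 1.0,
    tol: float = 1e-9,
) -> float:
    """Max relative change of steady final-layer response under total-protein perturbations.

    Each layer total is multiplied in turn by each factor and the steady
    state re-solved; returns max |LNp*(perturbed) - LNp*(base)| / LNp*(base).
    A bifunctional relay whose last-layer hydrolysis is negligible relative
    to enzymatic dephosphorylation shows absolute concentration robustness:
    the deviation is ~0 because LNp* = k1/k_on independently of the totals.
    """
    if not spec.bifunctional:
        raise ValueError("acr_deviation requires the bifunctional enzyme on")
    base = solve_steady(spec, k1, tol=tol).phospho[-1]
    if base <= 0:
        raise ValueError("base final-layer steady state is zero; deviation undefined")
    worst = 0.0
    for layer in range(spec.n_layers):
        for f in factors:
            totals = list(spec.totals)
            totals[layer] *= f
            pert = spec.with_(totals=tuple(totals))
            val = solve_steady(pert, k1, tol=tol).phospho[-1]
            worst = max(worst, abs(val - base) / base)
    return worst
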
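"""Figure-level analyses as parameter scans emitting tidy tables.

Each driver is a pure function of its settings (plus a seed where the scan
is stochastic) and returns pandas DataFrames; rerunning with identical
arguments reproduces the tables exactly (bit-identically for deterministic
scans, identically given the seed for stochastic ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import RelaySpec, build_relay, compile_reactions
from .steady import ResponseCurve, SteadyStateError, analytic_curve, sweep_input
from .metrics import (
    CurveRangeError,
    curve_metrics,
    noise_scaling_exponent,
    response_coefficient,
    sensitivity,
    _crossing_input,
)
from .ssa import staircase_protocol

__all__ = [
    "length_scan",
    "bifunctional_km_scan",
    "crosstalk_scan",
    "robustness_sampling",
    "dephos_rate_scan",
    "noise_analysis",
    "NoiseAnalysisResult",
]


def _grid(k1_max: float, n_points: int) -> np.ndarray:
    return np.linspace(0.0, k1_max, n_points)


@dataclass
class ScanResult:
    """A tidy results table plus the full response curves behind it."""

    table: pd.DataFrame
    curves: dict = field(default_factory=dict)
    heatmap: pd.DataFrame | None = None


def length_scan(
    lengths: Sequence[int] = (2, 3, 4, 5),
    k1_max: float = 2.0,
    n_points: int = 200,
) -> ScanResult:
    """Sweep relays of increasing length and quantify per-layer ultrasensitivity.

    For each length: the full input-response sweep, the response coefficient
    of every layer, which layer is the most ultrasensitive (smallest
    coefficient), and the final-layer sensitivity over [0, 2].
    """
    if any(n < 2 for n in lengths):
        raise ValueError("relay lengths must be at least 2")
    rows = []
    curves: dict[int, ResponseCurve] = {}
    for n in lengths:
        spec = build_relay(n)
        curve = sweep_input(spec, _grid(k1_max, n_points))
        curves[n] = curve
        cm = curve_metrics(curve, window=(0.0, min(2.0, k1_max)))
        best = cm.most_ultrasensitive_layer()
        for layer in range(1, n + 1):
            rows.append(
                {
                    "length": n,
                    "layer": layer,
                    "response_coefficient": cm.response_coefficient[layer - 1],
                    "is_most_ultrasensitive": layer == best,
                    "final_sensitivity": cm.sensitivity,
                }
            )
    return ScanResult(pd.DataFrame(rows), curves)


def bifunctional_km_scan(
    kms: Sequence[float | None] = (0.1, 1.0, 10.0, 100.0, None),
    k1_max: float = 10.0,
    n_points: int = 200,
    n_layers: int = 4,
) -> ScanResult:
    """Scan the Michaelis constant of the bifunctional first-layer kinase.

    ``None`` means the enzyme is off (the plain relay).  Km is set by varying
    the complex-formation rate k_on at fixed k_cat = 1 (Km = k_cat / k_on).
    Reports the final-layer sensitivity over the low ([0, 2]) and high
    ([2, 10]) input windows for each Km.
    """
    rows = []
    curves: dict = {}
    for km in kms:
        if km is None:
            spec = build_relay(n_layers)
            label = "off"
        else:
            if km <= 0:
                raise ValueError("Km must be positive")
            spec = build_relay(n_layers, bifunctional=True, k_cat=1.0, k_on=1.0 / km)
            label = f"{km:g}"
        curve = sweep_input(spec, _grid(k1_max, n_points))
        curves[label] = curve
        rows.append(
            {
                "km": np.inf if km is None else km,
                "km_label": label,
                "sensitivity_low": sensitivity(curve, n_layers, (0.0, 2.0)),
                "sensitivity_high": sensitivity(curve, n_layers, (2.0, min(10.0, k1_max))),
            }
        )
    return ScanResult(pd.DataFrame(rows), curves)


def crosstalk_scan(
    layer: int,
    mode: str,
    rates: Sequence[float] | None = None,
    k1_max: float = 2.0,
    n_points: int = 200,
    n_layers: int = 4,
) -> ScanResult:
    """Heat-map scan of one cross-talk point: final-layer response over
    (primary input, cross-talk rate).

    ``mode`` is ``"activation"`` (self-phosphorylation, talk-in; not allowed
    at layer 1) or ``"inhibition"`` (self-dephosphorylation, talk-out).  The
    summary table holds, per rate: the primary input reaching 90% of the
    baseline (rate 0) maximal response, the maximal response itself, and the
    sensitivity to the primary input over [0, 2].  Rate 0 is always included
    as the baseline row.
    """
    if mode not in ("activation", "inhibition"):
        raise ValueError(f"mode must be 'activation' or 'inhibition', got {mode!r}")
    if not 1 <= layer <= n_layers:
        raise ValueError(f"layer must be in 1..{n_layers}")
    if mode == "activation" and layer == 1:
        raise ValueError("cross-activation at layer 1 is the primary input itself")
    if rates is None:
        rates = np.geomspace(0.01, 1.0, 10)
    rates = np.concatenate([[0.0], np.asarray(rates, dtype=float)])
    grid = _grid(k1_max, n_points)

    heat_rows = []
    summary_rows = []
    curves: dict[float, ResponseCurve] = {}
    baseline_max = None
    for rate in rates:
        overrides: dict = {}
        if rate > 0:
            key = "act_rates" if mode == "activation" else "deact_rates"
            vec = [0.0] * n_layers
            vec[layer - 1] = rate
            overrides[key] = tuple(vec)
        spec = build_relay(n_layers, overrides)
        curve = sweep_input(spec, grid)
        curves[float(rate)] = curve
        r = curve.layer(n_layers)
        if baseline_max is None:
            baseline_max = float(r.max())
        try:
            input_90 = _crossing_input(grid, r, 0.9 * baseline_max)
        except CurveRangeError:
            input_90 = np.nan
        for k1, resp in zip(grid, r):
            heat_rows.append(
                {"crosstalk_rate": rate, "input": k1, "response": resp}
            )
        summary_rows.append(
            {
                "crosstalk_rate": rate,
                "input_90": input_90,
                "max_response": float(r.max()),
                "sensitivity": sensitivity(curve, n_layers, (0.0, min(2.0, k1_max))),
            }
        )
    return ScanResult(pd.DataFrame(summary_rows), curves, pd.DataFrame(heat_rows))


def robustness_sampling(
    n_samples: int = 1000,
    seed: int = 0,
    n_layers: int = 4,
    fixed_layer: int = 2,
    total_range: tuple[float, float] = (0.01, 10.0),
    rate_range: tuple[float, float] = (0.01, 2.0),
    n_curve_points: int = 256,
) -> pd.DataFrame:
    """Random-parameter robustness analysis of second-layer ultrasensitivity.

    Draws ``n_samples`` parameter sets — layer totals uniform on
    ``total_range`` (the total of ``fixed_layer`` held at its default 10),
    transfer and hydrolysis rates uniform on ``rate_range`` — and computes
    the response coefficient of L2p from the analytic steady-state curve.
    Samples whose curve cannot span the 10%/90% range are flagged (``ok`` =
    False) and counted, never dropped silently.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_samples):
        totals = rng.uniform(*total_range, size=n_layers)
        totals[fixed_layer - 1] = 10.0
        rates = rng.uniform(*rate_range, size=n_layers)  # k2..kN plus hydrolysis
        spec = build_relay(
            n_layers,
            totals=tuple(totals),
            transfer_rates=tuple(rates[:-1]),
            hydrolysis_rate=float(rates[-1]),
        )
        row = {
            "sample": i,
            **{f"L{j + 1}_tot": totals[j] for j in range(n_layers)},
            **{f"k{j + 2}": rates[j] for j in range(n_layers - 1)},
            "k_hyd": rates[-1],
        }
        try:
            curve = analytic_curve(spec, n_points=n_curve_points)
            row["response_coefficient"] = response_coefficient(curve, 2)
            row["ok"] = True
        except (CurveRangeError, SteadyStateError):
            row["response_coefficient"] = np.nan
            row["ok"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def dephos_rate_scan(
    k_hyd_values: Sequence[float] = (0.25, 0.5, 1.0, 2.0),
    k1_max: float = 2.0,
    n_points: int = 200,
    n_layers: int = 4,
) -> ScanResult:
    """Scan the last-layer dephosphorylation rate, which tunes the threshold.

    Per rate: the full sweep, the threshold location (input at 50% of the
    L2p maximum) and the L2p response coefficient.  A zero rate is rejected:
    without last-layer dephosphorylation no steady state exists for positive
    input (phosphate accumulates without bound).
    """
    rows = []
    curves: dict[float, ResponseCurve] = {}
    for k_hyd in k_hyd_values:
        if k_hyd <= 0:
            raise SteadyStateError(
                "k_hyd = 0 rejected: the relay has no phosphate outflux, so L4p "
                "saturates for any positive input and no steady state exists"
            )
        spec = build_relay(n_layers, hydrolysis_rate=float(k_hyd))
        curve = sweep_input(spec, _grid(k1_max, n_points))
        curves[float(k_hyd)] = curve
        r2 = curve.layer(2)
        rows.append(
            {
                "k_hyd": k_hyd,
                "threshold_input": _crossing_input(curve.inputs, r2, 0.5 * r2.max()),
                "L2p_response_coefficient": response_coefficient(curve, 2),
            }
        )
    return ScanResult(pd.DataFrame(rows), curves)


@dataclass
class NoiseAnalysisResult:
    """Per-level stochastic statistics plus per-length noise summaries."""

    stats: pd.DataFrame     # length, level, layer, mean, std, snr
    summary: pd.DataFrame   # length, median final-layer SNR, noise exponents


def noise_analysis(
    lengths: Sequence[int] = (2, 3, 4, 5),
    levels: Sequence[int] | None = None,
    burn_in: float = 50.0,
    sample_time: float = 200.0,
    record_interval: float = 0.1,
    seed: int = 0,
    mode: str = "intrinsic",
    count_scale: int = 100,
    exponent_mean_range: tuple[float, float] = (5.0, 80.0),
) -> NoiseAnalysisResult:
    """Staircase-input stochastic noise analysis across relay lengths.

    Runs the equilibrium-sampling staircase (signal count stepped 0..200) on
    a relay of each length, in intrinsic mode (explicit noise-free signal) or
    cascade mode (Poisson-noisy input), and reports per-level, per-layer
    mean, standard deviation and SNR, plus per-length summaries: the median
    final-layer SNR over input levels 100-200 and the log(std)-log(mean)
    noise-scaling exponent of each layer restricted to levels whose mean
    count lies pre-saturation (default 5-80 of 100).
    """
    if mode not in ("intrinsic", "cascade"):
        raise ValueError(f"mode must be 'intrinsic' or 'cascade', got {mode!r}")
    if levels is None:
        levels = range(0, 201, 2)
    levels = list(levels)
    stat_rows = []
    summary_rows = []
    for idx, n in enumerate(lengths):
        spec = build_relay(n)
        network = compile_reactions(
            spec,
            count_scale=count_scale,
            signal_mode="explicit-signal" if mode == "intrinsic" else "noisy-cascade",
        )
        stats = staircase_protocol(
            network,
            levels,
            burn_in=burn_in,
            sample_time=sample_time,
            record_interval=record_interval,
            seed=seed + idx,
        )
        for ls in stats:
            for layer in range(1, n + 1):
                stat_rows.append(
                    {
                        "length": n,
                        "level": ls.input_level,
                        "layer": layer,
                        "mean": ls.mean[layer - 1],
                        "std": ls.std[layer - 1],
                        "snr": ls.snr[layer - 1],
                    }
                )
        final_snr = np.array(
            [ls.snr[n - 1] for ls in stats if 100 <= ls.input_level <= 200]
        )
        summary = {
            "length": n,
            "median_final_snr_100_200": float(np.nanmedian(final_snr)),
        }
        lo, hi = exponent_mean_range
        for layer in range(1, n + 1):
            means = np.array([ls.mean[layer - 1] for ls in stats])
            stds = np.array([ls.std[layer - 1] for ls in stats])
            keep = (means >= lo) & (means <= hi)
            try:
                expo = noise_scaling_exponent(means[keep], stds[keep])
            except ValueError:
                expo = np.nan
            summary[f"noise_exponent_L{layer}"] = expo
        summary_rows.append(summary)
    return NoiseAnalysisResult(pd.DataFrame(stat_rows), pd.DataFrame(summary_rows))
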
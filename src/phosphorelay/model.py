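"""Core phosphorelay model: species, mass-action reactions, ODE right-hand side.

The model is a linear chain of ``n_layers`` proteins L1..LN.  An external
signal drives autophosphorylation of L1 at rate ``k1`` (the input); the
phosphoryl group is then passed down the chain by bimolecular phosphotransfer
(L(i)p + L(i+1) -> L(i) + L(i+1)p) and leaves the system by hydrolysis of the
last layer (LNp -> LN).  All reactions are unidirectional, ATP is not
modelled explicitly, and per-layer total protein is conserved.

Two optional variants extend the core chain:

* cross-talk — first-order self-phosphorylation (``act_rates``, "talk in")
  and self-dephosphorylation (``deact_rates``, "talk out") at each layer;
  self-phosphorylation is disallowed at layer 1, whose phosphorylation is the
  input itself;
* a bifunctional first-layer kinase — unphosphorylated L1 enzymatically
  dephosphorylates LNp through an explicit enzyme-substrate complex:
  L1 + LNp --k_on--> C --k_cat--> L1 + LN, with Michaelis constant
  Km = k_cat / k_on.

The same specification compiles to a discrete mass-action reaction network
(integer molecule counts) for exact stochastic simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "RelaySpec",
    "RelayState",
    "ReactionNetwork",
    "build_relay",
    "ode_rhs",
    "compile_reactions",
    "DEFAULT_TOTAL",
    "DEFAULT_RATE",
    "SSA_COUNT_SCALE",
    "SSA_ACTIVATION_CONSTANT",
]

#: Default per-layer total protein concentration (arbitrary concentration units).
DEFAULT_TOTAL = 10.0
#: Default value for every kinetic rate constant.
DEFAULT_RATE = 1.0
#: Default molecule count per layer in the stochastic model.
SSA_COUNT_SCALE = 100
#: Stochastic rate constant (per second) of signal-mediated L1 activation,
#: L1 + S -> L1p + S; chosen so a signal count S in [0, 200] corresponds to
#: the deterministic input k1 in [0, 2].
SSA_ACTIVATION_CONSTANT = 0.01


def _as_tuple(values: Sequence[float], name: str, length: int) -> tuple[float, ...]:
    out = tuple(float(v) for v in values)
    if len(out) != length:
        raise ValueError(f"{name} must have length {length}, got {len(out)}")
    return out


@dataclass(frozen=True)
class RelaySpec:
    """Full parameterization of an N-layer phosphorelay.

    Attributes
    ----------
    n_layers:
        Number of layers L1..LN (at least 2).
    totals:
        Total protein concentration per layer (length ``n_layers``).
    transfer_rates:
        Phosphotransfer rate constants k2..kN; ``transfer_rates[i]`` governs
        L(i+1)p + L(i+2) -> L(i+1) + L(i+2)p (0-based, length ``n_layers - 1``).
    hydrolysis_rate:
        First-order self-dephosphorylation rate of the last layer (LNp -> LN).
    act_rates:
        Cross-activation (self-phosphorylation) rate per layer; entry 0 must
        be zero — layer-1 phosphorylation is the input.
    deact_rates:
        Cross-inhibition (self-dephosphorylation) rate per layer.
    bifunctional:
        Whether unphosphorylated L1 enzymatically dephosphorylates LNp.
    k_on:
        Complex-formation rate of the bifunctional enzyme, L1 + LNp -> C.
    k_cat:
        Catalytic release rate, C -> L1 + LN.  The Michaelis constant of the
        bifunctional reaction is ``k_cat / k_on``.
    """

    n_layers: int
    totals: tuple[float, ...]
    transfer_rates: tuple[float, ...]
    hydrolysis_rate: float
    act_rates: tuple[float, ...]
    deact_rates: tuple[float, ...]
    bifunctional: bool = False
    k_on: float = DEFAULT_RATE
    k_cat: float = DEFAULT_RATE

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValueError(f"a relay needs at least 2 layers, got {self.n_layers}")
        object.__setattr__(self, "totals", _as_tuple(self.totals, "totals", self.n_layers))
        object.__setattr__(
            self,
            "transfer_rates",
            _as_tuple(self.transfer_rates, "transfer_rates", self.n_layers - 1),
        )
        object.__setattr__(self, "act_rates", _as_tuple(self.act_rates, "act_rates", self.n_layers))
        object.__setattr__(
            self, "deact_rates", _as_tuple(self.deact_rates, "deact_rates", self.n_layers)
        )
        if any(t <= 0 for t in self.totals):
            raise ValueError("all layer totals must be positive")
        rates = (
            self.transfer_rates
            + (self.hydrolysis_rate,)
            + self.act_rates
            + self.deact_rates
            + (self.k_on, self.k_cat)
        )
        if any(r < 0 for r in rates):
            raise ValueError("all rate constants must be non-negative")
        if self.act_rates[0] != 0.0:
            raise ValueError(
                "self-phosphorylation (cross-activation) is not allowed at layer 1; "
                "layer-1 phosphorylation is the input k1"
            )

    @property
    def km(self) -> float:
        """Michaelis constant k_cat / k_on of the bifunctional enzyme."""
        if self.k_on == 0:
            return float("inf")
        return self.k_cat / self.k_on

    def with_(self, **overrides) -> "RelaySpec":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **overrides)


@dataclass
class RelayState:
    """Phosphorylated concentration per layer plus the enzyme-substrate complex.

    ``complex`` is the concentration of the L1.LNp complex; identically zero
    unless the spec is bifunctional.  The complex sequesters one molecule of
    layer 1 and one of layer N, so free (unphosphorylated) concentrations are
    ``L1 = L1_tot - L1p - C`` and ``LN = LN_tot - LNp - C``.
    """

    phospho: np.ndarray
    complex: float = 0.0

    def __post_init__(self) -> None:
        self.phospho = np.asarray(self.phospho, dtype=float)

    @classmethod
    def zeros(cls, spec: RelaySpec) -> "RelayState":
        return cls(np.zeros(spec.n_layers), 0.0)

    def to_vector(self, spec: RelaySpec) -> np.ndarray:
        if spec.bifunctional:
            return np.concatenate([self.phospho, [self.complex]])
        return self.phospho.copy()

    @classmethod
    def from_vector(cls, spec: RelaySpec, y: np.ndarray) -> "RelayState":
        y = np.asarray(y, dtype=float)
        if spec.bifunctional:
            if y.shape != (spec.n_layers + 1,):
                raise ValueError(f"expected vector of length {spec.n_layers + 1}, got {y.shape}")
            return cls(y[:-1].copy(), float(y[-1]))
        if y.shape != (spec.n_layers,):
            raise ValueError(f"expected vector of length {spec.n_layers}, got {y.shape}")
        return cls(y.copy(), 0.0)

    def validate(self, spec: RelaySpec, tol: float = 1e-9) -> None:
        """Raise ValueError if concentrations violate the conservation bounds."""
        if self.phospho.shape != (spec.n_layers,):
            raise ValueError(
                f"state has {self.phospho.shape[0]} layers, spec has {spec.n_layers}"
            )
        totals = np.asarray(spec.totals)
        if np.any(self.phospho < -tol) or self.complex < -tol:
            raise ValueError("negative concentration in state")
        if np.any(self.phospho > totals + tol):
            raise ValueError("phosphorylated level exceeds layer total")
        if self.phospho[0] + self.complex > totals[0] + tol:
            raise ValueError("layer-1 phosphorylated + complex exceeds total")
        if self.phospho[-1] + self.complex > totals[-1] + tol:
            raise ValueError("last-layer phosphorylated + complex exceeds total")


def build_relay(n_layers: int, overrides: Mapping[str, object] | None = None, **kw) -> RelaySpec:
    """Build a validated RelaySpec at the model defaults with overrides applied.

    Defaults: every layer total 10, every transfer rate and the last-layer
    hydrolysis rate 1.0, all cross-talk rates zero, bifunctional enzyme off
    (k_on = k_cat = 1.0 when switched on).

    Parameters may be overridden via a mapping or keyword arguments using the
    :class:`RelaySpec` field names.  Unknown keys are rejected.
    """
    if n_layers < 2:
        raise ValueError(f"a relay needs at least 2 layers, got {n_layers}")
    fields = {
        "totals": (DEFAULT_TOTAL,) * n_layers,
        "transfer_rates": (DEFAULT_RATE,) * (n_layers - 1),
        "hydrolysis_rate": DEFAULT_RATE,
        "act_rates": (0.0,) * n_layers,
        "deact_rates": (0.0,) * n_layers,
        "bifunctional": False,
        "k_on": DEFAULT_RATE,
        "k_cat": DEFAULT_RATE,
    }
    merged = dict(overrides or {})
    merged.update(kw)
    for key, value in merged.items():
        if key == "n_layers":
            raise ValueError("n_layers is a positional argument, not an override")
        if key not in fields:
            raise ValueError(f"unknown RelaySpec field {key!r}")
        fields[key] = value
    return RelaySpec(n_layers=n_layers, **fields)


def ode_rhs(spec: RelaySpec, state: RelayState, k1: float) -> RelayState:
    """Time derivative of the relay state under input ``k1``.

    Mass-action kinetics; per-layer totals are conserved by construction
    (every phosphotransfer moves one phosphoryl group, the complex terms
    appear with opposite signs in the L1p/LNp/C equations).
    """
    if state.phospho.shape != (spec.n_layers,):
        raise ValueError(
            f"state has {state.phospho.shape[0]} layers, spec has {spec.n_layers}"
        )
    if k1 < 0:
        raise ValueError("input k1 must be non-negative")
    y = state.to_vector(spec)
    dy = _rhs_vector(spec, y, k1)
    return RelayState.from_vector(spec, dy)


def _rhs_vector(spec: RelaySpec, y: np.ndarray, k1: float) -> np.ndarray:
    """Vectorized RHS on the packed state vector (phospho, [complex])."""
    n = spec.n_layers
    p = y[:n]
    c = y[n] if spec.bifunctional else 0.0
    totals = np.asarray(spec.totals)
    free = totals - p
    if spec.bifunctional:
        free = free.copy()
        free[0] -= c
        free[-1] -= c
    kt = np.asarray(spec.transfer_rates)
    act = np.asarray(spec.act_rates)
    deact = np.asarray(spec.deact_rates)

    # bimolecular transfer fluxes: J_i = k_{i+2} * L(i+1)p * L(i+2), i = 0..n-2
    transfer = kt * p[:-1] * free[1:]

    dp = np.empty(n)
    dp[0] = k1 * free[0] - transfer[0]
    if n > 2:
        dp[1:-1] = transfer[:-1] - transfer[1:]
    dp[-1] = transfer[-1] - spec.hydrolysis_rate * p[-1]
    dp += act * free - deact * p

    if spec.bifunctional:
        binding = spec.k_on * free[0] * p[-1]
        dp[-1] -= binding
        dc = binding - spec.k_cat * c
        return np.concatenate([dp, [dc]])
    return dp


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction: reactant/product stoichiometry over species names."""

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate: float

    def format(self) -> str:
        def side(terms: tuple[tuple[str, int], ...]) -> str:
            if not terms:
                return "0"
            return " + ".join(name if n == 1 else f"{n} {name}" for name, n in terms)

        return f"{side(self.reactants)} -> {side(self.products)} @ {self.rate:g}"


@dataclass
class ReactionNetwork:
    """Discrete mass-action reaction network for the stochastic simulator.

    ``species`` maps name -> initial integer count.  Reactions are at most
    bimolecular; stochastic rate constants are per second.
    """

    species: dict[str, int]
    reactions: list[Reaction]
    n_layers: int
    signal_species: str = "S"
    conserved_groups: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def species_names(self) -> list[str]:
        return list(self.species)

    def index(self, name: str) -> int:
        return self.species_names.index(name)

    def initial_counts(self) -> np.ndarray:
        return np.array(list(self.species.values()), dtype=np.int64)

    def export_text(self) -> str:
        """Plain-text reaction list, one 'reactants -> products @ rate' per line."""
        return "\n".join(r.format() for r in self.reactions) + "\n"


def compile_reactions(
    spec: RelaySpec,
    count_scale: int = SSA_COUNT_SCALE,
    signal_mode: str = "explicit-signal",
    signal_count: int = 0,
    release_rate: float = 1.0,
    degradation_rate: float = 1.0,
) -> ReactionNetwork:
    """Compile a RelaySpec into a discrete reaction network.

    The concentration model (totals 10 per layer) maps onto molecule counts
    with ``count_scale`` molecules per layer (default 100, i.e. a volume
    factor of ``count_scale / 10`` molecules per concentration unit):
    unimolecular stochastic constants equal the deterministic rates,
    bimolecular constants are divided by the volume factor (1.0 -> 0.1 s^-1
    at the defaults).  L1 activation is signal-mediated, L1 + S -> L1p + S at
    0.01 s^-1 per signal molecule, so a signal count S in [0, 200] spans the
    deterministic input regime k1 in [0, 2].

    signal_mode:
      * ``"explicit-signal"`` — a signal species S of fixed count drives L1.
      * ``"noisy-cascade"`` — a two-step cascade: S1 releases S2
        (S1 -> S1 + S2) and S2 degrades (S2 -> 0), so the stationary S2 count
        is Poisson with mean S1 * release_rate / degradation_rate; S2 drives
        L1.  This is the extrinsic-noise (noisy Poisson input) configuration.
    """
    if count_scale <= 0 or int(count_scale) != count_scale:
        raise ValueError("count_scale must be a positive integer")
    if signal_mode not in ("explicit-signal", "noisy-cascade"):
        raise ValueError(f"unknown signal_mode {signal_mode!r}")
    if signal_count < 0:
        raise ValueError("signal_count must be non-negative")
    n = spec.n_layers
    omega = count_scale / DEFAULT_TOTAL  # molecules per concentration unit

    species: dict[str, int] = {}
    for i in range(1, n + 1):
        species[f"L{i}"] = int(round(omega * spec.totals[i - 1]))
        species[f"L{i}p"] = 0
    if signal_mode == "explicit-signal":
        species["S"] = int(signal_count)
        driver = "S"
    else:
        species["S1"] = int(signal_count)
        species["S2"] = 0
        driver = "S2"
    if spec.bifunctional:
        species["C"] = 0

    rx: list[Reaction] = []

    def add(reactants, products, rate):
        if rate > 0:
            rx.append(Reaction(tuple(reactants), tuple(products), float(rate)))

    if signal_mode == "noisy-cascade":
        if release_rate <= 0 or degradation_rate <= 0:
            raise ValueError("cascade release and degradation rates must be positive")
        add([("S1", 1)], [("S1", 1), ("S2", 1)], release_rate)
        add([("S2", 1)], [], degradation_rate)

    # signal-mediated activation of L1 (pseudo-first-order in L1 per signal molecule)
    add([("L1", 1), (driver, 1)], [("L1p", 1), (driver, 1)], SSA_ACTIVATION_CONSTANT)

    for i in range(n - 1):
        add(
            [(f"L{i + 1}p", 1), (f"L{i + 2}", 1)],
            [(f"L{i + 1}", 1), (f"L{i + 2}p", 1)],
            spec.transfer_rates[i] / omega,
        )
    add([(f"L{n}p", 1)], [(f"L{n}", 1)], spec.hydrolysis_rate)

    for i in range(n):
        add([(f"L{i + 1}", 1)], [(f"L{i + 1}p", 1)], spec.act_rates[i])
        add([(f"L{i + 1}p", 1)], [(f"L{i + 1}", 1)], spec.deact_rates[i])

    if spec.bifunctional:
        add([("L1", 1), (f"L{n}p", 1)], [("C", 1)], spec.k_on / omega)
        add([("C", 1)], [("L1", 1), (f"L{n}", 1)], spec.k_cat)

    groups: list[tuple[str, ...]] = []
    for i in range(1, n + 1):
        group = [f"L{i}", f"L{i}p"]
        if spec.bifunctional and i in (1, n):
            group.append("C")
        groups.append(tuple(group))

    return ReactionNetwork(
        species=species,
        reactions=rx,
        n_layers=n,
        signal_species=driver if signal_mode == "explicit-signal" else "S1",
        conserved_groups=groups,
    )
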
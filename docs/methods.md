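# Methods

## Model and assumptions

The core object is a linear phosphorelay of `n_layers ≥ 2` proteins.  The
model assumes: (i) the signal enters only as the first-layer
autophosphorylation rate `k1`; (ii) ATP is not rate-limiting and is not
tracked; (iii) phosphotransfer complexes between consecutive layers are
short-lived, so transfer is a single bimolecular step; (iv) all reactions
are unidirectional (no reverse phosphotransfer); (v) per-layer total protein
is constant over signalling timescales.  Under these assumptions the state
is the vector of phosphorylated concentrations plus, in the bifunctional
variant, the enzyme–substrate complex `C`, which sequesters one molecule
each of layers 1 and N (conservation reads `L1 + L1p + C = L1_tot` and
`LN + LNp + C = LN_tot`).

Reference parameterization (used everywhere unless overridden): totals 10
per layer, all transfer rates and the last-layer hydrolysis rate 1.0,
cross-talk rates 0, bifunctional off.  The "fifth" core reaction is
last-layer self-dephosphorylation with its own rate constant
`hydrolysis_rate`, kept separate from the cross-inhibition rate of the last
layer: a relay with zero cross-talk still needs a phosphate outflux for a
steady state to exist, and several analyses tune this rate independently.
With `hydrolysis_rate = 0` and the bifunctional enzyme off, any positive
input accumulates phosphate without bound; such configurations are rejected
with an explicit error rather than integrated forever.

Cross-talk is first-order: cross-activation `Li -> Lip` at `act_rates[i]`
(disallowed at layer 1, where phosphorylation *is* the input) and
cross-inhibition `Lip -> Li` at `deact_rates[i]`.  The bifunctional first-
layer kinase dephosphorylates the final layer via irreversible complex
formation `L1 + LNp -> C` (`k_on`) and catalytic release `C -> L1 + LN`
(`k_cat`), so `Km = k_cat / k_on`; Km scans hold `k_cat = 1` and vary
`k_on`.  Reversible complex dissociation is not modelled; with it, Km would
read `(k_off + k_cat)/k_on` but the qualitative behaviour is unchanged.

## Steady states

`solve_steady` integrates the ODEs (scipy LSODA, rtol 1e-10, atol 1e-12)
in stages up to t = 1e4, polishing each stage with a Newton solve of the
algebraic system (scipy `root`); convergence means max |dy/dt| < 1e-9
(default `tol`).  The tolerance is tight enough that interpolated 10%/90%
crossings of the curves are unaffected by solver error.  `sweep_input`
walks a strictly increasing input grid by continuation (each point seeded
with the previous solution, Newton-first with integration fallback); the
system is monostable in all regimes studied, so continuation and
independent cold-start solves agree, which the tests assert.

When cross-talk and the bifunctional enzyme are off, the steady state is a
one-parameter family in the phosphate flux J: `LNp = J/k_hyd`, then
backwards `Lip = J/(k_{i+1} (L_{i+1,tot} − L_{i+1}p))`, and finally
`k1 = J/(L1_tot − L1p)`.  `max_flux` brackets the saturation flux `J_max`
(beyond which some layer would exceed its total) by bisection to 1e-12
relative precision; `analytic_curve` places half of its default flux grid
linearly over [0, 0.9 J_max] and half geometrically crowding J_max, because
the inverse map k1(J) is extremely steep near saturation.  `analytic_state`
inverts k1(J) by bisection, which gives closed-form values at arbitrary
inputs for equivalence tests against the sweep (< 1e-6 agreement is the
standing acceptance bound; measured ~1e-10).

## Curve metrics

The response coefficient of a layer is `I90/I10` with both crossings found
by monotone linear interpolation and thresholds taken relative to the
curve's maximum *on the evaluated grid* (final-layer curves saturate below
the layer total, and no theoretical maximum is assumed).  Curves that never
leave zero, or that start above 10% of their maximum at zero input, raise a
range error instead of returning a number.  Sensitivity over a window
[a, b] is `(r(b) − r(a))/(b − a)` — the per-bin slope summed over the
window and normalized by bin count, hence independent of grid density and
additive over adjacent windows when weighted by width.  Default analysis
windows are [0, 2] (the responsive regime of the reference relay) and
[2, 10] for bifunctional scans, which shift the responsive regime upward.

## Stochastic model

`compile_reactions` maps concentrations onto counts with 100 molecules per
layer standing for a total of 10 concentration units (volume factor
Ω = 10): unimolecular stochastic constants equal the deterministic rates,
bimolecular constants are divided by Ω (1.0 → 0.1 s⁻¹ at the defaults).
L1 activation is signal-mediated, `L1 + S -> L1p + S` at 0.01 s⁻¹ per
signal molecule, so a signal count S ∈ [0, 200] spans the deterministic
input k1 ∈ [0, 2]; the lower activation constant exists purely to make the
input a discrete dial with 200 usable steps.  The extrinsic-noise variant
replaces the fixed signal with a two-step cascade `S1 -> S1 + S2` (1 s⁻¹
per S1), `S2 -> ∅` (1 s⁻¹), whose stationary S2 count is Poisson with mean
equal to the S1 count; equal release and degradation rates make the mean
track the dial one-to-one while matching the global unimolecular default.

The simulator is the exact direct-method SSA (not tau-leaping: variance
statistics are the point, and the system holds ≲ 900 molecules).  The inner
loop is a numba kernel seeded explicitly per call; states are recorded on a
fixed time grid so temporal means are unweighted, and if all propensities
vanish the frozen state fills the remaining grid.  Identical seed and
network give bit-identical trajectories; protocols derive per-stage
sub-seeds from the master seed via `numpy.random.SeedSequence` (reduced
below 2³¹).

The noise protocol steps the signal count through a non-decreasing
staircase (default 0…200 in steps of 2), carrying the molecular state
across levels; at each level 50 s are discarded as burn-in and the state is
then sampled every 0.1 s for 200 s (2000 samples per level, ~2×10⁵ per
staircase).  These problem sizes keep a full multi-length noise analysis in
the seconds-to-minutes range while leaving per-level statistics accurate to
a few percent; they are deliberately far smaller than an exhaustive
per-level equilibration, and all stochastic comparisons account for that
(below).

## Noise statistics

Per level and layer the protocol reports the temporal mean, population
(1/n) standard deviation and SNR = mean/std, with SNR flagged undefined
(NaN) where the std is zero.  The Poisson baseline is √mean.  Because
samples 0.1 s apart are strongly autocorrelated, standard errors for any
temporal statistic use batch means (`batched_statistic_se`): the series is
cut into 20 contiguous batches, the statistic is computed per batch, and
the SE is the batch spread over √20.  Stochastic-vs-deterministic
comparisons are made at 3 batch-means SEs.  Near the response threshold
(signal ≈ 100) relaxation is slow and fluctuations are large and slow, so
the deterministic-agreement checks use dedicated stationary runs (200 s
burn-in, 2000 s sampling) rather than the 200 s staircase windows.

The noise-scaling exponent is the least-squares slope of log(std) vs
log(mean).  "Pre-saturation" is operationalized as layer means between 5
and 80 counts (of 100): below 5 counts log-fit noise dominates, above 80
the occupancy constraint visibly suppresses variance.  The std–mean
relation of an intermediate layer is not a clean power law — it rises
super-Poissonially into the threshold (ultrasensitive amplification) and
bends down as the layer fills — so the summary exponent is computed on the
(mean, std) pairs of *both* intermediate layers of the four-layer relay
pooled, which averages these opposing local deviations; the per-layer
exponents are also reported.  The pooled value sits at ≈ 0.42 under the
default protocol, consistent with square-root scaling; the L2p-only fit
over the same window gives ≈ 0.38, and restricting to the rising branch
gives ≈ 0.75 — both reported here so downstream users know the summary is
window-sensitive.

Relevant emergent behaviour verified by the test suite: the final layer's
SNR stays at or above the Poisson line across the staircase (within 3
batch-means SEs per level; the stationary margin is genuinely small at low
occupancy, where the final layer is nearly a pure birth–death process), and
the median final-layer SNR over the upper half of the staircase grows from
the two-layer to the four-layer relay.

## Experiments

Each figure-level driver is a pure function of (settings, seed) returning
tidy pandas tables: relay-length scan (2…5), bifunctional Km scan
({0.1, 1, 10, 100, off}), cross-talk scans (per layer and mode, rate grids
defaulting to 10 log-spaced points in [0.01, 1] plus the zero baseline,
"threshold" reported as the input reaching 50% or 90% of the relevant
maximum), last-layer dephosphorylation scan, robustness sampling (totals
U[0.01, 10] with the second-layer total fixed, rates U[0.01, 2], response
coefficient from the analytic curve; infeasible samples flagged, not
dropped), and the multi-length noise analysis.  The cross-talk heat-map
axis scans rate constants (not fluxes); saturation-input comparisons are
made against the zero-rate baseline maximum so that "reaches saturation
earlier/later" is measured on a common scale.

## Synthetic inputs and what passing tests show

The input generators cover exactly the regimes the analyses assume:
constant inputs, piecewise-constant step programs (runnable through both
the ODE and SSA drivers, with stochastic counts 100× the deterministic
values), and the Poisson cascade.  Real signalling inputs are not Poisson
dials: receptor-level kinetics, bursty upstream processes and cell-to-cell
variability are all outside this model, as are transcriptional feedback,
dimerization, protein turnover and multi-domain hybrid kinases.  Passing
tests therefore certify the mathematical behaviour of the idealized relay
— conservation, the flux-parametric steady state, where ultrasensitivity
sits, directional effects of cross-talk and the bifunctional enzyme, and
intrinsic-noise propagation at counts of order 100 — not quantitative
predictions for any particular organism's relay.

## Numerical choices and degenerate inputs

Integration tolerances rtol 1e-10 / atol 1e-12; steady-state residual
tolerance 1e-9; Newton polish accepted only inside concentration bounds
(slack 1e-7, then clipped).  Bisections (J_max, k1 inversion) run to 1e-12
to 1e-14 relative.  Response-curve CSVs are written with 12 significant
digits, which round-trips all downstream metrics.  Degenerate inputs fail
loudly: zero-outflux relays, inputs beyond saturation in the analytic
solver, empty or non-monotone grids and schedules, cross-activation at
layer 1, identical-reactant bimolecular reactions in the SSA compiler.

## Known limitations

* The SSA count scale of 100 leaves visible finite-size effects near the
  threshold (stationary means ~0.3% below the deterministic value, shrinking
  to ~0.06% at counts of 1000).
* The staircase protocol's 200 s windows under-resolve the slowest
  threshold fluctuations; per-level stds there carry a few-percent bias,
  which the batch-means error bars absorb but do not remove.
* The bifunctional mechanism is irreversible two-step binding; Km is a
  lumped constant, not a fitted enzymological parameter.
* No bifurcation machinery: the solvers assume (and verify) monostability.
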
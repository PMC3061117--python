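"""A bifunctional first-layer kinase: sensitivity trade-off and concentration robustness.

The first-layer kinase can, in its unphosphorylated form, enzymatically
dephosphorylate the final layer (L1 + L4p -> C -> L1 + L4).  An efficient
enzyme (small Michaelis constant Km = k_cat/k_on) flattens the low-input
response but extends the range over which the relay keeps responding — and,
when last-layer self-hydrolysis is negligible, pins the steady final-layer
output to k1/k_on regardless of any protein total (absolute concentration
robustness).
"""

from phosphorelay import build_relay
from phosphorelay.experiments import bifunctional_km_scan
from phosphorelay.metrics import acr_deviation

scan = bifunctional_km_scan(kms=(0.1, 1.0, 10.0, 100.0, None))
print("final-layer sensitivity (dL4p/dinput) by Km of the bifunctional enzyme:")
for _, row in scan.table.iterrows():
    print(
        f"  Km = {row.km_label:>4}: inputs 0-2 -> {row.sensitivity_low:6.3f}   "
        f"inputs 2-10 -> {row.sensitivity_high:6.3f}"
    )
print(
    "\nLow-window sensitivity rises as the enzyme weakens (off = plain relay),"
    "\nbut only the efficient enzyme keeps the relay responsive above input 2."
)

acr = build_relay(4, bifunctional=True, hydrolysis_rate=0.0)
broken = build_relay(4, bifunctional=True, hydrolysis_rate=1.0)
print(
    f"\nACR test (twofold perturbation of every layer total, input k1 = 1):"
    f"\n  no self-hydrolysis:   max |change in L4p*| = "
    f"{100 * acr_deviation(acr, (0.5, 2.0), k1=1.0):.3f}%"
    f"\n  with self-hydrolysis: max |change in L4p*| = "
    f"{100 * acr_deviation(broken, (0.5, 2.0), k1=1.0):.3f}%"
)
print("The output is concentration-robust only when the enzymatic route dominates.")
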
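"""Steady-state input-response curves and ultrasensitivity across relay lengths.

Sweeps relays of 2-5 layers over the input range [0, 2] and prints the
response coefficient (input at 90% of maximal response over input at 10%) of
every layer.  A coefficient of 81 is a Michaelis hyperbola; values near 1
mean a switch-like, ultrasensitive response.
"""

import numpy as np

from phosphorelay import build_relay, sweep_input
from phosphorelay.metrics import curve_metrics

for n in (2, 3, 4, 5):
    spec = build_relay(n)
    curve = sweep_input(spec, np.linspace(0.0, 2.0, 200))
    cm = curve_metrics(curve)
    rc = ", ".join(f"L{i + 1}p={v:.2f}" for i, v in enumerate(cm.response_coefficient))
    print(f"length {n}: response coefficients {rc}")
    print(
        f"  most ultrasensitive layer: L{cm.most_ultrasensitive_layer()}; "
        f"final-layer sensitivity over [0, 2]: {cm.sensitivity:.3f}"
    )

print(
    "\nThe intermediate layers sharpen as the relay grows (coefficients fall"
    "\ntowards 1) while the final layer stays a nearly linear, saturating dial:"
    "\nthe relay shuttles one phosphoryl group, so layers above the bottleneck"
    "\nonly accumulate phosphate once everything below them has saturated."
)
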
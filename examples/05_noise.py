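"""Stochastic noise analysis: the staircase protocol and SNR per layer.

Runs the exact (Gillespie) stochastic model of the four-layer relay through
a staircase of signal counts 0..200 (the discrete analogue of the input
range 0..2), sampling the equilibrium at each level, and compares the
signal-to-noise ratio (temporal mean over standard deviation) of each layer
with the Poisson baseline sqrt(mean).  A two-layer relay is run for
comparison.
"""

import numpy as np

from phosphorelay import build_relay, compile_reactions, staircase_protocol
from phosphorelay.metrics import noise_scaling_exponent, poisson_snr

levels = list(range(0, 201, 2))
net4 = compile_reactions(build_relay(4))
stats4 = staircase_protocol(net4, levels, seed=1)
net2 = compile_reactions(build_relay(2))
stats2 = staircase_protocol(net2, levels, seed=2)

print("four-layer relay, intrinsic noise (counts of 100 per layer):")
print(" level |   L2p mean  std  |   L4p mean  std   SNR   Poisson-SNR")
for lv in (40, 80, 100, 120, 160, 200):
    s = stats4[levels.index(lv)]
    print(
        f"  {lv:>4} |  {s.mean[1]:7.1f} {s.std[1]:5.1f} |  {s.mean[3]:7.1f} "
        f"{s.std[3]:5.1f} {s.snr[3]:6.1f}   {poisson_snr(s.mean[3]):6.1f}"
    )

means, stds = [], []
for col in (1, 2):
    m = np.array([s.mean[col] for s in stats4])
    sd = np.array([s.std[col] for s in stats4])
    keep = (m >= 5) & (m <= 80)
    means.append(m[keep]); stds.append(sd[keep])
expo = noise_scaling_exponent(np.concatenate(means), np.concatenate(stds))

med4 = np.median([s.snr[3] for s in stats4 if s.input_level >= 100])
med2 = np.median([s.snr[1] for s in stats2 if s.input_level >= 100])
print(f"\nintermediate-layer noise-scaling exponent (pooled L2p/L3p, "
      f"means 5-80): {expo:.2f}  (0.5 = square-root scaling)")
print(f"median final-layer SNR over levels 100-200: four layers {med4:.1f}, "
      f"two layers {med2:.1f}")
print(
    "\nNoise is pushed backwards through the relay: intermediate layers absorb"
    "\nthe fluctuations around the threshold, so the final layer's SNR stays"
    "\nabove the Poisson line and improves with relay length."
)
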
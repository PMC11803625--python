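"""Extract per-cycle redox features from a synthetic 100-cycle voltammogram.

Generates a triangular-sweep voltammogram whose anodic/cathodic peaks sit at
0.30 / 0.134 V with peak currents decaying by exp(-0.01) per cycle, then runs
the full feature pipeline and fits the charge-decay constant back out.
"""

import numpy as np

from protoneuro import (
    CVSpec, extract_features, fit_charge_decay, gen_voltammogram, summarize,
)

vg = gen_voltammogram(CVSpec(alpha=0.01, n_cycles=100, noise_sd=0.05), seed=42)
features = extract_features(vg)
summary = summarize(features)

print(f"cycles analysed:     {summary.n_cycles}")
print(f"peak separation dEp: {summary.mean['delta_ep']:.3f} "
      f"+/- {summary.sd['delta_ep']:.3f} V")
print(f"peak current ratio:  {summary.mean['ratio']:.3f}")
print(f"hysteresis area:     {summary.mean['hyst_area']:.2f} uA*V")

q0, alpha, _ = fit_charge_decay([f.q for f in features])
print(f"charge decay:        Q0 = {q0:.2f} uC, alpha = {alpha:.4f} per cycle")
print()
print("dEp near 0.166 V marks fast, quasi-reversible electron transfer; the")
print("fitted alpha recovers the generator's 0.01 per-cycle current decay.")
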
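"""Recover pseudo individual patient data from a digitised Kaplan-Meier curve.

Published trials rarely share patient-level data; survival figures can be
digitised into (time, survival) points instead.  This example simulates a
trial arm, digitises its KM curve with a little plot-digitiser jitter,
reconstructs per-patient records, and measures how closely the reconstructed
curve tracks the original.
"""

import numpy as np

from pscea import ParametricSurvival, kaplan_meier, reconstruct_ipd
from pscea.synthetic import SimulationSpec, digitize_curve, simulate_ipd

truth = ParametricSurvival("loglogistic", (2.63812, 13.97048))  # OS-like curve
records = simulate_ipd(SimulationSpec(truth, n=200, seed=7))
km = kaplan_meier(records)

curve = digitize_curve(km, km.times, n_total=200, jitter_sd=0.003, seed=8)
rebuilt = reconstruct_ipd(curve)
km2 = kaplan_meier(rebuilt)

grid = np.union1d(km.times, km2.times)
sup = np.max(np.abs(km.evaluate(grid) - km2.evaluate(grid)))
print(f"digitised {len(curve.points)} points from a {len(records)}-patient arm")
print(f"reconstructed {len(rebuilt)} records, "
      f"{sum(r.event for r in rebuilt)} events")
print(f"sup-norm distance between original and reconstructed KM: {sup:.4f}")
print("(values near the 1/(2n) = 0.0025 quantisation limit mean the curve "
      "is recovered about as well as a step function allows)")
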
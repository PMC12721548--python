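"""Fit all five parametric families to simulated censored survival data.

Simulates individual patient data from a log-logistic distribution (shape 3.08,
scale 6.89 months — the fitted treatment-arm progression-free survival curve),
applies administrative censoring at 12 months, fits every family by censored
maximum likelihood, and ranks them by AIC.  The generating family should win.
"""

from pscea import ParametricSurvival, fit_all, rank_fits, select_best
from pscea.synthetic import SimulationSpec, simulate_ipd

truth = ParametricSurvival("loglogistic", (3.07673, 6.88847))
records = simulate_ipd(
    SimulationSpec(truth, n=800, censoring="administrative", t_max=12.0, seed=42)
)
n_events = sum(r.event for r in records)
print(f"simulated {len(records)} patients, {n_events} events "
      f"({100 * (1 - n_events / len(records)):.0f}% censored)\n")

fits = fit_all(records, seed=0)
print(rank_fits(fits).to_string(index=False))

best = select_best(fits)
a, b = best.model.params
print(f"\nAIC-best family: {best.model.family} (shape {a:.3f}, scale {b:.3f})")
print(f"median survival: {best.model.median():.2f} months "
      "(for the log-logistic the median equals the scale parameter)")
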
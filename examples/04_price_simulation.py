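"""Price-discount and threshold-price analysis for socazolimab.

The incremental cost is affine in the retained price fraction, with slope
equal to the drug's total discounted expenditure; that total is calibrated
from the published price-simulation table.  This example recomputes the ICER
at a ladder of price discounts (anchored on the published base-case
decomposition) and solves for the unit price at which the regimen just meets
the willingness-to-pay threshold.
"""

from pscea import CEResult, default_parameters, price_discount_analysis, threshold_price

params = default_parameters()
rep = params.reported
base = CEResult(rep.cost_treatment, rep.cost_control,
                rep.qaly_treatment, rep.qaly_control)
soca_total = params.soca_calibrated_total()
print(f"calibrated total discounted socazolimab spend: {soca_total:,.2f} CNY")
print(f"base-case ICER: {base.icer:,.2f} CNY/QALY\n")

table = price_discount_analysis(base, soca_total, [1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.3])
print(f"{'retained price':>15s}{'delta cost':>14s}{'ICER':>16s}")
for _, row in table.iterrows():
    print(f"{row['fraction']:>14.0%}{row['delta_cost']:>14,.2f}{row['icer']:>16,.2f}")

res = threshold_price(base, soca_total, unit_price=115.0, wtp=params.wtp)
print(f"\nAt the WTP of {params.wtp.wtp:,.0f} CNY/QALY the unit price must fall to "
      f"{res.price_per_mg:,.1f} CNY/mg "
      f"(a {100 * (1 - res.fraction):.0f}% discount from 115 CNY/mg).")
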
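# pscea — partitioned-survival cost-effectiveness analysis

`pscea` is a cost-utility model of **socazolimab (a PD-L1 inhibitor) plus
carboplatin/etoposide versus chemotherapy alone** as first-line treatment for
extensive-stage small-cell lung cancer (ES-SCLC), from the perspective of the
Chinese healthcare system. It is written for health economists and HTA
analysts as a reusable library: every stage — survival extrapolation, curve
reconstruction, the cohort engine, costing, and the sensitivity analyses — is
an importable, tested component.

## The model

**Survival extrapolation.** Progression-free survival (PFS) and overall
survival (OS) in each arm are modelled parametrically. Five families are
supported (exponential, Weibull, Gompertz, log-logistic, lognormal), fitted
to right-censored patient data by maximising

    ℓ(θ) = Σᵢ [ δᵢ · ln f(tᵢ; θ) + (1 − δᵢ) · ln S(tᵢ; θ) ]

with AIC/BIC-based family selection. The shipped base case uses log-logistic
fits, S(t) = 1 / (1 + (t/b)ᵃ), whose median equals the scale b. When only a
published Kaplan–Meier figure is available, `reconstruct_ipd` recovers
pseudo individual patient data from digitised curve coordinates (with or
without a numbers-at-risk table).

**Partitioned-survival cohort model.** Three health states; occupancy at
cycle time t comes directly from the curves:

    PFS(t)  = min(S_pfs(t), S_os(t))
    dead(t) = 1 − S_os(t)
    PD(t)   = S_os(t) − PFS(t)

21-day cycles over a 10-year horizon, 5% annual discounting applied as
(1.05)^(−t/12) with t in months (optionally with half-cycle correction).
QALYs accrue as Σ d(t)·[u_pfs·PFS(t) + u_pd·PD(t)]·Δt with u_pfs = 0.673 and
u_pd = 0.473; costs accrue per state (drugs and monitoring in PFS, monitoring
plus best supportive care in PD, adverse-event management once at entry).

**Decision analytics.** The base case reports ΔC, ΔE and the ICER = ΔC/ΔE
against a willingness-to-pay (WTP) threshold of 3× China's 2024 per-capita
GDP (3 × 95,797 = 287,391 CNY/QALY). Because the incremental cost is affine
in the retained fraction of the socazolimab price, price-discount and
threshold-price analyses are closed-form. One-way sensitivity analysis walks
each parameter across its published bounds; probabilistic sensitivity
analysis samples Gamma (costs), Beta (incidences, utilities) and Normal
(patient profile) distributions moment-matched to the bounds, and summarises
the draws as cost-effectiveness acceptability curves (CEAC).

**Socazolimab accrual.** The protocol rule (5 mg/kg every cycle until
progression, capped at two years) and the published incremental cost are
numerically irreconcilable; the package therefore defaults to a *calibrated*
mode that books the total discounted drug spend implied by the published
price-simulation table (43,232.73 CNY, the least-squares slope of incremental
cost against retained price fraction). Protocol mode is retained for
transparency. See `docs/methods.md` for the full account, including which
published figures the model does and does not reproduce.

## Worked example

```python
from pscea import base_case, default_parameters

params = default_parameters()
result = base_case(params, soca_mode="calibrated")
print(round(result.cost_control, 2), round(result.qaly_control, 4))
print(round(result.delta_cost, 2), round(result.delta_qaly, 4), round(result.icer, 2))
```

prints

```
60382.31 0.6943
44614.2 0.1161 384315.85
```

— the control arm costs 60,382 CNY and yields 0.694 QALYs; adding
socazolimab (at its calibrated expenditure) costs 44,614 CNY more and adds
0.116 QALYs, an ICER of ~384,316 CNY/QALY, well above the 287,391 CNY/QALY
threshold: the combination is not cost-effective at the current price. The
price ladder (`examples/04_price_simulation.py`) shows the unit price must
fall from 115 to about 77 CNY/mg to meet the threshold.

The `examples/` directory has one short script per capability (fitting,
KM reconstruction, base case, price simulation, sensitivity analyses), and
`pscea run` drives the whole pipeline from a YAML config on the command line.

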
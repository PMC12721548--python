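"""Cost-effectiveness analysis layer.

Builds on the partitioned-survival engine and the regimen costing to produce:

* the base-case incremental cost-effectiveness ratio (ICER),
* price-discount and threshold-price analyses (the incremental cost is affine
  in the retained price fraction, with slope equal to the drug's total
  discounted spend, so these are closed-form),
* one-way (tornado) sensitivity analysis over the parameter table's bounds,
* probabilistic sensitivity analysis by seeded Monte-Carlo sampling
  (Gamma for costs, Beta for incidences and utilities, Normal for the
  patient profile; method-of-moments from the min/max bounds read as a 95%
  interval, SD = (max - min)/3.92), and
* cost-effectiveness acceptability curves and their crossing point.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .costing import build_cost_schedule, scaled_calibrated_total
from .params import ParameterSet, WTPContext
from .psm import (
    CohortTrace,
    ModelSettings,
    accumulate_costs,
    accumulate_life_years,
    accumulate_qalys,
    build_trace,
)
from .survival import ParametricSurvival

__all__ = [
    "CEResult",
    "ThresholdResult",
    "PSADraws",
    "icer",
    "evaluate_arm",
    "base_case",
    "price_discount_analysis",
    "threshold_price",
    "owsa",
    "psa",
    "ceac",
    "ceac_crossing",
    "convention_grid",
]


@dataclass(frozen=True)
class CEResult:
    """Discounted totals per arm, increments, and the ICER."""

    cost_treatment: float
    cost_control: float
    qaly_treatment: float
    qaly_control: float

    @property
    def delta_cost(self) -> float:
        return self.cost_treatment - self.cost_control

    @property
    def delta_qaly(self) -> float:
        return self.qaly_treatment - self.qaly_control

    @property
    def icer(self) -> float:
        """Delta-cost per delta-QALY; NaN (flagged by ``dominance``) when undefined."""
        if self.delta_qaly == 0.0:
            return float("nan")
        return self.delta_cost / self.delta_qaly

    @property
    def dominance(self) -> str:
        """'none', 'dominant' (cheaper & better), 'dominated', or 'undefined'."""
        dc, de = self.delta_cost, self.delta_qaly
        if de == 0.0:
            return "undefined" if dc != 0.0 else "tie"
        if dc <= 0.0 and de > 0.0:
            return "dominant"
        if dc >= 0.0 and de < 0.0:
            return "dominated"
        return "none"

    @classmethod
    def from_increments(cls, delta_cost: float, delta_qaly: float) -> "CEResult":
        """A result carrying only increments (totals set to the increments)."""
        return cls(delta_cost, 0.0, delta_qaly, 0.0)


def icer(result: CEResult) -> float:
    """The incremental cost-effectiveness ratio of a :class:`CEResult`."""
    return result.icer


@functools.lru_cache(maxsize=64)
def _cached_trace(
    pfs: ParametricSurvival, os: ParametricSurvival, settings: ModelSettings
) -> CohortTrace:
    return build_trace(pfs, os, settings)


def _settings_for(params: ParameterSet, settings: ModelSettings | None) -> ModelSettings:
    base = settings if settings is not None else ModelSettings()
    return replace(base, annual_discount=params["discount_rate"])


def evaluate_arm(
    arm: str,
    params: ParameterSet,
    settings: ModelSettings | None = None,
    *,
    soca_mode: str = "calibrated",
) -> tuple[float, float]:
    """Discounted (cost, QALYs) for one arm under the current parameter set."""
    st = _settings_for(params, settings)
    trace = _cached_trace(
        params.survival_model(arm, "pfs"), params.survival_model(arm, "os"), st
    )
    costs = params.costs()
    profile = params.profile()
    soca_total = None
    if arm == "treatment" and soca_mode == "calibrated":
        soca_total = scaled_calibrated_total(
            params.soca_calibrated_total(), costs, profile
        )
    schedule = build_cost_schedule(
        arm, costs, profile, st, params.ae_profile(arm),
        soca_mode=soca_mode, soca_total_calibrated=soca_total,
    )
    cost = accumulate_costs(trace, schedule, st)
    qaly = accumulate_qalys(trace, params.utilities(), st)
    return cost, qaly


def base_case(
    params: ParameterSet,
    settings: ModelSettings | None = None,
    *,
    soca_mode: str = "calibrated",
) -> CEResult:
    """Run both arms under identical settings and assemble the CEResult."""
    ct, qt = evaluate_arm("treatment", params, settings, soca_mode=soca_mode)
    cc, qc = evaluate_arm("control", params, settings, soca_mode=soca_mode)
    return CEResult(ct, cc, qt, qc)


# ---------------------------------------------------------------------------
# Price simulation
# ---------------------------------------------------------------------------

def price_discount_analysis(
    base: CEResult,
    soca_total: float,
    fractions: Iterable[float],
) -> pd.DataFrame:
    """Recompute the ICER at retained price fractions of the socazolimab price.

    At retained fraction f the incremental cost falls by (1 - f) times the
    total discounted socazolimab expenditure; effects are unchanged.
    """
    if soca_total < 0:
        raise ValueError("soca_total must be >= 0")
    rows = []
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"retained fraction must lie in (0, 1], got {f}")
        dc = base.delta_cost - (1.0 - f) * soca_total
        res = CEResult(
            base.cost_treatment - (1.0 - f) * soca_total,
            base.cost_control,
            base.qaly_treatment,
            base.qaly_control,
        )
        rows.append(
            {
                "fraction": f,
                "cost_treatment": res.cost_treatment,
                "delta_cost": dc,
                "delta_qaly": base.delta_qaly,
                "icer": res.icer,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdResult:
    """Price at which the ICER meets the willingness-to-pay threshold."""

    feasible: bool
    fraction: float | None
    price_per_mg: float | None


def threshold_price(
    base: CEResult,
    soca_total: float,
    unit_price: float,
    wtp: WTPContext | float,
) -> ThresholdResult:
    """Solve delta_cost(1) - (1 - f) * soca_total = WTP * delta_qaly for f.

    Returns the retained fraction and the corresponding unit price; infeasible
    when even a 100% discount cannot reach the threshold.
    """
    if soca_total <= 0:
        raise ValueError("soca_total must be > 0")
    lam = wtp.wtp if isinstance(wtp, WTPContext) else float(wtp)
    f = 1.0 - (base.delta_cost - lam * base.delta_qaly) / soca_total
    if f > 1.0:
        # Already cost-effective at full price.
        return ThresholdResult(True, 1.0, unit_price)
    if f <= 0.0:
        return ThresholdResult(False, None, None)
    return ThresholdResult(True, f, f * unit_price)


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------

def owsa(
    params: ParameterSet,
    settings: ModelSettings | None = None,
    *,
    soca_mode: str = "calibrated",
    parameters: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's low and high bound, one at a time.

    Entries are sorted by descending span |ICER(high) - ICER(low)|.
    """
    names = list(parameters) if parameters is not None else params.names()
    base = base_case(params, settings, soca_mode=soca_mode)
    rows = []
    for name in names:
        pv = params.values[name]
        if pv.low > pv.high:
            raise ValueError(f"{name}: low bound exceeds high bound")
        icer_low = base_case(
            params.with_value(name, pv.low), settings, soca_mode=soca_mode
        ).icer
        icer_high = base_case(
            params.with_value(name, pv.high), settings, soca_mode=soca_mode
        ).icer
        rows.append(
            {
                "parameter": name,
                "low": pv.low,
                "high": pv.high,
                "icer_at_low": icer_low,
                "icer_at_high": icer_high,
                "span": abs(icer_high - icer_low),
            }
        )
    out = pd.DataFrame(rows).sort_values("span", ascending=False, kind="stable")
    out.attrs["base_icer"] = base.icer
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def _moment_matched_sampler(name: str, pv, rng: np.random.Generator):
    """Per-parameter sampler; bounds read as a 95% interval, SD = range/3.92."""
    m = pv.base
    sd = (pv.high - pv.low) / 3.92
    if pv.dist == "fixed" or sd == 0.0:
        return lambda n: np.full(n, m)
    if pv.dist == "gamma":
        if m <= 0:
            raise ValueError(f"{name}: gamma requires a positive mean")
        shape = (m / sd) ** 2
        scale = sd**2 / m
        return lambda n: rng.gamma(shape, scale, size=n)
    if pv.dist == "beta":
        if not 0.0 < m < 1.0:
            raise ValueError(f"{name}: beta requires mean in (0, 1), got {m}")
        nu = m * (1.0 - m) / sd**2 - 1.0
        if nu <= 0:
            raise ValueError(f"{name}: beta moment matching failed (variance too large)")
        return lambda n: rng.beta(m * nu, (1.0 - m) * nu, size=n)
    if pv.dist == "normal":
        # Support guard: the profile quantities are physically positive.
        return lambda n: np.maximum(rng.normal(m, sd, size=n), 1e-9)
    raise ValueError(f"{name}: unknown distribution {pv.dist!r}")


@dataclass(frozen=True)
class PSADraws:
    """Monte-Carlo cost/effect pairs per arm, with the seed that produced them."""

    draws: pd.DataFrame   # columns: cost_treatment, cost_control, qaly_treatment, qaly_control
    seed: int
    n: int

    @property
    def delta_cost(self) -> np.ndarray:
        return (self.draws["cost_treatment"] - self.draws["cost_control"]).to_numpy()

    @property
    def delta_qaly(self) -> np.ndarray:
        return (self.draws["qaly_treatment"] - self.draws["qaly_control"]).to_numpy()

    def ce_plane(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta_qaly": self.delta_qaly, "delta_cost": self.delta_cost}
        )


def psa(
    params: ParameterSet,
    n: int = 1000,
    seed: int = 2024,
    settings: ModelSettings | None = None,
    *,
    soca_mode: str = "calibrated",
) -> PSADraws:
    """Seeded probabilistic sensitivity analysis.

    Utilities and unit costs are shared between arms within a draw;
    adverse-event incidences are arm-specific parameters and are sampled
    independently.  The discount rate stays at its base value (its Beta tag in
    the source table has the wrong support for a rate and is ignored here).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    samples: dict[str, np.ndarray] = {}
    for name in params.names():
        sampler = _moment_matched_sampler(name, params.values[name], rng)
        samples[name] = sampler(n)
    # Independent Beta draws can invert the utility ordering in ~1% of draws;
    # the progressed state cannot be valued above progression-free, so clamp.
    inverted = samples["utility_pd"] > samples["utility_pfs"]
    if inverted.any():
        samples["utility_pd"] = np.minimum(
            samples["utility_pd"], samples["utility_pfs"]
        )

    records = []
    for i in range(n):
        draw = {name: float(col[i]) for name, col in samples.items()}
        p_i = params.with_values(draw)
        res = base_case(p_i, settings, soca_mode=soca_mode)
        records.append(
            (res.cost_treatment, res.cost_control, res.qaly_treatment, res.qaly_control)
        )
    frame = pd.DataFrame(
        records,
        columns=["cost_treatment", "cost_control", "qaly_treatment", "qaly_control"],
    )
    return PSADraws(draws=frame, seed=seed, n=n)


DEFAULT_WTP_GRID = np.arange(0.0, 600_000.0 + 1, 2_500.0)


def ceac(draws: PSADraws, wtp_grid: Sequence[float] | None = None) -> pd.DataFrame:
    """Acceptance probability of each arm across a willingness-to-pay grid.

    The treatment arm is accepted when its net monetary benefit strictly
    exceeds the control's (ties go to control); the two probabilities sum to 1
    at every threshold.
    """
    grid = np.asarray(
        DEFAULT_WTP_GRID if wtp_grid is None else list(wtp_grid), dtype=float
    )
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    dq = draws.delta_qaly
    dc = draws.delta_cost
    # NMB difference at threshold lam: lam * dq - dc > 0
    p_treat = np.array([(lam * dq - dc > 0).mean() for lam in grid])
    return pd.DataFrame(
        {"wtp": grid, "p_treatment": p_treat, "p_control": 1.0 - p_treat}
    )


def ceac_crossing(curves: pd.DataFrame) -> float | None:
    """WTP at which the treatment acceptance curve first reaches 0.5.

    Linear interpolation between grid points; ``None`` when the curve never
    reaches 0.5 on the grid.
    """
    wtp = curves["wtp"].to_numpy()
    p = curves["p_treatment"].to_numpy()
    above = np.nonzero(p >= 0.5)[0]
    if above.size == 0:
        return None
    j = int(above[0])
    if j == 0 or p[j] == 0.5:
        return float(wtp[j])
    w0, w1 = wtp[j - 1], wtp[j]
    p0, p1 = p[j - 1], p[j]
    return float(w0 + (0.5 - p0) / (p1 - p0) * (w1 - w0))


# ---------------------------------------------------------------------------
# Convention grid
# ---------------------------------------------------------------------------

def convention_grid(
    params: ParameterSet, settings: ModelSettings | None = None
) -> pd.DataFrame:
    """Discounted effect totals under {half-cycle on/off} x {QALY, life-year}.

    A validation aid: the published effect totals cannot be matched by the
    standard conventions, and this table documents what each cell yields.
    """
    rows = []
    base_settings = settings if settings is not None else ModelSettings()
    for hc in (False, True):
        st = replace(
            base_settings,
            half_cycle_correction=hc,
            annual_discount=params["discount_rate"],
        )
        per_arm = {}
        for arm in ("treatment", "control"):
            trace = _cached_trace(
                params.survival_model(arm, "pfs"),
                params.survival_model(arm, "os"),
                st,
            )
            per_arm[arm] = {
                "qaly": accumulate_qalys(trace, params.utilities(), st),
                "life_years": accumulate_life_years(trace, st),
            }
        for measure in ("qaly", "life_years"):
            rows.append(
                {
                    "half_cycle": hc,
                    "measure": measure,
                    "treatment": per_arm["treatment"][measure],
                    "control": per_arm["control"][measure],
                    "delta": per_arm["treatment"][measure] - per_arm["control"][measure],
                }
            )
    return pd.DataFrame(rows)
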
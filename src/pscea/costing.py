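"""Regimen costing: trial dosing rules and unit prices to per-cycle cost schedules.

Dosing follows the trial protocol: socazolimab 5 mg/kg on day 1 of every
3-week cycle (capped at 2 years), etoposide 100 mg/m^2 on days 1-3 and
carboplatin AUC 5 (Calvert formula, dose = AUC x (CCR + 25)) for the first
four cycles.  Monitoring (laboratory + radiology) accrues in every alive
cycle, best supportive care in every progressed cycle, and grade >=3 adverse
events with incidence >=5% are charged once at model entry as
incidence x unit management cost.

Socazolimab accrual has two modes.  ``protocol`` charges the per-cycle drug
cost against PFS occupancy up to the 2-year cap.  ``calibrated`` instead
books a single discounted expenditure equal to the total implied by the
published price-simulation table (the incremental cost falls linearly in the
retained price fraction, and the slope of that line is the drug's total
discounted spend); :func:`calibrate_socazolimab` recovers that slope by least
squares.  The two modes disagree by an order of magnitude — the protocol rule
cannot be reconciled with the published incremental cost — so ``calibrated``
is the default and the discrepancy is documented rather than resolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .psm import CostSchedule, ModelSettings

__all__ = [
    "PatientProfile",
    "CostTable",
    "AEProfile",
    "compute_dose",
    "adverse_event_cost",
    "socazolimab_cycle_cost",
    "chemo_cycle_cost",
    "build_cost_schedule",
    "calibrate_socazolimab",
]

#: 2-year socazolimab cap expressed in 21-day cycles: floor(730.5 / 21).
SOCA_CAP_CYCLES = 34

#: Chemotherapy is given in the first four treatment cycles.
CHEMO_CYCLES = (1, 4)


@dataclass(frozen=True)
class PatientProfile:
    """Average patient: weight (kg), body surface area (m^2), creatinine clearance (mL/min)."""

    weight: float = 59.0
    bsa: float = 1.72
    ccr: float = 90.0

    def __post_init__(self) -> None:
        if min(self.weight, self.bsa, self.ccr) <= 0:
            raise ValueError("profile fields must all be > 0")


@dataclass(frozen=True)
class CostTable:
    """Unit prices and per-event management costs, CNY."""

    socazolimab_per_mg: float = 115.0
    etoposide_per_mg: float = 3.16
    carboplatin_per_mg: float = 0.61
    laboratory_per_cycle: float = 166.0
    radiology_per_cycle: float = 300.0
    anemia: float = 1235.30
    leukocytopenia: float = 2309.99
    neutropenia: float = 2877.40
    thrombocytopenia: float = 822.89
    bsc_per_cycle: float = 3115.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def monitoring_per_cycle(self) -> float:
        return self.laboratory_per_cycle + self.radiology_per_cycle


@dataclass(frozen=True)
class AEProfile:
    """Whole-treatment probabilities of grade >=3 adverse events for one arm."""

    neutropenia: float
    leukocytopenia: float
    anemia: float
    thrombocytopenia: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"incidence {name} must lie in [0, 1], got {v}")


def compute_dose(rule: str, amount: float, profile: PatientProfile) -> float:
    """Dose in mg per administration.

    ``per_kg``: amount (mg/kg) x weight.  ``per_m2``: amount (mg/m^2) x BSA,
    per administration day.  ``calvert``: target AUC x (CCR + 25).
    """
    if amount <= 0:
        raise ValueError("dose amount must be > 0")
    if rule == "per_kg":
        return amount * profile.weight
    if rule == "per_m2":
        return amount * profile.bsa
    if rule == "calvert":
        return amount * (profile.ccr + 25.0)
    raise ValueError(f"unknown dosing rule {rule!r}")


def adverse_event_cost(profile: AEProfile, costs: CostTable) -> float:
    """One-off adverse-event management cost: sum of incidence x unit cost."""
    return (
        profile.neutropenia * costs.neutropenia
        + profile.leukocytopenia * costs.leukocytopenia
        + profile.anemia * costs.anemia
        + profile.thrombocytopenia * costs.thrombocytopenia
    )


def socazolimab_cycle_cost(costs: CostTable, profile: PatientProfile) -> float:
    """Socazolimab drug cost per 3-week cycle (5 mg/kg on day 1)."""
    return compute_dose("per_kg", 5.0, profile) * costs.socazolimab_per_mg


def chemo_cycle_cost(costs: CostTable, profile: PatientProfile) -> float:
    """Carboplatin + etoposide drug cost per chemotherapy cycle.

    Etoposide 100 mg/m^2 runs on three days of each cycle; carboplatin AUC 5
    is given once per cycle.
    """
    etoposide = compute_dose("per_m2", 100.0, profile) * 3.0 * costs.etoposide_per_mg
    carboplatin = compute_dose("calvert", 5.0, profile) * costs.carboplatin_per_mg
    return etoposide + carboplatin


def build_cost_schedule(
    arm: str,
    costs: CostTable,
    profile: PatientProfile,
    settings: ModelSettings,
    ae: AEProfile,
    *,
    soca_mode: str = "calibrated",
    soca_total_calibrated: float | None = None,
) -> CostSchedule:
    """Per-cycle, per-state cost vectors for one arm.

    PFS cycles carry monitoring, chemotherapy in cycles 1-4, and (treatment
    arm, protocol mode) socazolimab up to the 2-year cap; PD cycles carry
    monitoring plus best supportive care.  Drug costs ride on PFS occupancy,
    so patients who progress or die stop treatment automatically.
    """
    if arm not in ("treatment", "control"):
        raise ValueError(f"arm must be 'treatment' or 'control', got {arm!r}")
    if soca_mode not in ("protocol", "calibrated"):
        raise ValueError(f"soca_mode must be 'protocol' or 'calibrated', got {soca_mode!r}")

    n = settings.n_cycles + 1
    k = np.arange(n)
    pfs_cost = np.full(n, costs.monitoring_per_cycle, dtype=float)
    pd_cost = np.full(n, costs.monitoring_per_cycle + costs.bsc_per_cycle, dtype=float)

    chemo_mask = (k >= CHEMO_CYCLES[0]) & (k <= CHEMO_CYCLES[1])
    pfs_cost[chemo_mask] += chemo_cycle_cost(costs, profile)

    one_off = adverse_event_cost(ae, costs)
    if arm == "treatment":
        if soca_mode == "protocol":
            soca_mask = (k >= 1) & (k <= SOCA_CAP_CYCLES)
            pfs_cost[soca_mask] += socazolimab_cycle_cost(costs, profile)
        else:
            if soca_total_calibrated is None:
                raise ValueError("calibrated mode requires soca_total_calibrated")
            one_off += float(soca_total_calibrated)
    return CostSchedule(pfs_cost=pfs_cost, pd_cost=pd_cost, one_off=one_off)


def calibrate_socazolimab(
    price_discount_rows: Sequence[tuple[float, float]],
) -> float:
    """Total discounted socazolimab expenditure implied by a price-simulation table.

    Each row is (retained price fraction f, incremental cost at f).  Because
    the incremental cost is affine in f with slope equal to the drug's total
    discounted spend, the least-squares slope over >= 2 rows recovers that
    total exactly for exactly linear input.
    """
    rows = [(float(f), float(ic)) for f, ic in price_discount_rows]
    if len(rows) < 2:
        raise ValueError("need at least two (fraction, incremental cost) rows")
    f = np.array([r[0] for r in rows])
    ic = np.array([r[1] for r in rows])
    if np.allclose(f, f[0]):
        raise ValueError("price fractions must not all be identical")
    slope = np.polyfit(f, ic, 1)[0]
    return float(slope)


def scaled_calibrated_total(
    base_total: float,
    costs: CostTable,
    profile: PatientProfile,
    *,
    ref_price: float = 115.0,
    ref_weight: float = 59.0,
) -> float:
    """Rescale the calibrated socazolimab total to the current price and weight.

    The calibrated total is (mg per cycle x unit price) x an implied discounted
    cycle count, so it scales linearly in the unit price and in body weight
    relative to the anchor at which it was derived.
    """
    return (
        base_total
        * (costs.socazolimab_per_mg / ref_price)
        * (profile.weight / ref_weight)
    )
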
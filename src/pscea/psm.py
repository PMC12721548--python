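"""Partitioned-survival cohort engine.

Three health states — progression-free (PFS), progressed disease (PD), and
death — are occupied directly from the two survival curves: at cycle time t,

    PFS  = min(S_pfs(t), S_os(t))
    dead = 1 - S_os(t)
    PD   = S_os(t) - PFS        (clipped at 0 when the fitted curves cross)

Cycles are 21 days by default, the horizon 10 years, and both costs and QALYs
are discounted at 5% per year anchored in continuous time: the factor at cycle
start t months is (1 + r)^(-t/12).  Cycle 0 is a full cycle at discount 1, and
occupancy is evaluated at cycle start; an optional half-cycle correction
replaces the per-cycle reward with the trapezoidal average of adjacent cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import ParametricSurvival

__all__ = [
    "DAYS_PER_MONTH",
    "ModelSettings",
    "UtilitySet",
    "CohortTrace",
    "CostSchedule",
    "build_trace",
    "accumulate_qalys",
    "accumulate_life_years",
    "accumulate_costs",
]

log = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.4375


@dataclass(frozen=True)
class ModelSettings:
    """Cycle length, horizon, discounting, and the half-cycle switch."""

    cycle_days: float = 21.0
    horizon_years: float = 10.0
    annual_discount: float = 0.05
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.cycle_days <= 0:
            raise ValueError("cycle_days must be > 0")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be > 0")
        if not 0.0 <= self.annual_discount <= 0.08:
            raise ValueError("annual_discount must lie in [0, 0.08]")

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / DAYS_PER_MONTH

    @property
    def n_cycles(self) -> int:
        """Number of full cycle steps after cycle 0."""
        return int(np.floor(self.horizon_years * 365.25 / self.cycle_days))


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utilities per year of occupancy."""

    u_pfs: float = 0.673
    u_pd: float = 0.473

    def __post_init__(self) -> None:
        if not 0.0 <= self.u_pd <= self.u_pfs <= 1.0:
            raise ValueError(
                f"require 0 <= u_pd <= u_pfs <= 1, got ({self.u_pfs}, {self.u_pd})"
            )


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy and discount factors (rows = cycles 0..n_cycles)."""

    time_months: np.ndarray
    occupancy_pfs: np.ndarray
    occupancy_pd: np.ndarray
    occupancy_death: np.ndarray
    discount_factor: np.ndarray
    n_clipped: int = 0

    def __len__(self) -> int:
        return len(self.time_months)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self)),
                "time_months": self.time_months,
                "pfs": self.occupancy_pfs,
                "pd": self.occupancy_pd,
                "death": self.occupancy_death,
                "discount": self.discount_factor,
            }
        )


@dataclass(frozen=True)
class CostSchedule:
    """Per-cycle per-state costs for one arm plus a one-off entry cost.

    ``pfs_cost`` and ``pd_cost`` are either scalars (constant per cycle) or
    vectors aligned with the trace; all amounts are CNY per cycle applied per
    person occupying the state.
    """

    pfs_cost: np.ndarray | float
    pd_cost: np.ndarray | float
    one_off: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pfs_cost", "pd_cost"):
            v = getattr(self, name)
            arr = np.atleast_1d(np.asarray(v, dtype=float))
            if np.any(arr < 0):
                raise ValueError(f"{name} entries must be >= 0")
        if self.one_off < 0:
            raise ValueError("one_off must be >= 0")

    def _vector(self, which: str, n: int) -> np.ndarray:
        v = getattr(self, which)
        arr = np.asarray(v, dtype=float)
        if arr.ndim == 0:
            return np.full(n, float(arr))
        if len(arr) < n:
            raise ValueError(
                f"{which} has {len(arr)} entries but the trace has {n} cycles"
            )
        return arr[:n]


def build_trace(
    pfs: ParametricSurvival,
    os: ParametricSurvival,
    settings: ModelSettings,
) -> CohortTrace:
    """Evaluate state occupancy on the cycle grid from the two curves."""
    k = np.arange(settings.n_cycles + 1)
    t = k * settings.cycle_months
    s_pfs = np.asarray(pfs.survival(t))
    s_os = np.asarray(os.survival(t))
    occ_pfs = np.minimum(s_pfs, s_os)
    n_clipped = int(np.sum(s_pfs > s_os))
    if n_clipped:
        log.info("PFS curve exceeds OS at %d of %d cycles; PD clipped to 0",
                 n_clipped, len(t))
    occ_death = 1.0 - s_os
    occ_pd = np.clip(s_os - occ_pfs, 0.0, None)
    disc = (1.0 + settings.annual_discount) ** (-(t / 12.0))
    return CohortTrace(
        time_months=t,
        occupancy_pfs=occ_pfs,
        occupancy_pd=occ_pd,
        occupancy_death=occ_death,
        discount_factor=disc,
        n_clipped=n_clipped,
    )


def _per_cycle_sum(values: np.ndarray, settings: ModelSettings) -> float:
    """Sum per-cycle contributions, trapezoidal when half-cycle correction is on."""
    if settings.half_cycle_correction:
        return float(np.sum((values[:-1] + values[1:]) / 2.0))
    return float(np.sum(values))


def accumulate_qalys(
    trace: CohortTrace,
    utilities: UtilitySet,
    settings: ModelSettings,
) -> float:
    """Discounted QALYs per patient over the trace."""
    reward = (
        utilities.u_pfs * trace.occupancy_pfs
        + utilities.u_pd * trace.occupancy_pd
    ) * trace.discount_factor
    return _per_cycle_sum(reward, settings) * settings.cycle_months / 12.0


def accumulate_life_years(trace: CohortTrace, settings: ModelSettings) -> float:
    """Discounted life-years per patient (utilities set to 1)."""
    alive = (trace.occupancy_pfs + trace.occupancy_pd) * trace.discount_factor
    return _per_cycle_sum(alive, settings) * settings.cycle_months / 12.0


def accumulate_costs(
    trace: CohortTrace,
    schedule: CostSchedule,
    settings: ModelSettings | None = None,
) -> float:
    """Discounted total cost per patient: per-state accrual plus one-off costs.

    The one-off component is applied at model entry (undiscounted).
    """
    n = len(trace)
    pfs_c = schedule._vector("pfs_cost", n)
    pd_c = schedule._vector("pd_cost", n)
    per_cycle = (
        pfs_c * trace.occupancy_pfs + pd_c * trace.occupancy_pd
    ) * trace.discount_factor
    if settings is not None and settings.half_cycle_correction:
        total = float(np.sum((per_cycle[:-1] + per_cycle[1:]) / 2.0))
    else:
        total = float(np.sum(per_cycle))
    return total + float(schedule.one_off)
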
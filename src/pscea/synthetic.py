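"""Synthetic inputs: censored IPD, digitised curve point sets, parameter fixtures.

The trial's individual patient data are not public, so every pipeline input
can be generated here instead: event times drawn by inverse-CDF from any of
the parametric families (with administrative or random-exponential
censoring), digitised Kaplan-Meier point sets with truncated-Gaussian jitter
emulating plot-digitiser output, and the complete built-in parameter table.
All stochastic operations take explicit seeds and are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .km import DigitizedCurve, KMCurve
from .params import ParameterSet, default_parameters
from .survival import IPDRecord, ParametricSurvival

__all__ = ["SimulationSpec", "simulate_ipd", "digitize_curve", "fixture_parameter_table"]


@dataclass(frozen=True)
class SimulationSpec:
    """What to simulate: a survival model, a sample size, and a censoring scheme.

    ``censoring`` is one of ``"none"``, ``"administrative"`` (requires
    ``t_max``), or ``"random_exponential"`` (requires ``rate``).
    """

    model: ParametricSurvival
    n: int
    censoring: str = "none"
    t_max: float | None = None
    rate: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.censoring not in ("none", "administrative", "random_exponential"):
            raise ValueError(f"unknown censoring scheme {self.censoring!r}")
        if self.censoring == "administrative" and (self.t_max is None or self.t_max < 0):
            raise ValueError("administrative censoring requires t_max >= 0")
        if self.censoring == "random_exponential" and (self.rate is None or self.rate <= 0):
            raise ValueError("random_exponential censoring requires rate > 0")


def simulate_ipd(spec: SimulationSpec) -> list[IPDRecord]:
    """Draw censored time-to-event records per the simulation spec (inverse-CDF)."""
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n)
    times = np.asarray(spec.model.quantile(u), dtype=float)
    if spec.censoring == "none":
        return [IPDRecord(float(t), 1) for t in times]
    if spec.censoring == "administrative":
        t_max = float(spec.t_max)  # type: ignore[arg-type]
        return [
            IPDRecord(min(float(t), t_max), int(t <= t_max)) for t in times
        ]
    cens = rng.exponential(scale=1.0 / float(spec.rate), size=spec.n)  # type: ignore[arg-type]
    return [
        IPDRecord(float(min(t, c)), int(t <= c)) for t, c in zip(times, cens)
    ]


def digitize_curve(
    source: ParametricSurvival | KMCurve,
    times,
    n_total: int,
    jitter_sd: float = 0.0,
    seed: int = 0,
    risk_table=None,
) -> DigitizedCurve:
    """Emulate plot digitisation: sample survival at grid times, jitter, re-monotonise.

    Jitter is Gaussian with SD ``jitter_sd``, truncated so survival stays in
    [0, 1]; ``jitter_sd=0`` reproduces the curve exactly at the grid points.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    t = np.asarray(list(times), dtype=float)
    if t.size == 0:
        raise ValueError("digitisation grid must be non-empty")
    if isinstance(source, KMCurve):
        s = np.asarray(source.evaluate(t), dtype=float)
    else:
        s = np.asarray(source.survival(t), dtype=float)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        s = np.clip(s + rng.normal(0.0, jitter_sd, size=s.shape), 0.0, 1.0)
        # Re-monotonise: a survival curve cannot rise.
        s = np.minimum.accumulate(s)
    return DigitizedCurve(
        points=np.column_stack([t, s]), n_total=n_total, risk_table=risk_table
    )


def fixture_parameter_table() -> ParameterSet:
    """The built-in parameter table (costs, incidences, utilities, profile, WTP)."""
    return default_parameters()
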
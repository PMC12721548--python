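"""Kaplan–Meier estimation and pseudo-IPD reconstruction from digitised curves.

Published survival figures can be digitised into (time, survival) point lists;
:func:`reconstruct_ipd` inverts the product-limit estimator to recover a set of
per-patient time/event records whose KM curve matches the digitised one.  When
numbers-at-risk are available they anchor interval censoring (the approach of
Guyot et al.'s reconstruction algorithm); without them, censoring is assumed to
occur only after the last digitised point, which biases late-time extrapolation
toward the event-heavy reading of the curve tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .survival import IPDRecord

__all__ = ["KMCurve", "DigitizedCurve", "kaplan_meier", "reconstruct_ipd"]

# Digitiser jitter this small is snapped flat; larger monotonicity violations
# are treated as corrupt input.
SNAP_TOLERANCE = 0.005


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: right-continuous step function, S(0) = 1."""

    times: np.ndarray       # distinct event times, increasing
    survival: np.ndarray    # estimate just after each event time
    n_at_risk: np.ndarray   # at risk just before each event time
    n_events: np.ndarray    # events at each event time

    def evaluate(self, t) -> np.ndarray:
        """Step-function evaluation Ŝ(t) (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if len(self.times) == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out


def kaplan_meier(data: Sequence[IPDRecord]) -> KMCurve:
    """Product-limit estimator Ŝ(t) = Π (1 − d_i/n_i) over event times ≤ t."""
    recs = list(data)
    if not recs:
        raise ValueError("kaplan_meier requires at least one record")
    t = np.array([r.time for r in recs], dtype=float)
    e = np.array([r.event for r in recs], dtype=int)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]

    event_times = np.unique(t[e == 1])
    n = len(t)
    surv = []
    at_risk = []
    d_counts = []
    s = 1.0
    for et in event_times:
        n_i = int(np.sum(t >= et))
        d_i = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        d_counts.append(d_i)
        surv.append(s)
    return KMCurve(
        times=event_times,
        survival=np.array(surv, dtype=float),
        n_at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(d_counts, dtype=int),
    )


@dataclass
class DigitizedCurve:
    """Digitised survival coordinates for one arm.

    ``points`` is an (n, 2) array of (time, survival); times strictly increase
    and survival is non-increasing up to a small snapping tolerance.  ``n_total``
    is the arm's sample size (required: it is not recoverable from the curve).
    ``risk_table`` optionally lists (time, number at risk) rows.
    """

    points: np.ndarray
    n_total: int
    risk_table: np.ndarray | None = None
    snapped: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
            raise ValueError("points must be a non-empty (n, 2) array of (t, s)")
        if np.any(np.diff(pts[:, 0]) <= 0):
            raise ValueError("digitized times must be strictly increasing")
        if np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > 1):
            raise ValueError("survival values must lie in [0, 1]")
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")
        # Monotonicity repair: small upticks are digitiser jitter.
        s = pts[:, 1].copy()
        snapped = 0
        for i in range(1, len(s)):
            if s[i] > s[i - 1]:
                if s[i] - s[i - 1] <= SNAP_TOLERANCE:
                    s[i] = s[i - 1]
                    snapped += 1
                else:
                    raise ValueError(
                        f"survival rises by {s[i] - s[i - 1]:.4f} at t={pts[i, 0]:.4f}; "
                        f"exceeds the snap tolerance {SNAP_TOLERANCE}"
                    )
        pts[:, 1] = s
        self.points = pts
        self.snapped = snapped
        if self.risk_table is not None:
            rt = np.asarray(self.risk_table, dtype=float)
            if rt.ndim != 2 or rt.shape[1] != 2:
                raise ValueError("risk_table must be an (m, 2) array of (t, n_at_risk)")
            self.risk_table = rt


def _reconstruct_simple(curve: DigitizedCurve) -> list[IPDRecord]:
    """No risk table: invert the product limit, censor survivors at the end."""
    n = curve.n_total
    t_pts, s_pts = curve.points[:, 0], curve.points[:, 1]
    records: list[IPDRecord] = []
    at_risk = n
    s_prev = 1.0
    for t, s in zip(t_pts, s_pts):
        if at_risk <= 0:
            break
        d = int(round(at_risk * (1.0 - s / s_prev))) if s_prev > 0 else at_risk
        d = min(max(d, 0), at_risk)
        if d:
            records.extend(IPDRecord(float(t), 1) for _ in range(d))
            s_prev *= 1.0 - d / at_risk
            at_risk -= d
    records.extend(IPDRecord(float(t_pts[-1]), 0) for _ in range(at_risk))
    return records


def _reconstruct_with_risk_table(curve: DigitizedCurve) -> list[IPDRecord]:
    """Risk-table-anchored reconstruction (Guyot-style interval accounting).

    Within each risk-table interval the censor count is found iteratively:
    censor times are spread evenly across the interval, event counts are
    re-derived from the curve drops with the censor-adjusted at-risk numbers,
    and the count is corrected until the end-of-interval at-risk matches the
    table.
    """
    t_pts, s_pts = curve.points[:, 0], curve.points[:, 1]
    rt = curve.risk_table
    assert rt is not None
    rt_t, rt_n = rt[:, 0], rt[:, 1].astype(int)
    if rt_n[0] != curve.n_total:
        raise ValueError("first risk-table entry must equal n_total")

    records: list[IPDRecord] = []
    at_risk = int(rt_n[0])
    s_running = 1.0
    for i in range(len(rt_t)):
        lo = rt_t[i]
        hi = rt_t[i + 1] if i + 1 < len(rt_t) else float(t_pts[-1]) + 1.0
        target_next = int(rt_n[i + 1]) if i + 1 < len(rt_t) else None
        mask = (t_pts >= lo) & (t_pts < hi)
        seg_t, seg_s = t_pts[mask], s_pts[mask]

        n_cens = 0
        best: tuple[list, list, int, float] | None = None
        for _ in range(25):
            cens_times = list(np.linspace(lo, hi, n_cens + 2)[1:-1]) if n_cens else []
            # Walk events and censors in time order, inverting the product limit.
            n_cur = at_risk
            s_prev = s_running
            events: list[tuple[float, int]] = []
            ci = 0
            for t, s in zip(seg_t, seg_s):
                while ci < len(cens_times) and cens_times[ci] < t and n_cur > 0:
                    n_cur -= 1
                    ci += 1
                if n_cur <= 0:
                    break
                d = int(round(n_cur * (1.0 - s / s_prev))) if s_prev > 0 else n_cur
                d = min(max(d, 0), n_cur)
                if d:
                    events.append((float(t), d))
                    s_prev *= 1.0 - d / n_cur
                    n_cur -= d
            n_cur -= len(cens_times) - ci  # censors after the last event
            best = (events, cens_times, n_cur, s_prev)
            if target_next is None or n_cur == target_next:
                break
            n_cens = max(n_cens + (n_cur - target_next), 0)
        assert best is not None
        events, cens_times, n_end, s_end = best
        for t, d in events:
            records.extend(IPDRecord(t, 1) for _ in range(d))
        records.extend(IPDRecord(float(ct), 0) for ct in cens_times)
        s_running = s_end
        at_risk = target_next if target_next is not None else max(n_end, 0)
    if at_risk > 0:
        records.extend(IPDRecord(float(t_pts[-1]), 0) for _ in range(at_risk))
    return records


def reconstruct_ipd(curve: DigitizedCurve) -> list[IPDRecord]:
    """Recover ``n_total`` pseudo-IPD records consistent with a digitised curve.

    For an exactly digitised KM step curve the round trip is exact up to the
    1/(2n) quantisation of the product-limit estimator.
    """
    if curve.risk_table is not None:
        records = _reconstruct_with_risk_table(curve)
    else:
        records = _reconstruct_simple(curve)
    if len(records) != curve.n_total:
        # Quantisation may over/under-shoot by a record on noisy input; pad or
        # trim censored records at the last time to honour the n_total contract.
        last_t = float(curve.points[-1, 0])
        while len(records) < curve.n_total:
            records.append(IPDRecord(last_t, 0))
        if len(records) > curve.n_total:
            cens_idx = [i for i, r in enumerate(records) if r.event == 0]
            drop = set(cens_idx[curve.n_total - len(records):])
            records = [r for i, r in enumerate(records) if i not in drop]
    return records
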
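"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published KM plots plus their number-at-risk tables carry enough information
to rebuild event-level records whose product-limit estimator reproduces the
published curve.  ``reconstruct_ipd`` implements the iterative allocation
algorithm of Guyot et al. (BMC Med Res Methodol 2012): within each interval
between consecutive number-at-risk times, censorings are assumed uniformly
spread, their count is adjusted until the implied number at risk matches the
published one, and events at each digitized step follow from the KM ratio.

All times are in months.  Pseudo-IPD are plain DataFrames with columns
``time_months``, ``event`` (1/0) and ``arm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = ["DigitizedCurve", "ReconstructionError", "reconstruct_ipd", "km_estimate"]


class ReconstructionError(ValueError):
    pass


@dataclass
class DigitizedCurve:
    """Digitized KM step coordinates plus the number-at-risk table.

    ``points``: (time, survival) pairs, survival in [0,1] non-increasing,
    first point (0, 1.0).  ``risk_table``: (time, n at risk) pairs with
    non-increasing integer counts.  ``total_events``: optionally the reported
    total number of events, used to rescale the allocation.
    """

    points: np.ndarray
    risk_table: np.ndarray
    total_events: int | None = None
    arm: str = "arm"

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        rt = np.atleast_2d(np.asarray(self.risk_table, dtype=float))
        if pts.shape[1] != 2 or rt.shape[1] != 2:
            raise ValueError("points and risk_table must be (n, 2) arrays")
        if not (pts[0, 0] == 0.0 and abs(pts[0, 1] - 1.0) < 1e-9):
            raise ValueError("first digitized point must be (0, 1.0)")
        if np.any(np.diff(pts[:, 0]) < 0) or np.any(np.diff(rt[:, 0]) <= 0):
            raise ValueError("times must be sorted")
        if np.any((pts[:, 1] < -1e-9) | (pts[:, 1] > 1 + 1e-9)):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(rt[:, 1]) > 0):
            raise ValueError("at-risk counts must be non-increasing")
        if len(rt) < 1 or rt[0, 1] < 1:
            raise ValueError("risk table must start with a positive count")
        # absorb digitization noise: snap into [0,1] and monotonize
        pts[:, 1] = np.minimum.accumulate(np.clip(pts[:, 1], 0.0, 1.0))
        self.points = pts
        self.risk_table = rt


def km_estimate(data: pd.DataFrame) -> np.ndarray:
    """Product-limit estimator as ordered (time, survival) step coordinates.

    Starts at (0, 1); steps only at event times.  All-censored data yield the
    constant-1 function.
    """
    if len(data) == 0:
        raise ValueError("empty data")
    t = np.asarray(data["time_months"], dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, np.asarray(data["event"], dtype=int))
    sf = kmf.survival_function_
    times = np.asarray(sf.index, dtype=float)
    surv = np.asarray(sf.iloc[:, 0], dtype=float)
    # keep t=0 and actual steps only
    keep = np.concatenate([[True], np.diff(surv) < 0])
    out = np.column_stack([times[keep], surv[keep]])
    if out[0, 0] != 0.0:
        out = np.vstack([[0.0, 1.0], out])
    return out


def _interval_alloc(times, surv, s_entry, n_entry, n_cens):
    """Allocate events/censorings on one inter-risk interval.

    Censorings (``n_cens`` of them) are spread uniformly over the interval;
    events at each digitized step follow from the KM ratio.  Returns per-step
    event counts, per-step censor counts, number at risk after the interval,
    and the KM survival at interval end.
    """
    k = len(times)
    cens = np.zeros(k, dtype=int)
    if n_cens > 0 and k > 0:
        # uniform spread over the interval on the digitized grid
        pos = (np.arange(n_cens) + 0.5) / n_cens * k
        idx = np.minimum(pos.astype(int), k - 1)
        for i in idx:
            cens[i] += 1
    events = np.zeros(k, dtype=int)
    n = n_entry
    s = s_entry
    for i in range(k):
        if n <= 0 or s <= 0:
            break
        target = surv[i]
        # KM step: S_i = S_prev * (1 - d/n)
        d = int(round(n * (1.0 - target / s))) if s > 0 else 0
        d = max(0, min(d, n))
        events[i] = d
        if d > 0:
            s = s * (1.0 - d / n)
        n -= d
        c = min(cens[i], n)
        cens[i] = c
        n -= c
    return events, cens, n, s


def reconstruct_ipd(curve: DigitizedCurve) -> pd.DataFrame:
    """Guyot-style reconstruction of pseudo-IPD from a digitized curve.

    The returned records reproduce the digitized survival values under the
    KM estimator and are consistent with the number-at-risk table.  The
    output is deterministic.
    """
    pts = curve.points
    rt = curve.risk_table
    if len(rt) < 2:
        # single risk time: everyone censored at window end unless events known
        rt = np.vstack([rt, [max(pts[-1, 0], rt[0, 0]), rt[-1, 1]]])

    t_risk = rt[:, 0]
    n_risk = rt[:, 1].astype(int)

    records_t: list[np.ndarray] = []
    records_e: list[np.ndarray] = []

    n = int(n_risk[0])
    s = 1.0
    for j in range(len(t_risk) - 1):
        lo, hi = t_risk[j], t_risk[j + 1]
        sel = (pts[:, 0] > lo) & (pts[:, 0] <= hi)
        times = pts[sel, 0]
        surv = pts[sel, 1]
        if j == 0 and pts[0, 0] == lo:
            pass  # the (0,1) anchor carries no step
        n_target = int(n_risk[j + 1])
        # search the censoring count that lands on the published at-risk number
        best = None
        max_c = n
        guess = max(0, n - n_target - int(round(n * (1 - (surv[-1] / s if len(surv) else 1.0)))))
        order = sorted(range(max_c + 1), key=lambda c: abs(c - guess))
        for c in order:
            ev, ce, n_end, s_end = _interval_alloc(times, surv, s, n, c)
            miss = abs(n_end - n_target)
            if best is None or miss < best[0]:
                best = (miss, ev, ce, n_end, s_end)
            if miss == 0:
                break
        miss, ev, ce, n_end, s_end = best
        if miss > max(2, 0.05 * n_risk[0]) and len(times):
            raise ReconstructionError(
                f"risk table inconsistent with survival steps in interval "
                f"({lo}, {hi}]: implied at-risk {n_end}, published {n_target}"
            )
        for i, tt in enumerate(times):
            if ev[i]:
                records_t.append(np.full(ev[i], tt)); records_e.append(np.ones(ev[i]))
            if ce[i]:
                # uniform censor placement inside the step's neighbourhood
                prev_t = lo if i == 0 else times[i - 1]
                ct = prev_t + (tt - prev_t) * (np.arange(ce[i]) + 0.5) / ce[i]
                records_t.append(ct); records_e.append(np.zeros(ce[i]))
        # censor down to the published at-risk count if steps alone undershoot
        extra = n_end - n_target
        if extra > 0:
            ct = lo + (hi - lo) * (np.arange(extra) + 0.5) / extra
            records_t.append(ct); records_e.append(np.zeros(extra))
            n_end = n_target
        n, s = n_end, s_end

    # everyone still at risk is administratively censored at the window end
    if n > 0:
        records_t.append(np.full(n, t_risk[-1]))
        records_e.append(np.zeros(n))

    times = np.concatenate(records_t) if records_t else np.empty(0)
    events = np.concatenate(records_e).astype(int) if records_e else np.empty(0, int)

    if curve.total_events is not None:
        have = int(events.sum())
        want = int(curve.total_events)
        if have != want and have > 0:
            idx_ev = np.flatnonzero(events == 1)
            idx_ce = np.flatnonzero(events == 0)
            if want < have:
                # flip the latest events to censorings
                flip = idx_ev[np.argsort(times[idx_ev])][-(have - want):]
                events[flip] = 0
            else:
                flip = idx_ce[np.argsort(times[idx_ce])][-(want - have):]
                events[flip] = 1

    order = np.argsort(times, kind="mergesort")
    out = pd.DataFrame(
        {
            "time_months": times[order],
            "event": events[order],
            "arm": curve.arm,
        }
    )
    return out.reset_index(drop=True)
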
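"""Synthetic right-censored survival samples and digitized-curve fixtures.

Individual patient data from the underlying trial are not public, so every
input the reconstruction/fitting pipeline needs is generated here: event
times drawn by inverse-CDF sampling from a stated parametric family, an
administrative follow-up cutoff plus optional uniform dropout, and
digitized-KM fixtures (step values at a reporting grid plus exact
number-at-risk counts) that act as round-trip partners for
:func:`psmcea.reconstruct.reconstruct_ipd`.

Default sample sizes mirror the scale of a two-arm phase-3 trial
(~250 patients per arm); the trial's exact arm sizes and censoring pattern
are not public, so these fixtures are statistical stand-ins, not data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reconstruct import DigitizedCurve, km_estimate
from .survival import ParametricSurvival

__all__ = ["SimulationRecipe", "simulate_ipd", "make_km_fixture"]


@dataclass(frozen=True)
class SimulationRecipe:
    """One arm's generating model and censoring scheme."""

    model: ParametricSurvival
    n: int = 250
    cutoff_months: float = float("inf")   # administrative censoring
    dropout_fraction: float = 0.0         # chance of uniform dropout before cutoff
    arm: str = "arm"
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if not self.cutoff_months > 0:
            raise ValueError("cutoff must be positive")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout fraction must lie in [0, 1)")


def simulate_ipd(recipe: SimulationRecipe) -> pd.DataFrame:
    """Right-censored sample: time_months, event, arm (deterministic in seed)."""
    rng = np.random.default_rng(recipe.seed)
    event_t = recipe.model.rvs(recipe.n, rng)
    cens_t = np.full(recipe.n, recipe.cutoff_months)
    if recipe.dropout_fraction > 0:
        drops = rng.uniform(size=recipe.n) < recipe.dropout_fraction
        max_t = recipe.cutoff_months if np.isfinite(recipe.cutoff_months) else float(
            np.max(event_t[np.isfinite(event_t)], initial=1.0)
        )
        dropout_t = rng.uniform(0.0, max_t, size=recipe.n)
        cens_t = np.where(drops, np.minimum(cens_t, dropout_t), cens_t)
    time = np.minimum(event_t, cens_t)
    event = (event_t <= cens_t).astype(int)
    # guard against zero times (possible only for pathological parameters)
    time = np.maximum(time, 1e-6)
    return pd.DataFrame({"time_months": time, "event": event, "arm": recipe.arm})


def make_km_fixture(
    data: pd.DataFrame,
    report_times,
    noise: float = 0.0,
    seed: int = 0,
    total_events: bool = True,
) -> DigitizedCurve:
    """Digitized-curve fixture: KM step values plus exact at-risk counts.

    ``report_times`` is the grid at which the curve is 'read off' (the
    number-at-risk table uses the same grid).  ``noise`` perturbs the
    survival readings with N(0, noise) digitization error, after which the
    curve constructor re-monotonizes.
    """
    if len(data) == 0:
        raise ValueError("empty data")
    grid = np.asarray(report_times, dtype=float)
    if grid.ndim != 1 or len(grid) < 1 or grid[0] != 0.0:
        raise ValueError("report grid must start at 0")
    t = np.asarray(data["time_months"], dtype=float)
    if grid[-1] > t.max() + 1e-9:
        raise ValueError("report grid extends beyond the observation window")

    km = km_estimate(data)

    def step_at(x):
        idx = np.searchsorted(km[:, 0], x, side="right") - 1
        return km[np.maximum(idx, 0), 1]

    surv = step_at(grid)
    if noise > 0:
        rng = np.random.default_rng(seed)
        surv = surv + rng.normal(0.0, noise, size=len(surv))
        surv[0] = 1.0
    at_risk = np.array([(t >= g).sum() for g in grid])
    # include intermediate event-time points for reconstruction fidelity
    ev_times = np.unique(t[np.asarray(data["event"]) == 1])
    ev_times = ev_times[(ev_times > 0) & (ev_times <= grid[-1])]
    pt_times = np.unique(np.concatenate([grid, ev_times]))
    pt_surv = step_at(pt_times)
    if noise > 0:
        rng2 = np.random.default_rng(seed + 1)
        pt_surv = pt_surv + rng2.normal(0.0, noise, size=len(pt_surv))
        pt_surv[pt_times == 0.0] = 1.0
    n_events = int(((np.asarray(data["event"]) == 1) & (t <= grid[-1])).sum())
    return DigitizedCurve(
        points=np.column_stack([pt_times, pt_surv]),
        risk_table=np.column_stack([grid, at_risk]),
        total_events=n_events if total_events else None,
        arm=str(data["arm"].iloc[0]) if "arm" in data else "arm",
    )
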
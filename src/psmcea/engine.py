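"""Discrete-time three-state partitioned survival engine.

State occupancy is read directly off the overall-survival (OS) and
progression-free-survival (PFS) curves: PF = min(S_PFS, S_OS),
PD = S_OS - PF, dead = 1 - S_OS.  The cohort is evaluated on a 21-day cycle
grid (one treatment cycle) with occupancy taken at cycle midpoints — a
midpoint rule standing in for half-cycle correction — and each cycle's cost
and QALY flow discounted at the midpoint.

Accrual rules:

* Drug acquisition costs accrue on on-treatment occupancy.  Treatment is
  dispensed in whole 3-week cycles, so each drug's cap (reimbursement rule
  and/or clinical protocol) is realized as a number of complete cycles.
* The chemotherapy administration fee follows chemotherapy exposure (drugs
  flagged ``attracts_admin``), not the whole arm.
* PF non-medication services accrue on PF occupancy; supportive care, PD
  drug and PD administration on PD occupancy; terminal care is one month's
  rate per incident death.
* Taiwan's NHI pays non-medication services at a conversion factor (TWD per
  fee-schedule point); every non-drug rate is multiplied by it.  Drug
  acquisition costs are paid point-for-point.
* Grade >=3 adverse events occur in the first cycle only: a one-off
  management cost and a utility decrement lasting one full cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import ParametricSurvival

__all__ = [
    "DAYS_PER_MONTH",
    "ModelSettings",
    "DrugExposure",
    "AdverseEvent",
    "StrategyDefinition",
    "Trace",
    "AccrualResult",
    "state_occupancy",
    "treatment_exposure",
    "run_model",
]

DAYS_PER_MONTH = 365.25 / 12.0


@dataclass(frozen=True)
class ModelSettings:
    """Global settings: horizon, cycle, discounting, WTP, NHI point value."""

    horizon_years: float = 40.0
    cycle_days: float = 21.0
    discount_rate: float = 0.03
    wtp: float = 101_949.0
    conversion_factor: float = 0.9198
    currency: str = "2024 USD"

    def __post_init__(self):
        if not self.horizon_years > 0:
            raise ValueError("horizon must be positive")
        if not 0.0 <= self.discount_rate <= 1.0:
            raise ValueError("discount rate must lie in [0, 1]")
        if not 0.0 < self.conversion_factor <= 1.2:
            raise ValueError("conversion factor must lie in (0, 1.2]")
        if self.horizon_years * 12 * DAYS_PER_MONTH < self.cycle_days:
            raise ValueError("horizon shorter than one cycle")

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.25

    @property
    def n_cycles(self) -> int:
        return int(math.floor(self.horizon_years * 12.0 / self.cycle_months))


@dataclass(frozen=True)
class DrugExposure:
    """One drug's acquisition cost and its resolved exposure cap in cycles."""

    name: str
    annual_cost: float
    cap_cycles: float  # math.inf = until progression
    attracts_admin: bool = False

    def __post_init__(self):
        if self.annual_cost < 0:
            raise ValueError("drug cost must be non-negative")
        if not self.cap_cycles > 0:
            raise ValueError("cap must be positive")


@dataclass(frozen=True)
class AdverseEvent:
    name: str
    probability: float
    cost: float
    disutility: float

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("AE probability must lie in [0, 1]")
        if self.cost < 0 or self.disutility < 0:
            raise ValueError("AE cost and disutility must be non-negative")


@dataclass(frozen=True)
class StrategyDefinition:
    """One arm's survival models plus all its economic inputs.

    Annual cost rates are in USD; rates for non-medication services are
    fee-schedule point values (1 point = TWD 1 = USD 1/32.11 at authoring
    time) and are scaled by the conversion factor during accrual.
    """

    name: str
    os_model: ParametricSurvival
    pfs_model: ParametricSurvival
    drugs: tuple  # of DrugExposure
    admin_cost_rate: float
    pf_nonmed_rate: float
    pd_support_rate: float
    pd_drug_rate: float
    pd_admin_rate: float
    terminal_rate: float
    utility_pf: float
    utility_pd: float
    adverse_events: tuple = ()

    def __post_init__(self):
        for r in (
            self.admin_cost_rate, self.pf_nonmed_rate, self.pd_support_rate,
            self.pd_drug_rate, self.pd_admin_rate, self.terminal_rate,
        ):
            if r < 0:
                raise ValueError("cost rates must be non-negative")
        for u in (self.utility_pf, self.utility_pd):
            if not 0.0 <= u <= 1.0:
                raise ValueError("utilities must lie in [0, 1]")


@dataclass
class Trace:
    """Per-cycle state occupancy and on-treatment occupancy."""

    cycle: np.ndarray
    t_start: np.ndarray   # months
    t_mid: np.ndarray     # months
    pf: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    deaths: np.ndarray    # incident deaths in the cycle
    on_treatment: dict    # drug name -> occupancy array
    crossings: int = 0    # cycles where S_PFS exceeded S_OS (capped)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cycle": self.cycle,
                "t_start_months": self.t_start,
                "t_mid_months": self.t_mid,
                "pf": self.pf,
                "pd": self.pd,
                "dead": self.dead,
                "incident_deaths": self.deaths,
            }
        )
        for name, occ in self.on_treatment.items():
            df[f"on_treatment_{name}"] = occ
        return df


@dataclass
class AccrualResult:
    """Discounted totals over the horizon for one strategy."""

    ly: float
    ly_pf: float
    ly_pd: float
    qaly: float
    qaly_pf: float
    qaly_pd: float
    cost_pf_medication: float
    cost_pf_nonmedication: float
    cost_pd_medication: float
    cost_pd_nonmedication: float
    cost_ae: float
    cost_total: float
    diagnostics: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "diagnostics"}
        return d


def state_occupancy(os_model: ParametricSurvival, pfs_model: ParametricSurvival, t):
    """(pf, pd, dead) occupancy at time ``t`` months.

    PF is capped at S_OS when the fitted curves cross; the partition always
    sums to one.
    """
    s_os = os_model.sf(t)
    s_pfs = pfs_model.sf(t)
    pf = np.minimum(s_pfs, s_os)
    return pf, s_os - pf, 1.0 - s_os


def treatment_exposure(
    pfs_model: ParametricSurvival,
    cap_months: float,
    settings: ModelSettings,
    os_model: ParametricSurvival | None = None,
    quantize_cycles: bool = True,
) -> np.ndarray:
    """Per-cycle on-treatment time in years (occupancy x cycle length).

    ``cap_months`` stops treatment; with ``quantize_cycles`` (the engine
    default) the cap is realized as complete cycles, since drugs are
    dispensed per 3-week cycle.  With ``quantize_cycles=False`` the final
    fraction of a cycle is kept, which converges to the continuous rule
    integral min(t, cap) of S_PFS.  Treatment occupancy is capped at S_OS.
    """
    if not cap_months > 0:
        raise ValueError("cap must be positive")
    n = settings.n_cycles
    dt = settings.cycle_months
    t0 = np.arange(n) * dt
    if quantize_cycles:
        n_on = min(n, int(math.floor(cap_months / dt))) if math.isfinite(cap_months) else n
        frac = (np.arange(n) < n_on).astype(float)
        t_eval = t0 + dt / 2.0
    else:
        frac = np.clip((cap_months - t0) / dt, 0.0, 1.0)
        t_eval = t0 + frac * dt / 2.0
    occ = pfs_model.sf(t_eval)
    if os_model is not None:
        occ = np.minimum(occ, os_model.sf(t_eval))
    return occ * frac * settings.cycle_years


def _cap_to_cycles(cap_cycles: float, n: int) -> int:
    return n if math.isinf(cap_cycles) else min(n, int(cap_cycles))


def run_model(strategy: StrategyDefinition, settings: ModelSettings):
    """Run one arm over the horizon; returns ``(Trace, AccrualResult)``."""
    n = settings.n_cycles
    dt = settings.cycle_months
    dty = settings.cycle_years
    conv = settings.conversion_factor

    t0 = np.arange(n) * dt
    tm = t0 + dt / 2.0
    disc = (1.0 + settings.discount_rate) ** (-(tm / 12.0))

    s_os_mid = strategy.os_model.sf(tm)
    s_pfs_mid = strategy.pfs_model.sf(tm)
    crossings = int(np.sum(s_pfs_mid > s_os_mid + 1e-12))
    pf = np.minimum(s_pfs_mid, s_os_mid)
    pd_ = s_os_mid - pf
    dead = 1.0 - s_os_mid
    bounds = strategy.os_model.sf(np.append(t0, n * dt))
    deaths = bounds[:-1] - bounds[1:]

    idx = np.arange(n)
    on_treatment = {}
    cost_pf_med = 0.0
    chemo_exposure = np.zeros(n)
    for drug in strategy.drugs:
        nc = _cap_to_cycles(drug.cap_cycles, n)
        occ = np.where(idx < nc, pf, 0.0)
        on_treatment[drug.name] = occ
        cost_pf_med += drug.annual_cost * float(np.sum(occ * dty * disc))
        if drug.attracts_admin:
            chemo_exposure = np.maximum(chemo_exposure, occ)

    ly_pf = float(np.sum(pf * dty * disc))
    ly_pd = float(np.sum(pd_ * dty * disc))
    ly = float(np.sum(s_os_mid * dty * disc))
    dd = float(np.sum(deaths * disc))

    admin = strategy.admin_cost_rate * float(np.sum(chemo_exposure * dty * disc))
    pf_services = strategy.pf_nonmed_rate * ly_pf
    cost_pf_nonmed = (admin + pf_services) * conv

    cost_pd_med = strategy.pd_drug_rate * ly_pd
    supportive = strategy.pd_support_rate * ly_pd
    terminal = strategy.terminal_rate / 12.0 * dd
    pd_admin = strategy.pd_admin_rate * ly_pd
    cost_pd_nonmed = (supportive + terminal + pd_admin) * conv

    ae_cost = sum(a.probability * a.cost for a in strategy.adverse_events)
    cost_ae = ae_cost * float(disc[0]) * conv
    ae_decrement = (
        sum(a.probability * a.disutility for a in strategy.adverse_events)
        * dty * float(disc[0])
    )

    qaly_pf = strategy.utility_pf * ly_pf - ae_decrement
    qaly_pd = strategy.utility_pd * ly_pd

    total = cost_pf_med + cost_pf_nonmed + cost_pd_med + cost_pd_nonmed + cost_ae

    diagnostics = {
        "crossings": crossings,
        "survival_at_horizon": float(bounds[-1]),
        "absorbed": bool(bounds[-1] <= 0.01),
    }

    trace = Trace(
        cycle=idx, t_start=t0, t_mid=tm, pf=pf, pd=pd_, dead=dead,
        deaths=deaths, on_treatment=on_treatment, crossings=crossings,
    )
    result = AccrualResult(
        ly=ly, ly_pf=ly_pf, ly_pd=ly_pd,
        qaly=qaly_pf + qaly_pd, qaly_pf=qaly_pf, qaly_pd=qaly_pd,
        cost_pf_medication=cost_pf_med,
        cost_pf_nonmedication=cost_pf_nonmed,
        cost_pd_medication=cost_pd_med,
        cost_pd_nonmedication=cost_pd_nonmed,
        cost_ae=cost_ae,
        cost_total=total,
        diagnostics=diagnostics,
    )
    return trace, result
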
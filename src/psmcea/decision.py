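"""Pairwise cost-effectiveness comparison and price-threshold solving."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .engine import AccrualResult

__all__ = ["CEComparison", "compare_strategies", "price_threshold", "PriceThreshold"]


@dataclass(frozen=True)
class CEComparison:
    """Incremental comparison of an intervention against a comparator.

    ``icer`` is NaN when the incremental effect is non-positive (dominated or
    effect-neutral); ``inmb = delta_effect * wtp - delta_cost`` always.
    """

    delta_cost: float
    delta_effect: float
    icer: float
    inmb: float
    wtp: float
    effect_measure: str = "qaly"

    @property
    def icer_defined(self) -> bool:
        return math.isfinite(self.icer)


def compare_strategies(
    intervention: AccrualResult,
    comparator: AccrualResult,
    wtp: float,
    measure: str = "qaly",
) -> CEComparison:
    """ICER and INMB on unrounded model output.

    ``measure='qaly'`` uses quality-adjusted life-years; ``measure='ly'``
    values effectiveness in unweighted (discounted) life-years — the
    equal-value-of-life-years-gained convention.
    """
    if measure not in ("qaly", "ly"):
        raise ValueError("measure must be 'qaly' or 'ly'")
    d_cost = intervention.cost_total - comparator.cost_total
    if measure == "qaly":
        d_eff = intervention.qaly - comparator.qaly
    else:
        d_eff = intervention.ly - comparator.ly
    icer = d_cost / d_eff if d_eff > 0 else float("nan")
    return CEComparison(
        delta_cost=d_cost,
        delta_effect=d_eff,
        icer=icer,
        inmb=d_eff * wtp - d_cost,
        wtp=wtp,
        effect_measure=measure,
    )


@dataclass(frozen=True)
class PriceThreshold:
    """Solved drug-price multiplier at which the INMB crosses zero."""

    multiplier: float
    price_per_600mg: float
    inmb_at_solution: float
    already_cost_effective: bool = False


def price_threshold(
    inmb_of_multiplier: Callable[[float], float],
    baseline_price: float = 1720.0,
    tol: float = 0.5,
    max_iter: int = 200,
) -> PriceThreshold:
    """Bisection on the drug-price multiplier m in [0, 1] until |INMB| < tol USD.

    ``inmb_of_multiplier`` must be the INMB of the intervention as a function
    of the price multiplier, increasing as the price falls.  If the
    intervention is already cost-effective at full price, m=1 is returned
    flagged; if the INMB stays negative even at zero price there is no
    solution.
    """
    hi = inmb_of_multiplier(1.0)
    if hi >= 0:
        return PriceThreshold(1.0, baseline_price, hi, already_cost_effective=True)
    lo_val = inmb_of_multiplier(0.0)
    if lo_val < 0:
        raise ValueError("INMB negative even at zero drug price: no threshold exists")
    a, b = 0.0, 1.0  # inmb(a) >= 0 > inmb(b)
    val = lo_val
    m = a
    for _ in range(max_iter):
        m = 0.5 * (a + b)
        val = inmb_of_multiplier(m)
        if abs(val) < tol:
            break
        if val > 0:
            a = m
        else:
            b = m
    return PriceThreshold(m, baseline_price * m, val)
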
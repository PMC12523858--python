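"""Deterministic and probabilistic sensitivity analysis, CEAC and EVPI.

The one-way DSA re-runs both arms with each parameter at its lower and
upper bound (95% CI where published, otherwise +/-25%) and ranks parameters
by the INMB range they induce (tornado ordering).

The PSA draws every non-fixed parameter from its distribution — normal for
survival parameters (redrawn if a positivity-constrained parameter comes out
non-positive), gamma for cost rates, beta for utilities and disutilities,
uniform for the NHI conversion factor — and reruns both arms per draw.
Treatment durations, adverse-event probabilities, the discount rate and the
sugemalimab price are fixed in the PSA (they still vary in the DSA and in
scenarios).  Cost-rate draws are taken independently for each arm, so that
each strategy's realized accrual carries its own uncertainty; utilities are
per-arm parameters to begin with, while disutilities and the conversion
factor are shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ARMS, build_arms
from .decision import compare_strategies
from .engine import run_model
from .survival import _POSITIVE

__all__ = [
    "ParameterSpec",
    "parameter_specs",
    "sample_parameters",
    "one_way_dsa",
    "PSAResult",
    "run_psa",
    "evpi",
    "ceac",
]

DEFAULT_WTP_GRID = np.arange(0.0, 150_001.0, 1000.0)


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain model quantity.

    ``role`` is the override key understood by
    :func:`psmcea.config.build_arms`.  ``per_arm`` marks quantities whose PSA
    draws are taken independently for each strategy arm.  ``positive``
    enforces redraw-on-nonpositive for normal draws.
    """

    name: str
    role: str
    base_value: float
    dsa_low: float
    dsa_high: float
    dist: str = "fixed"            # normal | gamma | beta | uniform | fixed
    dist_params: tuple = ()
    per_arm: bool = False
    positive: bool = False

    def __post_init__(self):
        if not self.dsa_low <= self.base_value <= self.dsa_high:
            raise ValueError(
                f"{self.name}: DSA bounds [{self.dsa_low}, {self.dsa_high}] "
                f"must bracket base value {self.base_value}"
            )
        if self.dist == "normal":
            if not self.dist_params[1] > 0:
                raise ValueError(f"{self.name}: normal sd must be positive")
        elif self.dist == "gamma":
            mean, sd = self.dist_params
            if not (mean > 0 and sd > 0):
                raise ValueError(f"{self.name}: gamma mean and sd must be positive")
        elif self.dist == "beta":
            a, b = self.dist_params
            if not (a > 0 and b > 0):
                raise ValueError(f"{self.name}: beta shapes must be positive")
        elif self.dist == "uniform":
            lo, hi = self.dist_params
            if not lo < hi:
                raise ValueError(f"{self.name}: uniform needs min < max")
        elif self.dist != "fixed":
            raise ValueError(f"{self.name}: unknown distribution {self.dist!r}")

    def draw(self, rng: np.random.Generator) -> float:
        if self.dist == "fixed":
            return self.base_value
        if self.dist == "normal":
            mean, sd = self.dist_params
            x = rng.normal(mean, sd)
            if self.positive:
                while x <= 0:
                    x = rng.normal(mean, sd)
            return float(x)
        if self.dist == "gamma":
            mean, sd = self.dist_params
            shape = (mean / sd) ** 2
            scale = sd * sd / mean
            return float(rng.gamma(shape, scale))
        if self.dist == "beta":
            a, b = self.dist_params
            return float(rng.beta(a, b))
        if self.dist == "uniform":
            lo, hi = self.dist_params
            return float(rng.uniform(lo, hi))
        raise AssertionError(self.dist)


def _psa_tuple(node, kind):
    psa = node.get("psa", {"dist": "fixed"})
    dist = psa.get("dist", "fixed")
    if dist == "gamma":
        return "gamma", (node["value"] if "value" in node else node["annual_cost"], psa["sd"])
    if dist == "beta":
        return "beta", (psa["alpha"], psa["beta"])
    if dist == "uniform":
        return "uniform", (psa["min"], psa["max"])
    return "fixed", ()


def parameter_specs(cfg: dict, population: str = "cps5", survival_set: str = "base"):
    """All uncertain quantities of the model as :class:`ParameterSpec` list."""
    specs: list[ParameterSpec] = []

    surv = cfg["populations"][population]["survival"][survival_set]
    for arm in ARMS:
        for ep in ("os", "pfs"):
            node = surv[arm][ep]
            pos_idx = _POSITIVE[node["family"]]
            labels = {
                "loglogistic": ("shape", "scale"),
                "lognormal": ("meanlog", "sdlog"),
            }.get(node["family"], tuple(f"p{i}" for i in range(len(node["params"]))))
            for i, value in enumerate(node["params"]):
                lo, hi = node["ci"][i]
                specs.append(
                    ParameterSpec(
                        name=f"{ep}_{arm}_{labels[i]}",
                        role=f"survival.{population}.{survival_set}.{arm}.{ep}.{i}",
                        base_value=value, dsa_low=min(lo, value), dsa_high=max(hi, value),
                        dist="normal", dist_params=(value, node["se"][i]),
                        positive=i in pos_idx,
                    )
                )

    for name, node in cfg["drugs"].items():
        dist, dp = _psa_tuple(node, "cost")
        specs.append(
            ParameterSpec(
                name=f"cost_{name}", role=f"drugs.{name}.annual_cost",
                base_value=node["annual_cost"],
                dsa_low=node["dsa"][0], dsa_high=node["dsa"][1],
                dist=dist, dist_params=dp, per_arm=dist != "fixed", positive=True,
            )
        )
    for name, node in cfg["costs"].items():
        dist, dp = _psa_tuple(node, "cost")
        specs.append(
            ParameterSpec(
                name=f"cost_{name}", role=f"costs.{name}", base_value=node["value"],
                dsa_low=node["dsa"][0], dsa_high=node["dsa"][1],
                dist=dist, dist_params=dp, per_arm=True, positive=True,
            )
        )
    for name, node in cfg["utilities"].items():
        dist, dp = _psa_tuple(node, "utility")
        specs.append(
            ParameterSpec(
                name=f"utility_{name}", role=f"utilities.{name}", base_value=node["value"],
                dsa_low=node["dsa"][0], dsa_high=node["dsa"][1],
                dist=dist, dist_params=dp,
            )
        )
    for name, node in cfg["disutilities"].items():
        dist, dp = _psa_tuple(node, "utility")
        specs.append(
            ParameterSpec(
                name=f"disutility_{name}", role=f"disutilities.{name}",
                base_value=node["value"],
                dsa_low=node["dsa"][0], dsa_high=node["dsa"][1],
                dist=dist, dist_params=dp,
            )
        )
    for arm, block in cfg["ae_probabilities"].items():
        for ae, node in block.items():
            specs.append(
                ParameterSpec(
                    name=f"prob_{ae}_{arm}", role=f"ae_prob.{arm}.{ae}",
                    base_value=node["value"],
                    dsa_low=node["dsa"][0], dsa_high=node["dsa"][1],
                )
            )
    frac = cfg["durations"].get("dsa_fraction", 0.25)
    for arm in ARMS:
        v = cfg["durations"]["median_months"][arm]
        specs.append(
            ParameterSpec(
                name=f"duration_{arm}", role=f"durations.median.{arm}",
                base_value=v, dsa_low=v * (1 - frac), dsa_high=v * (1 + frac),
            )
        )
    su = cfg.get("settings_uncertainty", {})
    if "discount_rate" in su:
        specs.append(
            ParameterSpec(
                name="discount_rate", role="settings.discount_rate",
                base_value=cfg["settings"]["discount_rate"],
                dsa_low=su["discount_rate"]["dsa"][0],
                dsa_high=su["discount_rate"]["dsa"][1],
            )
        )
    if "conversion_factor" in su:
        dist, dp = _psa_tuple(
            {"value": cfg["settings"]["conversion_factor"], "psa": su["conversion_factor"]["psa"]},
            "settings",
        )
        specs.append(
            ParameterSpec(
                name="conversion_factor", role="settings.conversion_factor",
                base_value=cfg["settings"]["conversion_factor"],
                dsa_low=su["conversion_factor"]["dsa"][0],
                dsa_high=su["conversion_factor"]["dsa"][1],
                dist=dist, dist_params=dp,
            )
        )
    return specs


def sample_parameters(specs, rng: np.random.Generator) -> dict:
    """One PSA draw: override mapping role -> value.

    Per-arm specs get two independent draws keyed ``role@arm``.
    """
    draw = {}
    for spec in specs:
        if spec.dist == "fixed":
            continue
        if spec.per_arm:
            for arm in ARMS:
                draw[f"{spec.role}@{arm}"] = spec.draw(rng)
        else:
            draw[spec.role] = spec.draw(rng)
    return draw


def _run_comparison(cfg, overrides=None, **build_kw):
    i_arm, c_arm, settings = build_arms(cfg, overrides=overrides, **build_kw)
    _, res_i = run_model(i_arm, settings)
    _, res_c = run_model(c_arm, settings)
    return res_i, res_c, settings


def one_way_dsa(cfg: dict, population: str = "cps5", specs=None, **build_kw) -> pd.DataFrame:
    """Tornado table: ICER and INMB at each parameter's low and high bound.

    Sorted descending by the absolute INMB range.
    """
    if specs is None:
        specs = parameter_specs(cfg, population)
    res_i, res_c, settings = _run_comparison(cfg, population=population, **build_kw)
    base = compare_strategies(res_i, res_c, settings.wtp)
    rows = []
    for spec in specs:
        out = {}
        for side, value in (("low", spec.dsa_low), ("high", spec.dsa_high)):
            ri, rc, st = _run_comparison(
                cfg, overrides={spec.role: value}, population=population, **build_kw
            )
            cmp_ = compare_strategies(ri, rc, st.wtp)
            out[f"icer_{side}"] = cmp_.icer
            out[f"inmb_{side}"] = cmp_.inmb
        rows.append(
            {
                "parameter": spec.name,
                "base_value": spec.base_value,
                "low": spec.dsa_low,
                "high": spec.dsa_high,
                **out,
                "inmb_range": abs(out["inmb_high"] - out["inmb_low"]),
            }
        )
    table = pd.DataFrame(rows).sort_values("inmb_range", ascending=False, kind="mergesort")
    table.attrs["base_icer"] = base.icer
    table.attrs["base_inmb"] = base.inmb
    return table.reset_index(drop=True)


@dataclass
class PSAResult:
    """Per-draw incremental outcomes plus CEAC and EVPI summaries."""

    draws: pd.DataFrame          # delta_cost, delta_effect, inmb, nmb per arm
    seed: int
    wtp: float
    wtp_grid: np.ndarray
    ceac: np.ndarray             # P(cost-effective) on wtp_grid
    prob_cost_effective: float   # at wtp
    evpi: float                  # USD per person at wtp
    n: int = field(init=False)

    def __post_init__(self):
        self.n = len(self.draws)


def ceac(delta_effect: np.ndarray, delta_cost: np.ndarray, wtp_grid) -> np.ndarray:
    """P(INMB > 0) on a willingness-to-pay grid."""
    grid = np.asarray(wtp_grid, dtype=float)
    return np.array(
        [np.mean(delta_effect * lam - delta_cost > 0) for lam in grid]
    )


def evpi(nmb_intervention: np.ndarray, nmb_comparator: np.ndarray) -> float:
    """Per-person expected value of perfect information.

    Mean of the per-draw best net monetary benefit minus the net benefit of
    the on-average best strategy; non-negative by Jensen's inequality.
    """
    best_per_draw = np.maximum(nmb_intervention, nmb_comparator).mean()
    best_on_average = max(nmb_intervention.mean(), nmb_comparator.mean())
    return float(best_per_draw - best_on_average)


def run_psa(
    cfg: dict,
    population: str = "cps5",
    n: int = 5000,
    seed: int = 20240101,
    wtp_grid=None,
    specs=None,
    **build_kw,
) -> PSAResult:
    """Monte Carlo PSA: ``n`` draws, both arms per draw, CEAC and EVPI."""
    if n < 1:
        raise ValueError("need at least one draw")
    if specs is None:
        specs = parameter_specs(
            cfg, population, survival_set=build_kw.get("survival_set", "base")
        )
    if wtp_grid is None:
        wtp_grid = DEFAULT_WTP_GRID
    rng = np.random.default_rng(seed)
    wtp = cfg["settings"]["wtp"]

    cols = {k: np.empty(n) for k in
            ("cost_i", "qaly_i", "ly_i", "cost_c", "qaly_c", "ly_c",
             "delta_cost", "delta_effect")}
    for k in range(n):
        overrides = sample_parameters(specs, rng)
        res_i, res_c, _ = _run_comparison(cfg, overrides=overrides,
                                          population=population, **build_kw)
        cols["cost_i"][k] = res_i.cost_total
        cols["qaly_i"][k] = res_i.qaly
        cols["ly_i"][k] = res_i.ly
        cols["cost_c"][k] = res_c.cost_total
        cols["qaly_c"][k] = res_c.qaly
        cols["ly_c"][k] = res_c.ly
        cols["delta_cost"][k] = res_i.cost_total - res_c.cost_total
        cols["delta_effect"][k] = res_i.qaly - res_c.qaly

    nmb_i = cols["qaly_i"] * wtp - cols["cost_i"]
    nmb_c = cols["qaly_c"] * wtp - cols["cost_c"]
    inmb = nmb_i - nmb_c
    draws = pd.DataFrame({**cols, "nmb_i": nmb_i, "nmb_c": nmb_c, "inmb": inmb})
    curve = ceac(cols["delta_effect"], cols["delta_cost"], wtp_grid)
    return PSAResult(
        draws=draws,
        seed=seed,
        wtp=wtp,
        wtp_grid=np.asarray(wtp_grid, dtype=float),
        ceac=curve,
        prob_cost_effective=float(np.mean(inmb > 0)),
        evpi=evpi(nmb_i, nmb_c),
    )
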
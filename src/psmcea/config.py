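"""Model configuration: loading, validation, and strategy construction.

The configuration is a JSON document mirroring the model's input table: one
block per population (PD-L1 CPS >= 5 and >= 10) holding the fitted survival
parameters (base-case and scenario distribution sets), plus the shared
economic inputs — drug prices, annual cost rates, utilities, adverse-event
profiles, treatment-duration rules — each with deterministic sensitivity
bounds and a probabilistic distribution.

``build_arms`` turns a configuration into the two
:class:`~psmcea.engine.StrategyDefinition` arms plus
:class:`~psmcea.engine.ModelSettings`, applying scenario knobs (population,
survival set, duration rule, price multiplier, horizon, conversion factor)
and a flat ``overrides`` mapping used by the sensitivity machinery.

Override keys are dotted paths (e.g. ``costs.support``,
``utilities.intervention_pf``, ``survival.cps5.base.intervention.os.1``,
``settings.discount_rate``); a ``@intervention``/``@comparator`` suffix
scopes a value to one arm.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from importlib import resources

from .engine import (
    DAYS_PER_MONTH,
    AdverseEvent,
    DrugExposure,
    ModelSettings,
    StrategyDefinition,
)
from .survival import FAMILIES, ParametricSurvival

__all__ = [
    "load_config",
    "default_config",
    "validate_config",
    "write_config",
    "config_hash",
    "build_arms",
    "DURATION_RULES",
    "POPULATIONS",
    "ConfigError",
]

DURATION_RULES = ("median_duration", "median_pfs", "protocol_max", "until_progression")
POPULATIONS = ("cps5", "cps10")
ARMS = ("intervention", "comparator")


class ConfigError(ValueError):
    pass


def default_config() -> dict:
    """The bundled base-case configuration (all published model inputs)."""
    with resources.files("psmcea.data").joinpath("base_case.json").open() as fh:
        cfg = json.load(fh)
    validate_config(cfg)
    return cfg


def load_config(path=None) -> dict:
    """Load and validate a configuration file; ``None`` loads the bundled one."""
    if path is None:
        return default_config()
    with open(path) as fh:
        try:
            cfg = json.load(fh)
        except json.JSONDecodeError as err:
            raise ConfigError(f"cannot parse {path}: {err}") from err
    validate_config(cfg)
    return cfg


def write_config(cfg: dict, path) -> None:
    validate_config(cfg)
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")


def config_hash(cfg: dict) -> str:
    payload = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _require(cfg, *keys):
    node = cfg
    path = []
    for k in keys:
        path.append(str(k))
        if not isinstance(node, dict) or k not in node:
            raise ConfigError(f"missing required field {'.'.join(path)}")
        node = node[k]
    return node


def validate_config(cfg: dict) -> None:
    """Cross-field validation; raises :class:`ConfigError` naming the field."""
    if not isinstance(cfg, dict) or not cfg:
        raise ConfigError("empty or non-object configuration")
    s = _require(cfg, "settings")
    for f in ("horizon_years", "cycle_days", "discount_rate", "wtp", "conversion_factor"):
        _require(s, f)
    if not 0 <= s["discount_rate"] <= 1:
        raise ConfigError("settings.discount_rate out of [0, 1]")
    for pop in POPULATIONS:
        for sset in ("base", "scenario"):
            for arm in ARMS:
                for ep in ("os", "pfs"):
                    node = _require(cfg, "populations", pop, "survival", sset, arm, ep)
                    if node["family"] not in FAMILIES:
                        raise ConfigError(
                            f"populations.{pop}.survival.{sset}.{arm}.{ep}.family "
                            f"unknown: {node['family']}"
                        )
                    ParametricSurvival(node["family"], node["params"])
    for name, node in _require(cfg, "utilities").items():
        if not 0 <= node["value"] <= 1:
            raise ConfigError(f"utilities.{name}.value out of [0, 1]")
    for arm, block in _require(cfg, "ae_probabilities").items():
        for ae, node in block.items():
            if not 0 <= node["value"] <= 1:
                raise ConfigError(f"ae_probabilities.{arm}.{ae}.value out of [0, 1]")
    for name, node in _require(cfg, "costs").items():
        if node["value"] < 0:
            raise ConfigError(f"costs.{name}.value negative")
    for name, node in _require(cfg, "drugs").items():
        if node["annual_cost"] < 0:
            raise ConfigError(f"drugs.{name}.annual_cost negative")
        for arm in node["arms"]:
            if arm not in ARMS:
                raise ConfigError(f"drugs.{name}.arms contains unknown arm {arm!r}")
    d = _require(cfg, "durations")
    for rule_key in ("median_months", "median_pfs_months"):
        for arm in ARMS:
            if not _require(d, rule_key, arm) > 0:
                raise ConfigError(f"durations.{rule_key}.{arm} must be positive")


# ---------------------------------------------------------------------------
# strategy construction


def _ov(overrides, key, arm, default):
    if overrides:
        if f"{key}@{arm}" in overrides:
            return overrides[f"{key}@{arm}"]
        if key in overrides:
            return overrides[key]
    return default


def _survival_model(cfg, overrides, pop, sset, arm, endpoint):
    node = cfg["populations"][pop]["survival"][sset][arm][endpoint]
    params = list(node["params"])
    for i in range(len(params)):
        key = f"survival.{pop}.{sset}.{arm}.{endpoint}.{i}"
        params[i] = _ov(overrides, key, arm, params[i])
    return ParametricSurvival(node["family"], params)


def _drug_cap_cycles(drug_cfg, rule_cap_months, duration_rule, cycle_months):
    # drugs are dispensed in whole model cycles: caps quantize via floor
    # (the 1e-9 guards exact-multiple caps against float round-off)
    caps = []
    if math.isfinite(rule_cap_months):
        caps.append(math.floor(rule_cap_months / cycle_months + 1e-9))
    protocol_applies = not (
        duration_rule == "until_progression"
        and drug_cfg.get("protocol_binding") == "reimbursement"
    )
    if protocol_applies:
        if "protocol_max_cycles" in drug_cfg:
            # protocol cycles are dosing cycles (q3w), not model cycles
            dosing_days = drug_cfg.get("dosing_interval_days", 21.0)
            months = drug_cfg["protocol_max_cycles"] * dosing_days / DAYS_PER_MONTH
            caps.append(math.floor(months / cycle_months + 1e-9))
        elif "protocol_max_months" in drug_cfg:
            caps.append(math.floor(drug_cfg["protocol_max_months"] / cycle_months + 1e-9))
    return float(min(caps)) if caps else math.inf


def build_arms(
    cfg: dict,
    population: str = "cps5",
    survival_set: str = "base",
    duration_rule: str = "median_duration",
    price_multiplier: float = 1.0,
    horizon_years: float | None = None,
    conversion_factor: float | None = None,
    overrides: dict | None = None,
    survival_models: dict | None = None,
):
    """Build (intervention, comparator, settings) for one model run.

    ``survival_models`` may supply explicit
    ``{arm: {endpoint: ParametricSurvival}}`` objects (e.g. refitted
    best-AIC models), bypassing the configured parameter blocks.
    """
    if population not in POPULATIONS:
        raise ConfigError(f"unknown population {population!r}; choose from {POPULATIONS}")
    if duration_rule not in DURATION_RULES:
        raise ConfigError(f"unknown duration rule {duration_rule!r}; choose from {DURATION_RULES}")
    if survival_set not in ("base", "scenario"):
        raise ConfigError("survival_set must be 'base' or 'scenario'")
    if not 0.0 <= price_multiplier <= 1.0:
        raise ConfigError("price multiplier must lie in [0, 1]")

    s = cfg["settings"]
    settings = ModelSettings(
        horizon_years=horizon_years if horizon_years is not None else s["horizon_years"],
        cycle_days=s["cycle_days"],
        discount_rate=_ov(overrides, "settings.discount_rate", "", s["discount_rate"]),
        wtp=s["wtp"],
        conversion_factor=(
            conversion_factor
            if conversion_factor is not None
            else _ov(overrides, "settings.conversion_factor", "", s["conversion_factor"])
        ),
        currency=s.get("currency", "USD"),
    )

    strategies = []
    for arm in ARMS:
        if survival_models and arm in survival_models:
            os_model = survival_models[arm]["os"]
            pfs_model = survival_models[arm]["pfs"]
        else:
            os_model = _survival_model(cfg, overrides, population, survival_set, arm, "os")
            pfs_model = _survival_model(cfg, overrides, population, survival_set, arm, "pfs")

        if duration_rule == "median_duration":
            rule_cap = _ov(
                overrides, f"durations.median.{arm}", arm,
                cfg["durations"]["median_months"][arm],
            )
        elif duration_rule == "median_pfs":
            rule_cap = cfg["durations"]["median_pfs_months"][arm]
        else:
            rule_cap = math.inf

        drugs = []
        for name, dcfg in cfg["drugs"].items():
            if arm not in dcfg["arms"]:
                continue
            annual = _ov(overrides, f"drugs.{name}.annual_cost", arm, dcfg["annual_cost"])
            if name == "sugemalimab":
                annual *= price_multiplier
            drugs.append(
                DrugExposure(
                    name=name,
                    annual_cost=annual,
                    cap_cycles=_drug_cap_cycles(dcfg, rule_cap, duration_rule, settings.cycle_months),
                    attracts_admin=bool(dcfg.get("attracts_admin", False)),
                )
            )

        aes = []
        for ae_name, node in cfg["ae_probabilities"][arm].items():
            aes.append(
                AdverseEvent(
                    name=ae_name,
                    probability=_ov(overrides, f"ae_prob.{arm}.{ae_name}", arm, node["value"]),
                    cost=_ov(overrides, f"costs.ae_{ae_name}", arm, cfg["costs"][f"ae_{ae_name}"]["value"]),
                    disutility=_ov(overrides, f"disutilities.{ae_name}", arm, cfg["disutilities"][ae_name]["value"]),
                )
            )

        def cost(key):
            return _ov(overrides, f"costs.{key}", arm, cfg["costs"][key]["value"])

        def util(state):
            v = _ov(overrides, f"utilities.{arm}_{state}", arm, cfg["utilities"][f"{arm}_{state}"]["value"])
            return min(max(v, 0.0), 1.0)  # DSA bounds may touch 1; clamp to validity

        strategies.append(
            StrategyDefinition(
                name=arm,
                os_model=os_model,
                pfs_model=pfs_model,
                drugs=tuple(drugs),
                admin_cost_rate=cost("admin"),
                pf_nonmed_rate=cost("pf_nonmed"),
                pd_support_rate=cost("support"),
                pd_drug_rate=cost("pd_drug"),
                pd_admin_rate=cost("pd_admin"),
                terminal_rate=cost("terminal"),
                utility_pf=util("pf"),
                utility_pd=util("pd"),
                adverse_events=tuple(aes),
            )
        )

    return strategies[0], strategies[1], settings


def scenario_config(cfg: dict, **updates) -> dict:
    """Deep-copied configuration with top-level setting updates applied."""
    out = copy.deepcopy(cfg)
    for key, value in updates.items():
        if key not in out["settings"]:
            raise ConfigError(f"unknown setting {key!r}")
        out["settings"][key] = value
    return out
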
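"""Partitioned-survival engine: occupancy, exposure, accrual invariants."""

import copy
import dataclasses
import math

import numpy as np
import pytest

import psmcea as P
from psmcea.engine import DAYS_PER_MONTH


def strategy_with(cfg, **changes):
    arm_i, _, settings = P.build_arms(cfg)
    return dataclasses.replace(arm_i, **changes), settings


class TestStateOccupancy:
    def test_partition_from_curves(self):
        os_m = P.ParametricSurvival("exponential", (np.log(1 / 0.8) / 10,))
        pfs_m = P.ParametricSurvival("exponential", (np.log(1 / 0.6) / 10,))
        pf, pd_, dead = P.state_occupancy(os_m, pfs_m, 10.0)
        assert pf == pytest.approx(0.6, rel=1e-9)
        assert pd_ == pytest.approx(0.2, rel=1e-9)
        assert dead == pytest.approx(0.2, rel=1e-9)

    def test_time_zero_all_progression_free(self):
        os_m = P.ParametricSurvival("loglogistic", (1.9, 16.9))
        pfs_m = P.ParametricSurvival("loglogistic", (2.2, 9.0))
        pf, pd_, dead = P.state_occupancy(os_m, pfs_m, 0.0)
        assert (pf, pd_, dead) == (1.0, 0.0, 0.0)

    def test_crossing_curves_capped_at_os(self):
        # PFS above OS: PF capped, PD floored at zero
        os_m = P.ParametricSurvival("exponential", (np.log(1 / 0.8) / 10,))
        pfs_m = P.ParametricSurvival("exponential", (np.log(1 / 0.9) / 10,))
        pf, pd_, dead = P.state_occupancy(os_m, pfs_m, 10.0)
        assert pf == pytest.approx(0.8, rel=1e-9)
        assert pd_ == pytest.approx(0.0, abs=1e-12)

    def test_occupancy_conserved_every_cycle(self, cfg):
        arm_i, arm_c, settings = P.build_arms(cfg)
        for arm in (arm_i, arm_c):
            trace, _ = P.run_model(arm, settings)
            total = trace.pf + trace.pd + trace.dead
            assert np.all(np.abs(total - 1.0) < 1e-12)
            assert np.all(np.diff(trace.dead) >= -1e-12)
            for occ in trace.on_treatment.values():
                assert np.all(occ <= trace.pf + 1e-12)


class TestTreatmentExposure:
    def test_cap_truncates_exposure(self, cfg):
        _, _, settings = P.build_arms(cfg)
        pfs = P.ParametricSurvival("loglogistic", (2.2, 9.0))
        expo = P.treatment_exposure(pfs, 6.3, settings)
        n_on = int(np.sum(expo > 0))
        assert n_on == math.floor(6.3 / settings.cycle_months)
        assert np.all(expo[n_on:] == 0.0)

    def test_uncapped_follows_pfs(self, cfg):
        _, _, settings = P.build_arms(cfg)
        pfs = P.ParametricSurvival("loglogistic", (2.2, 9.0))
        expo = P.treatment_exposure(pfs, math.inf, settings)
        tm = (np.arange(settings.n_cycles) + 0.5) * settings.cycle_months
        expected = pfs.sf(tm) * settings.cycle_years
        assert np.allclose(expo, expected)

    def test_continuous_exposure_matches_closed_form(self, cfg):
        """Expected treated time for exponential PFS: (1-e^{-r*cap})/r."""
        _, _, settings = P.build_arms(cfg)
        pfs = P.ParametricSurvival("exponential", (0.2,))
        expo = P.treatment_exposure(pfs, 5.0, settings, quantize_cycles=False)
        expected_months = (1.0 - np.exp(-0.2 * 5.0)) / 0.2
        assert expo.sum() * 12.0 == pytest.approx(expected_months, rel=0.005)

    def test_quantized_exposure_matches_closed_form_at_cycle_cap(self, cfg):
        _, _, settings = P.build_arms(cfg)
        pfs = P.ParametricSurvival("exponential", (0.2,))
        expo = P.treatment_exposure(pfs, 5.0, settings, quantize_cycles=True)
        cap = math.floor(5.0 / settings.cycle_months) * settings.cycle_months
        expected_months = (1.0 - np.exp(-0.2 * cap)) / 0.2
        assert expo.sum() * 12.0 == pytest.approx(expected_months, rel=0.005)


class TestAccrual:
    def test_zero_rates_zero_costs_positive_ly(self, cfg):
        arm, settings = strategy_with(
            cfg,
            drugs=tuple(dataclasses.replace(d, annual_cost=0.0) for d in P.build_arms(cfg)[0].drugs),
            admin_cost_rate=0.0, pf_nonmed_rate=0.0, pd_support_rate=0.0,
            pd_drug_rate=0.0, pd_admin_rate=0.0, terminal_rate=0.0,
            utility_pf=0.0, utility_pd=0.0, adverse_events=(),
        )
        _, res = P.run_model(arm, settings)
        assert res.cost_total == 0.0
        assert res.qaly == 0.0
        assert res.ly > 0.0

    def test_undiscounted_full_utility_qaly_equals_survival_integral(self, cfg):
        arm_i, _, _ = P.build_arms(cfg)
        arm = dataclasses.replace(arm_i, utility_pf=1.0, utility_pd=1.0,
                                  adverse_events=())
        settings = dataclasses.replace(P.build_arms(cfg)[2], discount_rate=0.0)
        _, res = P.run_model(arm, settings)
        t = np.linspace(0.0, settings.n_cycles * settings.cycle_months, 20_000)
        integral_years = np.trapezoid(arm.os_model.sf(t), t) / 12.0
        assert res.qaly == pytest.approx(res.ly, rel=1e-12)
        assert res.ly == pytest.approx(integral_years, rel=0.002)

    def test_discounting_reduces_every_accrual(self, cfg, base_results):
        res_disc = base_results[0]
        settings0 = dataclasses.replace(base_results[2], discount_rate=0.0)
        arm_i, _, _ = P.build_arms(cfg)
        _, res0 = P.run_model(arm_i, settings0)
        for f in ("ly", "qaly", "cost_total", "cost_pf_medication",
                  "cost_pd_nonmedication"):
            assert getattr(res0, f) > getattr(res_disc, f)

    def test_grid_convergence_under_cycle_halving(self, cfg):
        outcomes = {}
        for days in (21.0, 10.5):
            c2 = copy.deepcopy(cfg)
            c2["settings"]["cycle_days"] = days
            arm_i, arm_c, settings = P.build_arms(c2)
            _, ri = P.run_model(arm_i, settings)
            _, rc = P.run_model(arm_c, settings)
            outcomes[days] = (ri.cost_total, ri.qaly, rc.cost_total, rc.qaly)
        for a, b in zip(outcomes[21.0], outcomes[10.5]):
            assert abs(a - b) / b < 0.005

    def test_cost_and_utility_monotonicity(self, cfg):
        arm_i, _, settings = P.build_arms(cfg)
        _, base = P.run_model(arm_i, settings)
        for f in ("pd_support_rate", "pf_nonmed_rate", "terminal_rate",
                  "admin_cost_rate", "pd_drug_rate", "pd_admin_rate"):
            bumped = dataclasses.replace(arm_i, **{f: getattr(arm_i, f) * 2.0})
            _, res = P.run_model(bumped, settings)
            assert res.cost_total >= base.cost_total
        up = dataclasses.replace(arm_i, utility_pf=min(1.0, arm_i.utility_pf + 0.1))
        _, res = P.run_model(up, settings)
        assert res.qaly > base.qaly

    def test_qaly_bounded_by_ly_per_state(self, base_results):
        for res in base_results[:2]:
            assert res.qaly_pf <= res.ly_pf + 1e-12
            assert res.qaly_pd <= res.ly_pd + 1e-12
            assert res.qaly <= res.ly + 1e-12

    def test_components_sum_to_total(self, base_results):
        for res in base_results[:2]:
            total = (res.cost_pf_medication + res.cost_pf_nonmedication
                     + res.cost_pd_medication + res.cost_pd_nonmedication
                     + res.cost_ae)
            assert res.cost_total == pytest.approx(total, rel=1e-12)
            assert res.ly == pytest.approx(res.ly_pf + res.ly_pd, rel=1e-12)

    def test_survival_absorbed_by_horizon(self, base_results):
        for res in base_results[:2]:
            assert res.diagnostics["absorbed"]

    def test_horizon_shorter_than_cycle_rejected(self):
        with pytest.raises(ValueError):
            P.ModelSettings(horizon_years=0.01, cycle_days=21.0)
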
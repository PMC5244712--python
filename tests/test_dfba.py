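"""Population dynamic FBA: step arithmetic, allocation, conservation, death."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trichodfba import dfba
from trichodfba.dfba import (
    DZ,
    PA,
    AllocationRecord,
    DFBAConfig,
    MetricsResult,
    PopulationState,
    SimulationTrace,
    StepRecord,
    allocate_differentiation,
    compute_metrics,
    diazotroph_glycogen_cap,
    required_glycogen_supply,
    run_ensemble,
    simulate_population,
)
from trichodfba.toy import ToyNetworkParams, make_toy_model

from conftest import make_inoculum


class TestStepArithmetic:
    def test_supply_factor_is_one_at_zero_growth(self):
        assert required_glycogen_supply(-0.2, mu_dz=0.0, biomass_ratio=1.0) == (
            pytest.approx(0.2)
        )

    def test_supply_scales_with_growth_and_ratio(self):
        # (mu dt + 1) * |v| * X_DZ/X_PA with mu = 0.5, dt = 2
        value = required_glycogen_supply(-0.3, mu_dz=0.5, biomass_ratio=0.25, dt=2.0)
        assert value == pytest.approx((0.5 * 2 + 1) * 0.3 * 0.25)

    def test_no_previous_demand_means_no_forced_export(self):
        assert required_glycogen_supply(0.0, 0.1, 3.0) == 0.0

    def test_glycogen_cap_direct_arithmetic(self):
        assert diazotroph_glycogen_cap(-0.927, 0.5) == pytest.approx(
            0.927 / (6 * 0.5)
        )

    def test_glycogen_cap_zero_cases(self):
        assert diazotroph_glycogen_cap(0.0, 0.5) == 0.0
        assert diazotroph_glycogen_cap(-1.0, 0.0) == 0.0


class TestAllocation:
    def test_single_consumer_gets_sigma_one(self):
        record, _ = allocate_differentiation(
            increments={DZ: 0.0, PA: 1.0},
            final_prime={DZ: 1.0, PA: 2.0},
            consumer_fluxes={"nh4": {PA: -0.5}},
            producer_fluxes={"nh4": {DZ: 0.1}},
        )
        assert record.per_metabolite["nh4"]["sigma_consumers"][PA] == pytest.approx(1.0)

    def test_alpha_from_signed_totals(self):
        # production 6, consumption -10 (mmol/step with unit biomass weights)
        # => alpha = (6 - 10) / -10 = 0.4
        record, final = allocate_differentiation(
            increments={DZ: 0.0, PA: 2.0},
            final_prime={DZ: 1.0, PA: 1.0},
            consumer_fluxes={"nh4": {PA: -10.0}},
            producer_fluxes={"nh4": {DZ: 6.0}},
        )
        entry = record.per_metabolite["nh4"]
        assert entry["alpha"] == pytest.approx(0.4)
        # pool = alpha * sigma * consumer increment, moved consumer -> producer
        assert entry["pool"] == pytest.approx(0.4 * 2.0)
        assert final[DZ] == pytest.approx(1.0 + 0.8)
        assert final[PA] == pytest.approx(1.0 - 0.8)
        assert sum(final.values()) == pytest.approx(2.0)

    def test_surplus_goes_entirely_to_photoautotroph(self):
        record, final = allocate_differentiation(
            increments={DZ: 0.3, PA: 0.7},
            final_prime={DZ: 1.3, PA: 1.7},
            consumer_fluxes={"nh4": {PA: -1.0}},
            producer_fluxes={"nh4": {DZ: 5.0}},       # over-supplied
        )
        assert record.surplus_to == PA
        assert final[PA] == pytest.approx(1.0 + 1.0)   # X0 + all increments
        assert final[DZ] == pytest.approx(1.0)

    def test_zero_consumption_triggers_no_allocation(self):
        record, final = allocate_differentiation(
            increments={DZ: 0.1, PA: 0.2},
            final_prime={DZ: 1.1, PA: 1.2},
            consumer_fluxes={"nh4": {PA: 0.0}},
            producer_fluxes={"nh4": {DZ: 0.5}},
        )
        assert record.per_metabolite["nh4"]["alpha"] == 0.0

    def test_biomass_is_conserved(self):
        record, final = allocate_differentiation(
            increments={DZ: 0.4, PA: 1.0},
            final_prime={DZ: 2.4, PA: 3.0},
            consumer_fluxes={"nh4": {PA: -3.0}, "glycogen": {DZ: -2.0}},
            producer_fluxes={"nh4": {DZ: 1.0}, "glycogen": {PA: 1.0}},
        )
        assert sum(final.values()) == pytest.approx(2.4 + 3.0)
        assert sum(record.transfers.values()) == pytest.approx(0.0, abs=1e-12)

    def test_negative_increment_rejected(self):
        with pytest.raises(ValueError, match="increments"):
            allocate_differentiation(
                increments={DZ: -0.1, PA: 0.0},
                final_prime={DZ: 0.9, PA: 1.0},
                consumer_fluxes={}, producer_fluxes={},
            )

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        inc_dz=st.floats(0.0, 10.0),
        inc_pa=st.floats(0.0, 10.0),
        x_dz=st.floats(0.01, 10.0),
        x_pa=st.floats(0.01, 10.0),
        v_gly_dz=st.floats(-5.0, 0.0),
        v_gly_pa=st.floats(0.0, 5.0),
        v_nh4_pa=st.floats(-5.0, 0.0),
        v_nh4_dz=st.floats(0.0, 5.0),
        semantics=st.sampled_from(["prose", "literal"]),
    )
    def test_invariants_hold_for_arbitrary_inputs(
        self, inc_dz, inc_pa, x_dz, x_pa, v_gly_dz, v_gly_pa, v_nh4_pa,
        v_nh4_dz, semantics
    ):
        record, final = allocate_differentiation(
            increments={DZ: inc_dz, PA: inc_pa},
            final_prime={DZ: x_dz + inc_dz, PA: x_pa + inc_pa},
            consumer_fluxes={"glycogen": {DZ: v_gly_dz}, "nh4": {PA: v_nh4_pa}},
            producer_fluxes={"glycogen": {PA: v_gly_pa}, "nh4": {DZ: v_nh4_dz}},
            semantics=semantics,
        )
        # biomass conserved; nobody loses more than this step's gain
        total = x_dz + inc_dz + x_pa + inc_pa
        assert sum(final.values()) == pytest.approx(total, rel=1e-9, abs=1e-12)
        assert final[DZ] >= x_dz - 1e-9 and final[PA] >= x_pa - 1e-9
        for entry in record.per_metabolite.values():
            assert 0.0 <= entry["alpha"] <= 1.0
            for sigmas in (entry["sigma_consumers"], entry["sigma_producers"]):
                if sigmas:
                    assert sum(sigmas.values()) == pytest.approx(1.0, abs=1e-9)

    def test_literal_semantics_also_conserves(self):
        _, final = allocate_differentiation(
            increments={DZ: 0.0, PA: 2.0},
            final_prime={DZ: 1.0, PA: 3.0},
            consumer_fluxes={"nh4": {PA: -10.0}},
            producer_fluxes={"nh4": {DZ: 6.0}},
            semantics="literal",
        )
        assert sum(final.values()) == pytest.approx(4.0)


class TestSimulationInvariants:
    def test_conservation_and_sigma_over_a_run(self, toy_bundle):
        model, dz_spec, pa_spec = toy_bundle
        subs = dfba.build_dfba_submodels(model, dz_spec, pa_spec)
        trace = simulate_population(
            subs, make_inoculum(0.3), DFBAConfig(horizon=120)
        )
        assert trace.status == "completed"
        for i, rec in enumerate(trace.records):
            before, after = trace.states[i], trace.states[i + 1]
            expected = before.total_biomass + sum(
                before.X[g] * (math.exp(rec.mu[g]) - 1.0) for g in (DZ, PA)
            )
            # allocation redistributes, never creates or destroys biomass
            assert after.total_biomass == pytest.approx(expected, rel=1e-12)
            for entry in rec.allocation.per_metabolite.values():
                for sigmas in (entry["sigma_consumers"], entry["sigma_producers"]):
                    if sigmas:
                        assert sum(sigmas.values()) == pytest.approx(1.0)

    def test_medium_mass_balance_each_step(self, toy_bundle):
        model, dz_spec, pa_spec = toy_bundle
        subs = dfba.build_dfba_submodels(model, dz_spec, pa_spec)
        cfg = DFBAConfig(horizon=80)
        trace = simulate_population(subs, make_inoculum(0.3), cfg)
        for i, rec in enumerate(trace.records[cfg.grace:], start=cfg.grace):
            before, after = trace.states[i], trace.states[i + 1]
            for m in ("glycogen", "nh4"):
                delta = after.C[m] - before.C[m]
                assert delta == pytest.approx(
                    rec.produced[m] - rec.consumed[m], abs=1e-8
                )

    def test_metrics_growth_identity(self, toy_bundle):
        model, dz_spec, pa_spec = toy_bundle
        subs = dfba.build_dfba_submodels(model, dz_spec, pa_spec)
        trace = simulate_population(subs, make_inoculum(0.4), DFBAConfig(horizon=60))
        metrics = compute_metrics(trace)
        ratio = trace.states[-1].total_biomass / trace.states[0].total_biomass
        assert math.exp(np.sum(metrics.mu_t)) == pytest.approx(ratio, rel=1e-9)

    def test_determinism(self, toy_bundle):
        model, dz_spec, pa_spec = toy_bundle
        frames = []
        for _ in range(2):
            table = run_ensemble(model, dz_spec, pa_spec, n=2,
                                 config=DFBAConfig(horizon=30), seed=7)
            frames.append(table)
        assert frames[0].equals(frames[1])

    def test_ensemble_row_count_and_fraction_construction(self, toy_bundle):
        model, dz_spec, pa_spec = toy_bundle
        table = run_ensemble(model, dz_spec, pa_spec, n=5,
                             config=DFBAConfig(horizon=20), seed=3)
        assert len(table) == 5
        assert np.allclose(
            table["f0_DZ"], table["X0_DZ"] / (table["X0_DZ"] + table["X0_PA"])
        )


class TestDeathRules:
    @pytest.mark.parametrize("f0", [0.0, 1.0])
    def test_single_phenotype_inocula_die_within_grace_plus_one(
        self, toy_bundle, f0
    ):
        model, dz_spec, pa_spec = toy_bundle
        subs = dfba.build_dfba_submodels(model, dz_spec, pa_spec)
        cfg = DFBAConfig(horizon=50)
        trace = simulate_population(subs, make_inoculum(f0), cfg)
        assert trace.status == "died"
        assert trace.death_time <= (cfg.grace + 1) * cfg.dt

    def test_energy_starved_population_dies_within_grace_plus_one(self):
        # maintenance demand exceeding the photon supply of either phenotype
        params = ToyNetworkParams(
            maintenance={"diazotroph": 500.0, "photoautotroph": 500.0}
        )
        model, dz_spec, pa_spec = make_toy_model(params)
        subs = dfba.build_dfba_submodels(model, dz_spec, pa_spec)
        cfg = DFBAConfig(horizon=50)
        trace = simulate_population(subs, make_inoculum(0.5), cfg)
        assert trace.status == "died"
        assert trace.death_time <= (cfg.grace + 1) * cfg.dt

    def test_zero_initial_biomass_reported_as_died(self):
        trace = SimulationTrace(
            states=[PopulationState(t=0.0, X={DZ: 0.0, PA: 0.0}, C={})],
            records=[], status="completed",
        )
        assert compute_metrics(trace).status == "died"


def _hand_trace():
    """Three steps with hand-chosen biomasses and medium amounts."""
    states = [
        PopulationState(t=0.0, X={DZ: 1.0, PA: 3.0}, C={"nh4": 0.0}),
        PopulationState(t=1.0, X={DZ: 1.1, PA: 3.3}, C={"nh4": 0.2}),
        PopulationState(t=2.0, X={DZ: 1.21, PA: 3.63}, C={"nh4": 0.5}),
        PopulationState(t=3.0, X={DZ: 1.331, PA: 3.993}, C={"nh4": 0.6}),
    ]
    empty = dict(
        mu={DZ: 0.0, PA: 0.0}, mu_effective={DZ: 0.0, PA: 0.0},
        fluxes={DZ: {}, PA: {}}, demand_fluxes={DZ: {}, PA: {}},
        consumed={"nh4": 0.0}, borrowed={}, allocation=None,
        infeasible={DZ: False, PA: False}, dead_step=False,
    )
    records = [
        StepRecord(t=1.0, produced={"nh4": 0.5}, **empty),
        StepRecord(t=2.0, produced={"nh4": 0.5}, **empty),
        StepRecord(t=3.0, produced={"nh4": 0.5}, **empty),
    ]
    return SimulationTrace(states=states, records=records, status="completed")


class TestMetricsByHand:
    def test_three_step_trace_matches_hand_arithmetic(self):
        metrics = compute_metrics(_hand_trace())
        # every step multiplies biomass by 1.1
        assert metrics.mu_total == pytest.approx(math.log(1.1**3) / 3.0)
        assert np.allclose(metrics.mu_t, math.log(1.1))
        # 0.6 mmol accumulated of 1.5 mmol produced
        assert metrics.nitrogen_release_fraction == pytest.approx(0.6 / 1.5)

    def test_no_accumulation_means_zero_yield(self):
        trace = _hand_trace()
        for s in trace.states:
            s.C["nh4"] = 0.0
        assert compute_metrics(trace).nitrogen_release_fraction == 0.0

    def test_doubling_time_identity(self):
        assert math.log(2) / 0.0146 == pytest.approx(47.5, abs=0.05)


class TestNitrogenSourceScenarios:
    def test_closed_source_reproduces_baseline(self, toy_bundle):
        model, dz_spec, pa_spec = toy_bundle
        cfg = DFBAConfig(horizon=40)
        _, closed = dfba.nitrogen_source_scenario(
            model, dz_spec, pa_spec, "glutamine", config=cfg, open_uptake=False
        )
        _, baseline = dfba.nitrogen_source_scenario(
            model, dz_spec, pa_spec, "N2", config=cfg
        )
        assert closed.mu_total == pytest.approx(baseline.mu_total, abs=1e-12)

    def test_growth_ladder(self, toy_bundle, oracle):
        model, dz_spec, pa_spec = toy_bundle
        cfg = DFBAConfig(horizon=150)
        init = make_inoculum(oracle.f_dz)
        mu = {}
        for source in ("N2", "urea", "NH4", "glutamate", "glutamine"):
            _, metrics = dfba.nitrogen_source_scenario(
                model, dz_spec, pa_spec, source, config=cfg,
                initial=make_inoculum(oracle.f_dz),
            )
            mu[source] = metrics.mu_total
        order = ["N2", "urea", "NH4", "glutamate", "glutamine"]
        assert all(mu[a] < mu[b] for a, b in zip(order, order[1:]))

    def test_unknown_source_raises(self, toy_bundle):
        model, dz_spec, pa_spec = toy_bundle
        with pytest.raises(KeyError, match="unknown nitrogen source"):
            dfba.nitrogen_source_scenario(model, dz_spec, pa_spec, "nitrite")
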
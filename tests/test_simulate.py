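"""Transaminase futile-cycle simulator tests.

Oracles: closed-form solutions of the (exactly linear) symmetric exchange
subsystem, conservation laws that hold by construction of the transfer
rules, and the simulator's hidden forward-event counter.
"""

import numpy as np
import pandas as pd
import pytest

from isodrift.chem import LabelSpec
from isodrift.simulate import (
    SimulationConfig,
    SimulationError,
    SpeciesState,
    ReactionSystem,
    apply_intervention,
    build_transaminase_system,
    generate_ms2_fixtures,
    label_based_cycle_estimate,
    observe_injection_series,
    parse_species,
    simulate_timecourse,
    species_name,
)

T24 = np.linspace(0.0, 24.0, 25)


class TestSpeciesNaming:
    @pytest.mark.parametrize(
        "name", ["Glu", "Glu:13C5,15N", "Glu:D5,alphaD", "aKG:13C5", "Asp:15N", "Glu:D4"]
    )
    def test_round_trip(self, name):
        assert species_name(*parse_species(name)) == name

    def test_restricted_space_enforced(self):
        with pytest.raises(SimulationError):
            parse_species("Glu:13C3")  # partial skeletons not allowed
        with pytest.raises(SimulationError):
            parse_species("aKG:15N")  # ketoacids carry no nitrogen label
        with pytest.raises(SimulationError):
            parse_species("Foo")


class TestLabelTransferRules:
    def test_d5_donor_yields_d4_ketoacid(self, default_config):
        system = build_transaminase_system(default_config)
        names = {sp.name for sp in system.species}
        assert "aKG:D4" in names  # α-deuterium lost on deamination
        assert "aKG:D5" not in names and "aKG:D5,alphaD" not in names

    def test_dual_label_splits_between_skeleton_and_amine(self, default_config):
        system = build_transaminase_system(default_config)
        names = {sp.name for sp in system.species}
        assert {"aKG:13C5", "Asp:15N"} <= names  # forward products
        assert {"Glu:13C5", "Glu:15N"} <= names  # reverse recombinations

    def test_filtered_scenario_has_no_enzyme(self):
        cfg = SimulationConfig(scenario="filtered")
        assert build_transaminase_system(cfg).enzyme_activity == 0.0

    def test_apply_intervention(self, default_config):
        system = build_transaminase_system(default_config)
        assert apply_intervention(system, "active").enzyme_activity == system.enzyme_activity
        assert apply_intervention(system, "filtered").enzyme_activity == 0.0
        aoa = apply_intervention(system, "aoa", inhibition_tau_hr=0.5)
        assert aoa.inhibition_tau_hr == 0.5
        assert aoa.enzyme_at(5.0) < 1e-4 < aoa.enzyme_at(0.0)
        with pytest.raises(SimulationError):
            apply_intervention(system, "boiled")


class TestIntegration:
    def test_no_enzyme_means_constant_concentrations(self):
        cfg = SimulationConfig(scenario="filtered")
        tc = simulate_timecourse(build_transaminase_system(cfg), T24, 0.05)
        assert np.allclose(tc.conc_uM, tc.conc_uM[:, [0]])
        assert tc.true_cycle_events_uM[-1] == 0.0

    def test_symmetric_exchange_reaches_half_partition(self):
        # huge, equal acceptor pools make the Glu<->aKG exchange pseudo
        # first order and symmetric: steady state is a 50/50 split
        system = ReactionSystem(
            species=[
                SpeciesState("Glu", LabelSpec(), 10.0),
                SpeciesState("OAA", LabelSpec(), 1e4),
                SpeciesState("Asp", LabelSpec(), 1e4),
            ],
            k_fwd=1e-3,
            k_rev=1e-3,
        )
        tc = simulate_timecourse(system, np.linspace(0, 1.0, 11), 0.001)
        glu = tc.concentration("Glu")
        akg = tc.concentration("aKG")
        assert glu[-1] == pytest.approx(akg[-1], rel=5e-3)
        assert glu[-1] + akg[-1] == pytest.approx(10.0, rel=1e-9)

    def test_rk4_matches_exact_linear_solution(self):
        # with k_fwd == k_rev the quadratic terms cancel exactly and
        # d[Glu]/dt = k*(c0 - c1*[Glu]) has a closed-form solution
        g0, a0, o0, s0, k = 10.0, 0.0, 1e4, 1e4, 1e-4
        system = ReactionSystem(
            species=[
                SpeciesState("Glu", LabelSpec(), g0),
                SpeciesState("OAA", LabelSpec(), o0),
                SpeciesState("Asp", LabelSpec(), s0),
            ],
            k_fwd=k,
            k_rev=k,
        )
        t = np.linspace(0, 5.0, 21)
        tc = simulate_timecourse(system, t, 0.01)
        # d g/dt = -k g (o0 - (g0-g)) + k (g0-g)(s0 + (g0-g))
        #        = k [ g0*s0 + g0^2 - (o0 + s0 + g0) g ]   (g^2 cancels)
        c1 = o0 + s0 + g0
        g_eq = (g0 * s0 + g0**2) / c1
        exact = g_eq + (g0 - g_eq) * np.exp(-k * c1 * t)
        assert np.max(np.abs(tc.concentration("Glu") - exact)) < 1e-6

    def test_conservation_of_skeletons_and_nitrogen(self, active_timecourse):
        c13 = active_timecourse.total_13C5_skeletons()
        n15 = active_timecourse.total_15N()
        assert np.max(np.abs(c13 - c13[0])) / c13[0] < 1e-8
        assert np.max(np.abs(n15 - n15[0])) / n15[0] < 1e-8

    def test_alpha_deuterium_is_monotonically_lost(self, active_timecourse):
        ad = active_timecourse.total_alpha_D()
        assert np.all(np.diff(ad) <= 1e-12)
        assert ad[-1] < ad[0]

    def test_solver_rejects_unstable_step(self):
        system = ReactionSystem(
            species=[
                SpeciesState("Glu", LabelSpec(), 100.0),
                SpeciesState("OAA", LabelSpec(), 100.0),
            ],
            k_fwd=10.0,
            k_rev=0.0,
        )
        with pytest.raises(SimulationError, match="smaller"):
            simulate_timecourse(system, np.linspace(0, 10, 3), step_hr=5.0)

    def test_time_grid_validation(self, default_config):
        system = build_transaminase_system(default_config)
        with pytest.raises(SimulationError):
            simulate_timecourse(system, [1.0, 2.0])
        with pytest.raises(SimulationError):
            simulate_timecourse(system, [0.0, 2.0, 1.0])


class TestScenarioOrdering:
    def test_d5_preserved_by_filtration_and_aoa(self):
        d5 = {}
        for scenario in ("active", "filtered", "aoa"):
            cfg = SimulationConfig(scenario=scenario)
            tc = simulate_timecourse(build_transaminase_system(cfg), T24, 0.01)
            series = tc.concentration("Glu", LabelSpec(n_D=5, alpha_D=True))
            d5[scenario] = series[-1] / series[0]
        assert d5["filtered"] == pytest.approx(1.0, abs=1e-9)
        assert d5["aoa"] == pytest.approx(1.0, abs=0.02)  # brief pre-inhibition turnover
        assert d5["active"] < 0.5 * min(d5["filtered"], d5["aoa"])

    def test_active_consumes_most_tracer_by_24h(self):
        cfg = SimulationConfig(scenario="active")
        tc = simulate_timecourse(build_transaminase_system(cfg), T24, 0.01)
        doubly = tc.concentration("Glu", LabelSpec(n_13C=5, n_15N=1))
        consumed = 1 - doubly[-1] / doubly[0]
        assert 0.7 < consumed < 0.95  # the ~80-90% design point


class TestCycleEstimate:
    def test_no_enzyme_gives_zero_estimate_and_zero_truth(self):
        cfg = SimulationConfig(scenario="filtered")
        tc = simulate_timecourse(build_transaminase_system(cfg), T24, 0.05)
        assert label_based_cycle_estimate(tc) == 0.0
        assert tc.true_cycle_events_uM[-1] == 0.0

    def test_estimate_strictly_underestimates_truth(self, active_timecourse):
        est = label_based_cycle_estimate(active_timecourse)
        true = active_timecourse.true_cycle_events_uM[-1]
        assert 0 < est < true

    def test_forward_only_run_is_invisible_to_labels(self):
        cfg = SimulationConfig(scenario="active", k_rev=0.0)
        tc = simulate_timecourse(build_transaminase_system(cfg), T24, 0.01)
        assert label_based_cycle_estimate(tc) == pytest.approx(0.0, abs=1e-12)
        assert tc.true_cycle_events_uM[-1] > 0


class TestParameterRecovery:
    def test_pseudo_first_order_rate_recovered_within_5pct(self):
        # small donor pool + huge acceptor + no reverse flux: D5-Glu decays
        # with effective rate k_fwd * [OAA] to within the acceptor depletion
        k, oaa0 = 5e-5, 2000.0
        system = ReactionSystem(
            species=[
                SpeciesState("Glu", LabelSpec(n_D=5, alpha_D=True), 5.0),
                SpeciesState("OAA", LabelSpec(), oaa0),
            ],
            k_fwd=k,
            k_rev=0.0,
        )
        t = np.linspace(0, 24, 25)
        tc = simulate_timecourse(system, t, 0.01)
        d5 = tc.concentration("Glu", LabelSpec(n_D=5, alpha_D=True))
        rng = np.random.default_rng(1)
        noisy = d5 * np.exp(rng.normal(0, 0.01, d5.size))  # 1% CV
        slope = np.polyfit(t, np.log(noisy), 1)[0]
        assert -slope == pytest.approx(k * oaa0, rel=0.05)


class TestObservationModel:
    def test_noiseless_areas_proportional_to_concentration(self, active_timecourse):
        cfg = SimulationConfig(
            scenario="active", noise_cv=0.0, mass_error_ppm_sd=0.0, rt_jitter_sd_min=0.0
        )
        series = observe_injection_series(active_timecourse, cfg)
        wide = series.wide()
        meta = series.feature_meta.set_index("feature_id")
        for sp in active_timecourse.system.species:
            truth = np.array(
                [active_timecourse.at_time(t)[active_timecourse.system.species.index(sp)]
                 for t in series.injection_times_hr]
            )
            expected = truth * meta.loc[sp.name, "response_factor"] * cfg.area_scale
            assert np.allclose(wide.loc[sp.name].to_numpy(), expected, rtol=1e-9)

    def test_noiseless_mz_is_theoretical(self, active_timecourse):
        cfg = SimulationConfig(scenario="active", mass_error_ppm_sd=0.0)
        series = observe_injection_series(active_timecourse, cfg)
        meta = series.feature_meta[~series.feature_meta.is_inert]
        assert np.allclose(meta.mz, meta.theoretical_mz, rtol=1e-12)

    def test_same_seed_reproduces_table_exactly(self, active_timecourse):
        cfg = SimulationConfig(scenario="active", seed=7)
        a = observe_injection_series(active_timecourse, cfg)
        b = observe_injection_series(active_timecourse, cfg)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_default_series_has_25_injections(self, active_timecourse, default_config):
        series = observe_injection_series(active_timecourse, default_config)
        assert series.injection_times_hr.size == 25
        assert series.table.injection_index.nunique() == 25
        assert series.injection_times_hr[-1] == 84.0

    def test_isotopologues_share_response_factor(self, active_timecourse, default_config):
        meta = observe_injection_series(active_timecourse, default_config).feature_meta
        glu = meta[meta.metabolite == "Glu"]
        assert glu.response_factor.nunique() == 1

    def test_negative_cv_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(noise_cv=-0.1)


class TestMS2Fixtures:
    def test_planted_records_carry_fragment(self, default_config):
        records = generate_ms2_fixtures(default_config, n_planted=14, n_decoys=0)
        assert len(records) == 14
        for rec in records:
            ppm = 1e6 * np.abs(rec.fragments_mz - 308.0912) / 308.0912
            assert ppm.min() <= 10.0

    def test_no_planted_means_no_fragment(self, default_config):
        records = generate_ms2_fixtures(default_config, n_planted=0, n_decoys=30)
        for rec in records:
            ppm = 1e6 * np.abs(rec.fragments_mz - 308.0912) / 308.0912
            assert ppm.min() > 10.0

    def test_ground_truth_labels_present(self, default_config):
        records = generate_ms2_fixtures(default_config, n_planted=3, n_decoys=5)
        assert sum(r.meta["planted"] for r in records) == 3
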
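"""Five-state Markov cohort engine: matrices, traces, MLE, economics."""

import math

import numpy as np
import pytest

import oncodelay as od
from oncodelay import markov as mk
from oncodelay import params

S, D, T, P, X = range(5)


class TestBuildMatrix:
    def test_overall_symptomatic_row(self, overall_matrix):
        assert overall_matrix[S, D] == pytest.approx(0.302)
        assert overall_matrix[S, S] == pytest.approx(0.698)

    def test_death_row_absorbing(self, overall_matrix):
        assert list(overall_matrix[X]) == [0, 0, 0, 0, 1]

    def test_rows_are_stochastic(self, overall_matrix):
        assert np.allclose(overall_matrix.sum(axis=1), 1.0)

    def test_stratified_value_overrides_overall(self):
        mat = mk.build_matrix(mk.default_table(), {"subtype": "TripleNegative"})
        assert mat[T, P] == pytest.approx(0.138)
        assert mat[S, D] == pytest.approx(0.302)  # unstratified edge falls back

    def test_stratum_priority_is_deterministic(self):
        # time_interval outranks symptom when both apply to the same edge
        mat = mk.build_matrix(
            mk.default_table(),
            {"time_interval": "2-6m", "symptom": "Breast lump"},
        )
        assert mat[S, D] == pytest.approx(0.623)

    def test_super_stochastic_exits_rejected(self):
        table = mk.TransitionTable()
        table.set("Treatment-Initiated", "Progressive-Disease", 0.6)
        table.set("Treatment-Initiated", "Death", 0.6)
        with pytest.raises(ValueError, match="Treatment-Initiated"):
            mk.build_matrix(table)

    def test_missing_stratified_entry_falls_back_to_overall(self):
        table = mk.default_table()
        mat = mk.build_matrix(table, {"subtype": "unheard-of"})
        assert mat[T, P] == pytest.approx(0.103)


class TestRunTrace:
    def test_single_cycle_diagnosis_share(self, overall_matrix):
        trace = mk.run_trace(overall_matrix, (1, 0, 0, 0, 0), 1)
        assert trace.occupancy[1, D] == pytest.approx(0.302)

    def test_rows_conserve_mass(self, overall_matrix):
        trace = mk.run_trace(overall_matrix, (1, 0, 0, 0, 0), 120)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)

    def test_death_column_nondecreasing(self, overall_matrix):
        trace = mk.run_trace(overall_matrix, (1, 0, 0, 0, 0), 120)
        assert (np.diff(trace.occupancy[:, X]) >= -1e-15).all()

    def test_conservation_and_monotone_death_on_all_strata(self):
        table = mk.default_table()
        strata = [{key: val} for cell in params.TRANSITIONS.values()
                  for key, val in cell if key != "overall"]
        for stratum in strata:
            mat = mk.build_matrix(table, stratum)
            trace = mk.run_trace(mat, (1, 0, 0, 0, 0), 120)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
            assert (np.diff(trace.occupancy[:, X]) >= -1e-15).all()

    def test_matches_matrix_power(self, overall_matrix):
        trace = mk.run_trace(overall_matrix, (1, 0, 0, 0, 0), 40)
        direct = np.array([1, 0, 0, 0, 0]) @ np.linalg.matrix_power(
            overall_matrix, 40
        )
        assert np.allclose(trace.occupancy[40], direct, atol=1e-12)

    def test_expected_time_in_state_is_geometric_mean(self, overall_matrix):
        # expected cycles before leaving the symptomatic state = 1/0.302
        trace = mk.run_trace(overall_matrix, (1, 0, 0, 0, 0), 600)
        assert trace.occupancy[:-1, S].sum() == pytest.approx(1 / 0.302, abs=1e-6)

    def test_non_normalised_initial_vector_rejected(self, overall_matrix):
        with pytest.raises(ValueError):
            mk.run_trace(overall_matrix, (0.5, 0, 0, 0, 0), 10)


class TestMicrosim:
    def test_agrees_with_trace_within_three_se(self, overall_matrix):
        n, cycles = 20_000, 60
        ms = mk.microsim(overall_matrix, n, cycles, seed=42)
        trace = mk.run_trace(overall_matrix, (1, 0, 0, 0, 0), cycles)
        se = np.where(ms.se > 0, ms.se, np.inf)
        z = np.abs(ms.occupancy - trace.occupancy) / se
        # deviations across bins are correlated along cycles; require the
        # standardised errors to look standard normal in aggregate
        assert (z < 3).mean() > 0.95
        assert (z[np.isfinite(z)] ** 2).mean() < 2.0
        assert z.max() < 6.0

    def test_single_path_is_valid(self, overall_matrix):
        ms = mk.microsim(overall_matrix, 1, 60, seed=0, keep_paths=True)
        path = ms.paths[0]
        assert path[0] == S
        # Death is absorbing along the path
        died = np.where(path == X)[0]
        if died.size:
            assert (path[died[0]:] == X).all()

    def test_fixed_seed_reproducible(self, overall_matrix):
        a = mk.microsim(overall_matrix, 500, 30, seed=9, keep_paths=True)
        b = mk.microsim(overall_matrix, 500, 30, seed=9, keep_paths=True)
        assert (a.paths == b.paths).all()


class TestMleTransitions:
    def test_count_ratio(self):
        # 30 observed exits in 100 person-months at risk
        histories = [["Symptomatic-Undiagnosed", "Diagnosed-Untreated"]] * 30
        histories += [["Symptomatic-Undiagnosed", "Symptomatic-Undiagnosed"]] * 70
        table = mk.mle_transitions(histories)
        got = table.lookup("Symptomatic-Undiagnosed", "Diagnosed-Untreated", None)
        assert got == pytest.approx(0.30)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mk.mle_transitions([])

    def test_recovers_generating_matrix(self, overall_matrix):
        n, cycles = 5000, 60
        ms = mk.microsim(overall_matrix, n, cycles, seed=7, keep_paths=True)
        histories = [[params.STATES[s] for s in path] for path in ms.paths]
        table = mk.mle_transitions(histories)
        exposure = np.zeros(5)
        for path in ms.paths:
            for s in path[:-1]:
                exposure[s] += 1
        zs = []
        for (frm, to), cell in params.TRANSITIONS.items():
            p = cell[("overall", "overall")]
            i = params.STATES.index(frm)
            est = table.lookup(frm, to, None)
            se = math.sqrt(p * (1 - p) / exposure[i])
            zs.append((est - p) / se)
        # joint criterion over the five estimated transitions
        assert max(abs(z) for z in zs) < 4.5
        assert sum(z * z for z in zs) < 20.5  # chi-square(5) 99.9th pct

    def test_unvisited_state_missing_then_falls_back(self):
        histories = [["Symptomatic-Undiagnosed", "Diagnosed-Untreated"]]
        table = mk.mle_transitions(histories)
        assert table.lookup("Progressive-Disease", "Death", None) is None
        merged = table.merged(mk.default_table())
        mat = mk.build_matrix(merged)
        assert mat[P, X] == pytest.approx(0.085)
        assert mat[S, D] == pytest.approx(1.0)  # observed MLE overrides

    def test_table_csv_roundtrip(self, tmp_path):
        table = mk.default_table()
        path = tmp_path / "transitions.csv"
        table.to_csv(path)
        loaded = mk.TransitionTable.from_csv(path)
        assert loaded.entries == table.entries


class TestAccumulate:
    def test_alive_year_with_unit_utility(self):
        # identity chain: one state occupied for 12 undiscounted cycles
        occ = np.zeros((13, 5))
        occ[:, T] = 1.0
        trace = mk.CohortTrace(occupancy=occ, cycles=12)
        econ = mk.EconomicParams(
            horizon_cycles=12, discount_rate=0.0,
            utilities={s: 1.0 for s in params.STATES if s != "Death"},
        )
        out = mk.accumulate(trace, econ)
        assert out.life_years == pytest.approx(1.0)
        assert out.qalys == pytest.approx(1.0)

    def test_discount_factor_one_year_out(self):
        econ = mk.EconomicParams()
        assert econ.discount_factor(12) == pytest.approx(1 / 1.035)

    def test_progressive_cycle_qaly_contribution(self):
        occ = np.zeros((2, 5))
        occ[0, P] = 1.0
        occ[1, P], occ[1, X] = 0.915, 0.085
        trace = mk.CohortTrace(occupancy=occ, cycles=1)
        econ = mk.EconomicParams(horizon_cycles=1, discount_rate=0.0)
        out = mk.accumulate(trace, econ)
        assert out.qalys == pytest.approx(0.45 / 12)

    def test_discounting_never_increases_outcomes(self, overall_matrix):
        trace = mk.run_trace(overall_matrix, (1, 0, 0, 0, 0), 120)
        disc = mk.accumulate(trace, mk.EconomicParams(), matrix=overall_matrix)
        undisc = mk.accumulate(
            trace, mk.EconomicParams(discount_rate=0.0), matrix=overall_matrix
        )
        assert disc.life_years < undisc.life_years
        assert disc.qalys < undisc.qalys
        assert disc.discounted_cost < undisc.discounted_cost

    def test_horizon_mismatch_rejected(self, overall_matrix):
        trace = mk.run_trace(overall_matrix, (1, 0, 0, 0, 0), 60)
        with pytest.raises(ValueError, match="horizon"):
            mk.accumulate(trace, mk.EconomicParams(horizon_cycles=120))

    def test_initial_treatment_cost_resolved_by_stage(self):
        econ = mk.EconomicParams()
        assert econ.initial_treatment_cost("I") == 15_300
        assert econ.initial_treatment_cost("IV") == 42_800
        assert 15_300 < econ.initial_treatment_cost("II") < 42_800


class TestCounterfactual:
    def test_identical_scenarios_have_zero_deltas(self):
        econ = mk.EconomicParams()
        sc = mk.Scenario(name="base")
        deltas = mk.counterfactual(mk.default_table(), econ, sc, sc)
        assert all(v == 0.0 for v in deltas.values())

    def test_delay_interval_life_year_delta_sign(self):
        # within the chain, a slower symptomatic->diagnosed transition
        # defers exposure to the post-treatment death hazards
        econ = mk.EconomicParams()
        a = mk.Scenario(
            name="TN delayed",
            stratum={"subtype": "TripleNegative", "time_interval": "2-6m"},
        )
        b = mk.Scenario(
            name="TN prompt",
            stratum={"subtype": "TripleNegative", "time_interval": "<2w"},
        )
        deltas = mk.counterfactual(mk.default_table(), econ, a, b)
        assert deltas["life_years"] > 0

    def test_migration_probability_delta_carried(self, curves):
        from oncodelay.migration import migration_at

        econ = mk.EconomicParams()
        a = mk.Scenario(
            name="a", migration_prob=migration_at(curves["TripleNegative"], 180)
        )
        b = mk.Scenario(
            name="b", migration_prob=migration_at(curves["TripleNegative"], 0)
        )
        deltas = mk.counterfactual(mk.default_table(), econ, a, b)
        assert deltas["migration_prob"] == pytest.approx(0.318)

    def test_two_state_toy_chain_matches_closed_form(self):
        # single transient state with monthly death risk q: undiscounted
        # life-years over H cycles are (1 - (1-q)^H) / q / 12
        table = mk.TransitionTable()
        table.set("Treatment-Initiated", "Death", 0.1)
        table.set("Treatment-Initiated", "Death", 0.2, key="toy", value="fast")
        econ = mk.EconomicParams(discount_rate=0.0, horizon_cycles=60)
        init = (0, 0, 1, 0, 0)
        a = mk.Scenario(name="slow", stratum={}, initial_occupancy=init, cycles=60)
        b = mk.Scenario(name="fast", stratum={"toy": "fast"},
                        initial_occupancy=init, cycles=60)
        deltas = mk.counterfactual(table, econ, a, b)

        def ly(q, h=60):
            return (1 - (1 - q) ** h) / q / 12

        assert deltas["life_years"] == pytest.approx(ly(0.1) - ly(0.2), abs=1e-12)
        assert deltas["death_prob"] == pytest.approx(
            (1 - 0.9**60) - (1 - 0.8**60), abs=1e-12
        )

    def test_mismatched_horizons_rejected(self):
        econ = mk.EconomicParams()
        a = mk.Scenario(name="a", cycles=120)
        b = mk.Scenario(name="b", cycles=60)
        with pytest.raises(ValueError, match="horizon"):
            mk.counterfactual(mk.default_table(), econ, a, b)
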
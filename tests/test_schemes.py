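"""Scheme validation, generator-matrix construction and steady states."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from gabakin import (
    ModulationSet,
    apply_modulation,
    check_detailed_balance,
    load_fixture,
    load_scheme,
    mean_open_time,
    q_matrix,
    steady_state,
)
from gabakin.schemes import (
    DisconnectedSchemeError,
    InvalidRateError,
    MissingConcentrationError,
    ReducibleChainError,
    UnknownRateError,
    UnknownStateError,
    list_fixtures,
)

TWO_STATE_DOC = {
    "name": "mini",
    "states": [
        {"name": "C", "class": "closed"},
        {"name": "O", "class": "open", "conductance_weight": 1.0},
    ],
    "transitions": [
        {"from": "C", "to": "O", "rate_name": "beta", "base_value": 2.0},
        {"from": "O", "to": "C", "rate_name": "alpha", "base_value": 8.0},
    ],
}


class TestLoading:
    def test_minimal_document(self):
        scheme = load_scheme(TWO_STATE_DOC)
        assert len(scheme.states) == 2
        assert len(scheme.transitions) == 2

    def test_yaml_string_round_trip(self):
        import yaml

        scheme = load_scheme(yaml.safe_dump(TWO_STATE_DOC))
        assert scheme.name == "mini"

    def test_liganded_fixture_shape(self, glig_wt):
        """Di-liganded flipped scheme: 7 states, 12 transitions."""
        assert len(glig_wt.states) == 7
        assert len(glig_wt.transitions) == 12
        assert set(glig_wt.state_names) == {
            "R", "AR", "A2R", "A2F", "A2O", "A2D", "A2Dp"}

    def test_undeclared_state_named_in_error(self):
        doc = dict(TWO_STATE_DOC)
        doc["transitions"] = TWO_STATE_DOC["transitions"] + [
            {"from": "O", "to": "X", "rate_name": "kx", "base_value": 1.0}]
        with pytest.raises(UnknownStateError, match="'X'"):
            load_scheme(doc)

    def test_non_positive_rate_rejected(self):
        doc = dict(TWO_STATE_DOC)
        doc["transitions"] = [
            {"from": "C", "to": "O", "rate_name": "beta", "base_value": 0.0},
            TWO_STATE_DOC["transitions"][1]]
        with pytest.raises(InvalidRateError, match="beta"):
            load_scheme(doc)

    def test_disconnected_graph_rejected(self):
        doc = {
            "name": "split",
            "states": TWO_STATE_DOC["states"] + [
                {"name": "Z1", "class": "closed"},
                {"name": "Z2", "class": "open", "conductance_weight": 1.0}],
            "transitions": TWO_STATE_DOC["transitions"] + [
                {"from": "Z1", "to": "Z2", "rate_name": "kz", "base_value": 1.0},
                {"from": "Z2", "to": "Z1", "rate_name": "kz2", "base_value": 1.0}],
        }
        with pytest.raises(DisconnectedSchemeError):
            load_scheme(doc)

    def test_all_shipped_fixtures_load(self):
        for name in list_fixtures():
            scheme = load_fixture(name)
            assert any(s.is_open for s in scheme.states)


class TestQMatrix:
    def test_two_state_by_construction(self, two_state):
        assert np.allclose(q_matrix(two_state), [[-2.0, 2.0], [8.0, -8.0]])

    def test_rows_sum_to_zero_on_all_fixtures(self):
        for name in list_fixtures():
            scheme = load_fixture(name)
            conc = {lig: 1e-3 for lig in scheme.ligands}
            Q = q_matrix(scheme, conc)
            assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-9 * max(1, np.abs(Q).max()))

    def test_zero_concentration_blocks_binding(self, glig_wt):
        Q = q_matrix(glig_wt, {"GABA": 0.0})
        i = glig_wt.state_index("R")
        assert Q[i].sum() == 0 and Q[i, i] == 0  # R absorbing toward liganded branch

    def test_concentration_linearity(self, glig_wt):
        Q1 = q_matrix(glig_wt, {"GABA": 0.05})
        Q2 = q_matrix(glig_wt, {"GABA": 0.1})
        i, j = glig_wt.state_index("R"), glig_wt.state_index("AR")
        assert Q2[i, j] == pytest.approx(2.0 * Q1[i, j], rel=1e-12)
        k = glig_wt.state_index("A2R")
        assert Q2[j, k] == pytest.approx(2.0 * Q1[j, k], rel=1e-12)
        # concentration-independent entries unchanged
        f, o = glig_wt.state_index("A2F"), glig_wt.state_index("A2O")
        assert Q2[f, o] == Q1[f, o]

    def test_missing_ligand_concentration(self, glig_wt):
        with pytest.raises(MissingConcentrationError, match="GABA"):
            q_matrix(glig_wt, {})


class TestSteadyState:
    def test_two_state_occupancy(self, two_state):
        p = steady_state(q_matrix(two_state))
        assert p[1] == pytest.approx(2.0 / 10.0, abs=1e-12)

    def test_symmetric_two_state(self, two_state):
        sym = two_state.with_rates({"alpha": 2.0})
        p = steady_state(q_matrix(sym))
        assert p == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_matches_relaxation_limit(self, spont_wt):
        """Stationary vector equals the long-time limit of relaxation."""
        Q = q_matrix(spont_wt)
        p_ss = steady_state(Q, spont_wt.state_names)
        slowest = 1.0 / min(abs(l.real) for l in np.linalg.eigvals(Q) if abs(l) > 1e-12)
        p = np.zeros(len(spont_wt.states))
        p[spont_wt.state_index("D0")] = 1.0  # start far from equilibrium
        p = p @ expm(Q * 100.0 * slowest)
        assert np.allclose(p, p_ss, atol=1e-6)

    def test_flux_balance_residual(self):
        for name in list_fixtures():
            scheme = load_fixture(name)
            conc = {lig: 1e-3 for lig in scheme.ligands}
            Q = q_matrix(scheme, conc)
            p = steady_state(Q, scheme.state_names)
            assert np.abs(p @ Q).max() < 1e-10 * max(1.0, np.abs(Q).max())

    def test_reducible_chain_reports_states(self):
        doc = {
            "name": "fork",
            "states": [
                {"name": "C", "class": "closed"},
                {"name": "A", "class": "open", "conductance_weight": 1.0},
                {"name": "B", "class": "open", "conductance_weight": 1.0}],
            "transitions": [
                {"from": "C", "to": "A", "rate_name": "ka", "base_value": 1.0},
                {"from": "C", "to": "B", "rate_name": "kb", "base_value": 1.0}],
        }
        scheme = load_scheme(doc)
        with pytest.raises(ReducibleChainError) as err:
            steady_state(q_matrix(scheme), scheme.state_names)
        assert {"A", "B"}.issubset(set(err.value.unreachable))

    def test_transient_states_get_zero_mass(self, glig_wt):
        """At zero agonist the liganded branch is transient, not an error."""
        p = steady_state(q_matrix(glig_wt, {"GABA": 0.0}), glig_wt.state_names)
        assert p[glig_wt.state_index("R")] == pytest.approx(1.0)
        assert p[glig_wt.state_index("A2O")] == 0.0


class TestDetailedBalance:
    def test_tree_topology_has_no_cycles(self, spont_wt):
        assert check_detailed_balance(spont_wt) == []

    def test_balanced_cycle_passes(self):
        doc = {
            "name": "cycle",
            "states": [
                {"name": "A", "class": "closed"},
                {"name": "B", "class": "closed"},
                {"name": "O", "class": "open", "conductance_weight": 1.0}],
            "transitions": [
                {"from": "A", "to": "B", "rate_name": "k1", "base_value": 2.0},
                {"from": "B", "to": "A", "rate_name": "k1r", "base_value": 4.0},
                {"from": "B", "to": "O", "rate_name": "k2", "base_value": 3.0},
                {"from": "O", "to": "B", "rate_name": "k2r", "base_value": 6.0},
                {"from": "O", "to": "A", "rate_name": "k3", "base_value": 5.0},
                {"from": "A", "to": "O", "rate_name": "k3r", "base_value": 1.25}],
        }
        report = check_detailed_balance(load_scheme(doc))
        assert len(report) == 1 and report[0]["ok"]

    def test_violated_cycle_reports_ratio(self):
        doc = {
            "name": "cycle",
            "states": [
                {"name": "A", "class": "closed"},
                {"name": "B", "class": "closed"},
                {"name": "O", "class": "open", "conductance_weight": 1.0}],
            "transitions": [
                {"from": "A", "to": "B", "rate_name": "k1", "base_value": 4.0},
                {"from": "B", "to": "A", "rate_name": "k1r", "base_value": 4.0},
                {"from": "B", "to": "O", "rate_name": "k2", "base_value": 3.0},
                {"from": "O", "to": "B", "rate_name": "k2r", "base_value": 6.0},
                {"from": "O", "to": "A", "rate_name": "k3", "base_value": 5.0},
                {"from": "A", "to": "O", "rate_name": "k3r", "base_value": 1.25}],
        }
        report = check_detailed_balance(load_scheme(doc))
        assert len(report) == 1 and not report[0]["ok"]
        ratio = report[0]["ratio"]
        assert ratio == pytest.approx(2.0) or ratio == pytest.approx(0.5)


class TestModulation:
    def test_identity_leaves_q_unchanged(self, glig_wt):
        mod = ModulationSet("identity", {"delta": 1.0, "d": 1.0})
        out = apply_modulation(glig_wt, mod)
        assert np.array_equal(q_matrix(out, {"GABA": 0.1}),
                              q_matrix(glig_wt, {"GABA": 0.1}))

    def test_halving_alpha_doubles_mean_open_time(self, two_state):
        mod = ModulationSet("slow-close", {"alpha": 0.5})
        assert mean_open_time(apply_modulation(two_state, mod)) == pytest.approx(
            2.0 * mean_open_time(two_state), rel=1e-12)

    def test_inverse_recovers_base_values(self, glig_leu):
        mod = ModulationSet("flu", {"delta": 1.6, "d": 2.5, "r": 1.2, "dp": 0.5})
        back = apply_modulation(apply_modulation(glig_leu, mod), mod.inverse())
        for name, value in glig_leu.rate_values().items():
            assert back.rate_values()[name] == pytest.approx(value, rel=1e-12)

    def test_unknown_rate_rejected(self, two_state):
        with pytest.raises(UnknownRateError, match="nope"):
            apply_modulation(two_state, ModulationSet("bad", {"nope": 2.0}))

    def test_original_scheme_unchanged(self, two_state):
        before = two_state.rate_values()
        apply_modulation(two_state, ModulationSet("m", {"alpha": 3.0}))
        assert two_state.rate_values() == before


@given(
    beta=st.floats(1e-3, 1e5), alpha=st.floats(1e-3, 1e5),
    kon=st.floats(1e3, 1e9), conc=st.floats(0.0, 1.0),
)
@settings(max_examples=50, deadline=None)
def test_generator_rows_sum_to_zero_random(beta, alpha, kon, conc):
    """Row sums vanish for arbitrary rates and concentrations."""
    doc = {
        "name": "random",
        "ligands": ["L"],
        "states": [
            {"name": "C", "class": "closed"},
            {"name": "CL", "class": "closed", "bound": {"L": 1}},
            {"name": "O", "class": "open", "conductance_weight": 1.0}],
        "transitions": [
            {"from": "C", "to": "CL", "rate_name": "kon", "base_value": kon,
             "ligand": "L", "order": 1},
            {"from": "CL", "to": "C", "rate_name": "koff", "base_value": 100.0},
            {"from": "CL", "to": "O", "rate_name": "beta", "base_value": beta},
            {"from": "O", "to": "CL", "rate_name": "alpha", "base_value": alpha}],
    }
    scheme = load_scheme(doc)
    Q = q_matrix(scheme, {"L": conc})
    assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-9 * max(1.0, np.abs(Q).max()))
    # homogeneity of degree 1 in concentration for the binding entry
    Q2 = q_matrix(scheme, {"L": 2.0 * conc})
    i, j = scheme.state_index("C"), scheme.state_index("CL")
    assert Q2[i, j] == pytest.approx(2.0 * Q[i, j], rel=1e-12, abs=1e-300)
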
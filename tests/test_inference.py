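import numpy as np
import pandas as pd
import pytest

from dilpnet import (
    MeasurementTable,
    SignedNetwork,
    auto_beta,
    brute_force_infer,
    build_model,
    fitting_precision,
    fixture_path,
    read_sif,
    restore_missing_edges,
    solve,
)

from helpers import consistency_holds, random_small_instance


def table(states: dict, timepoints) -> MeasurementTable:
    return MeasurementTable.from_states(
        pd.DataFrame(states, index=timepoints).T.astype(int)
    )


@pytest.fixture
def toy_t1():
    """Chain R->A with branches A->B and A-|C; B loses its signal at t2."""
    net = SignedNetwork.from_reactions(
        [("R", "A", 1), ("A", "B", 1), ("A", "C", -1)]
    )
    data = table(
        {"R": (1, 1), "A": (1, 1), "B": (1, 0), "C": (-1, -1)}, ["t1", "t2"]
    )
    return net, data


@pytest.fixture
def toy_t2():
    """Single edge whose target contradicts its source at both timepoints."""
    net = SignedNetwork.from_reactions([("R", "A", 1)])
    data = table({"R": (1, 1), "A": (-1, -1)}, ["t1", "t2"])
    return net, data


class TestBuildModel:
    def test_variable_bookkeeping(self):
        net = SignedNetwork.from_reactions([("R", "A", 1)])
        data = table({"R": (1, 1), "A": (1, 1)}, ["t1", "t2"])
        model = build_model(net, data)
        # x encoding for 2 proteins x 2 tps (xp+xn), 1 y, 2 z, 2 p, 2 q,
        # Pos/Neg for the single non-root x 2 tps, a for 2 measured x 2 tps
        assert model.n_variables == 8 + 1 + 2 + 4 + 4 + 4
        assert model.n_constraints > 0

    def test_auto_beta(self):
        net = read_sif(fixture_path("normoxia_generic.sif"))
        assert auto_beta(net.n_reactions) == pytest.approx(-1 / 90)

    def test_beta_validation(self, toy_t2):
        net, data = toy_t2
        with pytest.raises(ValueError, match="negative"):
            build_model(net, data, beta=0.5)
        with pytest.raises(ValueError, match="outweigh"):
            build_model(net, data, beta=-2.0)

    def test_measured_protein_missing_from_network(self, toy_t2):
        net, _ = toy_t2
        data = table({"R": (1,), "X": (0,)}, ["t1"])
        with pytest.raises(ValueError, match="X"):
            build_model(net, data)

    def test_requires_discretized_table(self, toy_t2):
        net, _ = toy_t2
        raw = MeasurementTable(pd.DataFrame({"t1": [1.0, 1.0]}, index=["R", "A"]))
        with pytest.raises(ValueError, match="discretized"):
            build_model(net, raw)


class TestSolve:
    def test_toy_t1_perfect_fit(self, toy_t1):
        net, data = toy_t1
        res = solve(build_model(net, data))
        assert res.optimal
        assert res.data_term == 0
        assert res.retained_edges == (0, 1, 2)
        # A->B transmits at t1 only: B drops to 0 when the edge stops
        assert bool(res.occurrence.iloc[1, 0]) is True
        assert bool(res.occurrence.iloc[1, 1]) is False
        assert list(res.predicted_states.loc["B"]) == [1, 0]
        assert list(res.predicted_states.loc["C"]) == [-1, -1]

    def test_toy_t2_removes_contradicted_edge(self, toy_t2):
        net, data = toy_t2
        res = solve(build_model(net, data))
        assert res.data_term == 2
        assert res.removed_edges == (0,)
        assert res.objective == pytest.approx(2 + res.beta)

    def test_all_zero_measurements_remove_everything(self):
        net = SignedNetwork.from_reactions(
            [("R", "A", 1), ("A", "B", -1), ("R", "B", 1)]
        )
        data = table({"R": (0, 0), "A": (0, 0), "B": (0, 0)}, ["t1", "t2"])
        res = solve(build_model(net, data))
        assert res.data_term == 0
        assert res.removed_edges == (0, 1, 2)
        assert (res.predicted_states.to_numpy() == 0).all()

    @pytest.mark.parametrize("seed", range(12))
    def test_objective_never_exceeds_trivial_upper_bound(self, seed):
        net, data = random_small_instance(seed)
        model = build_model(net, data)
        res = solve(model)
        roots = set(net.roots)
        trivial = sum(
            int(np.count_nonzero(data.states.loc[p]))
            for p in data.proteins
            if p not in roots
        )
        assert res.objective <= trivial + model.beta * net.n_reactions + 1e-9

    @pytest.mark.parametrize("seed", range(12))
    def test_retention_law_and_consistency(self, seed):
        net, data = random_small_instance(seed)
        res = solve(build_model(net, data))
        occ = res.occurrence.to_numpy()
        retained = set(res.retained_edges)
        for i in range(net.n_reactions):
            assert (i in retained) == bool(occ[i].any())
        assert consistency_holds(net, res.predicted_states, res.occurrence)

    def test_canonical_solution_is_reproducible(self):
        net, data = random_small_instance(7)
        a = solve(build_model(net, data))
        b = solve(build_model(net, data))
        assert a.retained_edges == b.retained_edges
        assert a.predicted_states.equals(b.predicted_states)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_solver_matches_brute_force(self, seed):
        net, data = random_small_instance(seed)
        res = solve(build_model(net, data), canonical=False)
        bf = brute_force_infer(net, data)
        assert res.objective == pytest.approx(bf.objective)
        assert res.data_term == bf.data_term

    def test_single_node_no_edges(self):
        net = SignedNetwork(("A",), ())
        data = table({"A": (1,)}, ["t1"])
        bf = brute_force_infer(net, data)
        # A is a root (no incoming), clamped to its measurement
        assert bf.data_term == 0

    def test_size_bound_enforced(self):
        net, data = random_small_instance(0)
        with pytest.raises(ValueError, match="bound"):
            brute_force_infer(net, data, max_edges=1)


class TestRestoration:
    def test_identity_when_nothing_removed(self, toy_t1):
        net, data = toy_t1
        model = build_model(net, data)
        res = solve(model)
        restored = restore_missing_edges(res, model)
        assert restored.restored_edges == ()
        assert restored.retained_edges == res.retained_edges

    def test_fit_degrading_edge_not_restored(self):
        # forcing A->B back in must transmit a +1 into B (measured 0 at all
        # timepoints) at whichever timepoint it occurs, or silence A
        # (measured +1); either way the data term rises, so no restoration
        net = SignedNetwork.from_reactions([("R", "A", 1), ("A", "B", 1)])
        data = table({"R": (1, 1), "A": (1, 1), "B": (0, 0)}, ["t1", "t2"])
        model = build_model(net, data)
        res = solve(model)
        assert res.data_term == 0 and res.removed_edges == (1,)
        restored = restore_missing_edges(res, model)
        assert restored.restored_edges == ()
        assert 1 not in restored.retained_edges
        assert restored.data_term == 0

    def test_mixed_influence_edge_is_fit_neutral_and_restored(self, toy_t1):
        # an extra edge B->C joins the occurring A-|C at t1, making C a
        # mixed-influence node that may keep its measured -1; the literal
        # unchanged-fit criterion therefore restores it
        net, data = toy_t1
        net2 = SignedNetwork.from_reactions(
            list((r.source, r.target, r.sign) for r in net.reactions)
            + [("B", "C", 1)]
        )
        model = build_model(net2, data)
        res = solve(model)
        restored = restore_missing_edges(res, model)
        assert restored.data_term == res.data_term == 0
        assert 3 in restored.retained_edges

    def test_fit_neutral_edge_restored(self, toy_t2):
        net, data = toy_t2
        model = build_model(net, data)
        restored = restore_missing_edges(solve(model), model)
        assert restored.restored_edges == (0,)
        assert restored.data_term == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_restoration_never_changes_data_term(self, seed):
        net, data = random_small_instance(seed)
        model = build_model(net, data)
        res = solve(model)
        restored = restore_missing_edges(res, model)
        assert restored.data_term == res.data_term
        assert set(res.retained_edges) <= set(restored.retained_edges)


class TestFittingPrecision:
    def test_perfect_and_worst(self, toy_t1):
        net, data = toy_t1
        res = solve(build_model(net, data))
        assert fitting_precision(res) == pytest.approx(100.0)

    def test_paper_granularity(self):
        # 11 mismatches over 24 proteins x 3 timepoints
        assert 100 * (1 - 11 / 72) == pytest.approx(84.7222, abs=1e-3)

    def test_undefined_without_measurements(self, toy_t1):
        net, data = toy_t1
        res = solve(build_model(net, data))
        res2 = type(res)(**{**res.__dict__, "n_measured_entries": 0})
        with pytest.raises(ValueError, match="undefined"):
            fitting_precision(res2)


class TestNoiseBound:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_flips_raise_data_term_by_at_most_f(self, seed):
        from dilpnet import generate_measurements, make_random_network, make_root_program

        net = make_random_network(10, 14, n_roots=2, seed=seed)
        program = make_root_program(net, 3, seed=seed)
        clean = generate_measurements(net, program, 3, seed=seed)
        assert solve(build_model(net, clean.clean_table)).data_term == 0
        f = 4
        measured = clean.clean_table.proteins
        rng = np.random.default_rng(seed)
        idx = [
            (measured[int(i)], int(k))
            for i, k in zip(
                rng.choice(len(measured), f, replace=False),
                rng.integers(0, 3, f),
            )
        ]
        noisy = generate_measurements(net, program, 3, seed=seed, flip_indices=idx)
        res = solve(build_model(net, noisy.noisy_table))
        assert res.data_term <= f
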
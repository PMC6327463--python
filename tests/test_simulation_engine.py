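import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncmsim.knowledge_map import KnowledgeMap, NeutrosophicWeight
from ncmsim.simulation_engine import (
    ACTIVATIONS,
    SimulationProtocol,
    elliott,
    initial_state,
    mse,
    run,
    step,
)

from conftest import make_random_map


def dense_step_oracle(state, kmap, protocol):
    """Naive dense NxN reference for step(): raw_j = sum_i W[i][j] * state_i."""
    n = kmap.n_nodes
    dense = np.zeros((n, n))
    for (i, j), w in kmap.edges.items():
        dense[i, j] = w.value
    raw = np.array([sum(dense[i, j] * state[i] for i in range(n)) for j in range(n)])
    new = np.array([ACTIVATIONS[protocol.activation](float(r)) for r in raw])
    for label in protocol.locked_on:
        new[kmap.index(label)] = 1.0
    for label in protocol.locked_off:
        new[kmap.index(label)] = -1.0
    return new


class TestElliott:
    def test_zero_fixed_point(self):
        assert elliott(0.0) == 0.0

    def test_direct_evaluation(self):
        assert elliott(2.0) == pytest.approx(2.0 / 3.0)
        assert elliott(-2.0) == pytest.approx(-2.0 / 3.0)

    @given(st.floats(min_value=-1e6, max_value=1e6))
    def test_odd_bounded_formula(self, x):
        y = elliott(x)
        assert abs(y) < 1.0
        assert y == pytest.approx(x / (1.0 + abs(x)))
        assert elliott(-x) == -y

    @given(st.floats(min_value=-100, max_value=99))
    def test_strictly_increasing(self, x):
        assert elliott(x + 1.0) > elliott(x)

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -float("inf")])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(ValueError):
            elliott(bad)

    def test_vectorized(self):
        np.testing.assert_allclose(
            elliott(np.array([0.0, 2.0, -2.0])), [0.0, 2 / 3, -2 / 3]
        )


class TestProtocol:
    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SimulationProtocol(on_nodes={"A"}, locked_on={"A"})

    def test_bad_activation_rejected(self):
        with pytest.raises(ValueError, match="activation"):
            SimulationProtocol(activation="relu")

    @pytest.mark.parametrize("kwargs", [
        {"convergence_tolerance": 0.0},
        {"convergence_tolerance": -1.0},
        {"max_iterations": 0},
    ])
    def test_bad_run_controls_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationProtocol(**kwargs)

    def test_unknown_label_named_in_error(self):
        kmap = KnowledgeMap(labels=["A"])
        with pytest.raises(KeyError, match="NOPE"):
            SimulationProtocol(on_nodes={"NOPE"}).validate_against(kmap)

    def test_yaml_round_trip(self, tmp_path):
        proto = SimulationProtocol(
            on_nodes={"A", "B"}, locked_off={"C"}, convergence_tolerance=1e-4
        )
        path = tmp_path / "p.yaml"
        import yaml

        path.write_text(yaml.safe_dump(proto.to_dict()))
        assert SimulationProtocol.from_file(path) == proto


class TestInitialState:
    def test_empty_protocol_is_zero_vector(self):
        kmap = KnowledgeMap(labels=["A", "B", "C"])
        np.testing.assert_array_equal(
            initial_state(kmap, SimulationProtocol()), [0.0, 0.0, 0.0]
        )

    def test_on_nodes_plus_one_in_node_order(self):
        kmap = KnowledgeMap(labels=["OCT4", "SOX2", "KLF4", "CMYC"])
        x = initial_state(kmap, SimulationProtocol(on_nodes={"OCT4", "SOX2"}))
        np.testing.assert_array_equal(x, [1.0, 1.0, 0.0, 0.0])

    def test_locked_off_minus_one(self):
        kmap = KnowledgeMap(labels=["MECP2", "X"])
        x = initial_state(kmap, SimulationProtocol(locked_off={"MECP2"}))
        np.testing.assert_array_equal(x, [-1.0, 0.0])


class TestStep:
    def make_ab(self):
        return KnowledgeMap(labels=["A", "B"], edges={(0, 1): NeutrosophicWeight(1.0)})

    def test_hand_evaluation_first_step(self):
        kmap = self.make_ab()
        out = step(np.array([1.0, 0.0]), kmap, SimulationProtocol())
        np.testing.assert_allclose(out, [0.0, 0.5])

    def test_hand_evaluation_second_step_decays(self):
        kmap = self.make_ab()
        out = step(np.array([0.0, 0.5]), kmap, SimulationProtocol())
        np.testing.assert_allclose(out, [0.0, 0.0])

    def test_self_loop_and_clamp(self):
        kmap = KnowledgeMap(labels=["A"], edges={(0, 0): NeutrosophicWeight(1.0)})
        np.testing.assert_allclose(
            step(np.array([1.0]), kmap, SimulationProtocol()), [0.5]
        )
        np.testing.assert_allclose(
            step(np.array([1.0]), kmap, SimulationProtocol(locked_on={"A"})), [1.0]
        )

    def test_input_untouched(self):
        kmap = self.make_ab()
        x = np.array([1.0, 0.0])
        step(x, kmap, SimulationProtocol())
        np.testing.assert_array_equal(x, [1.0, 0.0])

    def test_indeterminate_edges_are_precondition_error(self, abc_map):
        with pytest.raises(ValueError, match="to_fuzzy"):
            step(np.zeros(3), abc_map, SimulationProtocol())

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            step(np.zeros(3), self.make_ab(), SimulationProtocol())

    def test_sparse_agrees_with_dense_oracle(self, rng):
        for _ in range(30):
            kmap = make_random_map(rng, n_max=50, indet_prob=0.0)
            if kmap.n_nodes == 0:
                continue
            labels = kmap.labels
            protocol = SimulationProtocol(
                locked_on={labels[0]} if kmap.n_nodes > 1 else frozenset(),
                locked_off={labels[1]} if kmap.n_nodes > 1 else frozenset(),
            )
            x = rng.uniform(-1, 1, size=kmap.n_nodes)
            np.testing.assert_allclose(
                step(x, kmap, protocol),
                dense_step_oracle(x, kmap, protocol),
                atol=1e-12,
            )


class TestMse:
    def test_identical_vectors(self):
        assert mse(np.array([0.3, -0.7]), np.array([0.3, -0.7])) == 0.0

    def test_unit_displacement(self):
        assert mse(np.zeros(2), np.ones(2)) == 1.0

    def test_hand_evaluation(self):
        assert mse(np.array([0.5, 0.0]), np.zeros(2)) == pytest.approx(0.125)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mse(np.zeros(2), np.zeros(3))

    def test_empty_undefined(self):
        with pytest.raises(ValueError):
            mse(np.zeros(0), np.zeros(0))


class TestRun:
    def test_zero_edge_map_converges_iteration_two(self):
        kmap = KnowledgeMap(labels=["A", "B", "C"])
        res = run(kmap, SimulationProtocol(on_nodes={"A"}))
        assert res.converged
        assert res.iterations_to_converge == 2
        np.testing.assert_array_equal(res.final_state, np.zeros(3))
        assert res.mse_trajectory[0] == pytest.approx(1 / 3)
        assert res.mse_trajectory[1] == 0.0

    def test_all_locked_fixed_point_equals_initial_state(self):
        kmap = KnowledgeMap(labels=["A", "B", "C"],
                            edges={(0, 1): NeutrosophicWeight(1.0)})
        protocol = SimulationProtocol(locked_on={"A"}, locked_off={"B"})
        res = run(kmap, protocol)
        assert res.converged
        np.testing.assert_array_equal(
            res.final_state, initial_state(kmap, protocol)
        )

    def test_run_fuzzifies_itself(self, abc_map):
        res = run(abc_map, SimulationProtocol(on_nodes={"A"}))
        assert res.converged

    def test_converged_iff_min_mse_below_tolerance(self, rng):
        for _ in range(10):
            kmap = make_random_map(rng, n_max=20, indet_prob=0.0)
            if kmap.n_nodes < 2:
                continue
            protocol = SimulationProtocol(
                on_nodes={kmap.labels[0]}, max_iterations=40
            )
            res = run(kmap, protocol)
            assert res.converged == (
                min(res.mse_trajectory) < protocol.convergence_tolerance
            )
            if res.converged:
                below = [t for t, m in enumerate(res.mse_trajectory, start=1)
                         if m < protocol.convergence_tolerance]
                assert res.iterations_to_converge == below[0]

    def test_non_convergence_flagged(self):
        # period-2 flip-flop: locked driver pushes A, A drives B, B opposes A
        kmap = KnowledgeMap(labels=["D", "A", "B"])
        kmap.add_edge("D", "A", 1.0)
        kmap.add_edge("A", "B", 1.0)
        kmap.add_edge("B", "A", -1.0)
        res = run(kmap, SimulationProtocol(locked_on={"D"}, max_iterations=3))
        assert not res.converged
        assert res.iterations_to_converge is None
        assert len(res.mse_trajectory) == 3

    def test_trajectory_never_longer_than_max_iterations(self):
        kmap = KnowledgeMap(labels=["A"], edges={(0, 0): NeutrosophicWeight(1.0)})
        res = run(kmap, SimulationProtocol(on_nodes={"A"}, max_iterations=5))
        assert len(res.mse_trajectory) <= 5


class TestEngineProperties:
    def run_trajectory(self, kmap, protocol, n_steps=30):
        xs = [initial_state(kmap, protocol)]
        matrix = kmap.weight_matrix()
        for _ in range(n_steps):
            xs.append(step(xs[-1], kmap, protocol, matrix=matrix))
        return xs

    def test_boundedness_of_unclamped_components(self, rng):
        for _ in range(10):
            kmap = make_random_map(rng, n_max=30, indet_prob=0.0)
            if kmap.n_nodes == 0:
                continue
            protocol = SimulationProtocol(on_nodes={kmap.labels[0]})
            for x in self.run_trajectory(kmap, protocol)[1:]:
                assert np.all(np.abs(x) < 1.0)

    def test_sign_antisymmetry_negated_initialization(self, rng):
        # Because the activation is odd and the VMM linear, negating every
        # initial and clamped value (same weights) negates the trajectory
        # exactly.  (Negating the weights as well would cancel out: the raw
        # sums (-x)(-W) = xW are unchanged.)
        for _ in range(10):
            kmap = make_random_map(rng, n_max=20, indet_prob=0.0)
            if kmap.n_nodes < 2:
                continue
            proto = SimulationProtocol(on_nodes={kmap.labels[0]},
                                       locked_on={kmap.labels[1]})
            proto_neg = SimulationProtocol(off_nodes={kmap.labels[0]},
                                           locked_off={kmap.labels[1]})
            for x, y in zip(self.run_trajectory(kmap, proto),
                            self.run_trajectory(kmap, proto_neg)):
                np.testing.assert_array_equal(y, -x)  # exact, not approximate

    def test_locked_nodes_hold_clamp_every_iteration(self, rng):
        kmap = make_random_map(rng, n_max=20, indet_prob=0.0)
        while kmap.n_nodes < 3:
            kmap = make_random_map(rng, n_max=20, indet_prob=0.0)
        protocol = SimulationProtocol(locked_on={kmap.labels[0]},
                                      locked_off={kmap.labels[2]})
        for x in self.run_trajectory(kmap, protocol):
            assert x[0] == 1.0
            assert x[2] == -1.0

    def test_deterministic_bit_identical_reruns(self, rng):
        kmap = make_random_map(rng, n_max=30, indet_prob=0.0)
        while kmap.n_nodes == 0:
            kmap = make_random_map(rng, n_max=30, indet_prob=0.0)
        protocol = SimulationProtocol(on_nodes={kmap.labels[0]})
        r1, r2 = run(kmap, protocol), run(kmap, protocol)
        assert r1.final_state.tobytes() == r2.final_state.tobytes()
        assert r1.mse_trajectory == r2.mse_trajectory


class TestClosedFormFixedPoints:
    def scalar_oracle(self, gain_input, n_iter=500):
        """Brute-force scalar iteration x <- f(a + 0*x) style driver feed."""
        x = 0.0
        for _ in range(n_iter):
            x = gain_input / (1.0 + abs(gain_input))
        return x

    def test_self_loop_weight_in_unit_interval_decays_to_zero(self):
        # w < 1 contracts geometrically; w = 1 decays harmonically
        # (x -> x/(1+x) ~ 1/t), so the MSE rule stops near x ~ sqrt(tol).
        for w, bound in ((0.25, 1e-5), (0.5, 1e-4), (1.0, 5e-3)):
            kmap = KnowledgeMap(labels=["A"], edges={(0, 0): NeutrosophicWeight(w)})
            res = run(kmap, SimulationProtocol(on_nodes={"A"},
                                               convergence_tolerance=1e-10,
                                               max_iterations=10000,
                                               overtraining_check=False))
            assert abs(res.final_state[0]) < bound

    @pytest.mark.parametrize("gain", [1.25, 1.5, 2.0, 4.0])
    def test_driver_fed_node_matches_analytic_fixed_point(self, gain):
        # x* solves x = g*x/(1 + g*x)  =>  x* = (g - 1)/g
        a = gain - 1.0
        n_drivers = max(1, math.ceil(a))
        labels = ["T"] + [f"D{i}" for i in range(n_drivers)]
        kmap = KnowledgeMap(labels=labels)
        for i in range(n_drivers):
            kmap.add_edge(f"D{i}", "T", a / n_drivers)
        protocol = SimulationProtocol(locked_on=frozenset(labels[1:]))
        res = run(kmap, protocol)
        assert res.converged
        analytic = (gain - 1.0) / gain
        # independent scalar brute-force oracle for the same drive
        oracle = self.scalar_oracle(a)
        assert oracle == pytest.approx(analytic, abs=1e-9)
        assert res.final_state[0] == pytest.approx(
            analytic, abs=protocol.convergence_tolerance
        )
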
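"""Recurrence plots, the rewriting grammar, and state extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recurseg import (
    ContractViolationError,
    DimensionError,
    InputError,
    ParameterError,
    RecurrencePlot,
    SymbolicSequence,
    Trajectory,
    cosine_distance,
    extract_states,
    normalize_trajectory,
    recurrence_grammar_segment,
    recurrence_plot,
    relabel_transients,
)
from conftest import random_unit_rows


class TestCosineDistance:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 0), (1, 0), 0.0),
            ((1, 0), (0, 1), 1.0),
            ((1, 0), (-1, 0), 2.0),
        ],
    )
    def test_unit_vector_examples(self, x, y, expected):
        assert cosine_distance(np.array(x, float), np.array(y, float)) == pytest.approx(expected)
        assert cosine_distance(np.array(y, float), np.array(x, float)) == pytest.approx(expected)

    def test_rejects_length_mismatch(self):
        with pytest.raises(DimensionError):
            cosine_distance(np.array([1.0, 0.0]), np.array([1.0, 0.0, 0.0]))

    def test_rejects_non_unit_input(self):
        with pytest.raises(ContractViolationError):
            cosine_distance(np.array([2.0, 0.0]), np.array([1.0, 0.0]))


class TestNormalizeTrajectory:
    def test_unit_mode_scales_rows(self):
        traj = Trajectory(np.array([[3.0, 4.0], [1.0, 0.0]]))
        out = normalize_trajectory(traj, mode="unit")
        np.testing.assert_allclose(out.values[0], [0.6, 0.8])

    def test_unit_mode_idempotent(self, rng):
        values = random_unit_rows(rng, 20, 5)
        out = normalize_trajectory(Trajectory(values), mode="unit")
        np.testing.assert_allclose(out.values, values, atol=1e-12)

    def test_zscore_unit_hand_example(self):
        traj = Trajectory(np.array([[1.0, 2.0], [3.0, 4.0]]))
        out = normalize_trajectory(traj, mode="zscore_unit")
        r = 1.0 / np.sqrt(2.0)
        np.testing.assert_allclose(out.values, [[-r, -r], [r, r]])

    def test_zero_norm_row_names_time_index(self):
        traj = Trajectory(np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]]))
        with pytest.raises(InputError, match="2"):
            normalize_trajectory(traj, mode="unit")

    def test_zero_variance_column_is_centered_only(self, caplog):
        traj = Trajectory(np.array([[1.0, 5.0], [2.0, 5.0], [4.0, 5.0]]))
        with caplog.at_level("WARNING"):
            out = normalize_trajectory(traj, mode="zscore_unit")
        assert "zero-variance" in caplog.text
        norms = np.linalg.norm(out.values, axis=1)
        np.testing.assert_allclose(norms, 1.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ParameterError):
            normalize_trajectory(Trajectory(np.eye(2)), mode="bogus")


class TestRecurrencePlot:
    def test_revisit_is_the_only_offdiagonal_pair(self):
        traj = normalize_trajectory(
            Trajectory(np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])), "unit"
        )
        rp = recurrence_plot(traj, epsilon=0.5)
        expected = np.eye(3, dtype=bool)
        expected[0, 2] = expected[2, 0] = True
        np.testing.assert_array_equal(rp.matrix, expected)

    def test_epsilon_above_range_gives_all_ones(self, rng):
        traj = Trajectory(random_unit_rows(rng, 15, 4))
        rp = recurrence_plot(normalize_trajectory(traj, "unit"), epsilon=2.5)
        assert rp.matrix.all()

    def test_epsilon_below_min_distance_gives_identity(self, rng):
        values = random_unit_rows(rng, 12, 6)
        traj = normalize_trajectory(Trajectory(values), "unit")
        d = 1.0 - values @ values.T
        min_nonzero = d[~np.eye(12, dtype=bool)].min()
        rp = recurrence_plot(traj, epsilon=min_nonzero / 2)
        np.testing.assert_array_equal(rp.matrix, np.eye(12, dtype=bool))

    def test_rejects_nonpositive_epsilon(self, rng):
        traj = normalize_trajectory(Trajectory(random_unit_rows(rng, 5, 3)), "unit")
        with pytest.raises(ParameterError):
            recurrence_plot(traj, epsilon=0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=40), st.floats(min_value=1e-3, max_value=2.0))
    def test_symmetry_and_unit_diagonal(self, t, epsilon):
        rng = np.random.default_rng(t * 1000 + int(epsilon * 100))
        traj = normalize_trajectory(Trajectory(random_unit_rows(rng, t, 3)), "unit")
        rp = recurrence_plot(traj, epsilon)
        np.testing.assert_array_equal(rp.matrix, rp.matrix.T)
        assert rp.matrix.diagonal().all()


def _component_min_oracle(adjacency: np.ndarray) -> np.ndarray:
    """Independent oracle: map each vertex to the minimal 1-based index of
    its connected component, via graph traversal."""
    import networkx as nx

    g = nx.from_numpy_array(adjacency)
    out = np.zeros(adjacency.shape[0], dtype=np.int64)
    for comp in nx.connected_components(g):
        label = min(comp) + 1
        for v in comp:
            out[v] = label
    return out


class TestRecurrenceGrammar:
    def test_identity_plot_keeps_time_indices(self):
        rp = RecurrencePlot(np.eye(4, dtype=bool), 0.1)
        np.testing.assert_array_equal(recurrence_grammar_segment(rp).symbols, [1, 2, 3, 4])

    def test_all_ones_plot_collapses_to_one_symbol(self):
        rp = RecurrencePlot(np.ones((4, 4), dtype=bool), 0.1)
        np.testing.assert_array_equal(recurrence_grammar_segment(rp).symbols, [1, 1, 1, 1])

    def test_two_pass_hand_rewriting_example(self):
        # recurrent pairs (3,1) and (5,3): components {1,3,5}, {2}, {4}
        m = np.eye(5, dtype=bool)
        m[2, 0] = m[0, 2] = True
        m[4, 2] = m[2, 4] = True
        seq = recurrence_grammar_segment(RecurrencePlot(m, 0.1))
        np.testing.assert_array_equal(seq.symbols, [1, 2, 1, 4, 1])

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_connected_component_oracle(self, trial):
        rng = np.random.default_rng(trial)
        for _ in range(25):
            t = int(rng.integers(2, 201))
            density = rng.uniform(0.0, 0.15)
            m = rng.random((t, t)) < density
            m = m | m.T
            np.fill_diagonal(m, True)
            got = recurrence_grammar_segment(RecurrencePlot(m, 0.1)).symbols
            np.testing.assert_array_equal(got, _component_min_oracle(m))

    def test_fixed_point_is_idempotent(self, rng):
        t = 60
        m = rng.random((t, t)) < 0.05
        m = m | m.T
        np.fill_diagonal(m, True)
        once = recurrence_grammar_segment(RecurrencePlot(m, 0.1)).symbols
        # re-apply: every symbol must already be its component minimum
        again = recurrence_grammar_segment(RecurrencePlot(m, 0.1)).symbols
        np.testing.assert_array_equal(once, again)
        # symbols never exceed their own 1-based time index
        assert np.all(once <= np.arange(1, t + 1))


class TestRelabelTransients:
    def test_singleton_classes_become_transient(self):
        seq, n = relabel_transients(SymbolicSequence(np.array([1, 2, 1, 4, 1])))
        np.testing.assert_array_equal(seq.symbols, [1, 0, 1, 0, 1])
        assert n == 2

    def test_surviving_class_keeps_label(self):
        seq, n = relabel_transients(SymbolicSequence(np.array([1, 1, 1])))
        np.testing.assert_array_equal(seq.symbols, [1, 1, 1])
        assert n == 2

    def test_all_singletons_all_transient(self):
        seq, n = relabel_transients(SymbolicSequence(np.array([1, 2, 3])))
        np.testing.assert_array_equal(seq.symbols, [0, 0, 0])
        assert n == 1

    def test_min_dwell_validation(self):
        with pytest.raises(ParameterError):
            relabel_transients(SymbolicSequence(np.array([1, 1])), min_dwell=0)


class TestExtractStates:
    def test_symbol_groups_and_transients(self):
        traj = normalize_trajectory(
            Trajectory(np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])), "unit"
        )
        part = extract_states(traj, SymbolicSequence(np.array([1, 0, 1])))
        np.testing.assert_array_equal(part.classes[1], [1, 3])
        np.testing.assert_array_equal(part.transient_times, [2])
        np.testing.assert_allclose(part.clouds[1], [[1, 0], [1, 0]])

    def test_all_transient_gives_no_classes(self, rng):
        traj = normalize_trajectory(Trajectory(random_unit_rows(rng, 3, 2)), "unit")
        part = extract_states(traj, SymbolicSequence(np.zeros(3, dtype=int)))
        assert part.classes == {}
        assert part.transient_times.size == 3

    def test_two_classes_of_two(self, rng):
        traj = normalize_trajectory(Trajectory(random_unit_rows(rng, 4, 3)), "unit")
        part = extract_states(traj, SymbolicSequence(np.array([1, 1, 4, 4])))
        assert {k: v.size for k, v in part.classes.items()} == {1: 2, 4: 2}

    def test_partition_property_on_random_sequences(self, rng):
        for _ in range(20):
            t = int(rng.integers(2, 50))
            traj = normalize_trajectory(Trajectory(random_unit_rows(rng, t, 4)), "unit")
            symbols = rng.integers(0, 4, size=t)
            part = extract_states(traj, SymbolicSequence(symbols))
            pooled = np.concatenate(
                [part.transient_times] + [v for v in part.classes.values()]
            )
            assert sorted(pooled.tolist()) == list(range(1, t + 1))

    def test_length_mismatch_rejected(self, rng):
        traj = normalize_trajectory(Trajectory(random_unit_rows(rng, 4, 2)), "unit")
        with pytest.raises(DimensionError):
            extract_states(traj, SymbolicSequence(np.array([1, 1])))


class TestEpsilonLimits:
    def test_epsilon_above_diameter_gives_single_class(self, rng):
        traj = normalize_trajectory(Trajectory(random_unit_rows(rng, 30, 4)), "unit")
        seq, n = relabel_transients(
            recurrence_grammar_segment(recurrence_plot(traj, 2.5))
        )
        assert n - 1 == 1
        assert set(seq.symbols) == {1}

    def test_epsilon_below_min_distance_makes_everything_transient(self, rng):
        values = random_unit_rows(rng, 20, 5)
        traj = normalize_trajectory(Trajectory(values), "unit")
        d = 1.0 - values @ values.T
        eps = d[~np.eye(20, dtype=bool)].min() / 2
        seq, n = relabel_transients(
            recurrence_grammar_segment(recurrence_plot(traj, eps))
        )
        assert n - 1 == 0
        assert set(seq.symbols) == {0}
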
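"""Walk-circuit components: shift, coin, oracle, phase estimation, full
search."""

import itertools

import numpy as np
import pytest

from kmerwalk import qsim, walk
from kmerwalk.qsim import StateVector
from kmerwalk.walk import (
    DEFAULT_LAYOUT,
    RegisterLayout,
    SearchConfig,
    build_search_circuit,
    exact_node_marginal,
    grover_coin,
    phase_estimation_reflection,
    phase_oracle,
    run_search,
    shift_operator,
    walk_step,
)

from conftest import random_state

COIN_NODE_BASIS = [c * 256 + n * 16 for c in range(4) for n in range(16)]


def _restricted_matrix(seq):
    """64x64 action on the coin x node subspace (theta = aux = 0)."""
    mat = np.zeros((2048, 64), dtype=complex)
    mat[COIN_NODE_BASIS, np.arange(64)] = 1.0
    for step in seq:
        qsim._apply_inplace(mat, step, 11)
    return mat[COIN_NODE_BASIS, :]


class TestLayout:
    def test_default_partition(self):
        lay = DEFAULT_LAYOUT
        assert lay.theta == (0, 1, 2, 3)
        assert lay.node == (4, 5, 6, 7)
        assert lay.coin == (8, 9)
        assert lay.auxiliary == 10

    def test_overlapping_registers_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            RegisterLayout(theta=(0, 1, 2, 4), node=(4, 5, 6, 7))


class TestShiftOperator:
    def test_permutation_along_hypercube_edges(self):
        mat = _restricted_matrix(shift_operator())
        assert np.abs(np.abs(mat).sum(axis=0) - 1).max() < 1e-12  # permutation
        for c, n in itertools.product(range(4), range(16)):
            col = mat[:, c * 16 + n]
            dest = int(np.argmax(np.abs(col)))
            c2, n2 = divmod(dest, 16)
            assert c2 == c, "coin register must be restored"
            assert n2 == n ^ (1 << c), "coin value c flips node bit c"

    def test_examples_from_transcribed_code(self):
        mat = _restricted_matrix(shift_operator())
        # (node 0000, coin 00) -> node 0001 ; (node 0000, coin 11) -> node 1000
        assert mat[0 * 16 + 0b0001, 0] == pytest.approx(1.0)
        assert mat[3 * 16 + 0b1000, 3 * 16 + 0] == pytest.approx(1.0)

    def test_applied_twice_is_identity(self):
        mat = _restricted_matrix(shift_operator() * 2)
        assert np.abs(mat - np.eye(64)).max() < 1e-12


class TestGroverCoin:
    def test_matrix_is_half_minus_delta(self):
        mat = _restricted_matrix(grover_coin())
        want = np.kron(0.5 - np.eye(4), np.eye(16))
        assert np.abs(mat - want).max() < 1e-12

    def test_uniform_coin_is_fixed(self):
        mat = _restricted_matrix(grover_coin())
        uniform = np.zeros(64)
        uniform[[c * 16 for c in range(4)]] = 0.5
        assert np.abs(mat @ uniform - uniform).max() < 1e-12

    def test_reflection_squares_to_identity(self):
        mat = _restricted_matrix(grover_coin() * 2)
        assert np.abs(mat - np.eye(64)).max() < 1e-12


class TestPhaseOracle:
    @pytest.mark.parametrize("mark", ["0000", "0110", "1011"])
    def test_diagonal_minus_one_at_mark(self, mark):
        u = qsim.sequence_unitary(phase_oracle(mark), 11)
        idx = np.arange(2048)
        node_val = (idx >> 4) & 0b1111
        want = np.where(node_val == int(mark, 2), -1.0, 1.0)
        assert np.abs(u - np.diag(want)).max() < 1e-9

    def test_applied_twice_is_identity(self, rng):
        psi = random_state(11, rng)
        out = qsim.apply_sequence(
            StateVector(11, psi), phase_oracle("0101") * 2
        )
        assert np.abs(out.amplitudes - psi).max() < 1e-9

    def test_bad_mark_rejected(self):
        with pytest.raises(ValueError, match="mark"):
            phase_oracle("012")


class TestWalkStep:
    def test_matrix_is_shift_times_coin(self):
        got = _restricted_matrix(walk_step())
        shift = _restricted_matrix(shift_operator())
        coin = np.kron(0.5 - np.eye(4), np.eye(16))
        assert np.abs(got - shift @ coin).max() < 1e-12

    def test_unitary_on_random_state(self, rng):
        psi = StateVector(11, random_state(11, rng))
        out = qsim.apply_sequence(psi, walk_step())
        assert out.norm() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_node_marginal_preserved(self):
        # vertex-transitive graph: the uniform walker stays uniform
        lay = DEFAULT_LAYOUT
        st = qsim.apply_sequence(
            qsim.basis_state(11, "0" * 11),
            [qsim.H(q) for q in (*lay.node, *lay.coin)] + walk_step(),
        )
        probs = qsim.node_marginal(st, lay)
        assert np.abs(probs - 1 / 16).max() < 1e-9


class TestPhaseEstimationReflection:
    def test_norm_preserved(self, rng):
        psi = StateVector(11, random_state(11, rng))
        out = qsim.apply_sequence(psi, phase_estimation_reflection())
        assert out.norm() == pytest.approx(1.0, abs=1e-9)

    def test_powers_block_and_adjoint_cancel(self, rng):
        a = walk._controlled_powers(DEFAULT_LAYOUT)
        psi = random_state(11, rng)
        out = qsim.apply_sequence(
            StateVector(11, psi), a + qsim.adjoint_sequence(a)
        )
        assert np.abs(out.amplitudes - psi).max() < 1e-9

    def test_identity_on_phase_zero_eigenvector(self):
        # uniform node+coin with theta=0000 is the walk's +1 eigenvector
        lay = DEFAULT_LAYOUT
        prep = [qsim.H(q) for q in (*lay.node, *lay.coin)]
        before = qsim.apply_sequence(qsim.basis_state(11, "0" * 11), prep)
        after = qsim.apply_sequence(before, phase_estimation_reflection())
        phase = after.amplitudes[np.argmax(np.abs(before.amplitudes))]
        phase /= before.amplitudes[np.argmax(np.abs(before.amplitudes))]
        assert np.abs(after.amplitudes - phase * before.amplitudes).max() < 1e-9


class TestSearchCircuit:
    def test_all_zeros_init_has_empty_x_prefix(self):
        seq = build_search_circuit("0" * 11, "0000", SearchConfig(iterations=1))
        assert seq[0].kind == "H"

    def test_x_prefix_matches_binary_value(self):
        # "01001100010" = 610 = bits {1, 5, 6, 9}
        seq = build_search_circuit(
            "01001100010", "0000", SearchConfig(iterations=1)
        )
        prefix = []
        for s in seq:
            if s.kind != "X" or s.controls:
                break
            prefix.append(s.target)
        assert sorted(prefix) == [1, 5, 6, 9]

    def test_full_circuit_preserves_norm(self, rng):
        seq = build_search_circuit("01001100010", "1101", SearchConfig(iterations=1))
        out = qsim.apply_sequence(StateVector(11, random_state(11, rng)), seq)
        assert out.norm() == pytest.approx(1.0, abs=1e-9)

    def test_bad_strings_rejected(self):
        with pytest.raises(ValueError, match="11"):
            build_search_circuit("0000", "0000", SearchConfig(iterations=1))
        with pytest.raises(ValueError, match="mark"):
            build_search_circuit("0" * 11, "00002", SearchConfig(iterations=1))


class TestRunSearch:
    def test_counts_sum_and_reproducibility(self):
        cfg = SearchConfig(shots=256, seed=7)
        a = run_search("00000000000", "0101", cfg)
        b = run_search("00000000000", "0101", cfg)
        assert a.counts.sum() == 256
        assert np.array_equal(a.counts, b.counts)
        assert (a.aux, a.coin, a.node, a.theta) == ("0", "00", "0000", "0000")

    def test_marked_state_dominates_from_all_zeros(self):
        rec = run_search("00000000000", "0000", SearchConfig(seed=3))
        assert rec.marked_hits() > 800

    def test_avoidance_pattern(self):
        rec = run_search("00000000001", "0000", SearchConfig(seed=3))
        assert rec.marked_hits() == rec.counts.min()
        assert rec.marked_hits() < 20


class TestExactProbabilities:
    def test_marked_state_argmax_for_all_marks_from_zeros(self):
        for m in range(16):
            probs = exact_node_marginal("0" * 11, format(m, "04b"))
            assert int(np.argmax(probs)) == m

    def test_avoidance_argmin(self):
        for m in (0, 5, 12):
            probs = exact_node_marginal("00000000001", format(m, "04b"))
            assert int(np.argmin(probs)) == m

    def test_mark_bit_permutation_symmetry(self):
        # relabeling node bits together with the mark leaves the marked
        # probability invariant (hypercube symmetry)
        base = exact_node_marginal("0" * 11, "0001")[0b0001]
        for mark in ("0010", "0100", "1000"):
            probs = exact_node_marginal("0" * 11, mark)
            assert probs[int(mark, 2)] == pytest.approx(base, abs=1e-9)

    def test_aux_bit_has_no_effect(self, rng):
        for _ in range(5):
            rest = format(rng.integers(1024), "010b")
            mark = format(rng.integers(16), "04b")
            p0 = exact_node_marginal("0" + rest, mark)
            p1 = exact_node_marginal("1" + rest, mark)
            assert np.abs(p0 - p1).max() < 1e-9
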
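"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use a different mechanism than the package:
gate matrices are assembled from explicit Kronecker products over control
projectors, so agreement with the strided statevector kernel is a real
cross-check.
"""

import itertools

import numpy as np
import pytest

from kmerwalk.qsim import GateStep

I2 = np.eye(2, dtype=complex)
P0 = np.array([[1, 0], [0, 0]], dtype=complex)
P1 = np.array([[0, 0], [0, 1]], dtype=complex)

GATE_MATRICES = {
    "X": np.array([[0, 1], [1, 0]], dtype=complex),
    "H": np.array([[1, 1], [1, -1]], dtype=complex) / np.sqrt(2),
    "Z": np.array([[1, 0], [0, -1]], dtype=complex),
}


def gate_matrix_2x2(step: GateStep) -> np.ndarray:
    if step.kind == "PHASE":
        return np.array([[1, 0], [0, np.exp(1j * step.angle)]], dtype=complex)
    return GATE_MATRICES[step.kind]


def brute_gate_matrix(n: int, step: GateStep) -> np.ndarray:
    """Full 2**n x 2**n matrix of a (multi-)controlled gate, built from
    Kronecker products: sum over control-bit assignments of projector
    chains, with the 2x2 gate at the target only when all controls are 1.
    Qubit q is bit q of the basis index (kron factors ordered MSB first).
    """
    controls = sorted(step.controls)
    m2 = gate_matrix_2x2(step)
    total = np.zeros((2**n, 2**n), dtype=complex)
    for assignment in itertools.product((0, 1), repeat=len(controls)):
        factors = []
        for q in range(n - 1, -1, -1):
            if q in controls:
                factors.append(P1 if assignment[controls.index(q)] else P0)
            elif q == step.target:
                factors.append(m2 if all(assignment) else I2)
            else:
                factors.append(I2)
        term = factors[0]
        for f in factors[1:]:
            term = np.kron(term, f)
        total += term
    return total


def random_state(n: int, rng: np.random.Generator) -> np.ndarray:
    amps = rng.normal(size=2**n) + 1j * rng.normal(size=2**n)
    return amps / np.linalg.norm(amps)


@pytest.fixture
def rng():
    return np.random.default_rng(20240912)
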
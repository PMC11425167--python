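"""Minimal exact statevector simulator.

Dense complex amplitudes over computational basis states; basis index ``b``
encodes qubit ``q`` as bit ``q`` of ``b`` (qubit 0 = least-significant bit).
Supports (multi-)controlled X / H / Z / PHASE gates, the quantum Fourier
transform, node-register marginalization and seeded multinomial shot
sampling.  Sized for the 11-qubit walk circuit (2048 amplitudes); anything
up to ~16 qubits is fine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

#: absolute tolerance on state norm / probability sums
NORM_TOL = 1e-9

GATE_KINDS = ("X", "H", "Z", "PHASE")

_SQRT1_2 = 1.0 / math.sqrt(2.0)


@dataclass(frozen=True)
class GateStep:
    """One gate application: ``kind`` on ``target``, conditioned on ``controls``.

    ``angle`` (radians) is meaningful for PHASE only.  X with one control is
    the CNOT; X with two controls the Toffoli.
    """

    kind: str
    target: int
    controls: frozenset = frozenset()
    angle: float = 0.0

    def __post_init__(self):
        if self.kind not in GATE_KINDS:
            raise ValueError(f"unknown gate kind {self.kind!r}")
        object.__setattr__(self, "controls", frozenset(self.controls))
        if self.target in self.controls:
            raise ValueError(
                f"target qubit {self.target} also appears in controls"
            )


def X(target: int, controls: Iterable[int] = ()) -> GateStep:
    return GateStep("X", target, frozenset(controls))


def H(target: int, controls: Iterable[int] = ()) -> GateStep:
    return GateStep("H", target, frozenset(controls))


def Z(target: int, controls: Iterable[int] = ()) -> GateStep:
    return GateStep("Z", target, frozenset(controls))


def PHASE(angle: float, target: int, controls: Iterable[int] = ()) -> GateStep:
    return GateStep("PHASE", target, frozenset(controls), angle)


@dataclass
class StateVector:
    """Normalized amplitudes over the 2**n_qubits computational basis."""

    n_qubits: int
    amplitudes: np.ndarray

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.complex128)
        if self.amplitudes.shape != (2**self.n_qubits,):
            raise ValueError(
                f"expected {2**self.n_qubits} amplitudes for "
                f"{self.n_qubits} qubits, got shape {self.amplitudes.shape}"
            )

    def norm(self) -> float:
        return float(np.sqrt(np.sum(np.abs(self.amplitudes) ** 2)))

    def probabilities(self) -> np.ndarray:
        return np.abs(self.amplitudes) ** 2

    def copy(self) -> "StateVector":
        return StateVector(self.n_qubits, self.amplitudes.copy())


def basis_state(n: int, bits: str) -> StateVector:
    """Computational basis state from an initialization string.

    The rightmost character maps to qubit 0, so the basis index is simply
    the string read as a binary number: ``basis_state(11, "01001100010")``
    puts amplitude 1 at index 610.
    """
    if len(bits) != n:
        raise ValueError(
            f"initialization string has length {len(bits)}, expected {n}"
        )
    for i, ch in enumerate(bits):
        if ch not in "01":
            raise ValueError(
                f"non-binary character {ch!r} at position {i} in "
                f"initialization string"
            )
    amps = np.zeros(2**n, dtype=np.complex128)
    amps[int(bits, 2)] = 1.0
    return StateVector(n, amps)


def _validate_step(step: GateStep, n: int) -> None:
    for q in (step.target, *step.controls):
        if not 0 <= q < n:
            raise ValueError(f"qubit index {q} out of range for {n} qubits")


def _apply_inplace(amps: np.ndarray, step: GateStep, n: int) -> None:
    """Apply one gate in place.

    ``amps`` has shape ``(2**n, ...)`` — trailing axes are batch columns, so
    the same kernel drives both statevectors and whole transfer matrices.
    Indexing is done through a ``(2,)*n`` view with basic (strided) slices:
    axis ``n-1-q`` of the view is qubit ``q``.
    """
    view = amps.reshape((2,) * n + amps.shape[1:])
    sel = [slice(None)] * view.ndim
    for c in step.controls:
        sel[n - 1 - c] = 1
    t_ax = n - 1 - step.target
    sel0, sel1 = list(sel), list(sel)
    sel0[t_ax] = 0
    sel1[t_ax] = 1
    sel0, sel1 = tuple(sel0), tuple(sel1)

    if step.kind == "X":
        tmp = view[sel0].copy()
        view[sel0] = view[sel1]
        view[sel1] = tmp
    elif step.kind == "H":
        a = view[sel0]
        b = view[sel1]
        na = (a + b) * _SQRT1_2
        nb = (a - b) * _SQRT1_2
        view[sel0] = na
        view[sel1] = nb
    elif step.kind == "Z":
        view[sel1] *= -1.0
    elif step.kind == "PHASE":
        view[sel1] *= np.exp(1j * step.angle)
    else:  # pragma: no cover - guarded by GateStep
        raise ValueError(step.kind)


def apply_gate(state: StateVector, step: GateStep) -> StateVector:
    """Return the state with one gate applied (norm-preserving)."""
    _validate_step(step, state.n_qubits)
    out = state.copy()
    _apply_inplace(out.amplitudes, step, state.n_qubits)
    return out


def apply_sequence(
    state: StateVector, seq: Sequence[GateStep]
) -> StateVector:
    """Left-to-right composition of :func:`apply_gate`."""
    out = state.copy()
    for i, step in enumerate(seq):
        try:
            _validate_step(step, state.n_qubits)
            _apply_inplace(out.amplitudes, step, state.n_qubits)
        except ValueError as exc:
            raise ValueError(f"step {i}: {exc}") from exc
    return out


def adjoint_sequence(seq: Sequence[GateStep]) -> list:
    """Exact adjoint: reversed order, PHASE angles negated (X/H/Z are
    self-adjoint)."""
    out = []
    for step in reversed(seq):
        if step.kind == "PHASE":
            out.append(replace(step, angle=-step.angle))
        else:
            out.append(step)
    return out


def _swap_steps(a: int, b: int) -> list:
    # SWAP as three CNOTs
    return [X(b, {a}), X(a, {b}), X(b, {a})]


def qft_sequence(qubits: Sequence[int], inverse: bool = False) -> list:
    """Quantum Fourier transform on the given qubits.

    ``qubits[j]`` carries bit ``j`` of the register value (``qubits[0]`` is
    the least-significant bit).  The matrix realized is
    ``F[y, x] = exp(2*pi*i*x*y/N) / sqrt(N)``; ``inverse=True`` yields the
    exact adjoint.  Bit-reversal is handled by explicit swap steps so the
    sequence is self-contained.
    """
    qubits = list(qubits)
    if not qubits:
        raise ValueError("QFT needs at least one qubit")
    if len(set(qubits)) != len(qubits):
        raise ValueError(f"duplicate qubit indices in {qubits}")
    m = len(qubits)
    steps = []
    for j in range(m - 1, -1, -1):
        steps.append(H(qubits[j]))
        for k in range(j - 1, -1, -1):
            steps.append(
                PHASE(math.pi / 2 ** (j - k), qubits[j], {qubits[k]})
            )
    for i in range(m // 2):
        steps.extend(_swap_steps(qubits[i], qubits[m - 1 - i]))
    if inverse:
        steps = adjoint_sequence(steps)
    return steps


def sequence_unitary(seq: Sequence[GateStep], n: int) -> np.ndarray:
    """Dense ``2**n x 2**n`` unitary realized by a gate sequence (column
    ``b`` is the image of basis state ``b``)."""
    mat = np.eye(2**n, dtype=np.complex128)
    for step in seq:
        _validate_step(step, n)
        _apply_inplace(mat, step, n)
    return mat


def marginal_probabilities(
    state: StateVector, register: Sequence[int]
) -> np.ndarray:
    """Probability vector over the values of a qubit register.

    ``register[j]`` is bit ``j`` of the reported value, so the entry at
    index ``v`` corresponds to the register string read MSB-first.
    """
    idx = np.arange(2**state.n_qubits)
    value = np.zeros_like(idx)
    for j, q in enumerate(register):
        value |= ((idx >> q) & 1) << j
    probs = np.bincount(
        value, weights=state.probabilities(), minlength=2 ** len(register)
    )
    return probs


def node_marginal(state: StateVector, layout) -> np.ndarray:
    """16-vector of node-register probabilities (sums to 1 within 1e-9)."""
    probs = marginal_probabilities(state, layout.node)
    total = probs.sum()
    if abs(total - 1.0) > NORM_TOL:
        raise ValueError(f"node marginal sums to {total}, state not normalized")
    return probs


def sample_counts(probs: np.ndarray, shots: int, seed) -> np.ndarray:
    """Seeded multinomial draw of ``shots`` measurements.

    ``seed`` may be an int, a ``numpy.random.SeedSequence`` or a
    ``numpy.random.Generator``.  Counts always sum to ``shots`` and are
    reproducible for a fixed seed.
    """
    probs = np.asarray(probs, dtype=float)
    if shots < 1:
        raise ValueError(f"shots must be positive, got {shots}")
    if probs.min() < -NORM_TOL:
        raise ValueError(
            f"negative probability {probs.min()} beyond tolerance"
        )
    probs = np.clip(probs, 0.0, None)
    total = probs.sum()
    if abs(total - 1.0) > NORM_TOL:
        raise ValueError(f"probabilities sum to {total}, cannot renormalize")
    probs = probs / total
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return rng.multinomial(shots, probs)
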
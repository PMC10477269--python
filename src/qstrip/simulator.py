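"""Exact statevector execution and seeded shot sampling.

Amplitude ordering is little-endian: basis index ``b`` holds qubit ``q``'s
value in bit ``q`` of ``b``.  The single terminal measurement is simulated
analytically — the strip qubit's marginal probability is read from the
statevector — and finite-shot readout is a seeded binomial draw from that
probability, which is exact for a circuit with one terminal measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circuits import Circuit, Gate

__all__ = ["StateVector", "ShotCounts", "run_statevector", "strip_p1", "sample_strip"]

DEFAULT_QUBIT_CAP = 20


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class StateVector:
    n_qubits: int
    amplitudes: np.ndarray

    @property
    def probabilities(self) -> np.ndarray:
        return np.abs(self.amplitudes) ** 2


@dataclass(frozen=True)
class ShotCounts:
    """Tally of 0/1 readouts of the strip qubit over ``shots`` repetitions."""

    shots: int
    counts: dict[int, int]
    seed: int

    @property
    def p1_estimate(self) -> float:
        return self.counts[1] / self.shots

    def to_json_dict(self) -> dict:
        return {
            "0": self.counts[0],
            "1": self.counts[1],
            "shots": self.shots,
            "seed": self.seed,
        }


def _target_matrix(gate: Gate) -> np.ndarray:
    name = gate.name
    if name == "H":
        return np.array([[1, 1], [1, -1]], dtype=complex) / math.sqrt(2)
    if name in ("X", "CX", "MCX"):
        return np.array([[0, 1], [1, 0]], dtype=complex)
    if name == "T":
        return np.array([[1, 0], [0, np.exp(1j * math.pi / 4)]])
    if name == "Tdg":
        return np.array([[1, 0], [0, np.exp(-1j * math.pi / 4)]])
    if name in ("RY", "CRY", "MCRY"):
        (theta,) = gate.params
        c, s = math.cos(theta / 2), math.sin(theta / 2)
        return np.array([[c, -s], [s, c]], dtype=complex)
    if name == "U":
        theta, phi, lam = gate.params
        c, s = math.cos(theta / 2), math.sin(theta / 2)
        return np.array(
            [
                [c, -np.exp(1j * lam) * s],
                [np.exp(1j * phi) * s, np.exp(1j * (phi + lam)) * c],
            ]
        )
    raise SimulationError(f"unsupported gate {name!r}")


def _apply(psi: np.ndarray, gate: Gate, n: int) -> None:
    """In-place application; psi has shape (2,)*n, axis n-1-q holds qubit q."""
    mat = _target_matrix(gate)
    ax = lambda q: n - 1 - q
    idx: list = [slice(None)] * n
    for ctrl, bit in zip(gate.controls, gate.control_pattern):
        idx[ax(ctrl)] = bit
    t_ax = ax(gate.target) - sum(1 for c in gate.controls if ax(c) < ax(gate.target))
    sub = psi[tuple(idx)]
    sub = np.moveaxis(sub, t_ax, 0)
    sub = np.tensordot(mat, sub, axes=([1], [0]))
    psi[tuple(idx)] = np.moveaxis(sub, 0, t_ax)


def run_statevector(circuit: Circuit, *, qubit_cap: int = DEFAULT_QUBIT_CAP) -> StateVector:
    """Apply every gate in order to |0...0>; MEASURE is skipped.

    Raises when the circuit exceeds ``qubit_cap`` qubits (the dense state
    needs 2^n amplitudes) or contains a gate the simulator does not model.
    """
    n = circuit.n_qubits
    if n > qubit_cap:
        raise SimulationError(f"{n} qubits exceeds the cap of {qubit_cap}")
    psi = np.zeros((2,) * n, dtype=complex)
    psi[(0,) * n] = 1.0
    for gate in circuit.gates:
        if gate.name == "MEASURE":
            continue
        _apply(psi, gate, n)
    flat = psi.reshape(-1)
    norm = np.linalg.norm(flat)
    if abs(norm - 1.0) > 1e-12:
        raise SimulationError(f"norm drifted to {norm!r}")
    return StateVector(n_qubits=n, amplitudes=flat)


def strip_p1(state: StateVector, strip_qubit: int) -> float:
    """Marginal probability that ``strip_qubit`` reads 1."""
    if not (0 <= strip_qubit < state.n_qubits):
        raise SimulationError(f"qubit index {strip_qubit} out of range")
    idx = np.arange(state.amplitudes.size)
    mask = (idx >> strip_qubit) & 1 == 1
    return float(np.sum(state.probabilities[mask]))


def sample_strip(p1: float, shots: int, seed: int) -> ShotCounts:
    """Seeded Bernoulli(p1) readout of the strip qubit, ``shots`` times."""
    if not (0.0 <= p1 <= 1.0):
        raise SimulationError(f"p1={p1!r} is not a probability")
    if shots < 1:
        raise SimulationError(f"shots must be >= 1, got {shots}")
    ones = int(np.random.default_rng(seed).binomial(shots, p1))
    return ShotCounts(shots=shots, counts={0: shots - ones, 1: ones}, seed=int(seed))
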
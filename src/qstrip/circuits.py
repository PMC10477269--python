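"""Gate-list circuits for FRQI encoding and strip-qubit comparison.

The comparison circuit puts the strip qubit and the k-qubit index register
into uniform superposition, then writes each sequence's per-position angle
onto the value qubit with multi-controlled RY rotations — the strip qubit's
value selects the reference (|0>) or compared (|1>) branch, the index
register selects the position.  A final Hadamard on the strip converts the
branch overlap into the measured probability P1.

Qubit layout is ``[strip, index_{k-1} ... index_0, value]`` with the
position encoded big-endian on the index register.  Amplitude ordering in
the simulator is little-endian (basis index bit q is qubit q), fixed in
:mod:`qstrip.simulator`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .alphabet import EncodedSequence

__all__ = [
    "Gate",
    "Circuit",
    "build_comparison_circuit",
    "mcry_to_basis",
    "decompose_to_basis",
    "toffoli_basis_circuit",
    "circuit_depth",
    "gate_counts",
    "export_qasm",
]


class CircuitError(ValueError):
    """Malformed gate or circuit."""


# name -> (number of params, number of controls; None = any >= 1)
_GATE_SPECS: dict[str, tuple[int, int | None]] = {
    "H": (0, 0),
    "X": (0, 0),
    "T": (0, 0),
    "Tdg": (0, 0),
    "RY": (1, 0),
    "U": (3, 0),
    "CX": (0, 1),
    "CRY": (1, 1),
    "MCRY": (1, None),
    "MCX": (0, None),
    "MEASURE": (0, 0),
}


@dataclass(frozen=True)
class Gate:
    """One gate: ``qubits`` lists controls first, target last.

    ``control_pattern[j]`` is the classical value (0 or 1) the j-th control
    must hold for the target operation to fire; it defaults to all ones.
    """

    name: str
    qubits: tuple[int, ...]
    params: tuple[float, ...] = ()
    control_pattern: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.name not in _GATE_SPECS:
            raise CircuitError(f"unknown gate name {self.name!r}")
        n_params, n_controls = _GATE_SPECS[self.name]
        object.__setattr__(self, "qubits", tuple(int(q) for q in self.qubits))
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if len(self.params) != n_params:
            raise CircuitError(
                f"{self.name} takes {n_params} parameter(s), got {len(self.params)}"
            )
        if len(set(self.qubits)) != len(self.qubits):
            raise CircuitError(f"{self.name} has repeated qubits {self.qubits}")
        nc = len(self.qubits) - 1 if n_controls is None else n_controls
        if n_controls is None and nc < 1:
            raise CircuitError(f"{self.name} needs at least one control")
        if len(self.qubits) != nc + 1:
            raise CircuitError(
                f"{self.name} needs {nc + 1} qubit(s), got {len(self.qubits)}"
            )
        pattern = self.control_pattern or (1,) * nc
        pattern = tuple(int(b) for b in pattern)
        if len(pattern) != nc or any(b not in (0, 1) for b in pattern):
            raise CircuitError(
                f"control pattern {pattern} does not match {nc} control(s)"
            )
        object.__setattr__(self, "control_pattern", pattern)

    @property
    def n_controls(self) -> int:
        return len(self.control_pattern)

    @property
    def controls(self) -> tuple[int, ...]:
        return self.qubits[: self.n_controls]

    @property
    def target(self) -> int:
        return self.qubits[-1]


@dataclass(frozen=True)
class Circuit:
    """Ordered gate list over named registers plus one classical bit."""

    n_qubits: int
    gates: tuple[Gate, ...]
    registers: dict[str, tuple[int, ...]] = field(default_factory=dict)
    n_clbits: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "gates", tuple(self.gates))
        for g in self.gates:
            if any(not (0 <= q < self.n_qubits) for q in g.qubits):
                raise CircuitError(
                    f"gate {g.name} on {g.qubits} out of range for "
                    f"{self.n_qubits} qubits"
                )
        measures = [i for i, g in enumerate(self.gates) if g.name == "MEASURE"]
        if measures and measures != [len(self.gates) - 1]:
            raise CircuitError("MEASURE must be the single final gate")

    @property
    def strip_qubit(self) -> int:
        return self.registers["strip"][0]


def build_comparison_circuit(
    ref: EncodedSequence,
    cmp: EncodedSequence,
    *,
    elide_zero_angles: bool = False,
) -> Circuit:
    """Strip-qubit comparison circuit for two identically padded sequences.

    For each position ``i`` and each strip value ``s`` one MCRY writes the
    branch's state angle theta onto the value qubit (reference angles when
    the strip holds 0, compared angles when it holds 1); ``RY(theta)|0>``
    leaves the value qubit in ``cos(theta/2)|0> + sin(theta/2)|1>``.
    Zero-angle rotations are emitted by default and skipped when
    ``elide_zero_angles`` is set.
    """
    if ref.n_index_qubits != cmp.n_index_qubits:
        raise CircuitError(
            f"index-register mismatch: {ref.n_index_qubits} vs "
            f"{cmp.n_index_qubits} qubits (pad the pair identically first)"
        )
    k = ref.n_index_qubits
    strip = 0
    index = tuple(range(1, 1 + k))  # index[0] is the most significant bit
    value = 1 + k
    registers = {"strip": (strip,), "index": index, "value": (value,)}

    gates: list[Gate] = [Gate("H", (strip,))]
    gates += [Gate("H", (q,)) for q in index]
    for s, enc in ((0, ref), (1, cmp)):
        for i, theta in enumerate(enc.state_angles):
            if elide_zero_angles and theta == 0.0:
                continue
            bits = tuple((i >> (k - 1 - j)) & 1 for j in range(k))
            gates.append(
                Gate(
                    "MCRY" if k else "CRY",
                    (strip, *index, value),
                    params=(float(theta),),
                    control_pattern=(s, *bits),
                )
            )
    gates.append(Gate("H", (strip,)))
    gates.append(Gate("MEASURE", (strip,)))
    return Circuit(n_qubits=2 + k, gates=gates, registers=registers)


# -- decomposition to the {U, CX} basis -----------------------------------

def _multiplexed_ry(
    angles: Sequence[float], controls: Sequence[int], target: int
) -> list[Gate]:
    # Uniformly controlled RY: rotation angles[j] when the controls spell j
    # (first control = MSB).  Recursive halving; 2^c RY and 2^c CX, no
    # ancilla.  CX conjugation flips the sign of the later half-rotations,
    # which is what makes the two branches resolve to their own angles.
    if not controls:
        return [Gate("U", (target,), params=(float(angles[0]), 0.0, 0.0))]
    half = len(angles) // 2
    lo, hi = np.asarray(angles[:half]), np.asarray(angles[half:])
    out = _multiplexed_ry((lo + hi) / 2.0, controls[1:], target)
    out.append(Gate("CX", (controls[0], target)))
    out += _multiplexed_ry((lo - hi) / 2.0, controls[1:], target)
    out.append(Gate("CX", (controls[0], target)))
    return out


def mcry_to_basis(gate: Gate) -> list[Gate]:
    """Ancilla-free expansion of RY/CRY/MCRY into {U, CX} gates.

    The multi-controlled rotation is realised as a uniformly controlled RY
    whose only non-zero slot is the gate's control pattern; the unitary of
    the returned product matches the input gate to better than 1e-9.
    A bare RY comes back as a single equivalent U.
    """
    if gate.name not in ("RY", "CRY", "MCRY"):
        raise CircuitError(f"mcry_to_basis cannot expand {gate.name}")
    theta = gate.params[0]
    c = gate.n_controls
    if c == 0:
        return [Gate("U", (gate.target,), params=(theta, 0.0, 0.0))]
    slot = 0
    for bit in gate.control_pattern:
        slot = (slot << 1) | bit
    angles = np.zeros(2**c)
    angles[slot] = theta
    return _multiplexed_ry(angles, gate.controls, gate.target)


_U_EQUIV = {
    "H": (math.pi / 2, 0.0, math.pi),
    "X": (math.pi, 0.0, math.pi),
    "T": (0.0, 0.0, math.pi / 4),
    "Tdg": (0.0, 0.0, -math.pi / 4),
}


def decompose_to_basis(circuit: Circuit) -> Circuit:
    """Rewrite every gate over the {U, CX} basis (MEASURE kept as-is)."""
    out: list[Gate] = []
    for g in circuit.gates:
        if g.name in ("U", "CX", "MEASURE"):
            out.append(g)
        elif g.name in _U_EQUIV:
            out.append(Gate("U", g.qubits, params=_U_EQUIV[g.name]))
        elif g.name == "RY":
            out.append(Gate("U", g.qubits, params=(g.params[0], 0.0, 0.0)))
        elif g.name in ("CRY", "MCRY"):
            out.extend(mcry_to_basis(g))
        else:
            raise CircuitError(f"no basis decomposition for {g.name}")
    return replace(circuit, gates=tuple(out))


def toffoli_basis_circuit() -> Circuit:
    """Canonical 15-gate CCX decomposition over {H, T, Tdg, CX}.

    Nine single-qubit gates and six CNOTs; as-soon-as-possible layering
    gives depth 11, and the product of the gate unitaries is exactly the
    CCX permutation (controls q0, q1; target q2), with no residual global
    phase.
    """
    g = [
        Gate("H", (2,)),
        Gate("CX", (1, 2)),
        Gate("Tdg", (2,)),
        Gate("CX", (0, 2)),
        Gate("T", (2,)),
        Gate("CX", (1, 2)),
        Gate("Tdg", (2,)),
        Gate("CX", (0, 2)),
        Gate("T", (1,)),
        Gate("T", (2,)),
        Gate("H", (2,)),
        Gate("CX", (0, 1)),
        Gate("T", (0,)),
        Gate("Tdg", (1,)),
        Gate("CX", (0, 1)),
    ]
    return Circuit(n_qubits=3, gates=g, registers={"q": (0, 1, 2)}, n_clbits=0)


def circuit_depth(circuit: Circuit) -> int:
    """ASAP layer count: each gate sits at 1 + max layer of its qubits.

    MEASURE is excluded; disjoint gates share a layer.
    """
    layer = [0] * circuit.n_qubits
    for g in circuit.gates:
        if g.name == "MEASURE":
            continue
        here = 1 + max(layer[q] for q in g.qubits)
        for q in g.qubits:
            layer[q] = here
    return max(layer, default=0)


def gate_counts(circuit: Circuit) -> dict[str, Counter]:
    """Per-name and per-arity gate totals (MEASURE excluded from arities)."""
    names: Counter = Counter(g.name for g in circuit.gates)
    arities: Counter = Counter(
        len(g.qubits) for g in circuit.gates if g.name != "MEASURE"
    )
    return {"names": names, "arities": arities}


# -- OpenQASM 2.0 ----------------------------------------------------------

_QASM_STMT = {
    "H": "h",
    "X": "x",
    "T": "t",
    "Tdg": "tdg",
    "RY": "ry",
    "U": "u3",
    "CX": "cx",
}


def export_qasm(circuit: Circuit) -> str:
    """Emit the circuit as OpenQASM 2.0 text.

    Controlled rotations are expanded to {U, CX} first so that every
    statement is covered by qelib1.inc; MCX has no expansion here and is
    rejected.
    """
    lines = [
        "OPENQASM 2.0;",
        'include "qelib1.inc";',
        f"qreg q[{circuit.n_qubits}];",
    ]
    if circuit.n_clbits:
        lines.append(f"creg c[{circuit.n_clbits}];")
    for g in circuit.gates:
        if g.name in ("CRY", "MCRY"):
            gates: Iterable[Gate] = mcry_to_basis(g)
        else:
            gates = (g,)
        for gg in gates:
            if gg.name == "MEASURE":
                lines.append(f"measure q[{gg.target}] -> c[0];")
                continue
            stmt = _QASM_STMT.get(gg.name)
            if stmt is None:
                raise CircuitError(f"cannot export {gg.name} to OpenQASM 2.0")
            args = ",".join(repr(p) for p in gg.params)
            head = f"{stmt}({args})" if args else stmt
            operands = ",".join(f"q[{q}]" for q in gg.qubits)
            lines.append(f"{head} {operands};")
    return "\n".join(lines) + "\n"
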
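"""Independent dense-matrix oracles for the test suite.

Everything here builds full 2^n x 2^n unitaries by explicit basis-state
bookkeeping (little-endian: bit q of the basis index is qubit q), with its
own gate-matrix definitions — deliberately separate from the package's
tensor-contraction simulator so the two routes can check each other.
"""

from __future__ import annotations

import math
import re

import numpy as np

_SQ2 = 1 / math.sqrt(2)

H = np.array([[_SQ2, _SQ2], [_SQ2, -_SQ2]], dtype=complex)
X = np.array([[0, 1], [1, 0]], dtype=complex)
T = np.diag([1, np.exp(1j * math.pi / 4)])
TDG = np.diag([1, np.exp(-1j * math.pi / 4)])


def ry(theta: float) -> np.ndarray:
    c, s = math.cos(theta / 2), math.sin(theta / 2)
    return np.array([[c, -s], [s, c]], dtype=complex)


def u3(theta: float, phi: float, lam: float) -> np.ndarray:
    c, s = math.cos(theta / 2), math.sin(theta / 2)
    return np.array(
        [
            [c, -np.exp(1j * lam) * s],
            [np.exp(1j * phi) * s, np.exp(1j * (phi + lam)) * c],
        ]
    )


def controlled_unitary(
    mat2: np.ndarray,
    n: int,
    target: int,
    controls: tuple[int, ...] = (),
    pattern: tuple[int, ...] = (),
) -> np.ndarray:
    """Full unitary applying ``mat2`` to ``target`` when controls match."""
    pattern = pattern or (1,) * len(controls)
    dim = 2**n
    full = np.zeros((dim, dim), dtype=complex)
    for col in range(dim):
        if all((col >> c) & 1 == b for c, b in zip(controls, pattern)):
            t_in = (col >> target) & 1
            for t_out in (0, 1):
                row = (col & ~(1 << target)) | (t_out << target)
                full[row, col] = mat2[t_out, t_in]
        else:
            full[col, col] = 1.0
    return full


_NAMED = {"H": H, "X": X, "T": T, "Tdg": TDG}


def gate_unitary(gate, n: int) -> np.ndarray:
    """Full unitary of a qstrip Gate, built independently of the simulator."""
    name = gate.name
    if name in _NAMED:
        mat2 = _NAMED[name]
    elif name in ("RY", "CRY", "MCRY"):
        mat2 = ry(gate.params[0])
    elif name == "U":
        mat2 = u3(*gate.params)
    elif name in ("CX", "MCX"):
        mat2 = X
    else:
        raise ValueError(f"oracle has no matrix for {name}")
    return controlled_unitary(
        mat2, n, gate.target, gate.controls, gate.control_pattern
    )


def circuit_unitary(gates, n: int) -> np.ndarray:
    """Product of gate unitaries in application order (MEASURE skipped)."""
    full = np.eye(2**n, dtype=complex)
    for g in gates:
        if g.name == "MEASURE":
            continue
        full = gate_unitary(g, n) @ full
    return full


def ccx_unitary() -> np.ndarray:
    """CCX with controls q0, q1 and target q2, little-endian basis order."""
    perm = np.eye(8, dtype=complex)
    perm[[3, 7]] = perm[[7, 3]]
    return perm


_STMT = re.compile(r"^(\w+)(?:\(([^)]*)\))?\s+(.+);$")


def qasm_unitary(text: str) -> tuple[np.ndarray, int]:
    """Parse OpenQASM 2.0 (the qelib1 subset qstrip emits) into a unitary.

    Returns the full circuit unitary and the qubit count; measurement
    statements are ignored.  Independent of the package's exporter and
    simulator.
    """
    builders = {
        "h": lambda p: H,
        "x": lambda p: X,
        "t": lambda p: T,
        "tdg": lambda p: TDG,
        "ry": lambda p: ry(p[0]),
        "u3": lambda p: u3(*p),
    }
    n = None
    ops: list[tuple[np.ndarray, tuple[int, ...]]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(("OPENQASM", "include", "creg", "//")):
            continue
        if line.startswith("measure"):
            continue
        if line.startswith("qreg"):
            n = int(re.search(r"\[(\d+)\]", line).group(1))
            continue
        m = _STMT.match(line)
        if not m:
            raise ValueError(f"unparseable QASM line: {raw!r}")
        name, params, operands = m.groups()
        qubits = tuple(int(q) for q in re.findall(r"q\[(\d+)\]", operands))
        p = tuple(float(x) for x in params.split(",")) if params else ()
        if name == "cx":
            ops.append((None, qubits))
        else:
            ops.append((builders[name](p), qubits))
    assert n is not None, "no qreg declaration"
    full = np.eye(2**n, dtype=complex)
    for mat2, qubits in ops:
        if mat2 is None:
            step = controlled_unitary(X, n, qubits[1], (qubits[0],), (1,))
        else:
            step = controlled_unitary(mat2, n, qubits[0])
        full = step @ full
    return full, n
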
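import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from qstrip import (
    Circuit,
    Gate,
    build_comparison_circuit,
    circuit_depth,
    decompose_to_basis,
    encode_sequence,
    export_qasm,
    gate_counts,
    mcry_to_basis,
    run_statevector,
    strip_p1,
    toffoli_basis_circuit,
)
from qstrip.circuits import CircuitError


class TestGateValidation:
    def test_cx_arity(self):
        with pytest.raises(CircuitError):
            Gate("CX", (0, 1, 2))

    def test_repeated_qubits(self):
        with pytest.raises(CircuitError, match="repeated"):
            Gate("CX", (1, 1))

    def test_pattern_length(self):
        with pytest.raises(CircuitError, match="pattern"):
            Gate("MCRY", (0, 1, 2), params=(1.0,), control_pattern=(1,))

    def test_mcry_needs_a_control(self):
        with pytest.raises(CircuitError):
            Gate("MCRY", (0,), params=(1.0,))

    def test_unknown_name(self):
        with pytest.raises(CircuitError):
            Gate("SWAP", (0, 1))

    def test_measure_must_be_final(self):
        with pytest.raises(CircuitError, match="MEASURE"):
            Circuit(1, [Gate("MEASURE", (0,)), Gate("H", (0,))])


class TestComparisonCircuit:
    def test_four_position_layout(self, dna):
        circ = build_comparison_circuit(
            encode_sequence("AAAA", dna), encode_sequence("TTTT", dna)
        )
        assert circ.n_qubits == 4  # strip + 2 index + value
        assert circ.n_clbits == 1
        assert circ.registers == {"strip": (0,), "index": (1, 2), "value": (3,)}
        names = gate_counts(circ)["names"]
        assert names["H"] == 4 and names["MCRY"] == 8 and names["MEASURE"] == 1
        assert circ.gates[-1].name == "MEASURE"
        assert circ.gates[-1].target == circ.strip_qubit

    def test_single_position_pair(self, dna):
        circ = build_comparison_circuit(
            encode_sequence("A", dna), encode_sequence("A", dna)
        )
        assert circ.n_qubits == 2
        p1 = strip_p1(run_statevector(circ), circ.strip_qubit)
        assert p1 == pytest.approx(0.0, abs=1e-12)

    def test_identical_sequences_interfere_to_zero(self, dna):
        circ = build_comparison_circuit(
            encode_sequence("AAAA", dna), encode_sequence("AAAA", dna)
        )
        assert strip_p1(run_statevector(circ), 0) == pytest.approx(0.0, abs=1e-12)

    def test_register_mismatch_rejected(self, dna):
        with pytest.raises(CircuitError, match="mismatch"):
            build_comparison_circuit(
                encode_sequence("AAAA", dna), encode_sequence("AAAAA", dna)
            )

    def test_zero_angle_elision_drops_g_rotations(self, dna):
        ref, cmp_ = encode_sequence("AGGA", dna), encode_sequence("GGGG", dna)
        full = build_comparison_circuit(ref, cmp_)
        lean = build_comparison_circuit(ref, cmp_, elide_zero_angles=True)
        assert gate_counts(full)["names"]["MCRY"] == 8
        assert gate_counts(lean)["names"]["MCRY"] == 2  # only the two A's
        p_full = strip_p1(run_statevector(full), 0)
        p_lean = strip_p1(run_statevector(lean), 0)
        assert p_full == pytest.approx(p_lean, abs=1e-12)


class TestMcryDecomposition:
    def test_bare_ry_becomes_one_u(self):
        out = mcry_to_basis(Gate("RY", (0,), params=(0.7,)))
        assert [g.name for g in out] == ["U"]
        assert out[0].params == (0.7, 0.0, 0.0)

    def test_cry_is_four_gates(self):
        out = mcry_to_basis(Gate("CRY", (0, 1), params=(1.1,)))
        assert [g.name for g in out] == ["U", "CX", "U", "CX"]

    @pytest.mark.parametrize("n_controls", [1, 2, 3])
    @pytest.mark.parametrize("pattern_seed", [0, 1, 2])
    def test_unitary_equivalence(self, n_controls, pattern_seed, rng):
        n = n_controls + 1
        theta = float(rng.uniform(0, math.pi)) + 0.1
        pattern = tuple(
            int(b) for b in rng.integers(0, 2, size=n_controls)
        ) if pattern_seed else (1,) * n_controls
        gate = Gate(
            "MCRY" if n_controls > 1 else "CRY",
            tuple(range(n)),
            params=(theta,),
            control_pattern=pattern,
        )
        expected = oracles.gate_unitary(gate, n)
        got = oracles.circuit_unitary(mcry_to_basis(gate), n)
        assert np.max(np.abs(got - expected)) < 1e-9

    def test_basis_is_u_and_cx_only(self):
        out = mcry_to_basis(Gate("MCRY", (0, 1, 2, 3), params=(0.9,)))
        assert set(g.name for g in out) <= {"U", "CX"}

    def test_rejects_non_rotation(self):
        with pytest.raises(CircuitError):
            mcry_to_basis(Gate("CX", (0, 1)))


class TestToffoli:
    def test_gate_accounting(self):
        circ = toffoli_basis_circuit()
        counts = gate_counts(circ)
        assert len(circ.gates) == 15
        assert counts["arities"][1] == 9
        assert counts["arities"][2] == 6
        assert set(counts["names"]) <= {"H", "T", "Tdg", "CX"}

    def test_depth_eleven(self):
        assert circuit_depth(toffoli_basis_circuit()) == 11

    def test_unitary_is_exact_ccx(self):
        got = oracles.circuit_unitary(toffoli_basis_circuit().gates, 3)
        # no global-phase slack: direct elementwise comparison
        assert np.max(np.abs(got - oracles.ccx_unitary())) < 1e-12


class TestDepthAndCounts:
    def test_single_gate(self):
        assert circuit_depth(Circuit(1, [Gate("H", (0,))], n_clbits=0)) == 1

    def test_disjoint_gates_parallelize(self):
        c = Circuit(2, [Gate("H", (0,)), Gate("H", (1,))], n_clbits=0)
        assert circuit_depth(c) == 1

    def test_empty_circuit(self):
        c = Circuit(2, [], n_clbits=0)
        assert circuit_depth(c) == 0
        counts = gate_counts(c)
        assert sum(counts["names"].values()) == 0
        assert sum(counts["arities"].values()) == 0

    def test_measure_excluded_from_depth(self, dna):
        circ = build_comparison_circuit(
            encode_sequence("AT", dna), encode_sequence("TA", dna)
        )
        bare = Circuit(circ.n_qubits, circ.gates[:-1], circ.registers)
        assert circuit_depth(circ) == circuit_depth(bare)

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_depth_and_counts_invariant_under_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        n = 4
        gates = []
        for _ in range(12):
            if rng.random() < 0.5:
                gates.append(Gate("H", (int(rng.integers(n)),)))
            else:
                a, b = rng.choice(n, size=2, replace=False)
                gates.append(Gate("CX", (int(a), int(b))))
        perm = rng.permutation(n)
        relabeled = [
            Gate(g.name, tuple(int(perm[q]) for q in g.qubits)) for g in gates
        ]
        c1 = Circuit(n, gates, n_clbits=0)
        c2 = Circuit(n, relabeled, n_clbits=0)
        assert circuit_depth(c1) == circuit_depth(c2)
        assert gate_counts(c1)["arities"] == gate_counts(c2)["arities"]


class TestQasmExport:
    def test_toffoli_statement_count(self):
        qasm = export_qasm(toffoli_basis_circuit())
        stmts = [
            l for l in qasm.splitlines()
            if l and not l.startswith(("OPENQASM", "include", "qreg", "creg"))
        ]
        assert len(stmts) == 15

    def test_empty_circuit_header_only(self):
        qasm = export_qasm(Circuit(1, [], n_clbits=0))
        assert qasm.splitlines() == [
            "OPENQASM 2.0;",
            'include "qelib1.inc";',
            "qreg q[1];",
        ]

    def test_comparison_circuit_reimports_to_same_unitary(self, dna):
        circ = build_comparison_circuit(
            encode_sequence("AC", dna), encode_sequence("TG", dna)
        )
        unitary, n = oracles.qasm_unitary(export_qasm(circ))
        expected = oracles.circuit_unitary(circ.gates, circ.n_qubits)
        assert n == circ.n_qubits
        assert np.max(np.abs(unitary - expected)) < 1e-9

    def test_measure_statement_present(self, dna):
        circ = build_comparison_circuit(
            encode_sequence("A", dna), encode_sequence("T", dna)
        )
        assert "measure q[0] -> c[0];" in export_qasm(circ)

    def test_unsupported_gate_rejected(self):
        circ = Circuit(3, [Gate("MCX", (0, 1, 2))], n_clbits=0)
        with pytest.raises(CircuitError, match="export"):
            export_qasm(circ)


class TestBasisDecomposition:
    @pytest.mark.parametrize("pair", [("A", "T"), ("ACGT", "TGCA")])
    def test_unitary_preserved(self, pair, dna):
        circ = build_comparison_circuit(
            encode_sequence(pair[0], dna), encode_sequence(pair[1], dna)
        )
        basis = decompose_to_basis(circ)
        assert set(g.name for g in basis.gates) <= {"U", "CX", "MEASURE"}
        got = oracles.circuit_unitary(basis.gates, circ.n_qubits)
        expected = oracles.circuit_unitary(circ.gates, circ.n_qubits)
        assert np.max(np.abs(got - expected)) < 1e-9

    def test_simulates_to_same_p1(self, dna):
        circ = build_comparison_circuit(
            encode_sequence("ACGT", dna), encode_sequence("AAAA", dna)
        )
        p_hi = strip_p1(run_statevector(circ), 0)
        p_lo = strip_p1(run_statevector(decompose_to_basis(circ)), 0)
        assert p_hi == pytest.approx(p_lo, abs=1e-12)
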
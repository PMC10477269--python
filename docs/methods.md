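# Methods

## Encoding

A residue alphabet is a map from single characters to state-representation
angles θ ∈ [0, π] (radians) plus a designated pad symbol.  The built-in DNA
map is A → π, C → π/2, T → π/6, G → 0, with G as the pad.  Input is
uppercased before lookup; ambiguity codes (N, R, Y, …) are rejected rather
than guessed, naming the offending character and position.  Amino-acid
alphabets are not built in — a user can supply any map through the
plain-text alphabet-config format (`symbol angle` lines plus a
`pad <symbol>` directive), subject to the same [0, π] constraint.

The FRQI value qubit for a position with angle θ ends in
cos(θ/2)|0⟩ + sin(θ/2)|1⟩, i.e. the rotation applied is Rʏ(θ) and the
*half*-angles α = θ/2 are what enter the overlap formula.  The two
conventions ("angle" vs "half-angle") are easy to conflate; this package
fixes the amplitude convention above because it is the one under which the
uniform-pair probabilities come out at 0 / 0.146 / 0.371 / 0.5, and exposes
the half-angles explicitly (`frqi_half_angles`) so the relation is visible.

Sequences are right-padded with the pad symbol to N = 2^k, the smallest
power of two holding the sequence (k = 0 for a single residue), because the
index register needs a full basis.  The padded positions of a compared pair
always agree (both carry the pad angle), which inflates the raw similarity;
see "Padding correction" below.  Positions are a flat 1-D index i ∈ [0, 2^k)
— a 2×2 image layout is just the row-major special case k = 2.

## Circuit construction

Register layout is `[strip, index_{k-1} … index_0, value]`: the strip qubit
first, the index register big-endian, the value qubit last, plus one
classical bit for the terminal measurement.  The builder emits

1. H on the strip and on every index qubit;
2. for each strip value s ∈ {0, 1} and each position i, one
   multi-controlled Rʏ(θ) on the value qubit, controlled on strip = s and
   index = binary(i), with θ the reference angle when s = 0 and the
   compared angle when s = 1;
3. H on the strip;
4. a measurement of the strip qubit.

Zero-angle rotations (G positions) are emitted by default so the circuit
shape is independent of sequence content; `elide_zero_angles=True` drops
them (they are identities).  A four-residue pair therefore uses
2 + k = 4 qubits and, with zero-angle gates kept, 3 H + 8 MCRY + 1 H + 1
measurement.

Controlled-rotation decomposition targets the {U, CX} basis with no
ancilla: an MCRY with c controls is treated as a uniformly controlled Rʏ
whose only non-zero slot is the gate's control pattern, and split
recursively — each level halves the angle table into sum- and
difference-halves separated by a CX from the current control, so a
0-control simply selects the other slot and needs no X conjugation.  This
yields 2^c rotations and 2^c CNOTs (the familiar 4-gate CRY for c = 1) and
matches the exact gate unitary to well below the 1e-9 contract.  The
5-qubit scale of the target circuits leaves no room for ancilla-based
shortcuts, and none are needed.

The canonical Toffoli decomposition (H, T, T†, CX; 9 single-qubit gates,
6 CNOTs) is provided as a fixed reference circuit.  Its depth under
as-soon-as-possible layering — each gate placed at 1 + the maximum current
layer of its qubits, measurement excluded, no commutation or cancellation
— is 11.  Depth is scheduling-convention-dependent; ASAP on the emitted
gate order is the convention everywhere in this package.

OpenQASM 2.0 export covers the qelib1 subset (h, x, t, tdg, ry, u3, cx,
measure); CRY/MCRY are expanded to {U, CX} on the way out so that any
OpenQASM 2.0 consumer can replay the file.  The test suite re-imports the
emitted text through its own minimal parser and dense-matrix builder —
written independently of the exporter and the simulator — and checks
unitary equivalence to 1e-9.

## Simulation and measurement

The statevector simulator applies each gate's 2×2 target matrix (with
control conditioning) to the dense amplitude tensor; amplitude ordering is
little-endian (bit q of the basis index is qubit q), and the norm is
checked to 1e-12 after the run.  The default cap of 20 qubits keeps the
dense state below ~16 MiB; the circuits this package builds use 2 + k
qubits, so pairs up to 2^18 positions fit under the cap.

The single terminal measurement is simulated analytically: the strip
qubit's marginal P₁ is read from the statevector, and finite-shot readout
is a seeded binomial draw with that success probability.  For a circuit
with one terminal measurement this is exact, and much faster than per-shot
collapse.  The generator is NumPy's default PCG64, the seed is mandatory
in shots mode and recorded in every result — there is no silent
nondeterminism.  The default shot count is 8000, the scale at which the
binomial 3σ band around the A-vs-T value 0.3706 is ±0.016.

Only sampling noise is modelled.  Hardware readouts carry decoherence and
gate error on top of shot noise — a hardware estimate such as 0.378 for the
A-vs-T comparison sits inside the 3σ sampling band of the ideal value, but
nothing here models the hardware contribution itself.  Noise channels,
density matrices and mid-circuit measurement are out of scope.

## Scoring

sim = 1 − 2·P₁.  With every angle in [0, π] each per-position overlap
cos(αᵢ − βᵢ) is non-negative, so P₁ ≤ 0.5 and sim ∈ [0, 1]; the standalone
`similarity_score` rejects P₁ outside [0, 0.5] (tolerance 1e-9) as
unreachable.  In shots mode the reported similarity is 1 − 2·p̂₁ with the
raw frequency estimate p̂₁ = counts[1]/shots and no bias correction, even
when sampling noise pushes p̂₁ marginally past 0.5 — keeping the identity
between the reported p1 and similarity fields was judged more useful than
clamping.

Padding correction: with N = n_real + n_pad and mean overlap
m = N·(1 − 2·P₁), the corrected similarity is (m − n_pad)/n_real, clipped
to [−1, 1] — the guaranteed pad-vs-pad matches are subtracted and the mean
is taken over real positions only.  It is reported only when padding
occurred.  For mixed-length pairs (opt-in via padding), positions where
only the shorter member is padded compare a real residue against the pad
symbol and are *not* removed; only both-padded positions are.  This is a
package design choice — the encoding itself defines no gap or mixed-length
semantics.

## Synthetic fixtures

`generate_fixture` draws a uniform random reference over the alphabet,
mutates exactly `n_mutations` distinct positions (each substitution changes
the residue), and stores the analytic P₁ as the expectation, all from one
seed.  It emulates point substitutions only: no indels, no ambiguity
codes, no base-composition or positional structure of real genomes.
Passing tests on these fixtures demonstrates that the circuit, simulator
and closed form agree on arbitrary substitution patterns; it says nothing
about alignment quality on real, gapped data, which is outside what the
encoding can express.

## Numerical choices and problem sizes

- Oracle agreement (analytic vs statevector) is asserted at 1e-9,
  decomposition unitaries at 1e-9, simulator norm and gate-action checks
  at 1e-12; all comfortably above double-precision round-off at these
  dimensions.
- Angle-map construction tolerates 1e-12 above π before rejecting, then
  clamps, so that values like `math.pi` survive serialisation round-trips.
- Randomised suites use fixed seeds (hypothesis derandomised or explicit
  PCG64 seeds).  Cross-route agreement runs on ~100 random pairs of
  lengths 1–16 over random alphabets of 2–5 symbols; shot-noise
  concentration is checked over 1000 seeds at 8000 shots.  These sizes
  exercise every branch (k = 0 through 4, padded and unpadded) while the
  whole suite stays in the seconds range.

## Known limitations

- Pairwise only: no multi-sequence strip comparison, no alignment, gaps,
  or sliding windows — sequences are compared position by position.
- The similarity is a function of per-position angle differences under the
  chosen map; with the default DNA map the score is not a metric on
  sequences in any edit-distance sense (e.g. a C/T mismatch costs less
  than an A/G mismatch by construction of the angles).
- MCX has no basis decomposition here (nothing in the pipeline emits it);
  it simulates fine but is rejected by the QASM exporter.
- No hardware execution, transpilation, or noise modelling.
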
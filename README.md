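# qstrip

Pairwise nucleotide-sequence similarity scored on a simulated quantum
circuit.  Two equal-length DNA sequences are angle-encoded in the FRQI
(Flexible Representation of Quantum Images) convention, entangled with a
*strip qubit* that labels which sequence a branch of the superposition
carries, and interfered with a Hadamard so that the probability of
measuring the strip qubit in |1⟩ reports how different the sequences are.

`qstrip` is for people studying quantum encodings of biological data: it
builds the actual gate-level circuit, simulates it exactly (statevector)
or with seeded finite-shot sampling, and cross-checks everything against a
closed-form expression — all on an ordinary CPU.

## The model

Each residue gets a state-representation angle θ from the built-in map

| residue | θ |
|---|---|
| A | π |
| C | π/2 |
| T | π/6 |
| G | 0 |

and a sequence of length n is padded with G (θ = 0) to N = 2^k positions so
a k-qubit index register can address every position.  The circuit prepares

&nbsp;&nbsp;|Ψ⟩ = (1/√(2N)) Σᵢ ( |0⟩|i⟩·Rʏ(θᵢ)|0⟩ + |1⟩|i⟩·Rʏ(φᵢ)|0⟩ )

with the reference angles θᵢ on the strip-|0⟩ branch and the compared
angles φᵢ on the strip-|1⟩ branch, each written by a multi-controlled Rʏ;
Rʏ(θ)|0⟩ = cos(θ/2)|0⟩ + sin(θ/2)|1⟩.  A final Hadamard on the strip qubit
interferes the branches, giving

&nbsp;&nbsp;P₁ = ½ (1 − (1/N) Σᵢ cos(αᵢ − βᵢ)),  α = θ/2, β = φ/2,

and the similarity score **sim = 1 − 2·P₁**: identical sequences score 1,
and an A-vs-G pair (angle gap π) scores 0.  Because padded positions always
match, a padding-corrected score that removes their contribution is
reported whenever padding occurred.

For the four uniform four-residue pairs this gives P₁ = 0 (A/A),
0.146 (A/C), 0.371 (A/T) and 0.5 (A/G).

## Worked example

```sh
$ qstrip compare AAAA TTTT --method shots --seed 7
{
  "ref_id": "AAAA",
  "cmp_id": "TTTT",
  "length": 4,
  "padded_length": 4,
  "n_pad": 0,
  "method": "shots",
  "p1": 0.37,
  "similarity": 0.26,
  "similarity_corrected": null,
  "shots": 8000,
  "seed": 7,
  "counts": {
    "0": 5040,
    "1": 2960
  }
}
```

The 4-qubit comparison circuit (strip + 2 index + value) was built,
simulated, and its strip qubit sampled 8000 times with the given seed:
2960 of the 8000 shots read 1, so the estimated P₁ is 0.37 — a binomial
fluctuation around the exact value 0.3706 — and the similarity is
1 − 2·0.37 = 0.26.  With `--method statevector` the same run reports the
exact P₁ = 0.37059…; with the default `--method analytic` the closed form
is evaluated directly without building the circuit.

Other subcommands:

```sh
qstrip circuit AC GT --decompose --out pair.qasm   # OpenQASM 2.0 + summary
qstrip fixture --length 8 --mutations 2 --seed 3   # synthetic test pair
```

From Python:

```python
from qstrip import compare
compare("AAAA", "CCCC").p1          # 0.1464466...
compare("AAAA", "CCCC").similarity  # 0.7071067...
```

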
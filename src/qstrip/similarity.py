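"""P1 and similarity scoring for one pairwise comparison.

For identically padded angle vectors theta (reference) and phi (compared),
with FRQI half-angles alpha = theta/2 and beta = phi/2 over the padded
length N = 2^k, interference on the strip qubit gives

    P1  = 1/2 * (1 - (1/N) * sum_i cos(alpha_i - beta_i))
    sim = 1 - 2 * P1

so identical sequences score 1 and, with all angles in [0, pi], the
maximally different pair (angle gap pi) scores 0.  Padded positions always
match and inflate the raw score; ``similarity_corrected`` removes their
guaranteed contribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .alphabet import AlphabetMap, EncodedSequence, default_dna_map, encode_sequence
from .circuits import build_comparison_circuit
from .simulator import ShotCounts, run_statevector, sample_strip, strip_p1

__all__ = [
    "ComparisonResult",
    "p1_analytic",
    "similarity_score",
    "similarity_corrected",
    "compare",
]

Method = Literal["analytic", "statevector", "shots"]

TSV_COLUMNS = (
    "ref_id",
    "cmp_id",
    "length",
    "method",
    "p1",
    "similarity",
    "similarity_corrected",
    "shots",
    "seed",
)


def p1_analytic(ref: EncodedSequence, cmp: EncodedSequence) -> float:
    """Closed-form strip-qubit P1; equals the statevector result to 1e-9."""
    if ref.n_positions != cmp.n_positions:
        raise ValueError(
            f"padded lengths differ: {ref.n_positions} vs {cmp.n_positions}"
        )
    overlap = np.cos(ref.frqi_angles - cmp.frqi_angles).mean()
    return float(0.5 * (1.0 - overlap))


def similarity_score(p1: float) -> float:
    """sim = 1 - 2*P1.

    P1 outside [0, 0.5] (beyond 1e-9) is rejected: with every residue angle
    in [0, pi] the per-position overlaps are non-negative, so larger values
    are unreachable for an exact comparison.
    """
    if not (-1e-9 <= p1 <= 0.5 + 1e-9):
        raise ValueError(f"p1={p1!r} outside the reachable range [0, 0.5]")
    return 1.0 - 2.0 * min(max(p1, 0.0), 0.5)


def similarity_corrected(p1: float, n_real: int, n_pad: int) -> float:
    """Similarity with the padded positions' guaranteed match removed.

    With N = n_real + n_pad, the mean per-position overlap is
    m = N*(1 - 2*p1); subtracting the n_pad pad-vs-pad unit overlaps and
    renormalising over the real positions gives (m - n_pad)/n_real,
    clipped to [-1, 1].
    """
    if n_real < 1:
        raise ValueError("n_real must be >= 1")
    n_total = n_real + n_pad
    corrected = (n_total * (1.0 - 2.0 * p1) - n_pad) / n_real
    return float(min(1.0, max(-1.0, corrected)))


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one pairwise comparison.

    ``similarity`` is exactly ``1 - 2*p1`` for the reported ``p1`` (the
    shot-frequency estimate when ``method == "shots"``);
    ``similarity_corrected`` is present only when padding occurred.
    """

    ref_id: str
    cmp_id: str
    length: int
    padded_length: int
    n_pad: int
    method: Method
    p1: float
    similarity: float
    similarity_corrected: float | None
    shots: int | None = None
    seed: int | None = None
    counts: dict[int, int] | None = None

    def to_dict(self) -> dict:
        d = {
            "ref_id": self.ref_id,
            "cmp_id": self.cmp_id,
            "length": self.length,
            "padded_length": self.padded_length,
            "n_pad": self.n_pad,
            "method": self.method,
            "p1": self.p1,
            "similarity": self.similarity,
            "similarity_corrected": self.similarity_corrected,
        }
        if self.method == "shots":
            d["shots"] = self.shots
            d["seed"] = self.seed
            d["counts"] = {"0": self.counts[0], "1": self.counts[1]}
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self, header: bool = True) -> str:
        row = {
            **self.to_dict(),
            "similarity_corrected": (
                "" if self.similarity_corrected is None else self.similarity_corrected
            ),
            "shots": self.shots if self.shots is not None else "",
            "seed": self.seed if self.seed is not None else "",
        }
        lines = ["\t".join(TSV_COLUMNS)] if header else []
        lines.append("\t".join(str(row[c]) for c in TSV_COLUMNS))
        return "\n".join(lines) + "\n"


def compare(
    ref_seq: str,
    cmp_seq: str,
    alphabet: AlphabetMap | None = None,
    *,
    method: Method = "analytic",
    shots: int | None = None,
    seed: int | None = None,
    ref_id: str = "seq1",
    cmp_id: str = "seq2",
    pad_to_match: bool = False,
) -> ComparisonResult:
    """Run one pairwise comparison end to end.

    ``analytic`` evaluates the closed form; ``statevector`` builds and
    exactly simulates the strip-qubit circuit; ``shots`` additionally draws
    seeded measurement shots and estimates P1 as ``counts[1]/shots``.
    Unequal lengths are rejected unless ``pad_to_match``, in which case the
    shorter sequence is carried through the shared power-of-two padding.
    """
    if alphabet is None:
        alphabet = default_dna_map()
    if len(ref_seq) != len(cmp_seq) and not pad_to_match:
        raise ValueError(
            f"length mismatch: {len(ref_seq)} vs {len(cmp_seq)} "
            "(enable padding to compare anyway)"
        )
    ref = encode_sequence(ref_seq, alphabet)
    cmp_ = encode_sequence(cmp_seq, alphabet)
    k = max(ref.n_index_qubits, cmp_.n_index_qubits)
    if ref.n_index_qubits != k:
        ref = encode_sequence(ref_seq, alphabet, n_index_qubits=k)
    if cmp_.n_index_qubits != k:
        cmp_ = encode_sequence(cmp_seq, alphabet, n_index_qubits=k)

    n_real = max(ref.n_real, cmp_.n_real)
    n_pad = ref.n_positions - n_real  # positions where both members are padded

    shot_counts: ShotCounts | None = None
    if method == "analytic":
        p1 = p1_analytic(ref, cmp_)
    elif method in ("statevector", "shots"):
        circuit = build_comparison_circuit(ref, cmp_)
        p1 = strip_p1(run_statevector(circuit), circuit.strip_qubit)
        if method == "shots":
            if shots is None:
                raise ValueError("shots method requires a shot count")
            if seed is None:
                raise ValueError("shots method requires an explicit seed")
            shot_counts = sample_strip(p1, shots, seed)
            p1 = shot_counts.p1_estimate
    else:
        raise ValueError(f"unknown method {method!r}")

    return ComparisonResult(
        ref_id=ref_id,
        cmp_id=cmp_id,
        length=n_real,
        padded_length=ref.n_positions,
        n_pad=n_pad,
        method=method,
        p1=p1,
        similarity=1.0 - 2.0 * p1,
        similarity_corrected=(
            similarity_corrected(p1, n_real, n_pad) if n_pad else None
        ),
        shots=shot_counts.shots if shot_counts else None,
        seed=shot_counts.seed if shot_counts else None,
        counts=dict(shot_counts.counts) if shot_counts else None,
    )
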
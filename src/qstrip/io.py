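"""FASTA input/output, synthetic fixture pairs, and JSON report checking."""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .alphabet import AlphabetMap, default_dna_map, encode_sequence
from .similarity import p1_analytic

__all__ = [
    "SequenceRecord",
    "FixturePair",
    "read_fasta",
    "write_fasta",
    "generate_fixture",
    "load_result_schema",
    "validate_result_dict",
]


class FastaError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    description: str
    residues: str


@dataclass(frozen=True)
class FixturePair:
    """A reference sequence, a mutated copy, and the analytic expectation."""

    ref: SequenceRecord
    cmp: SequenceRecord
    mutated_positions: tuple[int, ...]
    expected_p1: float


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """All records of a FASTA file, line wrapping normalised away."""
    path = Path(path)
    if not path.exists():
        raise FastaError(f"no such file: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).strip()
        if not residues:
            raise FastaError(f"record {rec.id!r} in {path} has an empty sequence")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, description=desc, residues=residues))
    if not records:
        raise FastaError(f"{path} contains no FASTA records")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def generate_fixture(
    length: int,
    n_mutations: int,
    seed: int,
    alphabet: AlphabetMap | None = None,
) -> FixturePair:
    """Random reference plus a copy mutated at exactly ``n_mutations`` sites.

    Mutated positions are distinct and each substitution changes the
    residue; ``expected_p1`` is the analytic oracle on the padded pair.
    Deterministic for a given seed.
    """
    if alphabet is None:
        alphabet = default_dna_map()
    if not (0 <= n_mutations <= length):
        raise ValueError(f"n_mutations={n_mutations} not in [0, {length}]")
    rng = np.random.default_rng(seed)
    symbols = sorted(alphabet.entries)
    ref = [symbols[i] for i in rng.integers(len(symbols), size=length)]
    positions = tuple(
        int(p) for p in sorted(rng.choice(length, size=n_mutations, replace=False))
    )
    cmp_ = list(ref)
    for pos in positions:
        others = [s for s in symbols if s != ref[pos]]
        cmp_[pos] = others[rng.integers(len(others))]
    ref_s, cmp_s = "".join(ref), "".join(cmp_)
    expected = p1_analytic(
        encode_sequence(ref_s, alphabet), encode_sequence(cmp_s, alphabet)
    )
    return FixturePair(
        ref=SequenceRecord("ref", f"length={length} seed={seed}", ref_s),
        cmp=SequenceRecord("cmp", f"mutations={n_mutations} seed={seed}", cmp_s),
        mutated_positions=positions,
        expected_p1=expected,
    )


# -- JSON report schema ----------------------------------------------------

def load_result_schema() -> dict:
    """The JSON schema the `compare` report validates against."""
    text = resources.files("qstrip").joinpath(
        "schemas/comparison_result.schema.json"
    ).read_text()
    return json.loads(text)


_TYPES = {
    "string": str,
    "integer": int,
    "number": (int, float),
    "object": dict,
    "null": type(None),
}


def validate_result_dict(obj: dict, schema: dict | None = None) -> None:
    """Check a comparison report against the shipped schema.

    Covers the subset of JSON Schema the schema file uses: required keys,
    per-property type unions, enums, and numeric bounds.  Raises
    ``ValueError`` on the first violation.
    """
    if schema is None:
        schema = load_result_schema()
    for key in schema.get("required", ()):
        if key not in obj:
            raise ValueError(f"missing required key {key!r}")
    for key, rule in schema.get("properties", {}).items():
        if key not in obj:
            continue
        val = obj[key]
        types = rule.get("type")
        if types is not None:
            allowed = [types] if isinstance(types, str) else types
            py: tuple = ()
            for name in allowed:
                t = _TYPES[name]
                py += t if isinstance(t, tuple) else (t,)
            if isinstance(val, bool) or not isinstance(val, py):
                raise ValueError(f"{key}={val!r} is not of type {allowed}")
        if "enum" in rule and val not in rule["enum"]:
            raise ValueError(f"{key}={val!r} not in {rule['enum']}")
        if isinstance(val, (int, float)) and not isinstance(val, bool):
            if "minimum" in rule and val < rule["minimum"]:
                raise ValueError(f"{key}={val!r} below minimum {rule['minimum']}")
            if "maximum" in rule and val > rule["maximum"]:
                raise ValueError(f"{key}={val!r} above maximum {rule['maximum']}")
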
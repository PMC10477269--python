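"""Residue-to-angle alphabets and FRQI angle encoding of sequences.

Each residue symbol is assigned a *state-representation angle* theta in
[0, pi].  In the FRQI convention the value qubit for a position with angle
theta ends in cos(theta/2)|0> + sin(theta/2)|1>, so the per-position
half-angles alpha_i = theta_i / 2 are what enter the interference formula.

The built-in DNA map assigns A -> pi, C -> pi/2, T -> pi/6, G -> 0.
Sequences are right-padded with the pad symbol (default G, angle 0) to the
next power of two so that a k-qubit index register can address every
position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "AlphabetMap",
    "EncodedSequence",
    "default_dna_map",
    "encode_sequence",
    "frqi_half_angles",
    "load_alphabet",
    "save_alphabet",
]


class AlphabetError(ValueError):
    """Invalid alphabet map or a residue not covered by the map."""


@dataclass(frozen=True)
class AlphabetMap:
    """Mapping from residue symbols to state-representation angles (radians).

    Parameters
    ----------
    name:
        Short identifier of the map.
    entries:
        ``{symbol: theta}`` with single uppercase-character symbols and
        angles in ``[0, pi]``.
    pad_symbol:
        Symbol used to right-pad sequences to a power-of-two length; must
        be one of the entries.
    """

    name: str
    entries: Mapping[str, float]
    pad_symbol: str

    def __post_init__(self) -> None:
        if not self.entries:
            raise AlphabetError("alphabet map has no entries")
        clean: dict[str, float] = {}
        for sym, angle in dict(self.entries).items():
            if not (isinstance(sym, str) and len(sym) == 1):
                raise AlphabetError(f"symbol {sym!r} is not a single character")
            sym_u = sym.upper()
            if sym_u in clean:
                raise AlphabetError(f"duplicate symbol {sym_u!r}")
            angle = float(angle)
            if not (0.0 <= angle <= math.pi + 1e-12):
                raise AlphabetError(
                    f"angle for {sym_u!r} is {angle!r}, outside [0, pi]"
                )
            clean[sym_u] = min(angle, math.pi)
        object.__setattr__(self, "entries", clean)
        pad = self.pad_symbol.upper()
        if pad not in clean:
            raise AlphabetError(f"pad symbol {pad!r} is not in the alphabet")
        object.__setattr__(self, "pad_symbol", pad)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.entries

    def __getitem__(self, symbol: str) -> float:
        return self.entries[symbol.upper()]

    @property
    def pad_angle(self) -> float:
        return self.entries[self.pad_symbol]

    def inverse(self) -> dict[float, str]:
        """Angle -> symbol lookup (valid when all angles are distinct)."""
        inv = {angle: sym for sym, angle in self.entries.items()}
        if len(inv) != len(self.entries):
            raise AlphabetError("map is not invertible: repeated angles")
        return inv


@dataclass(frozen=True)
class EncodedSequence:
    """A residue string together with its padded per-position angles.

    ``state_angles`` holds theta_i for every addressable position
    (padded length ``2**n_index_qubits``); ``frqi_angles`` holds the
    half-angles alpha_i = theta_i / 2 used by the analytic overlap formula.
    """

    symbols: str
    state_angles: np.ndarray
    n_index_qubits: int
    n_real: int
    n_pad: int
    alphabet: AlphabetMap = field(repr=False)

    @property
    def frqi_angles(self) -> np.ndarray:
        return self.state_angles / 2.0

    @property
    def n_positions(self) -> int:
        """Padded length 2**k."""
        return int(self.state_angles.size)


def default_dna_map() -> AlphabetMap:
    """The built-in DNA alphabet: A -> pi, C -> pi/2, T -> pi/6, G -> 0.

    Padding uses G (zero rotation), so padded positions contribute no
    rotation to the value qubit.
    """
    return AlphabetMap(
        name="dna",
        entries={"A": math.pi, "C": math.pi / 2, "T": math.pi / 6, "G": 0.0},
        pad_symbol="G",
    )


def _index_qubits_for(n: int) -> int:
    # smallest k with 2**k >= n; a single position needs no index qubit
    return max(0, (n - 1).bit_length())


def encode_sequence(
    seq: str, alphabet: AlphabetMap | None = None, *, n_index_qubits: int | None = None
) -> EncodedSequence:
    """Convert a residue string into padded state angles.

    Input is uppercased before lookup; ambiguity codes and any symbol not in
    the map are rejected with the offending position.  ``n_index_qubits``
    may force a larger index register so that two members of a compared pair
    are padded identically.
    """
    if alphabet is None:
        alphabet = default_dna_map()
    if not seq:
        raise AlphabetError("empty sequence cannot be encoded")
    seq_u = seq.upper()
    angles = []
    for pos, sym in enumerate(seq_u):
        try:
            angles.append(alphabet.entries[sym])
        except KeyError:
            raise AlphabetError(
                f"unknown residue symbol {sym!r} at position {pos}"
            ) from None
    n_real = len(seq_u)
    k = _index_qubits_for(n_real)
    if n_index_qubits is not None:
        if n_index_qubits < k:
            raise AlphabetError(
                f"n_index_qubits={n_index_qubits} cannot address {n_real} positions"
            )
        k = n_index_qubits
    n_total = 2**k
    n_pad = n_total - n_real
    angles.extend([alphabet.pad_angle] * n_pad)
    return EncodedSequence(
        symbols=seq_u,
        state_angles=np.asarray(angles, dtype=float),
        n_index_qubits=k,
        n_real=n_real,
        n_pad=n_pad,
        alphabet=alphabet,
    )


def frqi_half_angles(enc: EncodedSequence) -> np.ndarray:
    """Per-position FRQI half-angles alpha_i = theta_i / 2."""
    return enc.frqi_angles


# -- plain-text alphabet configs ------------------------------------------
#
# Format: one "symbol angle-in-radians" pair per line; optional "name <id>"
# and "pad <symbol>" directives; '#' starts a comment.

def save_alphabet(alphabet: AlphabetMap, path: str | Path) -> None:
    lines = [f"name {alphabet.name}", f"pad {alphabet.pad_symbol}"]
    lines += [f"{sym} {angle!r}" for sym, angle in alphabet.entries.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def load_alphabet(path: str | Path) -> AlphabetMap:
    name = Path(path).stem
    pad: str | None = None
    entries: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, rest = line.partition(" ")
        rest = rest.strip()
        if key == "name":
            name = rest
        elif key == "pad":
            pad = rest
        else:
            try:
                entries[key] = float(rest)
            except ValueError:
                raise AlphabetError(f"malformed alphabet line: {raw!r}") from None
    if pad is None:
        raise AlphabetError("alphabet config is missing a 'pad <symbol>' line")
    return AlphabetMap(name=name, entries=entries, pad_symbol=pad)
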
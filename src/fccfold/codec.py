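"""Conformation encodings and similarity matching.

A walk of n monomers is a sequence of n-1 steps, each a lattice basis
vector.  The *absolute encoding* records the basis index of each step; it
is translation-invariant but not rotation-invariant — the same fold picked
up and rotated yields a different code string.

The *non-isomorphic encoding* removes that rotational (and reflective)
degeneracy in a single O(n) pass: absolute directions are relabeled by
first occurrence, so the first direction used becomes 0, the next distinct
direction 1, and so on.  Any lattice isometry permutes the absolute
directions consistently along the chain, which leaves the first-occurrence
labels unchanged; hence two walks related by rotation, reflection, or
translation always share one code.  The encoding conflates some
geometrically distinct walks as well (it forgets the angles between
distinct directions), which is acceptable — and even helpful — for its
purpose: approximate revisitation control in a memory-based search.

Codes are packed 4 bits per symbol (the FCC alphabet has 12 < 16
directions) for compact storage in the local-minima memory; similarity is
the Hamming distance over code symbols.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .lattice import FCC, Conformation, Lattice, LatticePoint, validate

PACK_BITS = 4  # fixed nibble width; enough for any lattice with <= 16 directions


@dataclass(frozen=True)
class PackedCode:
    """A code sequence packed two symbols per byte (4-bit nibbles)."""

    data: bytes
    n_symbols: int

    @property
    def bit_length(self) -> int:
        return PACK_BITS * self.n_symbols

    @property
    def symbols(self) -> tuple[int, ...]:
        out = []
        for k in range(self.n_symbols):
            byte = self.data[k // 2]
            out.append((byte >> 4) & 0xF if k % 2 == 0 else byte & 0xF)
        return tuple(out)

    def hex(self) -> str:
        return self.data.hex()


def absolute_encode(c: Conformation, lattice: Lattice = FCC) -> list[int]:
    """Basis index of every step of a valid walk (length n-1)."""
    report = validate(c, lattice)
    if not report.ok:
        raise ValueError(
            f"invalid conformation: chain violations at {report.chain_violations}, "
            f"collisions at {report.collisions}"
        )
    return steps_to_codes(c.coords, lattice)


def steps_to_codes(coords: Sequence[LatticePoint], lattice: Lattice = FCC) -> list[int]:
    """Absolute direction codes of a coordinate path (no validity check)."""
    return [
        lattice.step_index(
            (
                coords[i + 1][0] - coords[i][0],
                coords[i + 1][1] - coords[i][1],
                coords[i + 1][2] - coords[i][2],
            )
        )
        for i in range(len(coords) - 1)
    ]


def absolute_decode(
    codes: Sequence[int],
    start: LatticePoint = (0, 0, 0),
    lattice: Lattice = FCC,
) -> tuple[LatticePoint, ...]:
    """Prefix-sum a code sequence back into coordinates (round-trip inverse)."""
    coords = [tuple(start)]
    x, y, z = start
    for d in codes:
        if not 0 <= d < lattice.coordination:
            raise ValueError(f"direction code {d} out of range for {lattice.name}")
        v = lattice.basis[d]
        x, y, z = x + v[0], y + v[1], z + v[2]
        coords.append((x, y, z))
    return tuple(coords)


def noniso_encode(
    source: Union[Conformation, Sequence[int]],
    lattice: Lattice = FCC,
) -> list[int]:
    """First-occurrence relabeling of the absolute encoding (O(n)).

    Accepts a conformation or a ready absolute code sequence.  The result
    is invariant under translations and under every rotation/reflection of
    the lattice point group.
    """
    if isinstance(source, Conformation):
        codes: Sequence[int] = absolute_encode(source, lattice)
    else:
        codes = source
    mapping: dict[int, int] = {}
    out = []
    for d in codes:
        if d not in mapping:
            mapping[d] = len(mapping)
        out.append(mapping[d])
    return out


def _check_noniso(codes: Sequence[int], lattice: Lattice) -> None:
    high = -1
    for k, d in enumerate(codes):
        if d > high + 1:
            raise ValueError(
                f"not a first-occurrence code: symbol {d} at position {k} "
                f"skips {high + 1}"
            )
        if d >= lattice.coordination:
            raise ValueError(f"code symbol {d} exceeds lattice coordination")
        high = max(high, d)


def canonical_coords(
    codes: Sequence[int],
    lattice: Lattice = FCC,
) -> tuple[LatticePoint, ...]:
    """One representative walk of a non-isomorphic code.

    Code k is read as the (k+1)-th basis vector in the fixed printed order
    (0 -> v1, 1 -> v2, ...), which is consistent with first-occurrence
    labeling; any fixed assignment would do, this one is reproducible.
    Raises ValueError if the code violates the first-occurrence invariants.
    """
    _check_noniso(codes, lattice)
    return absolute_decode(codes, (0, 0, 0), lattice)


def get_packed(codes: Sequence[int]) -> PackedCode:
    """Pack a code sequence into 4-bit nibbles, big-end nibble first."""
    buf = bytearray((len(codes) + 1) // 2)
    for k, d in enumerate(codes):
        if not 0 <= d < 16:
            raise ValueError(f"code symbol {d} does not fit in {PACK_BITS} bits")
        if k % 2 == 0:
            buf[k // 2] |= d << 4
        else:
            buf[k // 2] |= d
    return PackedCode(bytes(buf), len(codes))


def unpack(p: PackedCode) -> list[int]:
    return list(p.symbols)


def hamming(a: PackedCode, b: PackedCode) -> int:
    """Number of symbol positions at which two packed codes differ."""
    if a.n_symbols != b.n_symbols:
        raise ValueError(
            f"length mismatch: {a.n_symbols} vs {b.n_symbols} symbols"
        )
    return sum(x != y for x, y in zip(a.symbols, b.symbols))


def match(b: PackedCode, memory, proximity: int) -> bool:
    """True iff some stored code is within ``proximity`` Hamming symbols of ``b``.

    ``memory`` may be any object with a ``matches(packed, proximity)`` method
    (e.g. the search engine's local-minima memory) or a plain iterable of
    :class:`PackedCode`.
    """
    if proximity < 0:
        raise ValueError("proximity must be >= 0")
    matcher = getattr(memory, "matches", None)
    if matcher is not None:
        return matcher(b, proximity)
    return any(hamming(b, m) <= proximity for m in memory)


def symbols_array(codes: Sequence[int]) -> np.ndarray:
    """Code symbols as a uint8 vector (vectorized memory comparisons)."""
    return np.asarray(codes, dtype=np.uint8)


def serialize_codes(codes: Iterable[int]) -> str:
    """Comma-separated textual form of a code sequence."""
    return ",".join(str(d) for d in codes)


def parse_codes(text: str) -> list[int]:
    text = text.strip()
    if not text:
        return []
    return [int(tok) for tok in text.split(",")]
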
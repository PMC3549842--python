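"""HP sequences: amino-acid classification, file input, synthetic fixtures.

In the HP model the 20 standard amino acids collapse into two classes:
hydrophobic (H) and polar (P).  The classification used here assigns
Gly, Ala, Pro, Val, Leu, Ile, Met, Phe, Tyr, Trp to H and Ser, Thr, Cys,
Asn, Gln, Lys, His, Arg, Asp, Glu to P.  Placing glycine (and proline)
on the hydrophobic side differs from some hydrophobicity scales in the
literature; it is kept deliberately for consistency with the lineage of
FCC-lattice HP benchmarks this solver targets.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from Bio import SeqIO

HYDROPHOBIC = frozenset("GAPVLIMFYW")
POLAR = frozenset("STCNQKHRDE")


@dataclass(frozen=True)
class HPSequence:
    """A non-empty H/P string, optionally carrying its amino-acid source."""

    residues: str
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("HP sequence must be non-empty")
        bad = set(self.residues) - {"H", "P"}
        if bad:
            raise ValueError(f"invalid HP characters: {sorted(bad)}")

    def __str__(self) -> str:
        return self.residues

    def __len__(self) -> int:
        return len(self.residues)


def hp_from_protein(aa_sequence: str) -> HPSequence:
    """Collapse a one-letter amino-acid string to its H/P class string.

    Only the 20 standard residues are accepted; ambiguity codes (B, Z, X)
    raise ValueError.
    """
    aa = aa_sequence.strip().upper()
    out = []
    for k, letter in enumerate(aa):
        if letter in HYDROPHOBIC:
            out.append("H")
        elif letter in POLAR:
            out.append("P")
        else:
            raise ValueError(
                f"unknown amino-acid letter {letter!r} at position {k + 1}"
            )
    return HPSequence("".join(out), source=aa)


def read_sequence(
    path,
    fmt: str = "hp",
    record_id: Optional[str] = None,
) -> HPSequence:
    """Read an HP sequence from a plain H/P file or a FASTA record.

    ``fmt='hp'``: the file is whitespace-stripped and must contain only
    H/P characters.  ``fmt='fasta'``: the (single) record's amino-acid
    sequence is converted via :func:`hp_from_protein`; with several
    records, ``record_id`` must name the one to use.
    """
    path = Path(path)
    if fmt == "hp":
        text = "".join(path.read_text().split())
        if not text:
            raise ValueError(f"{path}: empty sequence file")
        return HPSequence(text)
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"{path}: no FASTA records found")
        if record_id is None:
            if len(records) > 1:
                raise ValueError(
                    f"{path}: {len(records)} records; pass record_id to pick one"
                )
            record = records[0]
        else:
            matches = [r for r in records if r.id == record_id]
            if not matches:
                raise ValueError(f"{path}: no record with id {record_id!r}")
            record = matches[0]
        return hp_from_protein(str(record.seq))
    raise ValueError(f"unknown sequence format {fmt!r} (expected 'hp' or 'fasta')")


def generate_fixture_sequence(n: int, h_fraction: float, seed: int) -> HPSequence:
    """Seeded random HP string with i.i.d. per-residue H probability.

    Synthetic stand-in for benchmark sequences; deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= h_fraction <= 1.0:
        raise ValueError("h_fraction must lie in [0, 1]")
    rng = random.Random(seed)
    return HPSequence(
        "".join("H" if rng.random() < h_fraction else "P" for _ in range(n))
    )
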
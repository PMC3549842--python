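"""Result reporting: relative improvement and run-output writers."""

from __future__ import annotations

import csv
import json
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Iterable

from .lattice import Conformation

#: Cosmetic lattice-unit -> Angstrom scale for the CA-only PDB writer.
PDB_SCALE = 1.9


def relative_improvement(e_o: float, e_r: float, e_l: float) -> float:
    """Progress toward the optimal energy bound relative to a baseline.

        RI = (E_o - E_r) / (E_l - E_r) x 100  [%]

    ``e_o``: energy achieved by the approach under evaluation; ``e_r``:
    energy achieved by the reference approach; ``e_l``: optimal lower
    bound.  The measure weights a gain more heavily the closer the
    baseline already is to the bound.  Rounded half-even to two decimals.
    Raises ValueError when the bound equals the baseline (undefined).
    """
    if e_l == e_r:
        raise ValueError("relative improvement undefined when E_l == E_r")
    value = (e_o - e_r) / (e_l - e_r) * 100.0
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), ROUND_HALF_EVEN))


def write_coords_tsv(conformation: Conformation, path) -> None:
    """Tab-separated conformation: 1-based index, residue, x, y, z."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for k, (letter, (x, y, z)) in enumerate(
            zip(conformation.sequence, conformation.coords), start=1
        ):
            writer.writerow([k, letter, x, y, z])


def read_coords_tsv(path) -> Conformation:
    sequence = []
    coords = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        _idx, letter, x, y, z = line.split("\t")
        sequence.append(letter)
        coords.append((int(x), int(y), int(z)))
    return Conformation("".join(sequence), tuple(coords))


def write_ca_pdb(conformation: Conformation, path, scale: float = PDB_SCALE) -> None:
    """CA-only PDB trace of the walk, lattice units scaled by ``scale`` A.

    Purely cosmetic (for viewers); lattice geometry is not physical and
    the inter-CA distances do not reproduce real backbone spacing.
    """
    lines = []
    for k, (letter, (x, y, z)) in enumerate(
        zip(conformation.sequence, conformation.coords), start=1
    ):
        resname = "HPH" if letter == "H" else "POL"
        lines.append(
            f"ATOM  {k:5d}  CA  {resname} A{k:4d}    "
            f"{x * scale:8.3f}{y * scale:8.3f}{z * scale:8.3f}"
            f"  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trace_csv(trace: Iterable[tuple], path) -> None:
    """Per-iteration trace: iteration, fitness, energy, best energy, event."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["iteration", "current_fitness", "current_energy", "best_energy", "event"]
        )
        writer.writerows(trace)


def write_summary_json(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
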
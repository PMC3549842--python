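"""HP contact energy and the distance-based search fitness.

The HP model scores a conformation by counting hydrophobic contacts:

    E = sum_{i+1<j} c_ij * e_ij,   e_ij = -1 iff s_i = s_j = H,

where c_ij = 1 iff monomers i and j occupy neighboring lattice sites.
Minimizing E is the same as maximizing the number of non-consecutive H-H
contacts.  E is the quantity reported for a structure.

The search itself is driven by a smoother surrogate: the sum over all
non-consecutive H-H pairs of the squared deviation of their squared
Euclidean distance from the contact distance,

    f(c) = sum_{i+1<j, s_i=s_j=H} (d(i,j) - 2)^2,

with d(i,j) the squared distance in lattice units.  On the FCC lattice
every reachable pair of distinct sites has even squared distance >= 2, so
each term is a nonnegative integer and f = 0 exactly when every
non-consecutive H-H pair is in contact (a perfectly packed core).  A
``literal`` deviation variant, (d(i,j)^2 - 2)^2, is kept for comparison;
it penalizes even perfect contacts and is not used by the search.
"""

from __future__ import annotations

from typing import Literal

from .lattice import FCC, Conformation, Lattice, validate

DeviationRule = Literal["contact-zero", "literal"]


def _check_valid(c: Conformation, lattice: Lattice) -> None:
    report = validate(c, lattice)
    if not report.ok:
        raise ValueError(
            f"invalid conformation: chain violations at {report.chain_violations}, "
            f"collisions at {report.collisions}"
        )


def _sqdist(p, q) -> int:
    return (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2


def hp_energy(c: Conformation, lattice: Lattice = FCC) -> int:
    """HP contact energy: -1 per non-consecutive H-H lattice contact.

    Raises ValueError if the conformation violates the chain or
    self-avoidance constraints.
    """
    _check_valid(c, lattice)
    seq, coords = c.sequence, c.coords
    h_idx = [i for i, a in enumerate(seq) if a == "H"]
    energy = 0
    for a in range(len(h_idx)):
        i = h_idx[a]
        for b in range(a + 1, len(h_idx)):
            j = h_idx[b]
            if j - i > 1 and lattice.contains_step(
                (
                    coords[j][0] - coords[i][0],
                    coords[j][1] - coords[i][1],
                    coords[j][2] - coords[i][2],
                )
            ):
                energy -= 1
    return energy


def pair_deviation(d: int, rule: DeviationRule = "contact-zero") -> int:
    """Deviation of a squared pair distance ``d`` from the contact distance."""
    if rule == "contact-zero":
        return d - 2
    if rule == "literal":
        return d * d - 2
    raise ValueError(f"unknown deviation rule: {rule!r}")


def fitness(
    c: Conformation,
    lattice: Lattice = FCC,
    deviation: DeviationRule = "contact-zero",
) -> int:
    """Search fitness: summed squared H-H distance deviations (0 = packed core)."""
    _check_valid(c, lattice)
    seq, coords = c.sequence, c.coords
    h_idx = [i for i, a in enumerate(seq) if a == "H"]
    total = 0
    for a in range(len(h_idx)):
        i = h_idx[a]
        for b in range(a + 1, len(h_idx)):
            j = h_idx[b]
            if j - i > 1:
                dv = pair_deviation(_sqdist(coords[i], coords[j]), deviation)
                total += dv * dv
    return total


def delta_fitness(
    c: Conformation,
    monomer: int,
    target,
    lattice: Lattice = FCC,
    deviation: DeviationRule = "contact-zero",
) -> int:
    """Fitness change if ``monomer`` (0-based) were relocated to ``target``.

    Computed incrementally from the pairs involving the moved monomer only;
    contractually identical to recomputing :func:`fitness` on the moved
    conformation.  Moving a P monomer never changes the fitness.
    Raises ValueError if the move is not applicable (target occupied, or not
    in contact with the chain neighbors of ``monomer``).
    """
    _check_valid(c, lattice)
    n = len(c)
    if not 0 <= monomer < n:
        raise ValueError(f"monomer index {monomer} out of range")
    target = tuple(target)
    if target in c.coords:
        raise ValueError("move target is occupied")
    for nb in (monomer - 1, monomer + 1):
        if 0 <= nb < n and not lattice.contains_step(
            (
                target[0] - c.coords[nb][0],
                target[1] - c.coords[nb][1],
                target[2] - c.coords[nb][2],
            )
        ):
            raise ValueError(
                f"target {target} not in contact with chain neighbor {nb}"
            )
    if c.sequence[monomer] != "H":
        return 0
    old = c.coords[monomer]
    delta = 0
    for j, a in enumerate(c.sequence):
        if a != "H" or abs(j - monomer) <= 1:
            continue
        dv_old = pair_deviation(_sqdist(old, c.coords[j]), deviation)
        dv_new = pair_deviation(_sqdist(target, c.coords[j]), deviation)
        delta += dv_new * dv_new - dv_old * dv_old
    return delta
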
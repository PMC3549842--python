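"""Integer lattice geometry for lattice protein models.

The face-centered cubic (FCC) lattice is the densest sphere packing in
three dimensions and gives each site 12 nearest neighbors, which makes it
the standard discretization for coarse-grained protein backbones.  A
conformation of an n-monomer chain is a self-avoiding walk (SAW): n
distinct lattice points in which consecutive monomers occupy neighboring
sites (the *chain* constraint) and no site is occupied twice (the
*self-avoiding* constraint).

Besides the basic geometry (neighbors, contacts, walk validation) the
module provides the point-group symmetries of a lattice and an exhaustive
SAW enumerator with optional symmetry reduction; the enumerator serves as
a ground-truth oracle for optimal energies on small chains.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

LatticePoint = tuple[int, int, int]
"""A lattice site: integer (x, y, z) coordinates, unbounded."""


@dataclass(frozen=True)
class Lattice:
    """A Bravais-style lattice defined by its displacement basis.

    The basis lists every displacement to a nearest neighbor; it must be
    closed under negation (a lattice walk can be traversed backwards).
    """

    name: str
    basis: tuple[LatticePoint, ...]

    def __post_init__(self) -> None:
        if len(set(self.basis)) != len(self.basis):
            raise ValueError("basis vectors must be pairwise distinct")
        bset = set(self.basis)
        for v in self.basis:
            if (-v[0], -v[1], -v[2]) not in bset:
                raise ValueError("basis must be closed under negation")
        object.__setattr__(self, "_basis_set", bset)
        object.__setattr__(self, "_basis_index", {v: i for i, v in enumerate(self.basis)})

    @property
    def coordination(self) -> int:
        return len(self.basis)

    def contains_step(self, v: LatticePoint) -> bool:
        return v in self._basis_set  # type: ignore[attr-defined]

    def step_index(self, v: LatticePoint) -> int:
        """Index of a displacement in the fixed basis order; raises KeyError."""
        return self._basis_index[v]  # type: ignore[attr-defined]


#: The 12 FCC nearest-neighbor displacements, in the conventional v1..v12 order.
FCC = Lattice(
    "fcc",
    (
        (1, 1, 0), (-1, -1, 0), (-1, 1, 0), (1, -1, 0),
        (0, 1, 1), (0, 1, -1), (0, -1, -1), (0, -1, 1),
        (1, 0, 1), (-1, 0, 1), (-1, 0, -1), (1, 0, -1),
    ),
)

#: Simple cubic lattice (6 neighbors); used only for small illustrative walks.
CUBIC = Lattice(
    "cubic",
    (
        (1, 0, 0), (-1, 0, 0),
        (0, 1, 0), (0, -1, 0),
        (0, 0, 1), (0, 0, -1),
    ),
)


@dataclass(frozen=True)
class Conformation:
    """An HP sequence embedded on a lattice as a self-avoiding walk."""

    sequence: str
    coords: tuple[LatticePoint, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.coords):
            raise ValueError(
                f"sequence length {len(self.sequence)} != number of coordinates "
                f"{len(self.coords)}"
            )
        if set(self.sequence) - {"H", "P"}:
            raise ValueError("sequence alphabet must be {H, P}")
        object.__setattr__(self, "coords", tuple(tuple(p) for p in self.coords))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SymmetryOp:
    """A lattice isometry: a signed-permutation rotation plus a translation."""

    rotation: tuple[tuple[int, int, int], ...]
    translation: LatticePoint = (0, 0, 0)

    def apply(self, p: LatticePoint) -> LatticePoint:
        r, t = self.rotation, self.translation
        return (
            r[0][0] * p[0] + r[0][1] * p[1] + r[0][2] * p[2] + t[0],
            r[1][0] * p[0] + r[1][1] * p[1] + r[1][2] * p[2] + t[1],
            r[2][0] * p[0] + r[2][1] * p[1] + r[2][2] * p[2] + t[2],
        )

    def rotate(self, p: LatticePoint) -> LatticePoint:
        r = self.rotation
        return (
            r[0][0] * p[0] + r[0][1] * p[1] + r[0][2] * p[2],
            r[1][0] * p[0] + r[1][1] * p[1] + r[1][2] * p[2],
            r[2][0] * p[0] + r[2][1] * p[1] + r[2][2] * p[2],
        )


@dataclass
class ValidationReport:
    """Outcome of checking the chain and self-avoidance constraints.

    ``chain_violations`` lists step indices i where coords[i+1]-coords[i]
    is not a basis vector; ``collisions`` lists monomer indices (0-based)
    whose site was already occupied by an earlier monomer.
    """

    chain_violations: list[int] = field(default_factory=list)
    collisions: list[int] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.chain_violations and not self.collisions

    def __bool__(self) -> bool:
        return self.ok


def neighbors(p: LatticePoint, lattice: Lattice = FCC) -> list[LatticePoint]:
    """All nearest-neighbor sites of ``p``, in fixed basis order."""
    return [(p[0] + v[0], p[1] + v[1], p[2] + v[2]) for v in lattice.basis]


def is_contact(p: LatticePoint, q: LatticePoint, lattice: Lattice = FCC) -> bool:
    """True iff ``p`` and ``q`` are nearest neighbors on the lattice."""
    return lattice.contains_step((q[0] - p[0], q[1] - p[1], q[2] - p[2]))


def validate(c: Conformation, lattice: Lattice = FCC) -> ValidationReport:
    """Check the chain and self-avoidance constraints; never raises."""
    report = ValidationReport()
    seen: set[LatticePoint] = set()
    for i, p in enumerate(c.coords):
        if p in seen:
            report.collisions.append(i)
        seen.add(p)
    for i in range(len(c.coords) - 1):
        p, q = c.coords[i], c.coords[i + 1]
        if not lattice.contains_step((q[0] - p[0], q[1] - p[1], q[2] - p[2])):
            report.chain_violations.append(i)
    return report


def _signed_permutation_matrices() -> Iterator[tuple[tuple[int, int, int], ...]]:
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            rows = []
            for axis in range(3):
                row = [0, 0, 0]
                row[perm[axis]] = signs[axis]
                rows.append(tuple(row))
            yield tuple(rows)


def lattice_symmetries(lattice: Lattice = FCC) -> list[SymmetryOp]:
    """All signed-permutation rotations/reflections preserving the basis set.

    For both the FCC and cubic lattices this is the full octahedral group
    of order 48 (reflections included).
    """
    ops = []
    basis_set = set(lattice.basis)
    for rot in _signed_permutation_matrices():
        op = SymmetryOp(rot)
        if {op.rotate(v) for v in lattice.basis} == basis_set:
            ops.append(op)
    return ops


def apply_symmetry(c: Conformation, op: SymmetryOp, lattice: Lattice = FCC) -> Conformation:
    """Rotate then translate every monomer; the sequence is unchanged.

    Raises ValueError if the rotation does not preserve the lattice basis.
    """
    basis_set = set(lattice.basis)
    if {op.rotate(v) for v in lattice.basis} != basis_set:
        raise ValueError("symmetry operation does not preserve the lattice")
    return Conformation(c.sequence, tuple(op.apply(p) for p in c.coords))


#: Largest chain length accepted by :func:`enumerate_saws`.
MAX_ENUMERATION_LENGTH = 8


def _direction_permutation(op: SymmetryOp, lattice: Lattice) -> tuple[int, ...]:
    """How a rotation permutes the basis indices (direction relabeling)."""
    return tuple(lattice.step_index(op.rotate(v)) for v in lattice.basis)


def _stabilizer_permutations(lattice: Lattice) -> list[tuple[int, ...]]:
    """Direction permutations of the symmetries fixing basis vector v1."""
    perms = []
    for op in lattice_symmetries(lattice):
        perm = _direction_permutation(op, lattice)
        if perm[0] == 0 and perm not in perms:
            perms.append(perm)
    return perms


def enumerate_saws(
    n: int,
    lattice: Lattice = FCC,
    reduce_symmetry: bool = False,
) -> Iterator[tuple[LatticePoint, ...]]:
    """Exhaustively enumerate n-monomer self-avoiding walks from the origin.

    With ``reduce_symmetry`` the first step is fixed to v1 and only walks
    whose direction code is lexicographically minimal under the point-group
    stabilizer of v1 are yielded: exactly one representative per rotation/
    reflection class.  The canonicity test is prefix-monotone, so failing
    branches are pruned during the depth-first search.

    Intended as a small-n oracle; ``n`` above ``MAX_ENUMERATION_LENGTH``
    raises ValueError.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > MAX_ENUMERATION_LENGTH:
        raise ValueError(
            f"n={n} exceeds the enumeration cap ({MAX_ENUMERATION_LENGTH})"
        )
    origin: LatticePoint = (0, 0, 0)
    if n == 1:
        yield (origin,)
        return

    basis = lattice.basis
    # Stabilizer permutations excluding the identity; identity never rejects.
    perms = [p for p in _stabilizer_permutations(lattice) if p != tuple(range(len(basis)))]

    path: list[LatticePoint] = [origin]
    code: list[int] = []
    occupied = {origin}

    first_steps = [0] if reduce_symmetry else range(len(basis))

    def canonical_prefix_ok(k: int) -> bool:
        # Reject iff some relabeled image of the code is lexicographically
        # smaller; ties so far keep the branch alive.
        c_k = code[k]
        for perm in perms:
            img = perm[c_k]
            if img < c_k:
                # strictly smaller at position k — but only decisive if the
                # images agreed on the prefix before k
                if all(perm[code[j]] == code[j] for j in range(k)):
                    return False
        return True

    def extend() -> Iterator[tuple[LatticePoint, ...]]:
        if len(path) == n:
            yield tuple(path)
            return
        p = path[-1]
        for d, v in enumerate(basis):
            q = (p[0] + v[0], p[1] + v[1], p[2] + v[2])
            if q in occupied:
                continue
            code.append(d)
            if reduce_symmetry and not canonical_prefix_ok(len(code) - 1):
                code.pop()
                continue
            path.append(q)
            occupied.add(q)
            yield from extend()
            occupied.discard(q)
            path.pop()
            code.pop()

    for d in first_steps:
        v = basis[d]
        q = (v[0], v[1], v[2])
        code.append(d)
        path.append(q)
        occupied.add(q)
        yield from extend()
        occupied.discard(q)
        path.pop()
        code.pop()


def orbit_size(coords: Sequence[LatticePoint], lattice: Lattice = FCC) -> int:
    """Number of distinct origin-anchored images of a walk under the point group.

    Equals |group| / |automorphisms of the walk|; useful for checking that a
    symmetry-reduced enumeration accounts for every unreduced walk.
    """
    ops = lattice_symmetries(lattice)
    base = tuple(
        (p[0] - coords[0][0], p[1] - coords[0][1], p[2] - coords[0][2]) for p in coords
    )
    images = {tuple(op.apply(p) for p in base) for op in ops}
    return len(images)
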
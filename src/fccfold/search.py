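"""Stagnation-aware local search for HP folding on the FCC lattice.

The solver is a single-candidate local search over self-avoiding walks.
Each iteration targets one monomer class (mostly H, periodically P),
enumerates single-monomer relocations — monomer i may move to any free
site in contact with both chain neighbors — and greedily applies the best
move by fitness delta, subject to three control layers:

* a **tabu list** (short-term memory) freezing recently moved monomers for
  a tenure drawn uniformly from [4, n/4];
* a **local-minima memory** (long-term): a sampled archive of packed
  non-isomorphic encodings of 1-move local minima.  A candidate whose
  encoding lies within a Hamming ``proximity`` of a stored minimum is
  discarded, which suppresses revisits to already-exhausted regions in any
  rotated/translated guise;
* an **elite set**: runner-up candidates that were generated but not
  selected, kept in a priority store ordered by (fitness, recency).  When
  the search stagnates (``max_stable`` iterations without a fitness
  improvement, or no admissible move), the tabu list is re-initialized and
  the search *retreats* to the best elite conformation not yet ruled out
  by the memory, discarding a fixed fraction of the top elements so that
  consecutive retreats land in genuinely different regions.

Fitness (see :mod:`fccfold.energy`) drives the moves; HP contact energy
scores the best structure found.  P-monomer moves never change the
fitness, so P iterations pick uniformly at random and act purely as
conformational stirring.
"""

from __future__ import annotations

import math
import random
from bisect import insort
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import codec
from .lattice import FCC, Conformation, Lattice, LatticePoint


@dataclass(frozen=True)
class Move:
    """Relocation of one monomer to a free site adjacent to its chain neighbors."""

    monomer: int  # 0-based index
    target: LatticePoint
    delta: int  # fitness change if applied


@dataclass
class SearchParams:
    """Tunable knobs of the local search (defaults follow the study setup)."""

    max_iterations: int = 10_000
    max_stable: int = 100          # non-improving iterations before a retreat
    proximity: int = 3             # Hamming radius for memory discards
    memory_rate: float = 0.05      # fraction of detected local minima stored
    elite_release: float = 0.05    # fraction of top elite entries dropped per retreat
    elite_capacity: int = 5000
    type_period: tuple[int, int] = (9, 1)  # (H iterations, P iterations) per cycle
    move_ends: bool = True
    deviation: str = "contact-zero"
    seed: int = 0
    record_trace: bool = True

    def validate(self) -> None:
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.max_stable < 1:
            raise ValueError("max_stable must be >= 1")
        if self.proximity < 0:
            raise ValueError("proximity must be >= 0")
        for name in ("memory_rate", "elite_release"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.type_period[0] < 1 or self.type_period[1] < 0:
            raise ValueError("type_period must be (>=1, >=0)")
        if self.deviation not in ("contact-zero", "literal"):
            raise ValueError(f"unknown deviation rule {self.deviation!r}")


class LocalMinimaMemory:
    """Sampled archive of packed encodings of visited local minima.

    Stores each offered encoding with probability ``rate``; never forgets.
    Matching is vectorized Hamming comparison over code symbols.
    """

    def __init__(self, rate: float = 0.05, proximity: int = 3):
        self.rate = rate
        self.proximity = proximity
        self.encountered = 0
        self._rows: list[np.ndarray] = []
        self._stack: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self._rows)

    def _stacked(self) -> Optional[np.ndarray]:
        if self._rows and (self._stack is None or len(self._stack) != len(self._rows)):
            self._stack = np.vstack(self._rows)
        return self._stack if self._rows else None

    @staticmethod
    def _as_array(code) -> np.ndarray:
        if isinstance(code, codec.PackedCode):
            return np.asarray(code.symbols, dtype=np.uint8)
        return np.asarray(code, dtype=np.uint8)

    def add(self, code) -> None:
        self._rows.append(self._as_array(code))

    def offer(self, code, rng: random.Random) -> bool:
        """Record one local-minimum detection; store it at the sampling rate."""
        self.encountered += 1
        if rng.random() < self.rate:
            self.add(code)
            return True
        return False

    def matches(self, code, proximity: Optional[int] = None) -> bool:
        """True iff some stored encoding is within ``proximity`` symbol flips."""
        if proximity is None:
            proximity = self.proximity
        stack = self._stacked()
        if stack is None:
            return False
        arr = self._as_array(code)
        if arr.shape[0] != stack.shape[1]:
            raise ValueError("encoding length differs from stored encodings")
        dists = np.count_nonzero(stack != arr[None, :], axis=1)
        return bool(dists.min() <= proximity)


class EliteSet:
    """Bounded priority store of runner-up conformations.

    Ordered by fitness ascending; among equal fitness the more recent
    iteration ranks first (a fresher region is the better retreat target).
    """

    def __init__(self, capacity: int = 5000):
        self.capacity = capacity
        # entries: (fitness, -iteration, tiebreak, coords)
        self._entries: list[tuple[int, int, int, tuple[LatticePoint, ...]]] = []
        self._counter = 0

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def entries(self):
        return self._entries

    def push(self, fitness: int, iteration: int, coords: Sequence[LatticePoint]) -> None:
        self._counter += 1
        insort(self._entries, (fitness, -iteration, self._counter, tuple(coords)))
        if len(self._entries) > self.capacity:
            self._entries.pop()  # evict worst

    def top(self):
        return self._entries[0] if self._entries else None

    def pop_top(self) -> None:
        self._entries.pop(0)

    def release(self, count: int) -> None:
        del self._entries[:count]


@dataclass
class SearchResult:
    """Outcome of one :func:`run`: best structure, score, and run statistics."""

    sequence: str
    best_conformation: Conformation
    best_energy: int
    best_fitness: int
    iterations: int
    retreats: int
    restarts: int
    discards: int
    minima_detected: int
    minima_stored: int
    memory_size: int
    elite_size: int
    seed: int
    params: SearchParams
    trace: list = field(default_factory=list)

    def summary(self) -> dict:
        p = self.params
        return {
            "sequence": self.sequence,
            "length": len(self.sequence),
            "best_energy": self.best_energy,
            "best_fitness": self.best_fitness,
            "iterations": self.iterations,
            "retreats": self.retreats,
            "restarts": self.restarts,
            "discards": self.discards,
            "local_minima_detected": self.minima_detected,
            "local_minima_stored": self.minima_stored,
            "memory_size": self.memory_size,
            "elite_size": self.elite_size,
            "seed": self.seed,
            "params": {
                "max_iterations": p.max_iterations,
                "max_stable": p.max_stable,
                "proximity": p.proximity,
                "memory_rate": p.memory_rate,
                "elite_release": p.elite_release,
                "elite_capacity": p.elite_capacity,
                "type_period": list(p.type_period),
                "move_ends": p.move_ends,
                "deviation": p.deviation,
            },
        }


def random_saw(
    sequence_length: int,
    rng: random.Random,
    lattice: Lattice = FCC,
) -> list[LatticePoint]:
    """Grow a seeded random self-avoiding walk, backtracking on dead ends.

    Exhaustive backtracking makes failure impossible on the FCC lattice
    (a straight walk always exists), so the walk returned is always valid.
    """
    origin: LatticePoint = (0, 0, 0)
    path = [origin]
    occupied = {origin}
    choice_stack: list[list[LatticePoint]] = []
    while len(path) < sequence_length:
        if len(choice_stack) < len(path):
            p = path[-1]
            cands = [
                (p[0] + v[0], p[1] + v[1], p[2] + v[2])
                for v in lattice.basis
            ]
            cands = [q for q in cands if q not in occupied]
            rng.shuffle(cands)
            choice_stack.append(cands)
        cands = choice_stack[-1]
        if cands:
            q = cands.pop()
            path.append(q)
            occupied.add(q)
        else:
            choice_stack.pop()
            if len(path) == 1:
                raise RuntimeError("self-avoiding walk growth exhausted the lattice")
            occupied.discard(path.pop())
    return path


class LocalSearch:
    """Mutable engine state for one search run (see module docstring).

    Exposes the individual phases (move generation, selection, elite
    update, retreat) for testing and instrumentation; :func:`run` drives
    the full loop.
    """

    def __init__(
        self,
        sequence: str,
        params: Optional[SearchParams] = None,
        lattice: Lattice = FCC,
    ):
        if not sequence or set(sequence) - {"H", "P"}:
            raise ValueError("sequence must be a non-empty string over {H, P}")
        params = params or SearchParams()
        params.validate()
        self.sequence = sequence
        self.params = params
        self.lattice = lattice
        self.n = len(sequence)
        self.rng = random.Random(params.seed)

        self.h_indices = [i for i, a in enumerate(sequence) if a == "H"]
        # per-monomer H partners at chain distance >= 2 (the fitness pairs)
        self._h_partners = [
            np.asarray([j for j in self.h_indices if abs(j - i) > 1], dtype=np.intp)
            for i in range(self.n)
        ]

        coords = random_saw(self.n, self.rng, lattice)
        self._set_conformation(coords)

        self.memory = LocalMinimaMemory(params.memory_rate, params.proximity)
        self.elite = EliteSet(params.elite_capacity)
        self.tabu: dict[int, int] = {}
        self.tenure = 0
        self.initialize_tabu()

        self.iteration = 0
        self.non_improving = 0
        self.reference_fitness = self.fitness
        self.best_fitness = self.fitness
        self.best_energy = self.energy
        self.best_coords = tuple(self.coords)

        self.retreats = 0
        self.restarts = 0
        self.discards = 0
        self.minima_detected = 0
        self.minima_stored = 0
        self.trace: list[tuple] = []
        self.last_events: list[str] = []
        self.last_move: Optional[Move] = None
        self.last_retreat_target: Optional[tuple[LatticePoint, ...]] = None

    # -- state plumbing ----------------------------------------------------

    def _set_conformation(self, coords: Sequence[LatticePoint]) -> None:
        self.coords: list[LatticePoint] = [tuple(p) for p in coords]
        self.coords_np = np.asarray(self.coords, dtype=np.int64)
        self.occupied: dict[LatticePoint, int] = {
            p: i for i, p in enumerate(self.coords)
        }
        if len(self.occupied) != self.n:
            raise ValueError("conformation is not self-avoiding")
        self.abs_codes = codec.steps_to_codes(self.coords, self.lattice)
        self.fitness = self._full_fitness()
        self.energy = self._full_energy()

    def conformation(self) -> Conformation:
        return Conformation(self.sequence, tuple(self.coords))

    def _dv(self, d: np.ndarray) -> np.ndarray:
        if self.params.deviation == "literal":
            return d * d - 2
        return d - 2

    def _full_fitness(self) -> int:
        h = self.coords_np[self.h_indices]
        if len(self.h_indices) < 2:
            return 0
        idx = np.asarray(self.h_indices)
        diff = h[:, None, :] - h[None, :, :]
        d = (diff * diff).sum(axis=2)
        mask = (idx[None, :] - idx[:, None]) > 1  # j - i > 1, upper triangle
        dv = self._dv(d[mask])
        return int((dv * dv).sum())

    def _full_energy(self) -> int:
        h = self.coords_np[self.h_indices]
        if len(self.h_indices) < 2:
            return 0
        idx = np.asarray(self.h_indices)
        diff = h[:, None, :] - h[None, :, :]
        d = (diff * diff).sum(axis=2)
        mask = (idx[None, :] - idx[:, None]) > 1
        return -int(((d == 2) & mask).sum())

    # -- phases ------------------------------------------------------------

    def initialize_tabu(self) -> None:
        """Clear the tabu list and resample the tenure from [4, n/4]."""
        self.tabu.clear()
        self.tenure = self.rng.randint(4, max(4, self.n // 4))

    def is_tabu(self, monomer: int) -> bool:
        expiry = self.tabu.get(monomer)
        return expiry is not None and self.iteration < expiry

    def select_monomer_type(self, iteration: Optional[int] = None) -> str:
        """H for the first k_H iterations of each cycle, then P for k_P."""
        if iteration is None:
            iteration = self.iteration
        k_h, k_p = self.params.type_period
        if k_p == 0:
            return "H"
        return "H" if (iteration - 1) % (k_h + k_p) < k_h else "P"

    def _candidate_targets(self, monomer: int) -> list[LatticePoint]:
        """Free sites in contact with both chain neighbors of ``monomer``.

        Chain ends have a single neighbor; any of its free neighbor sites
        is admissible (disable via ``params.move_ends``).
        """
        n = self.n
        if n == 1:
            return []
        lattice = self.lattice
        occupied = self.occupied
        if monomer == 0 or monomer == n - 1:
            if not self.params.move_ends:
                return []
            anchor = self.coords[1] if monomer == 0 else self.coords[n - 2]
            return [
                q
                for v in lattice.basis
                if (q := (anchor[0] + v[0], anchor[1] + v[1], anchor[2] + v[2]))
                not in occupied
            ]
        left, right = self.coords[monomer - 1], self.coords[monomer + 1]
        out = []
        for v in lattice.basis:
            q = (left[0] + v[0], left[1] + v[1], left[2] + v[2])
            if q not in occupied and lattice.contains_step(
                (right[0] - q[0], right[1] - q[1], right[2] - q[2])
            ):
                out.append(q)
        return out

    def _deltas_for(self, monomer: int, targets: list[LatticePoint]) -> np.ndarray:
        """Fitness deltas of moving an H ``monomer`` to each target (vectorized)."""
        partners = self._h_partners[monomer]
        if partners.size == 0 or not targets:
            return np.zeros(len(targets), dtype=np.int64)
        pts = self.coords_np[partners]
        old = self.coords_np[monomer]
        diff_old = pts - old
        dv_old = self._dv((diff_old * diff_old).sum(axis=1))
        base = (dv_old * dv_old).sum()
        t = np.asarray(targets, dtype=np.int64)
        diff_new = t[:, None, :] - pts[None, :, :]
        dv_new = self._dv((diff_new * diff_new).sum(axis=2))
        return (dv_new * dv_new).sum(axis=1) - base

    def generate_moves(self, monomer_type: str) -> list[Move]:
        """All admissible moves of non-tabu monomers of the given type.

        H moves come sorted best-delta-first (ties by monomer index then
        target, for determinism); P moves are shuffled, implementing the
        uniform-random P selection.
        """
        moves: list[Move] = []
        for i in range(self.n):
            if self.sequence[i] != monomer_type or self.is_tabu(i):
                continue
            targets = self._candidate_targets(i)
            if not targets:
                continue
            if monomer_type == "H":
                deltas = self._deltas_for(i, targets)
                moves.extend(
                    Move(i, q, int(d)) for q, d in zip(targets, deltas)
                )
            else:
                moves.extend(Move(i, q, 0) for q in targets)
        if monomer_type == "H":
            moves.sort(key=lambda m: (m.delta, m.monomer, m.target))
        else:
            self.rng.shuffle(moves)
        return moves

    def _candidate_encoding(self, move: Move) -> np.ndarray:
        """Non-isomorphic encoding of the conformation after ``move`` (O(n))."""
        codes = list(self.abs_codes)
        i, q = move.monomer, move.target
        lattice = self.lattice
        if i > 0:
            p = self.coords[i - 1]
            codes[i - 1] = lattice.step_index((q[0] - p[0], q[1] - p[1], q[2] - p[2]))
        if i < self.n - 1:
            p = self.coords[i + 1]
            codes[i] = lattice.step_index((p[0] - q[0], p[1] - q[1], p[2] - q[2]))
        return np.asarray(codec.noniso_encode(codes, lattice), dtype=np.uint8)

    def select_move(self, moves: list[Move]) -> Optional[Move]:
        """Walk the candidate list; discard memory-matched candidates.

        The first candidate whose encoding does not match the local-minima
        memory is returned, after the elite set has been fed this
        iteration's runner-ups.  An exhausted list signals stagnation by
        forcing the non-improving counter past ``max_stable``.
        """
        for k, move in enumerate(moves):
            enc = self._candidate_encoding(move)
            if self.memory.matches(enc, self.params.proximity):
                self.discards += 1
                continue
            self.update_elite_set(self._runner_ups(moves, move))
            return move
        self.non_improving = self.params.max_stable + 1
        return None

    def _runner_ups(self, moves: list[Move], selected: Move) -> list[Move]:
        """Second-best candidates: the move(s) at the best delta strictly
        worse than the selected move's, capped at 3."""
        worse = [m.delta for m in moves if m.delta > selected.delta]
        if not worse:
            return []
        runner_delta = min(worse)
        return [m for m in moves if m.delta == runner_delta][:3]

    def update_elite_set(self, candidates: Sequence[Move]) -> None:
        """Push each memory-unmatched runner-up conformation into the elite set."""
        for move in candidates:
            enc = self._candidate_encoding(move)
            if self.memory.matches(enc, self.params.proximity):
                continue
            coords = list(self.coords)
            coords[move.monomer] = move.target
            self.elite.push(self.fitness + move.delta, self.iteration, coords)

    def perform_move(self, move: Move) -> None:
        """Apply a move: update coordinates, fitness, energy, tabu, and best."""
        i, q = move.monomer, move.target
        old = self.coords[i]
        # incremental energy: only H-H contacts of the moved monomer change
        if self.sequence[i] == "H":
            partners = self._h_partners[i]
            if partners.size:
                pts = self.coords_np[partners]
                d_old = ((pts - self.coords_np[i]) ** 2).sum(axis=1)
                t = np.asarray(q, dtype=np.int64)
                d_new = ((pts - t) ** 2).sum(axis=1)
                self.energy += -int((d_new == 2).sum()) + int((d_old == 2).sum())
        del self.occupied[old]
        self.occupied[q] = i
        self.coords[i] = q
        self.coords_np[i] = q
        lattice = self.lattice
        if i > 0:
            p = self.coords[i - 1]
            self.abs_codes[i - 1] = lattice.step_index(
                (q[0] - p[0], q[1] - p[1], q[2] - p[2])
            )
        if i < self.n - 1:
            p = self.coords[i + 1]
            self.abs_codes[i] = lattice.step_index(
                (p[0] - q[0], p[1] - q[1], p[2] - q[2])
            )
        self.fitness += move.delta
        self.tabu[i] = self.iteration + self.tenure
        if self.fitness < self.best_fitness:
            self.best_fitness = self.fitness
        if self.energy < self.best_energy:
            self.best_energy = self.energy
            self.best_coords = tuple(self.coords)

    def detect_local_minimum(self) -> bool:
        """1-move local optimality: no applicable H move improves or ties.

        Tabu status is ignored — local optimality is a property of the
        conformation, not of the search bookkeeping.  Vacuously true when
        no H move is applicable.
        """
        for i in self.h_indices:
            targets = self._candidate_targets(i)
            if not targets:
                continue
            deltas = self._deltas_for(i, targets)
            if deltas.min() <= 0:
                return False
        return True

    def store_local_minimum(self) -> bool:
        """Offer the current conformation's encoding to the long-term memory."""
        self.minima_detected += 1
        enc = np.asarray(
            codec.noniso_encode(self.abs_codes, self.lattice), dtype=np.uint8
        )
        stored = self.memory.offer(enc, self.rng)
        if stored:
            self.minima_stored += 1
        return stored

    def select_from_elite_set(self):
        """Pop memory-matched elites; release a fraction at the first survivor.

        Returns ``(coords, fitness)`` of the retreat target, or ``None``
        when the elite set exhausts.  The released block (a fraction
        ``elite_release`` of the current size, at least the returned top
        element) removes fitness- and time-proximate near-duplicates.
        """
        while len(self.elite):
            fit, _negit, _cnt, coords = self.elite.top()
            enc = np.asarray(
                codec.noniso_encode(
                    codec.steps_to_codes(coords, self.lattice), self.lattice
                ),
                dtype=np.uint8,
            )
            if self.memory.matches(enc, self.params.proximity):
                self.elite.pop_top()
                continue
            release = max(1, math.ceil(self.params.elite_release * len(self.elite)))
            self.elite.release(release)
            return coords, fit
        return None

    def retreat(self) -> None:
        """Stagnation response: fresh tabu, then jump to an elite conformation.

        Falls back to restarting from the best structure found so far when
        the elite set is exhausted.
        """
        self.initialize_tabu()
        selected = self.select_from_elite_set()
        if selected is not None:
            coords, _fit = selected
            self._set_conformation(coords)
            self.last_retreat_target = tuple(self.coords)
            self.retreats += 1
            self.last_events.append("retreat")
        else:
            self._set_conformation(self.best_coords)
            self.last_retreat_target = None
            self.restarts += 1
            self.last_events.append("restart")
        if self.fitness < self.best_fitness:
            self.best_fitness = self.fitness
        if self.energy < self.best_energy:
            self.best_energy = self.energy
            self.best_coords = tuple(self.coords)
        self.reference_fitness = self.fitness
        self.non_improving = 0

    def step(self) -> None:
        """One iteration of the search loop."""
        self.iteration += 1
        self.last_events = []
        self.last_move = None
        monomer_type = self.select_monomer_type()
        moves = self.generate_moves(monomer_type)
        move = self.select_move(moves) if moves else None
        if moves and move is None:
            pass  # list exhausted inside select_move; counter already forced
        elif not moves:
            self.non_improving = self.params.max_stable + 1
            self.last_events.append("stall")
        if move is not None:
            self.perform_move(move)
            self.last_move = move
            self.last_events.append("move")
            if self.fitness < self.reference_fitness:
                self.reference_fitness = self.fitness
                self.non_improving = 0
            else:
                self.non_improving += 1
            if monomer_type == "H" and self.detect_local_minimum():
                if self.store_local_minimum():
                    self.last_events.append("minimum_stored")
        if self.non_improving >= self.params.max_stable:
            self.retreat()
        if self.params.record_trace:
            self.trace.append(
                (
                    self.iteration,
                    self.fitness,
                    self.energy,
                    self.best_energy,
                    "+".join(self.last_events) or "none",
                )
            )

    def result(self) -> SearchResult:
        return SearchResult(
            sequence=self.sequence,
            best_conformation=Conformation(self.sequence, self.best_coords),
            best_energy=self.best_energy,
            best_fitness=self.best_fitness,
            iterations=self.iteration,
            retreats=self.retreats,
            restarts=self.restarts,
            discards=self.discards,
            minima_detected=self.minima_detected,
            minima_stored=self.minima_stored,
            memory_size=len(self.memory),
            elite_size=len(self.elite),
            seed=self.params.seed,
            params=self.params,
            trace=self.trace,
        )


def run(
    sequence: str,
    params: Optional[SearchParams] = None,
    observer: Optional[Callable[[LocalSearch], None]] = None,
) -> SearchResult:
    """Run the full search loop and return the best structure found.

    ``observer``, if given, is called after every iteration with the live
    engine (used for instrumentation and invariant checking).
    """
    engine = LocalSearch(sequence, params)
    while engine.iteration < engine.params.max_iterations:
        engine.step()
        if observer is not None:
            observer(engine)
    return engine.result()
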
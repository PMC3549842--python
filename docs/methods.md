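# Methods

## Model

A protein of length *n* is a string over {H, P}; a conformation embeds it
on the FCC lattice as a self-avoiding walk.  Two sites are in contact iff
their difference is one of the 12 basis vectors
`(±1,±1,0), (0,±1,±1), (±1,0,±1)` (fixed in that order, v1…v12, which
every encoding and the enumerator's canonicalization depend on).
Coordinates are unbounded signed integers; nothing in the model bounds
the lattice.  All FCC sites reachable from the origin have even
coordinate sum, so the squared distance between any two monomers is even
and ≥ 2; 2 means contact.

**Energy.**  `E = −(number of non-consecutive H–H contacts)`.  This is
the reported score of a structure, always an integer ≤ 0.

**Fitness.**  The search is driven by
`f(c) = Σ_{i+1<j, both H} dv(i,j)²` with `dv = d − 2` and `d` the squared
Euclidean distance.  `f` is a nonnegative integer, zero exactly when
every non-consecutive H–H pair is in contact; gradients of `f` pull
distant H pairs together long before they can form contacts, which pure
contact counting cannot do.  A `deviation="literal"` variant
(`dv = d² − 2`) is retained for comparison; it assigns a perfect contact
the positive penalty (2²−2)² = 4, so its minimum is not the packed core,
and it is not used by the search.  P monomers never enter `f`, hence
P-moves are fitness-neutral by construction.

## Search procedure

One iteration: pick the monomer class for this iteration (default cycle:
9 H-iterations, then 1 P-iteration), enumerate all single-monomer
relocations of non-tabu monomers of that class — monomer *i* may move to
any free site in contact with both chain neighbors; chain ends use their
single interior neighbor (configurable off) — then select, apply, and
book-keep.  H-move lists are sorted by incremental fitness delta (ties
broken by monomer index then target, for determinism); P-moves are
selected uniformly at random.

Selection walks the sorted list: each candidate conformation is encoded
(see below) and discarded if it matches the local-minima memory within
the Hamming `proximity`; the first survivor is applied, after the elite
set has been offered this iteration's runner-ups.  If the list empties,
the non-improving counter is forced past `max_stable`, triggering the
stagnation response immediately.

**Tabu.**  A moved monomer may not move again for `tenure` iterations;
`tenure` is drawn uniformly from [4, n/4] (clamped to ≥ 4 for short
chains) and resampled whenever the tabu list is re-initialized, which
happens at the start and at every stagnation.  The list is cleared, not
merely re-tenured, at stagnation.

**Local-minima memory.**  A conformation is a 1-move local minimum when
its fitness is strictly below that of every applicable H move (tabu
status is ignored: local optimality is a property of the conformation,
not of the search bookkeeping; the condition holds vacuously if no H move
is applicable).  Each detected minimum's packed encoding is stored with
probability `memory_rate` (default 0.05); the memory is never cleared —
it is the long-term map of exhausted regions.  Matching is Hamming
distance over code *symbols* (not packed bits: packing is a storage
device, and bit-level distance would weight symbol pairs unevenly) with
default `proximity` 3; codes of different lengths never match.

**Elite set.**  The runner-ups of an iteration are the moves at the best
fitness delta strictly worse than the selected move's, capped at 3; each
is encoded and inserted only if it does not match the memory.  The store
is a priority queue ordered by fitness ascending, ties broken toward the
more recent iteration (a fresher region is the better retreat target),
with capacity 5,000 and worst-element eviction.  At stagnation
(`max_stable` = 100 consecutive iterations without improving the best
fitness seen since the last retreat), the engine re-initializes the tabu
list and retreats: it pops elite elements that meanwhile match the grown
memory, and on the first survivor releases `max(1, ⌈0.05·size⌉)` top
elements (the survivor included) and continues from it.  Releasing a
block removes entries similar in fitness and time, so consecutive
retreats diverge.  If the elite set exhausts, the search restarts from
the best conformation found so far.  Measuring improvement against the
best fitness *since the last retreat* (rather than the global best)
gives each retreat a full `max_stable` window to explore before the next
one; against the global best, a retreat to a worse elite conformation
would almost always be followed by another retreat exactly `max_stable`
iterations later.

**Initialization.**  A seeded random self-avoiding walk grown step by
step, choosing uniformly among free neighbors with exhaustive
backtracking on dead ends — simple, valid, and reproducible; a single
`random.Random(seed)` instance drives every stochastic choice, so runs
are bit-reproducible from the seed.

## Conformation encoding

The absolute encoding of a walk is the sequence of basis indices of its
n−1 steps; it is translation-invariant only.  The non-isomorphic encoding
relabels absolute directions by first occurrence in a single O(n) pass.
Any lattice isometry acts on a walk by applying one fixed permutation of
the 12 directions along the whole chain, and first-occurrence labels are
invariant under any such relabeling — hence the code is identical for all
48 rotations/reflections and all translations of a structure.  The code
is *not* injective on symmetry classes: it forgets the angles between
distinct directions, so geometrically different walks can share a code.
For revisitation control this conflation is acceptable (it only makes the
memory veto slightly more aggressive), and it is the price of O(n)
encoding with no decoding step.  `canonical_coords` maps code k to basis
vector v_{k+1}, a fixed assignment chosen for reproducibility; the
resulting representative path can self-intersect, which is irrelevant to
its role (code-level round trips).

Codes are packed 4 bits per symbol (12 < 16 symbols; larger lattices are
out of scope) and stored in the memory as byte vectors for vectorized
Hamming comparison.

## Enumeration oracle

`enumerate_saws` yields every n-monomer walk from the origin (cap n = 8).
With symmetry reduction the first step is fixed to v1 and a walk is kept
iff its direction code is lexicographically minimal under the 4
point-group symmetries stabilizing v1; the test is prefix-monotone, so
non-canonical branches are pruned during the DFS.  Each symmetry class of
walks appears exactly once (verified against unreduced counts times orbit
sizes for n ≤ 4; e.g. 132 unreduced walks of length 3).  Reduced
enumeration at n = 8 visits 337,056 classes in about a second, and ground
states for any octamer sequence follow by scoring the shared walk table.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `max_stable` | 100 | non-improving iterations before a retreat |
| `proximity` | 3 | Hamming radius (symbols) for memory discards |
| `memory_rate` | 0.05 | fraction of detected local minima stored |
| `elite_release` | 0.05 | fraction of top elite entries dropped per retreat |
| `elite_capacity` | 5000 | elite store bound (worst evicted) |
| `type_period` | (9, 1) | H-iterations : P-iterations per cycle |
| `move_ends` | true | chain termini may move around their single neighbor |

`max_stable`, `proximity` and `memory_rate` follow the published study
setup for this solver family.  The elite release fraction, capacity, the
recency tie-break, the runner-up cap of 3, the 9:1 type period, and
movable chain ends are this package's own choices where the procedure
leaves them open; each is configurable.  All quantities are dimensionless
(lattice units, iterations).

## Synthetic data

`generate_fixture_sequence(n, h_fraction, seed)` draws i.i.d. H/P strings
(default studies here use h_fraction = 0.5).  These match real HP
benchmark instances in alphabet and composition but not in the correlated
hydrophobicity patterns of natural sequences; passing tests on them
demonstrates correctness of the machinery (energies, encodings, search
invariants, small-instance optimality), not predictive performance on
real proteins.  The amino-acid→HP table maps Gly/Ala/Pro/Val/Leu/Ile/
Met/Phe/Tyr/Trp → H and Ser/Thr/Cys/Asn/Gln/Lys/His/Arg/Asp/Glu → P;
placing Gly and Pro on the H side differs from some hydrophobicity
scales but matches the FCC/HP benchmark lineage this solver targets.

## Validation scale

The end-to-end suite checks, at desk scale: the four published
relative-improvement cells recomputed exactly; encoding invariance over
500 random 30-mers × all 48 isometries plus translations; brute-force
energy/fitness/delta oracles on 1,000 random walks and 500 moves;
ground-state recovery on ten random octamers (10⁵ iterations each,
vs. exhaustive enumeration, ≥ 9/10 required); a 10⁵-iteration invariant
sweep on a 50-mer; and a 3-standard-error binomial bound on the memory
sampling rate.  Cluster-scale benchmark campaigns (200-monomer proteins,
dozens of multi-hour runs) are out of scope; nothing here estimates the
solver's competitive standing on those instances.

## Known limitations

* FCC only for the search (the cubic lattice exists for encoding
  examples); no pull moves or other composite neighborhoods — single
  monomer relocations only, so some transitions require long move
  sequences the tabu/memory machinery must discover.
* The encoding's conflation of symmetry classes (above) can discard a
  genuinely new conformation whose code happens to collide near a stored
  minimum.
* Relative improvement is undefined when the bound equals the reference
  energy (raises) and is reported rounded half-even to two decimals.
* The PDB writer scales lattice units by 1.9 Å per unit for viewing
  convenience; the geometry is not physical.
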
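# fccfold

Local-search structure prediction for HP-model proteins on the
face-centered cubic (FCC) lattice.

## The problem

In the hydrophobic–polar (HP) model each residue of a protein is either
hydrophobic (**H**) or polar (**P**), and a structure is a self-avoiding
walk on a lattice: consecutive monomers occupy neighboring sites, and no
site is occupied twice.  The energy of a conformation counts hydrophobic
contacts,

```
E = Σ_{i+1<j} c_ij · e_ij ,      e_ij = −1  iff  s_i = s_j = H,
```

where `c_ij = 1` iff monomers *i* and *j* are lattice neighbors.
Minimizing `E` means packing a maximal hydrophobic core.  The FCC lattice
(12 neighbors per site, basis vectors `(±1,±1,0), (0,±1,±1), (±1,0,±1)`)
is the standard choice because it is the densest sphere packing and
avoids the parity artifacts of the cubic lattice.  Finding the ground
state is NP-hard, so practical solvers are stochastic local searches.

`fccfold` is for people studying lattice protein models and search
heuristics: it implements a tabu local search over single-monomer moves,
driven by a distance-based fitness `f(c) = Σ (d(i,j) − 2)²` over
non-consecutive H–H pairs (`d` = squared Euclidean distance; `f = 0` is a
perfectly packed core), with two diversification devices:

* **Non-isomorphic encoding** — an O(n) canonical code for conformations.
  The absolute direction string of a walk is relabeled by first
  occurrence (first direction seen → 0, next new direction → 1, …), which
  makes the code invariant under all translations, rotations and
  reflections of the lattice.  A long-term memory stores packed codes of
  a sample of visited local minima; candidate moves whose code lies
  within a Hamming proximity of a stored minimum are discarded, so the
  search cannot revisit an exhausted region in a rotated guise.
* **Elite retreat** — runner-up candidates that were generated but never
  selected are kept in a bounded priority store ordered by (fitness,
  recency).  When the search stagnates (`max_stable` non-improving
  iterations), it retreats to the best elite conformation not ruled out
  by the memory, discarding a fixed fraction of the top entries so that
  consecutive retreats diverge into different regions.

An exhaustive, symmetry-reduced self-avoiding-walk enumerator provides
ground-truth optima on small chains for validation.

## Worked example

```
$ printf 'HPHHPPHHPHHPHHHPHPHH\n' > seq20.txt
$ fccfold fold --seq seq20.txt --max-iter 20000 --seed 11 --out demo_out
folding n=20 sequence, 20000 iterations, seed 11
best HP energy -30 (fitness 648), 183 retreats, 379 memory discards
results in demo_out/
```

The best structure found has 30 non-consecutive H–H contacts (`E = −30`);
along the way the search retreated to an elite conformation 183 times and
the local-minima memory vetoed 379 candidate conformations as revisits.
`demo_out/` contains the best coordinates (TSV: index, residue, x, y, z),
the per-iteration trace (CSV) and a JSON summary; `--pdb` adds a cosmetic
CA-only PDB trace.  Runs are exactly reproducible from `(input, flags,
seed)`.

The canonical encoding of any stored conformation:

```
$ fccfold encode --coords demo_out/best_coords.tsv
encoding: 0,1,2,3,4,5,6,1,0,7,8,4,0,9,9,10,6,7,10
packed:   012345610784099a67a0
```

and two library-level views of the same machinery:

```python
>>> from fccfold import run, SearchParams, noniso_encode, Conformation
>>> run("HPHHPPHH", SearchParams(max_iterations=5000, seed=1)).best_energy
-6
>>> noniso_encode(Conformation("PPP", ((0,0,0), (0,1,1), (1,2,1))))
[0, 1]
```

Progress between two solvers is compared as relative improvement toward
the optimal bound, `RI = (E_o − E_r)/(E_l − E_r) × 100`:

```
$ fccfold report --eo -339 --er -326 --el -384
22.41%
```

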
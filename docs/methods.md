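# Methods

## The model

Four homologous protein structures A–D are assumed to have diverged from a
common ancestor along a rooted binary tree, at an approximately equal rate
of structural change per lineage (a structural molecular clock). The
observable is, for each pair, the number *r* of Cα atoms that can be
structurally equivalenced; *r* shrinks as structures diverge, so an
evolutionary distance is defined either subtractively, `d = P − r`, or as a
ratio, `d = 100·P/r`, where P is a constant approximating the residue count
of the ancestral, functioning protein (default 600). P is deliberately
crude: under the ratio scheme it is a pure scale factor and provably cannot
change the ranking (asserted in tests over P ∈ {300, 600, 1000}); under the
subtractive scheme it shifts all distances equally and must satisfy
P ≥ max r. Note the ratio scheme has a self-distance floor of 100 at r = P;
only distance *differences* carry signal there, which the linear fit
absorbs into the branch lengths.

## Tree enumeration

A rooted binary tree on four leaves has one of two shapes: balanced
((L1,L2),(L3,L4)) or caterpillar (((L1,L2),L3),L4), with six branches in
either case, named a–f in a fixed slot convention (leaf branches a, b for
the first cherry; see `portalphylo/trees.py` for the full layout). Dividing
the 4! leaf assignments per shape by the shape's symmetry group (order 8 for
balanced: swaps within each cherry and the cherry swap; order 2 for
caterpillar: the basal-cherry swap) leaves 3 + 12 = 15 distinct varieties,
ids `1.1`–`1.3` and `2.1`–`2.12` in lexicographic order of the canonical
leaf assignment. Because any such numbering is a convention, every report
prints the full leaf arrangement next to the id. An independent brute-force
orbit canonicalisation in the test suite confirms the counts.

## Least-squares fit and R factor

For one variety the six observed pairwise distances give six linear
equations (each distance = sum of branch lengths on the leaf-to-leaf path),
and the clock gives four more (each root-to-leaf path sum = g): ten
equations in seven unknowns (a–f, g), solved by `numpy.linalg.lstsq` on the
design matrix. The fit quality is summarised by a crystallographic-style
relative residual over the six pairwise distances,

    R = Σ |d_obs − d_calc| / Σ d_obs ,

computed for the clock-constrained fit (`R_all`) and for the unconstrained
six-equation fit (`R_pair`). The absolute-value form of R is a design
choice of this package; it is isolated in a single function
(`trees.r_factor`) so a squared-residual variant is a one-line swap. Root
rows have zero observed values and therefore never enter the R denominator —
they constrain the parameters only.

Numerical choices:

- The pairwise-only system is rank-deficient (the two root-adjacent branches
  enter every path as a sum, and g is unconstrained); the minimum-norm
  solution is returned with an explicit `pair_rank_deficient` flag, never
  silently.
- Negative fitted branch lengths are reported as fitted, never clamped;
  feasibility (min branch ≥ −1e−9) is a filter applied at ranking time.
- Ranking sorts by (feasible first, R_all ascending, variety id). R_all is
  rounded to 1e−12 in the sort key so exactly symmetric ties are not broken
  by floating-point noise; tied varieties resolve by id.

## Superposition and equivalencing

The pairwise structural alignment is sequence-free:

1. *Seeding*: every gapless 9-residue window of one chain is rigidly fitted
   to every window of the other (batched closed-form RMSD via the singular
   values of the windowed cross-covariance); the lowest-RMSD window pair is
   the initial equivalence.
2. *Iteration*: superpose (Kabsch, SVD with reflection correction) on the
   current pairs → recompute the maximal order-preserving pairing whose
   post-superposition Cα separations are all ≤ the cutoff → repeat until
   the pair set repeats (cycle detection over the last three sets) or 50
   iterations. The pairing maximises pair count with ties broken by smaller
   total separation, computed by dynamic programming over candidate cells
   with a Fenwick prefix-maximum (O(m log n)); a brute-force recursion
   validates it on small chains. The returned separations are those under
   the superposition that produced the final pairing, so every separation
   respects the cutoff by construction.

The default cutoff of 3.8 Å is one Cα–Cα virtual bond length — a residue
displaced by more than one residue spacing is no longer "the same position"
in the fold. Published r values obtained with other programs can be
bracketed by a cutoff sweep (`examples/real_portals.py` does 3.0/3.8/4.5 Å);
the cutoff is recorded in every report. Degenerate geometry (collinear
point sets, under which the optimal rotation is not unique) is rejected
explicitly. Fewer than three surviving pairs aborts with an empty-alignment
error.

## Sequence statistics

The minimum base change per codon between two amino acids is the smallest
Hamming distance between any of their codons under the standard genetic code
(61 coding codons, from Biopython's table; stop codons excluded). The 20×20
matrix is generated by enumeration at first use and cached — never typed in —
and equals an independent 61×61 codon-pair scan in the tests. Percent
identity and mean MBC are computed over equivalenced pairs only, keeping the
sequence statistics independent of the (structure-only) alignment. The
MBC-vs-separation trend uses default bin edges (0, 1, 2, 3, 3.8) Å, last bin
closed on the right; empty bins report n = 0 with no mean.

## Synthetic data: what it emulates, and what it does not

- *Tree distances*: exact path sums over a known rooted tree; ultrametric
  specs are validated for equal root-to-leaf sums at construction. Noise is
  i.i.d. Gaussian per pair with σ expressed as a fraction of the mean
  distance (negatives resampled) — the simplest perturbation consistent with
  independent measurement error on each pair; real r-derived distances share
  the measurement (the alignments), so their errors need not be independent.
- *Cα families*: one self-avoiding random walk (3.8 Å steps, 3.0 Å exclusion
  radius) is the shared core; each taxon receives an independently perturbed
  copy (per-taxon Gaussian σ on coordinates, so two taxa with σ_s, σ_t sit
  at RMS separation ≈ √(3(σ_s²+σ_t²)) before superposition error), flanked by
  unrelated self-avoiding walks and randomly rigidly placed. Random walks
  have protein-like connectivity but no secondary structure, so alignment
  statistics on them probe the algorithm, not the realism of fold space:
  passing tests demonstrate recovery of a rigid common core under noise and
  a small false-positive floor between unrelated chains (empirically r ≤ 30
  for 100-residue pairs), not performance on real folds.
- *Sequences*: the first taxon gets a uniform random sequence; other taxa
  copy the reference residue at core position k with probability
  exp(−sep_k/λ), where sep_k is the true structural separation of the cores
  and λ (default 4 Å) the conservation decay scale, all other residues
  uniform. This reproduces the qualitative structure the similarity
  statistics assume — closer positions are more conserved — not any real
  substitution process.

All generators are deterministic under their seed.

## Problem sizes in tests and the acceptance script

The default suite and `scripts/acceptance.py` run on synthetic inputs sized
to exercise every code path at portal-like magnitudes: 60-residue cores in
100-residue chains for alignment, distances of order 100–400 for the tree
fits, 200 replicates for the stochastic-recovery rate and 20 for the
frozen alignment bounds. These sizes were chosen as the smallest that make
the statistical assertions stable across reruns.

## Known limitations

- Strictly four taxa: the exhaustive 15-variety scheme does not generalise;
  there is no tree search, bootstrap, or likelihood model.
- Rigid-body alignment only — no hinged or flexible superposition; domains
  whose relative orientation varies (the crown) must be masked out by the
  user.
- The iterative equivalencing converges to a fixed point that may depend on
  the seed window for pathological inputs; determinism is guaranteed, global
  optimality is not.
- Running the pipeline on the real portal structures requires the deposited
  coordinate files (the T4 portal model is not bundled and its accession
  must be supplied by the user); `examples/real_portals.py` documents the
  procedure, including crown masks and a cutoff sweep.
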
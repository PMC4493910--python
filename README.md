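# portalphylo

Structure-based phylogenetic inference for tailed-bacteriophage portal
proteins — and for any other four-member family of homologous folds whose
sequences have diverged beyond recognition.

Portal proteins (the dodecameric DNA-translocation vertex of phages such as
T4, SPP1, P22 and φ29) share a conserved clip–stem–wing fold but show no
detectable sequence similarity. When sequences cannot be aligned, the
evolutionary separation between two structures can still be measured
structurally: superimpose the monomers, count the Cα atoms *r* that can be
equivalenced within a distance cutoff, and convert that count into an
evolutionary distance. `portalphylo` implements this pipeline end to end:

1. **Cα extraction** (`portalphylo.structures`) — PDB/mmCIF → ordered Cα
   traces, with residue-range masks (e.g. excluding the crown domain, whose
   orientation varies between assemblies).
2. **Iterative equivalencing** (`portalphylo.superpose`) — sequence-independent
   pairwise alignment: best window seed → alternate Kabsch superposition and
   maximal order-preserving pairing with all separations ≤ cutoff
   (default 3.8 Å). Yields *r*, RMSD and per-pair separations.
3. **Similarity statistics** (`portalphylo.similarity`) — percent identity of
   equivalenced residues and the *minimum base change per codon* (MBC): the
   fewest nucleotide substitutions connecting some codon of one residue to
   some codon of the other, plus the MBC-vs-separation trend.
4. **Tree inference** (`portalphylo.trees`) — distances
   `d = P − r` or `d = 100·P/r` (P ≈ residue count of a functioning portal,
   default 600); exhaustive enumeration of all 15 rooted 4-taxon tree
   varieties (3 balanced + 12 caterpillar after symmetry reduction); for each
   variety a linear least-squares fit of branch lengths *a–f* and
   root-to-leaf distance *g* over 10 observational equations — six pairwise
   path sums `d(X,Y) = Σ branches on the X–Y path` and four molecular-clock
   constraints `(root-to-leaf sum) = g`; ranking by the R factor
   `R = Σ|obs − calc| / Σ obs` over the six pairwise distances, with trees
   requiring negative branch lengths flagged infeasible. `R_all` uses the
   clock-constrained fit, `R_pair` the unconstrained 6-equation fit.
5. **Synthetic data** (`portalphylo.synthetic`) — distances from known rooted
   trees (± noise) and Cα families with a known conserved core, so every
   stage is testable with ground truth and no downloads.

## Worked example

`python examples/rank_trees_from_distances.py` generates clock-like
distances from a known tree `(((SPP1,T4),P22),phi29)` with 2% noise and
ranks all 15 varieties:

```
 rank variety_id             arrangement  r_all  r_pair  feasible
    1        2.7 (((SPP1,T4),P22),phi29) 0.0033  0.0028      True
    2        1.3 ((P22,phi29),(SPP1,T4)) 0.0546  0.0028     False
    3        2.8 (((SPP1,T4),phi29),P22) 0.0572  0.0028     False
    ...
best tree Newick: (((SPP1:57.4,T4:56.9):72.6,P22:131.2):77.9,phi29:208.2);
```

The generating arrangement ranks first with the smallest R factor, and every
arrangement that forces a wrong grouping needs at least one negative branch
length (`feasible = False`). Other examples: `align_synthetic_family.py`
(iterative equivalencing with ground truth, identity and MBC trend),
`distance_schemes.py` (robustness of the ranking to the distance scheme and
to P), `real_portals.py` (running the full pipeline on user-downloaded
portal coordinates, crown domains masked).

A thin CLI mirrors the library: `portalphylo align|distances|trees|simulate|run`
(see `portalphylo --help`).

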
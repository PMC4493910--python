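"""Rank all 15 rooted 4-taxon tree varieties against known distances.

Generates clock-like distances from a known caterpillar tree with 2% noise,
then fits every variety by constrained least squares and prints the ranking.
The R factor (Σ|obs−calc|/Σobs over the six pairwise distances) measures how
well each tree reproduces the observations; a feasible tree has no negative
fitted branch length.
"""
import numpy as np

from portalphylo import (
    SyntheticTreeSpec,
    distances_from_tree,
    rank_trees,
    ranking_table,
    to_newick,
    ultrametric_branches,
)

spec = SyntheticTreeSpec(
    shape="caterpillar",
    leaves=("T4", "SPP1", "P22", "phi29"),
    branches=ultrametric_branches("caterpillar", (60.0, 130.0, 210.0)),
    noise_sigma=0.02,
    seed=7,
)
D, truth = distances_from_tree(spec)

print("observed distances (clock-like, 2% noise):")
print(np.array_str(D.d, precision=1), "\n")

fits = rank_trees(D)
cols = ["rank", "variety_id", "arrangement", "r_all", "r_pair", "feasible"]
print(ranking_table(fits)[cols].to_string(index=False,
                                          float_format=lambda v: f"{v:.4f}"))
print(f"\ntrue tree: {spec.shape} {truth.canonical_leaves}")
print(f"best tree Newick: {to_newick(fits[0])}")
print("\nThe generating arrangement should rank first with the smallest "
      "R factor; trees forcing the wrong grouping need negative branch "
      "lengths and are flagged infeasible.")
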
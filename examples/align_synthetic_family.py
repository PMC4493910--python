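"""Structurally align two synthetic chains sharing a conserved core.

Builds a two-chain family with a 60-residue common core (perturbed by 0.3 Å
per taxon) inside unrelated flanks, runs the iterative Cα equivalencing and
prints r, RMSD, sequence identity and the chemical-similarity trend.
"""
from portalphylo import (
    SyntheticFamilySpec,
    ca_family,
    iterative_equivalence,
    mbc_vs_separation,
    mean_mbc,
    percent_identity,
)

spec = SyntheticFamilySpec(
    labels=("A", "B"),
    core_length=60,
    core_noise={"A": 0.3, "B": 0.3},
    identity_lambda=2.0,
    seed=0,
)
fam = ca_family(spec)
a, b = fam.chains["A"], fam.chains["B"]

eq = iterative_equivalence(a, b, cutoff=3.8)
true_pairs = set(fam.core_pairs("A", "B"))
precision = 100.0 * sum(p in true_pairs for p in eq.pairs) / eq.r

print(f"chains: {len(a)} and {len(b)} residues, shared core of "
      f"{spec.core_length}")
print(f"r = {eq.r} equivalenced Cα pairs "
      f"(RMSD {eq.superposition.rmsd:.2f} Å, {eq.n_iterations} iterations)")
print(f"{precision:.1f}% of returned pairs are true core pairs")
print(f"sequence identity over aligned pairs: "
      f"{percent_identity(eq, a, b):.1f}%")
print(f"mean minimum base change per codon: {mean_mbc(eq, a, b):.2f}\n")
print("mean MBC by Cα separation (closer pairs are more conserved):")
print(mbc_vs_separation(eq, a, b).to_string(index=False))
print("\nr measures the size of the common rigid core — the raw input to "
      "the evolutionary-distance schemes.")
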
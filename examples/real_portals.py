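"""Four-taxon portal phylogeny from deposited coordinates (user-supplied).

The monomer structures of the phi29, SPP1 and P22 portal proteins are in the
PDB under accessions 1FOU, 2JES and 3LJ4; the T4 portal (gp20) coordinates
must also be supplied by the user.  Download the four files into a directory
and point this script at it:

    python examples/real_portals.py /path/to/pdbs

Crown domains are excluded from the structural comparison via residue-range
masks (the crown orientation varies between assemblies; e.g. residues
451-524 in T4 — adjust the other masks to the deposited numbering you use).
Expect structurally aligned sequence identities of ~10% or less for every
pair, and a cutoff sweep bracketing the equivalenced-residue counts.
"""
import itertools
import sys
from pathlib import Path

from portalphylo import (
    DomainMask,
    apply_mask,
    distance_matrix_from_alignments,
    iterative_equivalence,
    percent_identity,
    rank_trees,
    ranking_table,
    read_ca_chain,
)

FILES = {           # label -> (file name, chain)
    "phi29": ("1fou.pdb", "A"),
    "SPP1": ("2jes.pdb", "A"),
    "P22": ("3lj4.pdb", "A"),
    "T4": ("t4_gp20.pdb", "A"),
}
CROWN_MASKS = {     # author-numbered crown ranges to exclude; edit as needed
    "T4": DomainMask.excluding(451, 524),
}

root = Path(sys.argv[1]) if len(sys.argv) > 1 else Path(".")
missing = [f for f, _ in FILES.values() if not (root / f).exists()]
if missing:
    sys.exit(f"coordinate files not found in {root}: {', '.join(missing)}\n"
             "Download them first; see the module docstring.")

chains = {}
for label, (fname, chain_id) in FILES.items():
    chain = read_ca_chain(root / fname, chain_id)
    if label in CROWN_MASKS:
        chain = apply_mask(chain, CROWN_MASKS[label])
    chains[label] = chain
    print(f"{label}: {len(chain)} Cα residues after masking")

for cutoff in (3.0, 3.8, 4.5):
    equivs = {}
    print(f"\ncutoff {cutoff} Å:")
    for t1, t2 in itertools.combinations(sorted(chains), 2):
        eq = iterative_equivalence(chains[t1], chains[t2], cutoff=cutoff)
        equivs[frozenset((t1, t2))] = eq
        pid = percent_identity(eq, chains[t1], chains[t2])
        print(f"  {t1}-{t2}: r = {eq.r}, identity {pid:.1f}%")
    D = distance_matrix_from_alignments(equivs, P=600, scheme="ratio")
    fits = rank_trees(D)
    print(ranking_table(fits).head(3)[
        ["variety_id", "arrangement", "r_all", "feasible"]
    ].to_string(index=False))
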
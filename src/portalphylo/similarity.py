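"""Chemical-similarity statistics over structurally equivalenced residues.

Portal proteins from different phages have no detectable sequence similarity,
so residue-level conservation is assessed *after* structural alignment:

* percent identity of the equivalenced residue pairs;
* minimum base change per codon (MBC) — the smallest number of nucleotide
  substitutions converting some codon of one amino acid into some codon of
  the other under the standard genetic code.  MBC of 0 means identical
  residues; the genetic code caps it at 3.  Averaged over aligned pairs it is
  a chemical-similarity proxy that does not require a substitution matrix.
* the MBC-vs-Cα-separation trend: pairs binned by post-superposition Cα
  separation, mean MBC per bin.  Closely superimposed residues are expected
  to be the most conserved.

The codon table is the standard genetic code (61 coding codons) taken from
Biopython; the MBC matrix is generated from it by enumeration, never typed in.
"""
from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .structures import CaChain
from .superpose import EquivalenceSet

AMINO_ACIDS = tuple(sorted(set(standard_dna_table.forward_table.values())))


@lru_cache(maxsize=1)
def codons_by_aa() -> dict[str, tuple[str, ...]]:
    """Coding codons of each standard amino acid (stop codons excluded)."""
    table: dict[str, list[str]] = {aa: [] for aa in AMINO_ACIDS}
    for codon, aa in standard_dna_table.forward_table.items():
        table[aa].append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in table.items()}


def min_base_change(aa1: str, aa2: str) -> int:
    """Minimum Hamming distance between any codon of aa1 and any codon of aa2."""
    for aa in (aa1, aa2):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"not a standard amino acid: {aa!r}")
    m = mbc_matrix()
    return int(m.loc[aa1, aa2])


@lru_cache(maxsize=1)
def _mbc_array() -> np.ndarray:
    table = codons_by_aa()
    n = len(AMINO_ACIDS)
    m = np.zeros((n, n), dtype=int)
    for i, a1 in enumerate(AMINO_ACIDS):
        for j, a2 in enumerate(AMINO_ACIDS):
            if j < i:
                continue
            best = min(
                sum(x != y for x, y in zip(c1, c2))
                for c1, c2 in product(table[a1], table[a2])
            )
            m[i, j] = m[j, i] = best
    return m


def mbc_matrix() -> pd.DataFrame:
    """20×20 minimum-base-change matrix, generated from the genetic code."""
    return pd.DataFrame(_mbc_array(), index=AMINO_ACIDS, columns=AMINO_ACIDS)


def _aligned_residues(equiv: EquivalenceSet, a: CaChain, b: CaChain):
    for ia, ib in equiv.pairs:
        if ia >= len(a) or ib >= len(b):
            raise IndexError(
                f"equivalence pair ({ia}, {ib}) out of range for chains of "
                f"length {len(a)}, {len(b)}"
            )
        yield a.residues[ia].aa, b.residues[ib].aa


def percent_identity(equiv: EquivalenceSet, a: CaChain, b: CaChain) -> float:
    """100 × (identical residue pairs among equivalenced pairs) / r."""
    if equiv.r == 0:
        raise ValueError("empty equivalence set: percent identity undefined")
    matches = sum(aa1 == aa2 for aa1, aa2 in _aligned_residues(equiv, a, b))
    return 100.0 * matches / equiv.r


def mean_mbc(equiv: EquivalenceSet, a: CaChain, b: CaChain) -> float:
    """Average minimum base change per codon over equivalenced pairs.

    Pairs involving a non-standard residue ('X') are skipped.
    """
    vals = [
        min_base_change(aa1, aa2)
        for aa1, aa2 in _aligned_residues(equiv, a, b)
        if aa1 in AMINO_ACIDS and aa2 in AMINO_ACIDS
    ]
    if not vals:
        raise ValueError("no standard-residue pairs to average")
    return float(np.mean(vals))


DEFAULT_BIN_EDGES = (0.0, 1.0, 2.0, 3.0, 3.8)


def mbc_vs_separation(
    equiv: EquivalenceSet,
    a: CaChain,
    b: CaChain,
    bin_edges=DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Mean MBC of equivalenced pairs binned by Cα separation.

    Bins are [edge_k, edge_{k+1}) with the last bin closed on the right.
    Empty bins are reported with n = 0 and a missing mean.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be a strictly increasing 1-D sequence")
    aas = list(_aligned_residues(equiv, a, b))
    seps = np.asarray(equiv.separations, dtype=float)
    mbc = np.array([
        min_base_change(x, y) if x in AMINO_ACIDS and y in AMINO_ACIDS else -1
        for x, y in aas
    ])
    valid = mbc >= 0
    idx = np.digitize(seps, edges, right=False) - 1
    idx[seps == edges[-1]] = len(edges) - 2  # last bin closed on the right
    rows = []
    for k in range(len(edges) - 1):
        sel = valid & (idx == k)
        n = int(sel.sum())
        rows.append({
            "bin_low": edges[k],
            "bin_high": edges[k + 1],
            "n": n,
            "mean_mbc": float(mbc[sel].mean()) if n else np.nan,
        })
    return pd.DataFrame(rows)
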
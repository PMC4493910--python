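"""Coordinate-file handling: Cα trace extraction and residue-range masks.

Structural comparison of portal monomers works on the ordered Cα trace of a
single chain.  This module turns a PDB or mmCIF file into a :class:`CaChain`
(one entry per residue that has a Cα atom, in author numbering) and applies
:class:`DomainMask` range selections such as the crown-domain exclusion used
when measuring structural distances.

Parsing is delegated to :mod:`gemmi`; this module only decides which atoms
count as the trace (altloc resolution, non-standard residues, missing Cα).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Cα–Cα distance band outside which a chain break / geometry warning is logged.
CA_CA_MIN = 2.0
CA_CA_MAX = 5.0


class StructureError(ValueError):
    """Base class for coordinate-extraction failures."""


class UnknownChainError(StructureError):
    pass


class EmptyChainError(StructureError):
    pass


@dataclass(frozen=True)
class Residue:
    """One residue of a Cα trace.

    ``seq_position`` is the author residue number; ``icode`` keeps insertion
    codes as distinct positions ordered after their base number.  ``aa`` is a
    one-letter code, with non-standard residues (e.g. MSE) mapped to their
    parent amino acid and unknowns to ``'X'``.
    """

    chain_label: str
    seq_position: int
    aa: str
    ca_xyz: tuple[float, float, float]
    icode: str = ""

    def __post_init__(self) -> None:
        if self.aa not in _STANDARD_AA and self.aa != "X":
            raise ValueError(f"invalid one-letter code {self.aa!r}")
        if not all(math.isfinite(c) for c in self.ca_xyz):
            raise ValueError(f"non-finite Cα coordinate for residue {self.seq_position}")

    @property
    def order_key(self) -> tuple[int, str]:
        return (self.seq_position, self.icode)


@dataclass
class CaChain:
    """Ordered Cα trace of one monomer."""

    residues: list[Residue]
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 3:
            raise StructureError(
                f"chain {self.source_id!r} has {len(self.residues)} Cα residues; need ≥ 3"
            )
        keys = [r.order_key for r in self.residues]
        if any(k2 <= k1 for k1, k2 in zip(keys, keys[1:])):
            raise StructureError(
                f"residue numbering not strictly increasing in {self.source_id!r}"
            )
        self._warn_geometry()

    def _warn_geometry(self) -> None:
        xyz = self.coords
        d = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        bad = np.sum((d < CA_CA_MIN) | (d > CA_CA_MAX))
        if bad:
            logger.warning(
                "%s: %d consecutive Cα–Cα distances outside [%.1f, %.1f] Å "
                "(chain breaks allowed; order kept as deposited)",
                self.source_id or "chain", bad, CA_CA_MIN, CA_CA_MAX,
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of Cα coordinates in Å."""
        return np.array([r.ca_xyz for r in self.residues], dtype=float)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def seq_positions(self) -> list[int]:
        return [r.seq_position for r in self.residues]


@dataclass(frozen=True)
class DomainMask:
    """Inclusive author-numbering residue ranges to retain.

    Masks select what stays, e.g. everything outside the crown domain; ranges
    are inclusive on both ends, non-overlapping and sorted.
    """

    include_ranges: tuple[tuple[int, int], ...]

    def __init__(self, include_ranges: Iterable[Sequence[int]]):
        ranges = tuple((int(a), int(b)) for a, b in include_ranges)
        for a, b in ranges:
            if a > b:
                raise ValueError(f"mask range [{a}, {b}] has start > end")
        for (_, b1), (a2, _) in zip(ranges, ranges[1:]):
            if a2 <= b1:
                raise ValueError("mask ranges must be sorted and non-overlapping")
        object.__setattr__(self, "include_ranges", ranges)

    def contains(self, seq_position: int) -> bool:
        return any(a <= seq_position <= b for a, b in self.include_ranges)

    @classmethod
    def excluding(cls, start: int, end: int, lo: int = -9999, hi: int = 99999) -> "DomainMask":
        """Mask keeping everything except [start, end] (e.g. a crown domain)."""
        ranges = []
        if start > lo:
            ranges.append((lo, start - 1))
        if end < hi:
            ranges.append((end + 1, hi))
        return cls(ranges)


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code in _STANDARD_AA:
            return code
    return "X"


def _pick_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Cα of a residue, resolving altlocs: highest occupancy, then first alphabetically."""
    cas = [a for a in residue if a.name == "CA" and a.element.name != "Ca"]
    if not cas:
        return None
    return min(cas, key=lambda a: (-a.occ, a.altloc))


def read_ca_chain(path: str | Path, chain: str, model_index: int = 0) -> CaChain:
    """Extract the Cα trace of one chain from a PDB or mmCIF file.

    Residues without a Cα atom are skipped (count logged); altlocs resolve to
    the highest-occupancy conformer.  ``model_index`` selects the model
    (default: first, as deposited).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"coordinate file not found: {path}")
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    if model_index >= len(structure):
        raise StructureError(
            f"model index {model_index} out of range for {path.name} "
            f"({len(structure)} model(s))"
        )
    model = structure[model_index]
    gchain = model.find_chain(chain)
    if gchain is None:
        available = ", ".join(c.name for c in model) or "none"
        raise UnknownChainError(
            f"chain {chain!r} not found in {path.name} model {model_index} "
            f"(available: {available})"
        )
    residues: list[Residue] = []
    skipped = 0
    for res in gchain:
        ca = _pick_ca(res)
        if ca is None:
            if gemmi.find_tabulated_residue(res.name) is not None and \
                    gemmi.find_tabulated_residue(res.name).is_amino_acid():
                skipped += 1
            continue
        residues.append(
            Residue(
                chain_label=chain,
                seq_position=res.seqid.num,
                aa=_one_letter(res.name),
                ca_xyz=(ca.pos.x, ca.pos.y, ca.pos.z),
                icode=res.seqid.icode.strip(),
            )
        )
    if skipped:
        logger.info("%s chain %s: skipped %d amino-acid residues lacking Cα",
                    path.name, chain, skipped)
    if not residues:
        raise EmptyChainError(f"chain {chain!r} of {path.name} contains no Cα atoms")
    return CaChain(residues, source_id=f"{path.name}:{chain}:{model_index}")


def apply_mask(chain: CaChain, mask: DomainMask) -> CaChain:
    """Retain exactly the residues whose author number falls in an include range."""
    kept = [r for r in chain.residues if mask.contains(r.seq_position)]
    if not kept:
        raise StructureError(f"mask removes all residues of {chain.source_id!r}")
    return CaChain(kept, source_id=chain.source_id)


def write_tsv(chain: CaChain, path: str | Path) -> None:
    """Plain TSV dump (seq_position, aa, x, y, z) for debugging."""
    with open(path, "w") as fh:
        fh.write("seq_position\taa\tx\ty\tz\n")
        for r in chain.residues:
            x, y, z = r.ca_xyz
            fh.write(f"{r.seq_position}{r.icode}\t{r.aa}\t{x:.3f}\t{y:.3f}\t{z:.3f}\n")


_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def write_pdb(chains: Sequence[CaChain], path: str | Path,
              chain_ids: Sequence[str] | None = None) -> None:
    """Write Cα-only chains as a PDB file (one model, one chain per CaChain)."""
    st = gemmi.Structure()
    st.name = "portalphylo"
    model = gemmi.Model("1")
    if chain_ids is None:
        chain_ids = [chr(ord("A") + i) for i in range(len(chains))]
    for cid, chain in zip(chain_ids, chains):
        gch = gemmi.Chain(cid)
        for r in chain.residues:
            gres = gemmi.Residue()
            gres.name = _AA3[r.aa]
            gres.seqid = gemmi.SeqId(r.seq_position, r.icode or " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*r.ca_xyz)
            atom.occ = 1.0
            gres.add_atom(atom)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
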
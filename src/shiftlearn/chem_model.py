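"""Molecular graphs with explicit hydrogens and proton equivalence classes.

Molecules enter as MDL V2000 molfile/SDF records and are held as RDKit
graphs behind a light :class:`Molecule` wrapper.  Proton equivalence is
constitutional (graph-automorphism) equivalence of the labelled graph:
two hydrogens belong to the same class iff some automorphism maps one to
the other, which is what makes them contribute to the same NMR signal.
Stereochemistry and diastereotopicity are deliberately ignored — the
fragment codes used downstream are constitution-only.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from rdkit import Chem, RDLogger
from rdkit.Chem import rdchem

RDLogger.DisableLog("rdApp.*")

#: Heavy elements whose attached protons are treated as labile (exchangeable).
LABILE_NEIGHBOURS = frozenset({"O", "N", "S"})

_BOND_SYMBOL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


class MoleculeParseError(ValueError):
    """A molfile record could not be parsed."""


class ValenceError(ValueError):
    """An atom's existing bonds exceed its allowed valence."""


@dataclass(frozen=True)
class AtomInfo:
    symbol: str
    charge: int


@dataclass(frozen=True)
class BondInfo:
    a: int
    b: int
    order: str  # one of "-", "=", "#", ":"


@dataclass(frozen=True)
class ProtonClass:
    """A set of symmetry-equivalent hydrogens (one NMR signal)."""

    members: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def representative(self) -> int:
        """Smallest member atom index; used wherever one proton stands for the class."""
        return self.members[0]


class Molecule:
    """A connected molecular graph, optionally hydrogen-complete."""

    def __init__(self, rdmol: Chem.Mol, id: str, hydrogen_complete: bool = False):
        self._rdmol = rdmol
        self.id = id
        self.hydrogen_complete = hydrogen_complete

    # -- container views ------------------------------------------------
    @property
    def rdkit(self) -> Chem.Mol:
        return self._rdmol

    @property
    def atoms(self) -> list[AtomInfo]:
        return [
            AtomInfo(a.GetSymbol(), a.GetFormalCharge()) for a in self._rdmol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[BondInfo]:
        return [
            BondInfo(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_SYMBOL[b.GetBondType()])
            for b in self._rdmol.GetBonds()
        ]

    @property
    def num_atoms(self) -> int:
        return self._rdmol.GetNumAtoms()

    @property
    def num_hydrogens(self) -> int:
        return sum(1 for a in self._rdmol.GetAtoms() if a.GetAtomicNum() == 1)

    @property
    def hydrogen_indices(self) -> list[int]:
        return [a.GetIdx() for a in self._rdmol.GetAtoms() if a.GetAtomicNum() == 1]

    def is_hydrogen(self, idx: int) -> bool:
        return self._rdmol.GetAtomWithIdx(idx).GetAtomicNum() == 1

    # -- constructors / exports ----------------------------------------
    @classmethod
    def from_smiles(cls, smiles: str, id: str | None = None) -> "Molecule":
        """Build a hydrogen-complete molecule from a SMILES string."""
        rdmol = Chem.MolFromSmiles(smiles)
        if rdmol is None:
            raise MoleculeParseError(f"invalid SMILES: {smiles!r}")
        rdmol = Chem.AddHs(rdmol)
        return cls(rdmol, id if id is not None else smiles, hydrogen_complete=True)

    def to_molblock(self) -> str:
        mol = Chem.Mol(self._rdmol)
        mol.SetProp("_Name", self.id)
        return Chem.MolToMolBlock(mol, kekulize=True)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Molecule({self.id!r}, atoms={self.num_atoms}, H={self.num_hydrogens})"


def read_sdf(path: str | Path) -> list[Molecule]:
    """Read all V2000 molfile records of an SDF file.

    Hydrogen counts are *not* completed here; call :func:`complete_hydrogens`
    on each record before computing classes or fragment codes.  Disconnected
    records (salts, solvates) are reduced to their largest connected
    component with a warning.  V3000 records are rejected.
    """
    text = Path(path).read_text()
    records: list[str] = []
    current: list[str] = []
    for line in text.splitlines():
        if line.startswith("$$$$"):
            records.append("\n".join(current))
            current = []
        else:
            current.append(line)
    if any(l.strip() for l in current):
        records.append("\n".join(current))

    molecules: list[Molecule] = []
    for i, block in enumerate(records, start=1):
        if not block.strip():
            continue
        head = block.splitlines()[:4]
        if any("V3000" in l for l in head):
            raise MoleculeParseError(f"record {i}: V3000 molfiles are not supported")
        rdmol = Chem.MolFromMolBlock(block, sanitize=False, removeHs=False)
        if rdmol is None:
            raise MoleculeParseError(f"record {i}: malformed molfile record")
        name = block.splitlines()[0].strip() if block.splitlines() else ""
        mol_id = name or f"record-{i}"
        frags = Chem.GetMolFrags(rdmol)
        if len(frags) > 1:
            warnings.warn(
                f"record {i} ({mol_id}): disconnected record, keeping largest component",
                stacklevel=2,
            )
            frag_mols = Chem.GetMolFrags(rdmol, asMols=True, sanitizeFrags=False)
            rdmol = max(frag_mols, key=lambda m: m.GetNumAtoms())
        molecules.append(Molecule(rdmol, mol_id))
    return molecules


def complete_hydrogens(molecule: Molecule) -> Molecule:
    """Return a copy with explicit hydrogens filling every standard valence.

    Heavy atoms are completed to their default charge-adjusted valence
    (C:4, N:3, O:2, S per existing bonds, halogens:1); hydrogens already
    explicit in the record are preserved, so the operation is idempotent
    and never renumbers existing atoms.
    """
    mol = Chem.Mol(molecule.rdkit)
    try:
        mol.UpdatePropertyCache(strict=True)
        Chem.SanitizeMol(mol)
    except rdchem.MolSanitizeException as exc:
        raise ValenceError(f"{molecule.id}: {exc}") from exc
    with_h = Chem.AddHs(mol)
    return Molecule(with_h, molecule.id, hydrogen_complete=True)


def proton_classes(molecule: Molecule, exclude_labile: bool = False) -> list[ProtonClass]:
    """Partition the hydrogens into symmetry-equivalence classes.

    Equivalence is computed by iterative neighbourhood-label (Morgan-style)
    refinement via RDKit's canonical ranking with tie-breaking disabled, so
    the partition is invariant under any permutation of the input atom
    order.  Classes are returned sorted by their smallest member index.

    With ``exclude_labile`` set, hydrogens bound to O/N/S are dropped from
    the partition (exchangeable protons carry unreliable shifts).
    """
    if not molecule.hydrogen_complete:
        raise ValueError("proton_classes requires a hydrogen-complete molecule")
    mol = molecule.rdkit
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False, includeChirality=False))
    groups: dict[int, list[int]] = {}
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 1:
            continue
        if exclude_labile:
            heavy = [n for n in atom.GetNeighbors() if n.GetAtomicNum() != 1]
            if heavy and heavy[0].GetSymbol() in LABILE_NEIGHBOURS:
                continue
        groups.setdefault(ranks[atom.GetIdx()], []).append(atom.GetIdx())
    classes = [ProtonClass(tuple(sorted(m))) for m in groups.values()]
    classes.sort(key=lambda c: c.members[0])
    return classes


def graph_diameter(molecule: Molecule) -> int:
    """Longest shortest-path bond distance between any two atoms."""
    mol = molecule.rdkit
    n = mol.GetNumAtoms()
    adj = [[n.GetIdx() for n in mol.GetAtomWithIdx(i).GetNeighbors()] for i in range(n)]
    diameter = 0
    for start in range(n):
        dist = {start: 0}
        frontier = [start]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        diameter = max(diameter, max(dist.values()))
    return diameter
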
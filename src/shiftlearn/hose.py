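"""Spherical environment extraction and canonical fragment codes.

The environment of a proton is the substructure spanned by all atoms up to
``r`` bonds from it (its *n-sphere*); ``r = 1`` is the heavy atom the proton
is bonded to.  Environments are serialised as canonical strings in the
spirit of HOSE codes.  The dialect is this package's own and is only
required to be internally consistent — the shift database is always built
and queried with the same encoder:

* atoms are encoded on the heavy-atom skeleton; attached hydrogens appear
  as ``H<n>`` counts on heavy atoms, never as shell members.  A count is
  emitted only for atoms at depth < r, since a hydrogen on a depth-r atom
  lies r+1 bonds from the proton, outside the sphere;
* bond symbols are ``-`` ``=`` ``#`` and ``:`` (aromatic); a branch closing
  a ring onto an atom already on the path is encoded as ``<bond>&``;
* at every atom the branches are ordered by the lexicographic order of
  their complete sub-codes, which makes the string independent of atom
  input order and equal for symmetry-equivalent protons.
"""
from __future__ import annotations

from dataclasses import dataclass

from .chem_model import Molecule, _BOND_SYMBOL


@dataclass(frozen=True)
class HoseCode:
    code: str
    radius: int


@dataclass(frozen=True)
class Fragment:
    """Shell-wise view of a proton's n-sphere (heavy atoms only)."""

    center: int
    radius: int
    shells: tuple[tuple[int, ...], ...]  # shells[d-1] = atoms at bond distance d

    @property
    def atom_set(self) -> frozenset[int]:
        return frozenset(a for shell in self.shells for a in shell)


def _require_proton(molecule: Molecule, proton: int) -> None:
    if not molecule.hydrogen_complete:
        raise ValueError("fragment extraction requires a hydrogen-complete molecule")
    if not molecule.is_hydrogen(proton):
        raise ValueError(f"atom {proton} is not a hydrogen")


def n_sphere(molecule: Molecule, proton: int, r: int) -> Fragment:
    """Breadth-first shells of heavy atoms at bond distance 1..r from the proton."""
    _require_proton(molecule, proton)
    if r < 1:
        raise ValueError("radius must be >= 1")
    mol = molecule.rdkit
    dist: dict[int, int] = {}
    frontier = [
        n.GetIdx()
        for n in mol.GetAtomWithIdx(proton).GetNeighbors()
        if n.GetAtomicNum() != 1
    ]
    for idx in frontier:
        dist[idx] = 1
    d = 1
    while frontier and d < r:
        nxt = []
        for u in frontier:
            for nb in mol.GetAtomWithIdx(u).GetNeighbors():
                v = nb.GetIdx()
                if nb.GetAtomicNum() == 1 or v in dist:
                    continue
                dist[v] = d + 1
                nxt.append(v)
        frontier = nxt
        d += 1
    shells = tuple(
        tuple(sorted(i for i, dd in dist.items() if dd == d)) for d in range(1, r + 1)
    )
    return Fragment(center=proton, radius=r, shells=shells)


def _atom_token(mol, idx: int, include_h: bool, center: int) -> str:
    atom = mol.GetAtomWithIdx(idx)
    token = atom.GetSymbol()
    charge = atom.GetFormalCharge()
    if charge:
        token += f"{charge:+d}"
    if include_h:
        n_h = sum(
            1
            for nb in atom.GetNeighbors()
            if nb.GetAtomicNum() == 1 and nb.GetIdx() != center
        )
        if n_h:
            token += f"H{n_h}"
    return token


def _encode_from(mol, idx: int, parent: int | None, depth: int, r: int,
                 path: frozenset[int], center: int) -> str:
    token = _atom_token(mol, idx, depth < r, center)
    if depth == r:
        return token
    branches: list[str] = []
    for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
        j = nb.GetIdx()
        if nb.GetAtomicNum() == 1 or j == parent:
            continue
        bond = _BOND_SYMBOL[mol.GetBondBetweenAtoms(idx, j).GetBondType()]
        if j in path:  # ring closure onto an ancestor
            branches.append(bond + "&")
        else:
            branches.append(
                bond + _encode_from(mol, j, idx, depth + 1, r, path | {j}, center)
            )
    if branches:
        token += "(" + ",".join(sorted(branches)) + ")"
    return token


def encode(molecule: Molecule, proton: int, r: int) -> HoseCode:
    """Canonical code of the radius-``r`` environment of ``proton``.

    Deterministic: the same molecule, proton and radius always yield a
    byte-identical string, regardless of atom numbering, and protons in the
    same symmetry class yield equal codes at every radius.
    """
    _require_proton(molecule, proton)
    if r < 1:
        raise ValueError("radius must be >= 1")
    mol = molecule.rdkit
    heavy = [n.GetIdx() for n in mol.GetAtomWithIdx(proton).GetNeighbors()
             if n.GetAtomicNum() != 1]
    if not heavy:
        # a bare proton (e.g. H2); encode its hydrogen neighbourhood trivially
        return HoseCode("", r)
    root = heavy[0]
    code = _encode_from(mol, root, None, 1, r, frozenset({root}), proton)
    return HoseCode(code, r)


def encode_all_radii(molecule: Molecule, proton: int, r_min: int, r_max: int) -> list[HoseCode]:
    """Codes for every radius ``r_min..r_max`` inclusive, ascending."""
    if not (1 <= r_min <= r_max):
        raise ValueError("require 1 <= r_min <= r_max")
    return [encode(molecule, proton, r) for r in range(r_min, r_max + 1)]
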
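"""Desk-scale synthetic corpora with the statistics the learning loop assumes.

Nature is emulated by a *shift rule*: the true chemical shift of a proton
class is a fixed function of its radius-2 environment code plus a small
Gaussian perturbation, one draw per class per molecule (equivalent protons
share one signal by construction).  Peak lists carry integrals equal to
class sizes, with close-lying signals merged at their integral-weighted
mean position.  Because truth lives at radius 2, a predictor with
``r_min = 2`` is asymptotically unbiased on these corpora and its error
should approach the noise floor as learning proceeds.

Molecules are grown from a small fragment grammar — alkyl/ether/amine
growth plus six-membered aromatic rings — deterministic under a fixed seed.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from . import hose
from .chem_model import Molecule, ProtonClass, proton_classes

_VALENCE = {"C": 4, "N": 3, "O": 2}


class GenerationError(ValueError):
    """The grammar requested something chemically impossible."""


@dataclass(frozen=True)
class FragmentGrammar:
    """Growable-fragment alphabet for the molecule generator.

    ``element_weights`` govern single-atom growth steps; ``ring_weight`` is
    the relative weight of attaching a benzene ring (six heavy atoms at
    once).  Heteroatoms bond only to carbon, which keeps the output within
    ordinary organic chemistry.
    """

    element_weights: tuple[tuple[str, float], ...] = (("C", 0.60), ("O", 0.20), ("N", 0.20))
    ring_weight: float = 0.20

    def __post_init__(self) -> None:
        for symbol, weight in self.element_weights:
            if symbol not in _VALENCE:
                raise GenerationError(f"element {symbol!r} has no valence rule")
            if weight < 0:
                raise GenerationError("weights must be non-negative")


DEFAULT_GRAMMAR = FragmentGrammar()


def _grow_one(rng: np.random.Generator, target: int, grammar: FragmentGrammar) -> Chem.Mol:
    mol = Chem.RWMol()
    free: list[int] = []  # free single-bond slots per atom

    def add_atom(symbol: str, valence_used: int) -> int:
        idx = mol.AddAtom(Chem.Atom(symbol))
        free.append(_VALENCE[symbol] - valence_used)
        return idx

    def add_ring(site: int) -> None:
        ring = [mol.AddAtom(Chem.Atom("C")) for _ in range(6)]
        free.extend([1] * 6)
        for k in range(6):  # Kekulé alternation; aromaticity perceived at sanitise
            order = Chem.BondType.DOUBLE if k % 2 else Chem.BondType.SINGLE
            mol.AddBond(ring[k], ring[(k + 1) % 6], order)
        mol.AddBond(site, ring[0], Chem.BondType.SINGLE)
        free[site] -= 1
        free[ring[0]] -= 1

    add_atom("C", 0)
    symbols = [s for s, _ in grammar.element_weights]
    weights = np.array([w for _, w in grammar.element_weights], dtype=float)
    while mol.GetNumAtoms() < target:
        sites = [i for i in range(mol.GetNumAtoms()) if free[i] > 0]
        if not sites:
            break
        site = int(rng.choice(sites))
        room = target - mol.GetNumAtoms()
        ring_ok = room >= 6 and grammar.ring_weight > 0
        p_ring = grammar.ring_weight / (grammar.ring_weight + weights.sum()) if ring_ok else 0.0
        if rng.random() < p_ring:
            add_ring(site)
            continue
        if mol.GetAtomWithIdx(site).GetSymbol() != "C":
            symbol = "C"  # heteroatoms grow only carbon neighbours
        else:
            symbol = str(rng.choice(symbols, p=weights / weights.sum()))
        new = add_atom(symbol, 1)
        mol.AddBond(site, new, Chem.BondType.SINGLE)
        free[site] -= 1
    mol.UpdatePropertyCache(strict=True)
    Chem.SanitizeMol(mol)
    return Chem.AddHs(mol)


def gen_molecules(seed: int, count: int,
                  heavy_atom_range: tuple[int, int] = (2, 9),
                  grammar: FragmentGrammar = DEFAULT_GRAMMAR) -> list[Molecule]:
    """Grow ``count`` hydrogen-complete molecules, deterministic under ``seed``."""
    if count < 1:
        raise ValueError("count must be >= 1")
    lo, hi = heavy_atom_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid heavy-atom range")
    rng = np.random.default_rng(seed)
    molecules = []
    for i in range(count):
        target = int(rng.integers(lo, hi + 1))
        rdmol = _grow_one(rng, target, grammar)
        molecules.append(Molecule(rdmol, f"syn{i:04d}", hydrogen_complete=True))
    return molecules


@dataclass(frozen=True)
class ShiftRule:
    """Ground truth: radius-2 environment code -> base shift, plus noise."""

    lookup: dict[str, float]
    sigma: float = 0.05        # ppm, per-class Gaussian perturbation
    fallback: float = 5.0      # ppm, for codes outside the lookup
    seed: int = 0


def build_shift_rule(molecules: list[Molecule], seed: int = 0, sigma: float = 0.05,
                     shift_range: tuple[float, float] = (0.5, 9.5),
                     fallback: float = 5.0) -> ShiftRule:
    """Assign every radius-2 code seen in ``molecules`` a base shift.

    Base shifts are evenly spaced across ``shift_range`` and permuted by the
    seed, so distinct environments sit at well-separated positions that bear
    no relation to the lexicographic order of their codes.
    """
    codes = sorted({
        hose.encode(mol, cls.representative, 2).code
        for mol in molecules
        for cls in proton_classes(mol)
    })
    rng = np.random.default_rng(seed)
    k = len(codes)
    lo, hi = shift_range
    positions = np.linspace(lo, hi, k) if k > 1 else np.array([(lo + hi) / 2.0])
    rng.shuffle(positions)
    return ShiftRule(lookup=dict(zip(codes, positions.tolist())),
                     sigma=sigma, fallback=fallback, seed=seed)


def apply_shift_rule(rule: ShiftRule, molecule: Molecule) -> list[tuple[ProtonClass, float]]:
    """True dyads for one molecule: one noisy draw per proton class.

    The noise stream is derived from the rule seed and the molecule id, so
    dyads are reproducible and independent of corpus order.
    """
    classes = proton_classes(molecule)
    rng = np.random.default_rng([rule.seed, zlib.crc32(molecule.id.encode())])
    dyads = []
    for cls in classes:
        code = hose.encode(molecule, cls.representative, 2).code
        base = rule.lookup.get(code, rule.fallback)
        dyads.append((cls, float(base + rng.normal(0.0, rule.sigma)) if rule.sigma > 0
                      else float(base)))
    return dyads


def simulate_peaks(dyads: list[tuple[ProtonClass, float]],
                   merge_width: float = 0.02) -> list[tuple[float, float]]:
    """Peak list from true dyads; signals within ``merge_width`` coalesce.

    Merged peaks sit at the integral-weighted mean position and carry the
    summed class sizes, conserving the total integral.
    """
    if not dyads:
        raise ValueError("dyads must be non-empty")
    ordered = sorted(((shift, cls.size) for cls, shift in dyads))
    clusters: list[list[tuple[float, int]]] = [[ordered[0]]]
    for shift, size in ordered[1:]:
        if merge_width > 0 and shift - clusters[-1][-1][0] <= merge_width:
            clusters[-1].append((shift, size))
        else:
            clusters.append([(shift, size)])
    peaks = []
    for cluster in clusters:
        total = sum(size for _, size in cluster)
        position = sum(shift * size for shift, size in cluster) / total
        peaks.append((position, float(total)))
    return peaks


@dataclass
class SyntheticRecord:
    molecule: Molecule
    true_dyads: list[tuple[ProtonClass, float]]
    peaks: list[tuple[float, float]]

    @property
    def reference(self) -> dict[int, float]:
        """Reference dyads keyed by each class's representative proton."""
        return {cls.representative: shift for cls, shift in self.true_dyads}


def make_dataset(seed: int, count: int, sigma: float = 0.05,
                 heavy_atom_range: tuple[int, int] = (2, 9),
                 merge_width: float = 0.02,
                 grammar: FragmentGrammar = DEFAULT_GRAMMAR,
                 rule: ShiftRule | None = None,
                 ) -> tuple[list[SyntheticRecord], ShiftRule]:
    """Generate molecules, truth and peak lists in one call.

    When ``rule`` is given it is reused (so train and test sets can share
    one ground truth); otherwise a rule is built from the generated
    molecules themselves.
    """
    molecules = gen_molecules(seed, count, heavy_atom_range, grammar)
    if rule is None:
        rule = build_shift_rule(molecules, seed=seed, sigma=sigma)
    records = []
    for mol in molecules:
        dyads = apply_shift_rule(rule, mol)
        records.append(SyntheticRecord(mol, dyads, simulate_peaks(dyads, merge_width)))
    return records, rule


# -- on-disk interchange (same formats the main pipeline reads) ---------

def write_peak_table(peaks: list[tuple[float, float]], path: str | Path) -> None:
    pd.DataFrame(peaks, columns=["delta_ppm", "integral"]).to_csv(
        path, sep="\t", index=False)


def read_peak_table(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path, sep="\t")
    return [(float(r.delta_ppm), float(r.integral)) for r in df.itertuples(index=False)]


def write_corpus(records: list[SyntheticRecord], out_dir: str | Path) -> None:
    """SDF + per-molecule peak TSVs + reference-dyad TSV under ``out_dir``."""
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    with open(out / "molecules.sdf", "w") as fh:
        for rec in records:
            fh.write(rec.molecule.to_molblock())
            fh.write("$$$$\n")
    rows = []
    for rec in records:
        write_peak_table(rec.peaks, out / "peaks" / f"{rec.molecule.id}.tsv")
        for proton, shift in rec.reference.items():
            rows.append({"molecule_id": rec.molecule.id, "atom_index": proton,
                         "delta_ppm": shift})
    pd.DataFrame(rows, columns=["molecule_id", "atom_index", "delta_ppm"]).to_csv(
        out / "reference.tsv", sep="\t", index=False)


def read_reference_table(path: str | Path) -> dict[str, dict[int, float]]:
    df = pd.read_csv(path, sep="\t")
    refs: dict[str, dict[int, float]] = {}
    for row in df.itertuples(index=False):
        refs.setdefault(str(row.molecule_id), {})[int(row.atom_index)] = float(row.delta_ppm)
    return refs
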
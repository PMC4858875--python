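import networkx as nx
import numpy as np
import pytest
from hypothesis import settings
from networkx.algorithms.isomorphism import (
    GraphMatcher,
    categorical_edge_match,
    categorical_node_match,
)
from rdkit import Chem

import shiftlearn as sl

settings.register_profile("suite", derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def methane():
    return sl.Molecule.from_smiles("C", "methane")


@pytest.fixture
def ethanol():
    return sl.Molecule.from_smiles("CCO", "ethanol")


@pytest.fixture
def benzene():
    return sl.Molecule.from_smiles("c1ccccc1", "benzene")


@pytest.fixture
def propane():
    return sl.Molecule.from_smiles("CCC", "propane")


def permute_molecule(molecule: sl.Molecule, rng: np.random.Generator):
    """Renumber atoms randomly; returns (permuted molecule, old->new index map)."""
    n = molecule.num_atoms
    new_order = [int(x) for x in rng.permutation(n)]  # new i holds old new_order[i]
    rd = Chem.RenumberAtoms(molecule.rdkit, new_order)
    old_to_new = {old: new for new, old in enumerate(new_order)}
    return (
        sl.Molecule(rd, molecule.id, hydrogen_complete=molecule.hydrogen_complete),
        old_to_new,
    )


def automorphism_proton_orbits(molecule: sl.Molecule) -> set[frozenset[int]]:
    """Brute-force oracle: hydrogen orbits under all graph automorphisms."""
    g = nx.Graph()
    rd = molecule.rdkit
    for atom in rd.GetAtoms():
        g.add_node(atom.GetIdx(), el=atom.GetSymbol(), ch=atom.GetFormalCharge())
    for bond in rd.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(),
                   order=str(bond.GetBondType()))
    matcher = GraphMatcher(
        g, g,
        node_match=categorical_node_match(["el", "ch"], [None, 0]),
        edge_match=categorical_edge_match("order", None),
    )
    parent = {i: i for i in g.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for iso in matcher.isomorphisms_iter():
        for a, b in iso.items():
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    orbits: dict[int, set[int]] = {}
    for h in molecule.hydrogen_indices:
        orbits.setdefault(find(h), set()).add(h)
    return {frozenset(v) for v in orbits.values()}


def batch_semantics_training():
    """Two spectra of chloroethane plus 1-bromo-2-chloroethane.

    The halide is ambiguous on integrals alone (two size-2 classes, two
    integral-2 peaks); the radius-2 Cl-CH2 environment learnt from the two
    chloroethane spectra disambiguates it from iteration 1 onwards.
    """
    a1 = sl.Molecule.from_smiles("CCCl", "A1")
    a2 = sl.Molecule.from_smiles("CCCl", "A2")
    b = sl.Molecule.from_smiles("ClCCBr", "B")
    return [
        (a1, [(1.45, 3.0), (3.47, 2.0)]),
        (a2, [(1.47, 3.0), (3.49, 2.0)]),
        (b, [(3.50, 2.0), (3.30, 2.0)]),
    ]


def brute_force_solutions(problem: sl.AssignmentProblem) -> list[tuple[int, ...]]:
    """Exhaustive oracle: filter every class->peak map by the two constraints."""
    import itertools

    k = len(problem.class_sizes)
    n = len(problem.peaks)
    targets = [p.integer_integral for p in problem.peaks]
    out = []
    for combo in itertools.product(range(n), repeat=k):
        if any(combo[i] not in problem.allowed[i] for i in range(k)):
            continue
        load = [0] * n
        for i, j in enumerate(combo):
            load[j] += problem.class_sizes[i]
        if load == targets:
            out.append(combo)
    return sorted(out)


def random_assignment_problem(rng: np.random.Generator) -> sl.AssignmentProblem:
    """Random feasible-shaped problem with <= 8 classes and <= 4 peaks."""
    k = int(rng.integers(1, 9))
    sizes = rng.integers(1, 4, size=k)
    n_peaks = int(rng.integers(1, min(4, k) + 1))
    peak_of = rng.integers(0, n_peaks, size=k)
    integrals = [int(sizes[peak_of == j].sum()) for j in range(n_peaks)]
    positions = np.sort(rng.uniform(0.0, 10.0, size=n_peaks))
    peaks = tuple(
        sl.Peak(position=float(p), integral=float(i), integer_integral=i)
        for p, i in zip(positions, integrals)
    )
    allowed = []
    for _ in range(k):
        if rng.random() < 0.5:
            allowed.append(frozenset(range(n_peaks)))
        else:
            subset = {j for j in range(n_peaks) if rng.random() < 0.6}
            allowed.append(frozenset(subset))
    return sl.AssignmentProblem(
        class_sizes=tuple(int(s) for s in sizes),
        peaks=peaks,
        allowed=tuple(allowed),
    )
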
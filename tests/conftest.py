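"""Shared fixtures: hand-written molfiles and small synthetic universes."""

from __future__ import annotations

import numpy as np
import pytest

from pathassoc.chemgraph import Atom, Bond, MolecularGraph, write_molfile


def molfile(atoms: list[str], bonds: list[tuple[int, int, int]], mid: str = "X") -> str:
    """Build V2000 text from element symbols and 0-based (a, b, order) bonds."""
    g = MolecularGraph(
        mid,
        [Atom(i, el) for i, el in enumerate(atoms)],
        [Bond(a, b, o) for a, b, o in bonds],
    )
    return write_molfile(g)


@pytest.fixture
def water_molfile() -> str:
    return molfile(["O", "H", "H"], [(0, 1, 1), (0, 2, 1)], "water")


@pytest.fixture
def ethanol_molfile() -> str:
    # CH3-CH2-OH with all 6 hydrogens explicit: 9 atoms, 8 bonds
    atoms = ["C", "C", "O", "H", "H", "H", "H", "H", "H"]
    bonds = [
        (0, 1, 1), (1, 2, 1),
        (0, 3, 1), (0, 4, 1), (0, 5, 1),
        (1, 6, 1), (1, 7, 1),
        (2, 8, 1),
    ]
    return molfile(atoms, bonds, "ethanol")


@pytest.fixture
def methanol_molfile() -> str:
    atoms = ["C", "O", "H", "H", "H", "H"]
    bonds = [(0, 1, 1), (0, 2, 1), (0, 3, 1), (0, 4, 1), (1, 5, 1)]
    return molfile(atoms, bonds, "methanol")


def random_graph(rng: np.random.Generator, n_atoms: int | None = None) -> MolecularGraph:
    """Random connected labeled tree plus a few extra edges."""
    elements = ["C", "N", "O", "S", "P"]
    n = int(rng.integers(2, 15)) if n_atoms is None else n_atoms
    atoms = [Atom(i, elements[rng.integers(len(elements))]) for i in range(n)]
    bonds = [
        Bond(int(rng.integers(i)), i, int(rng.integers(1, 5))) for i in range(1, n)
    ]
    existing = {b.key for b in bonds}
    for _ in range(int(rng.integers(0, 3))):
        a, b = rng.choice(n, size=2, replace=False)
        key = (min(a, b), max(a, b))
        if key not in existing:
            existing.add(key)
            bonds.append(Bond(int(a), int(b), int(rng.integers(1, 5))))
    return MolecularGraph("rand", atoms, bonds)


@pytest.fixture(scope="session")
def tiny_universe():
    """Small high-signal synthetic universe plus its featurized dataset."""
    import pathassoc as pa

    mols, hierarchy = pa.generate_universe(
        pa.SyntheticSpec(n_l2=2, l3_per_l2=2, size_mu=1.8, size_sigma=0.4, seed=7)
    )
    vectors, atom_counts = pa.featurize_molecules(mols)
    dataset = pa.build_dataset(vectors, hierarchy, pa.DatasetSpec(), atom_counts)
    return {
        "molfiles": mols,
        "hierarchy": hierarchy,
        "vectors": vectors,
        "atom_counts": atom_counts,
        "dataset": dataset,
    }
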
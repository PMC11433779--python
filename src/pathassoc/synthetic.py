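"""Synthetic molecule + pathway-hierarchy universes with controllable signal.

The generator emulates the statistical shape of a curated metabolic
knowledgebase: a two-level hierarchy in which every individual (L3) pathway
belongs to exactly one category (L2), right-skewed pathway sizes with a
minimum of three members, small molecular graphs over {C, N, O, S, P}, and
every metabolite belonging to at least one pathway.

The learnable signal is a *scaffold motif*: a 3-atom labeled chain unique
to each L3 pathway, grafted onto a member molecule with probability
``scaffold_signal``.  Because pathway features are sums of member features,
a shared motif couples the metabolite and pathway feature blocks — which is
exactly why the cross-join design can work.  Chemical validity (valence) is
deliberately not enforced; the featurization consumes arbitrary labeled
graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from .chemgraph import Atom, Bond, MolecularGraph, write_molfile
from .dataset import Level, Pathway, PathwayHierarchy

__all__ = [
    "SyntheticSpec",
    "Motif",
    "generate_molecule",
    "generate_universe",
    "write_fixture",
]

_ELEMENTS = ("C", "N", "O", "S", "P")
# unique 3-atom chain motifs: element triple x bond-order pair
_MOTIF_POOL = [
    (elems, orders)
    for elems in product(_ELEMENTS, repeat=3)
    for orders in product((1, 2, 3), repeat=2)
]


@dataclass(frozen=True)
class Motif:
    """A 3-atom labeled chain unique to one pathway."""

    elements: tuple[str, str, str]
    orders: tuple[int, int]

    @classmethod
    def for_pathway(cls, index: int) -> "Motif":
        elems, orders = _MOTIF_POOL[index % len(_MOTIF_POOL)]
        return cls(elems, orders)


@dataclass(frozen=True)
class SyntheticSpec:
    """Universe parameters.

    Defaults give roughly 150 molecules in 2 L2 categories x 3 L3 pathways
    each (8 pathways total): L3 sizes are ``size_min + floor(lognormal(mu,
    sigma))`` — heavy right tail, minimum 3 members.
    """

    n_l2: int = 2
    l3_per_l2: int = 3
    size_min: int = 3
    size_mu: float = 3.0
    size_sigma: float = 0.5
    scaffold_signal: float = 1.0
    molecule_size_range: tuple[int, int] = (8, 24)
    overlap_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_min < 3:
            raise ValueError("minimum pathway size is 3 members")
        for p in (self.scaffold_signal, self.overlap_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_l2 < 1 or self.l3_per_l2 < 1:
            raise ValueError("need at least one L2 and one L3 per L2")
        lo, hi = self.molecule_size_range
        if lo < 1 or hi < lo:
            raise ValueError("bad molecule_size_range")


def generate_molecule(
    rng: np.random.Generator,
    motifs: list[Motif] | Motif | None,
    size: int,
    metabolite_id: str = "synthetic",
) -> MolecularGraph:
    """Random labeled tree of ``size`` atoms with zero or more motif chains
    grafted on (each adds 3 atoms, attached by a single bond)."""
    if size < 1:
        raise ValueError("size must be >= 1")
    if motifs is None:
        motifs = []
    elif isinstance(motifs, Motif):
        motifs = [motifs]
    atoms = [Atom(0, _ELEMENTS[rng.integers(len(_ELEMENTS))])]
    bonds: list[Bond] = []
    for i in range(1, size):
        parent = int(rng.integers(i))
        order = int(rng.choice([1, 1, 1, 2]))
        atoms.append(Atom(i, _ELEMENTS[rng.integers(len(_ELEMENTS))]))
        bonds.append(Bond(parent, i, order))
    for motif in motifs:
        anchor = int(rng.integers(len(atoms)))
        base = len(atoms)
        for k, elem in enumerate(motif.elements):
            atoms.append(Atom(base + k, elem))
        bonds.append(Bond(anchor, base, 1))
        bonds.append(Bond(base, base + 1, motif.orders[0]))
        bonds.append(Bond(base + 1, base + 2, motif.orders[1]))
    return MolecularGraph(metabolite_id, atoms, bonds)


@dataclass
class _Molecule:
    metabolite_id: str
    memberships: list[int] = field(default_factory=list)  # L3 pathway indices


def generate_universe(spec: SyntheticSpec) -> tuple[dict[str, str], PathwayHierarchy]:
    """Generate (molfile texts keyed by metabolite id, pathway hierarchy).

    With ``scaffold_signal`` 1 the pathway label is (near-)deterministic
    given the features; with 0, membership is random relative to structure.
    L2 membership is always the union of its child L3 memberships.
    """
    rng = np.random.default_rng(spec.seed)
    n_l3 = spec.n_l2 * spec.l3_per_l2
    l3_sizes = [
        spec.size_min + int(np.floor(rng.lognormal(spec.size_mu, spec.size_sigma)))
        for _ in range(n_l3)
    ]
    molecules: list[_Molecule] = []
    l3_members: list[list[int]] = [[] for _ in range(n_l3)]
    for j in range(n_l3):
        for _ in range(l3_sizes[j]):
            reusable = [
                m for m in range(len(molecules)) if j not in molecules[m].memberships
            ]
            if reusable and rng.random() < spec.overlap_rate:
                m = int(rng.choice(reusable))
            else:
                m = len(molecules)
                molecules.append(_Molecule(f"M{m:05d}"))
            molecules[m].memberships.append(j)
            l3_members[j].append(m)

    lo, hi = spec.molecule_size_range
    molfiles: dict[str, str] = {}
    for mol in molecules:
        motifs = [
            Motif.for_pathway(j)
            for j in mol.memberships
            if rng.random() < spec.scaffold_signal
        ]
        target = int(rng.integers(lo, hi + 1))
        base_size = max(1, target - 3 * len(motifs))
        graph = generate_molecule(rng, motifs, base_size, mol.metabolite_id)
        molfiles[mol.metabolite_id] = write_molfile(graph)

    pathways: list[Pathway] = []
    for c in range(spec.n_l2):
        l2_id = f"L2_{c:02d}"
        union: set[str] = set()
        children: list[Pathway] = []
        for k in range(spec.l3_per_l2):
            j = c * spec.l3_per_l2 + k
            members = {molecules[m].metabolite_id for m in l3_members[j]}
            union |= members
            children.append(Pathway(f"L3_{c:02d}_{k:02d}", Level.L3, members, l2_id))
        pathways.append(Pathway(l2_id, Level.L2, union))
        pathways.extend(children)
    return molfiles, PathwayHierarchy(pathways)


def write_fixture(spec: SyntheticSpec, out_dir: str | Path) -> tuple[Path, Path]:
    """Write molfiles (``<metabolite_id>.mol``) and ``hierarchy.tsv`` in the
    dialects the dataset stage reads.  Returns (molfile dir, hierarchy path)."""
    out_dir = Path(out_dir)
    mol_dir = out_dir / "molfiles"
    mol_dir.mkdir(parents=True, exist_ok=True)
    molfiles, hierarchy = generate_universe(spec)
    for mid, text in molfiles.items():
        (mol_dir / f"{mid}.mol").write_text(text)
    hier_path = out_dir / "hierarchy.tsv"
    hierarchy.to_tsv(hier_path)
    return mol_dir, hier_path
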
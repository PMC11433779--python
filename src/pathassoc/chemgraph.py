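"""Molecular graphs and atom-color features.

A metabolite is represented as a labeled graph over its non-hydrogen atoms.
Each atom is assigned a canonical *color* string at bond radii 0..3: the
radius-0 color is the element symbol, and the radius-r color encodes the
element together with the sorted list of (bond order, neighbor radius-(r-1)
color) pairs.  Counting the colors present in a molecule yields a feature
vector that is invariant to atom ordering, in the spirit of
Weisfeiler-Lehman / ECFP-style neighborhood fingerprints.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "AtomColor",
    "ColorCountVector",
    "MolfileParseError",
    "GraphStructureError",
    "parse_molfile",
    "write_molfile",
    "strip_hydrogens",
    "color_atoms",
    "count_colors",
]

MAX_RADIUS = 3


class MolfileParseError(ValueError):
    """Raised when molfile text cannot be parsed as V2000."""


class GraphStructureError(ValueError):
    """Raised when a graph violates structural invariants (bad bond indices,
    duplicate bonds, empty structure)."""


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.element:
            raise GraphStructureError("atom element symbol must be nonempty")


@dataclass(frozen=True)
class Bond:
    """Undirected bond between atom indices ``a`` and ``b``.

    ``order`` uses the molfile code: 1, 2, 3 or 4 (aromatic).
    """

    a: int
    b: int
    order: int

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise GraphStructureError(f"self-bond on atom {self.a}")

    @property
    def key(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


@dataclass
class MolecularGraph:
    metabolite_id: str
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for bond in self.bonds:
            if not (0 <= bond.a < n and 0 <= bond.b < n):
                raise GraphStructureError(
                    f"{self.metabolite_id}: bond ({bond.a}, {bond.b}) references "
                    f"a nonexistent atom (graph has {n} atoms)"
                )
            if bond.key in seen:
                raise GraphStructureError(
                    f"{self.metabolite_id}: duplicate bond between atoms "
                    f"{bond.key[0]} and {bond.key[1]}"
                )
            seen.add(bond.key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> list[list[tuple[int, int]]]:
        """Neighbor lists as (neighbor index, bond order) pairs."""
        adj: list[list[tuple[int, int]]] = [[] for _ in self.atoms]
        for bond in self.bonds:
            adj[bond.a].append((bond.b, bond.order))
            adj[bond.b].append((bond.a, bond.order))
        return adj

    def permuted(self, perm: list[int]) -> "MolecularGraph":
        """Relabel atoms: new index of old atom i is perm[i]."""
        if sorted(perm) != list(range(self.n_atoms)):
            raise GraphStructureError("perm must be a permutation of atom indices")
        new_atoms = [None] * self.n_atoms  # type: ignore[list-item]
        for old, atom in enumerate(self.atoms):
            new_atoms[perm[old]] = Atom(perm[old], atom.element, atom.charge)
        new_bonds = [Bond(perm[b.a], perm[b.b], b.order) for b in self.bonds]
        return MolecularGraph(self.metabolite_id, list(new_atoms), new_bonds)


class AtomColor(NamedTuple):
    """One neighborhood feature: the bond radius (0-3) and its canonical key.

    The same textual key at different radii is a different feature; the
    radius is what the entry-wise normalization groups on.
    """

    radius: int
    key: str


@dataclass
class ColorCountVector:
    """Sparse counts of atom colors in one metabolite (or pathway sum)."""

    counts: Counter

    def __add__(self, other: "ColorCountVector") -> "ColorCountVector":
        return ColorCountVector(self.counts + other.counts)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ColorCountVector) and self.counts == other.counts

    def n_atoms(self) -> int:
        """Number of non-hydrogen atoms = sum of radius-0 counts."""
        return sum(c for color, c in self.counts.items() if color.radius == 0)


# ---------------------------------------------------------------------------
# Molfile V2000 I/O
# ---------------------------------------------------------------------------

def parse_molfile(text: str, metabolite_id: str) -> MolecularGraph:
    """Parse MDL molfile (V2000) text into a :class:`MolecularGraph`.

    Hydrogens written explicitly in the atom block are kept; remove them
    with :func:`strip_hydrogens`.  Bond indices are converted to 0-based.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileParseError(
            f"{metabolite_id}: molfile has {len(lines)} lines; "
            "expected 3 header lines plus a counts line"
        )
    counts_line = lines[3]
    try:
        n_atoms = int(counts_line[0:3])
        n_bonds = int(counts_line[3:6])
    except (ValueError, IndexError) as exc:
        raise MolfileParseError(
            f"{metabolite_id}: malformed counts line {counts_line!r}"
        ) from exc
    if len(lines) < 4 + n_atoms + n_bonds:
        raise MolfileParseError(
            f"{metabolite_id}: counts line declares {n_atoms} atoms and "
            f"{n_bonds} bonds but only {len(lines) - 4} block lines follow"
        )
    atoms: list[Atom] = []
    for i in range(n_atoms):
        line = lines[4 + i]
        # V2000 atom block: x(10) y(10) z(10) space, element in cols 31-34
        element = line[31:34].strip()
        if not element:
            # tolerate whitespace-separated atom lines
            parts = line.split()
            if len(parts) < 4:
                raise MolfileParseError(
                    f"{metabolite_id}: malformed atom line {i + 1}: {line!r}"
                )
            element = parts[3]
        atoms.append(Atom(i, element))
    bonds: list[Bond] = []
    for i in range(n_bonds):
        line = lines[4 + n_atoms + i]
        try:
            a = int(line[0:3])
            b = int(line[3:6])
            order = int(line[6:9])
        except (ValueError, IndexError) as exc:
            raise MolfileParseError(
                f"{metabolite_id}: malformed bond line {i + 1}: {line!r}"
            ) from exc
        if not (1 <= a <= n_atoms and 1 <= b <= n_atoms):
            raise GraphStructureError(
                f"{metabolite_id}: bond line {i + 1} references atom "
                f"{a if not (1 <= a <= n_atoms) else b} "
                f"outside 1..{n_atoms}"
            )
        bonds.append(Bond(a - 1, b - 1, order))
    return MolecularGraph(metabolite_id, atoms, bonds)


def write_molfile(g: MolecularGraph, title: str | None = None) -> str:
    """Serialize a graph back to V2000 text (zero coordinates)."""
    lines = [title if title is not None else g.metabolite_id, "  pathassoc", ""]
    lines.append(f"{g.n_atoms:3d}{len(g.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for atom in g.atoms:
        lines.append(
            f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {atom.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for bond in g.bonds:
        lines.append(f"{bond.a + 1:3d}{bond.b + 1:3d}{bond.order:3d}  0  0  0  0")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def strip_hydrogens(g: MolecularGraph) -> MolecularGraph:
    """Remove explicit hydrogen atoms and their bonds; re-index densely."""
    keep = [a.index for a in g.atoms if a.element != "H"]
    remap = {old: new for new, old in enumerate(keep)}
    atoms = [Atom(remap[a.index], a.element, a.charge) for a in g.atoms if a.element != "H"]
    bonds = [
        Bond(remap[b.a], remap[b.b], b.order)
        for b in g.bonds
        if b.a in remap and b.b in remap
    ]
    return MolecularGraph(g.metabolite_id, atoms, bonds)


# ---------------------------------------------------------------------------
# Atom coloring
# ---------------------------------------------------------------------------

def color_atoms(
    g: MolecularGraph, max_radius: int = MAX_RADIUS
) -> dict[int, list[AtomColor]]:
    """Assign each atom one canonical color per radius 0..max_radius.

    radius 0: the element symbol.
    radius r: ``element + "(" + ",".join(sorted(str(order) + neighbor's
    radius-(r-1) key)) + ")"``.

    The sort makes the key independent of atom input order; because each
    radius-r key embeds the element prefix of the radius-(r-1) key, colors
    refine (never merge) as the radius grows.
    """
    prev = [atom.element for atom in g.atoms]
    per_atom: dict[int, list[AtomColor]] = {
        atom.index: [AtomColor(0, atom.element)] for atom in g.atoms
    }
    adj = g.adjacency()
    for radius in range(1, max_radius + 1):
        cur: list[str] = []
        for atom in g.atoms:
            parts = sorted(f"{order}{prev[nbr]}" for nbr, order in adj[atom.index])
            key = f"{atom.element}({','.join(parts)})"
            cur.append(key)
            per_atom[atom.index].append(AtomColor(radius, key))
        prev = cur
    return per_atom


def count_colors(g: MolecularGraph, max_radius: int = MAX_RADIUS) -> ColorCountVector:
    """Count the atom colors present in a hydrogen-free graph.

    At every radius the counts sum to the number of non-hydrogen atoms.
    """
    if g.n_atoms == 0:
        raise GraphStructureError(
            f"{g.metabolite_id}: structure has no non-hydrogen atoms"
        )
    counts: Counter = Counter()
    for colors in color_atoms(g, max_radius).values():
        counts.update(colors)
    return ColorCountVector(counts)
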
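"""Pathway hierarchy, cross-join dataset construction and CV splits.

The dataset design reduces a many-pathway multi-label problem to a single
binary classification: every metabolite is paired with every pathway
(cross-join), the entry's features are the concatenated metabolite and
pathway feature rows, and the label says whether the metabolite is a member
of the pathway.  Entry feature rows are assembled lazily — random access by
entry index without materializing the |metabolites| x |pathways| dense grid.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .featurization import FeatureMatrix

__all__ = [
    "Level",
    "Pathway",
    "PathwayHierarchy",
    "DatasetSpec",
    "CrossJoinEntry",
    "CrossJoinDataset",
    "SplitPlan",
    "select_pathways",
    "filter_by_size",
    "cross_join",
    "assemble_input_width",
    "stratified_split",
]


class Level(str, Enum):
    """KEGG-style hierarchy level: L2 = pathway category, L3 = individual
    pathway (every L3 pathway belongs to exactly one L2 category)."""

    L2 = "L2"
    L3 = "L3"


@dataclass
class Pathway:
    pathway_id: str
    level: Level
    members: set[str]
    parent_l2: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class PathwayHierarchy:
    pathways: list[Pathway]

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(set(ids)) != len(ids):
            raise ValueError("pathway ids must be unique")
        l2_ids = {p.pathway_id for p in self.pathways if p.level == Level.L2}
        for p in self.pathways:
            if p.level == Level.L3 and p.parent_l2 is not None and p.parent_l2 not in l2_ids:
                raise ValueError(
                    f"L3 pathway {p.pathway_id!r} has unknown parent {p.parent_l2!r}"
                )

    def __iter__(self):
        return iter(self.pathways)

    def by_level(self, level: Level) -> list[Pathway]:
        return [p for p in self.pathways if p.level == level]

    def get(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    @property
    def metabolite_ids(self) -> set[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.members
        return out

    # -- TSV dialect: one row per membership -------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "PathwayHierarchy":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"pathway_id", "level", "parent_l2", "metabolite_id"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"hierarchy TSV must have columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        pathways: dict[str, Pathway] = {}
        for row in df.itertuples(index=False):
            pid = row.pathway_id
            if pid not in pathways:
                pathways[pid] = Pathway(
                    pid, Level(row.level), set(), row.parent_l2 or None
                )
            pathways[pid].members.add(row.metabolite_id)
        return cls(list(pathways.values()))

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (p.pathway_id, p.level.value, p.parent_l2 or "", m)
            for p in sorted(self.pathways, key=lambda q: (q.level.value, q.pathway_id))
            for m in sorted(p.members)
        ]
        pd.DataFrame(
            rows, columns=["pathway_id", "level", "parent_l2", "metabolite_id"]
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DatasetSpec:
    """Which pathways enter the dataset and how features are treated."""

    level_selection: str = "combined"  # 'L2_only' | 'L3_only' | 'combined'
    scaled: bool = True
    min_pathway_size: int = 0


@dataclass(frozen=True)
class CrossJoinEntry:
    metabolite_id: str
    pathway_id: str
    label: int


def select_pathways(h: PathwayHierarchy, spec: DatasetSpec) -> list[Pathway]:
    """L2_only / L3_only / combined selection, deterministically ordered by
    (level, pathway id)."""
    if not h.pathways:
        raise ValueError("hierarchy is empty")
    if spec.level_selection == "L2_only":
        chosen = h.by_level(Level.L2)
    elif spec.level_selection == "L3_only":
        chosen = h.by_level(Level.L3)
    elif spec.level_selection == "combined":
        chosen = list(h.pathways)
    else:
        raise ValueError(f"unknown level selection {spec.level_selection!r}")
    if not chosen:
        raise ValueError(f"no pathways at selection {spec.level_selection!r}")
    return sorted(chosen, key=lambda p: (p.level.value, p.pathway_id))


def filter_by_size(
    pathways: Sequence[Pathway], min_pathway_size: int
) -> tuple[list[Pathway], set[str]]:
    """Drop pathways with fewer members than the threshold, then drop
    metabolites left with no association among the survivors.

    Returns (surviving pathways, surviving metabolite ids).
    """
    if min_pathway_size < 0:
        raise ValueError("min_pathway_size must be >= 0")
    survivors = [p for p in pathways if p.size >= min_pathway_size]
    if not survivors:
        raise ValueError(
            f"size threshold {min_pathway_size} removes all "
            f"{len(pathways)} pathways"
        )
    metabolites: set[str] = set()
    for p in survivors:
        metabolites |= p.members
    return survivors, metabolites


def assemble_input_width(metabolite_width: int, pathway_width: int) -> int:
    """Width of a cross-join entry row: metabolite block + pathway block."""
    if metabolite_width <= 0 or pathway_width <= 0:
        raise ValueError("feature widths must be positive")
    return metabolite_width + pathway_width


class CrossJoinDataset:
    """Lazy cross-join of metabolites with pathways.

    Entry index e maps to (metabolite i, pathway j) with e = i * n_pathways
    + j; the feature row is metabolite row i concatenated with pathway row
    j and is assembled on demand, batch by batch.
    """

    def __init__(
        self,
        metabolite_matrix: FeatureMatrix,
        pathway_matrix: FeatureMatrix,
        pathways: Sequence[Pathway],
        metabolite_atom_counts: dict[str, int] | None = None,
    ) -> None:
        pw_ids = [p.pathway_id for p in pathways]
        if list(pathway_matrix.row_ids) != pw_ids:
            raise ValueError("pathway matrix rows must match the pathway list order")
        met_index = {m: i for i, m in enumerate(metabolite_matrix.row_ids)}
        for p in pathways:
            for m in p.members:
                if m not in met_index:
                    raise KeyError(
                        f"pathway {p.pathway_id!r} member {m!r} missing from "
                        "metabolite matrix"
                    )
        self.metabolite_matrix = metabolite_matrix
        self.pathway_matrix = pathway_matrix
        self.pathways = list(pathways)
        self.metabolite_atom_counts = metabolite_atom_counts or {}
        self._met_index = met_index

        n_met, n_pw = metabolite_matrix.n_rows, len(pathways)
        labels = np.zeros((n_met, n_pw), dtype=np.int8)
        for j, p in enumerate(pathways):
            for m in p.members:
                labels[met_index[m], j] = 1
        self.labels = labels.reshape(-1)
        # every metabolite and every pathway must carry >= 1 positive entry
        if n_pw and not labels.any(axis=1).all():
            orphans = [metabolite_matrix.row_ids[i] for i in np.flatnonzero(~labels.any(axis=1))]
            raise ValueError(f"metabolites with no pathway association: {orphans[:5]}")
        if n_met and not labels.any(axis=0).all():
            empty = [pw_ids[j] for j in np.flatnonzero(~labels.any(axis=0))]
            raise ValueError(f"pathways with no member in the matrix: {empty[:5]}")

    @property
    def n_metabolites(self) -> int:
        return self.metabolite_matrix.n_rows

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)

    @property
    def n_entries(self) -> int:
        return self.n_metabolites * self.n_pathways

    @property
    def input_width(self) -> int:
        return assemble_input_width(self.metabolite_matrix.width, self.pathway_matrix.width)

    def entry_pairs(self, entry_indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(metabolite row index, pathway row index) for each entry index."""
        entry_indices = np.asarray(entry_indices)
        return entry_indices // self.n_pathways, entry_indices % self.n_pathways

    def features(self, entry_indices: np.ndarray) -> np.ndarray:
        """Assemble the feature rows for a batch of entry indices."""
        met_idx, pw_idx = self.entry_pairs(entry_indices)
        return np.hstack(
            [self.metabolite_matrix.values[met_idx], self.pathway_matrix.values[pw_idx]]
        )

    def entry(self, e: int) -> CrossJoinEntry:
        i, j = divmod(int(e), self.n_pathways)
        return CrossJoinEntry(
            self.metabolite_matrix.row_ids[i],
            self.pathways[j].pathway_id,
            int(self.labels[e]),
        )

    def pathway_of_entries(self, entry_indices: np.ndarray) -> np.ndarray:
        return np.asarray(entry_indices) % self.n_pathways

    def pathway_sizes(self) -> pd.DataFrame:
        """Per-pathway size in member metabolites and summed non-hydrogen atoms."""
        rows = []
        for p in self.pathways:
            atoms = sum(self.metabolite_atom_counts.get(m, 0) for m in p.members)
            rows.append((p.pathway_id, p.level.value, p.size, atoms))
        return pd.DataFrame(
            rows, columns=["pathway_id", "level", "size_metabolites", "size_atoms"]
        )

    def content_hash(self) -> str:
        """SHA-256 over the logical content (ids, labels, feature values)."""
        h = hashlib.sha256()
        h.update("\n".join(self.metabolite_matrix.row_ids).encode())
        h.update("\n".join(p.pathway_id for p in self.pathways).encode())
        h.update(self.labels.tobytes())
        h.update(np.ascontiguousarray(self.metabolite_matrix.values).tobytes())
        h.update(np.ascontiguousarray(self.pathway_matrix.values).tobytes())
        return h.hexdigest()


def cross_join(
    metabolite_matrix: FeatureMatrix,
    pathway_matrix: FeatureMatrix,
    pathways: Sequence[Pathway],
    metabolite_atom_counts: dict[str, int] | None = None,
) -> CrossJoinDataset:
    """Construct the lazy |metabolites| x |pathways| cross-join dataset."""
    return CrossJoinDataset(metabolite_matrix, pathway_matrix, pathways, metabolite_atom_counts)


@dataclass
class SplitPlan:
    """One CV iteration's fold assignment; only the designated test fold is
    consumed (jackknife-style 10% hold-out)."""

    iteration: int
    seed: int
    fold_assignment: np.ndarray
    test_fold: int = 0
    n_folds: int = 10

    def test_indices(self) -> np.ndarray:
        return np.flatnonzero(self.fold_assignment == self.test_fold)

    def train_indices(self) -> np.ndarray:
        return np.flatnonzero(self.fold_assignment != self.test_fold)


def stratified_split(
    labels: np.ndarray, n_folds: int = 10, seed: int = 0, iteration: int = 0
) -> SplitPlan:
    """Stratified k-fold assignment over entries, keyed on the binary label.

    Per-class fold sizes differ by at most 1; the plan is a pure function
    of (labels, n_folds, seed).  Fold 0 is the designated test fold.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < n_folds):
        short = classes[counts < n_folds]
        raise ValueError(
            f"class(es) {short.tolist()} have fewer entries than {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=np.int16)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return SplitPlan(iteration=iteration, seed=seed, fold_assignment=assignment, n_folds=n_folds)
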
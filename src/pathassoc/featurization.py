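"""Feature matrices over atom-color vocabularies and their normalizations.

Two normalizations are applied to raw color counts, mirroring the dataset
engineering of the cross-join approach:

1. *Bond-count normalization* (entry-wise): features are grouped by the
   radius (bond count) of their color, 0-3; each group of a row is divided
   by the group's sum, so every nonempty group sums to 1.  The field calls
   this "softmax by bond count" although the operation described is
   group-sum division; an exponential softmax variant is available behind
   a flag for comparison.
2. *Min-max scaling* (feature-wise): each column mapped to [0, 1] by
   (x - min) / (max - min), constant columns mapping to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import h5py
import numpy as np

from .chemgraph import AtomColor, ColorCountVector

__all__ = [
    "FeatureVocabulary",
    "FeatureMatrix",
    "ScalingParams",
    "build_matrix",
    "aggregate_pathways",
    "dedupe_columns",
    "bond_count_normalize",
    "bond_count_normalize_matrix",
    "minmax_fit",
    "minmax_apply",
]


@dataclass(frozen=True)
class FeatureVocabulary:
    """Ordered atom-color columns; order is sorted by (radius, key)."""

    colors: tuple[AtomColor, ...]

    def __post_init__(self) -> None:
        if len(set(self.colors)) != len(self.colors):
            raise ValueError("duplicate AtomColor in vocabulary")

    @classmethod
    def from_colors(cls, colors) -> "FeatureVocabulary":
        return cls(tuple(sorted(set(colors))))

    def __len__(self) -> int:
        return len(self.colors)

    @property
    def index(self) -> dict[AtomColor, int]:
        return {c: i for i, c in enumerate(self.colors)}

    @property
    def radii(self) -> np.ndarray:
        """Per-column radius, the grouping key of bond-count normalization."""
        return np.array([c.radius for c in self.colors], dtype=np.int8)


@dataclass
class FeatureMatrix:
    """Rows = entities (metabolites or pathways), columns = atom colors."""

    row_ids: list[str]
    vocabulary: FeatureVocabulary
    values: np.ndarray
    column_provenance: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.row_ids), len(self.vocabulary)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.vocabulary)} columns"
            )

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def width(self) -> int:
        return len(self.vocabulary)

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self.row_ids.index(entity_id)]

    def to_hdf5(self, h5group: h5py.Group) -> None:
        h5group.create_dataset("values", data=self.values)
        str_dt = h5py.string_dtype(encoding="utf-8")
        h5group.create_dataset("row_ids", data=np.array(self.row_ids, dtype=object), dtype=str_dt)
        h5group.create_dataset(
            "color_keys",
            data=np.array([c.key for c in self.vocabulary.colors], dtype=object),
            dtype=str_dt,
        )
        h5group.create_dataset("color_radii", data=self.vocabulary.radii)

    @classmethod
    def from_hdf5(cls, h5group: h5py.Group) -> "FeatureMatrix":
        keys = [k.decode() for k in h5group["color_keys"][()]]
        radii = h5group["color_radii"][()]
        vocab = FeatureVocabulary(tuple(AtomColor(int(r), k) for r, k in zip(radii, keys)))
        row_ids = [r.decode() for r in h5group["row_ids"][()]]
        return cls(row_ids, vocab, h5group["values"][()])


@dataclass
class ScalingParams:
    """Fitted per-column min/max for feature-wise [0, 1] scaling."""

    vocabulary: FeatureVocabulary
    col_min: np.ndarray
    col_max: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.col_min > self.col_max):
            raise ValueError("per-column min must not exceed max")


def build_matrix(vectors: Mapping[str, ColorCountVector]) -> FeatureMatrix:
    """Assemble sparse count vectors into a dense matrix over their union
    vocabulary (missing entries are 0)."""
    if not vectors:
        raise ValueError("build_matrix requires at least one vector")
    all_colors: set[AtomColor] = set()
    for vec in vectors.values():
        all_colors.update(vec.counts.keys())
    vocab = FeatureVocabulary.from_colors(all_colors)
    index = vocab.index
    row_ids = list(vectors.keys())
    values = np.zeros((len(row_ids), len(vocab)), dtype=np.float64)
    for i, rid in enumerate(row_ids):
        for color, count in vectors[rid].counts.items():
            values[i, index[color]] = count
    return FeatureMatrix(row_ids, vocab, values)


def aggregate_pathways(
    membership: Mapping[str, set],
    metabolite_vectors: Mapping[str, ColorCountVector],
) -> dict[str, ColorCountVector]:
    """Pathway feature vector = element-wise sum of member metabolite vectors."""
    out: dict[str, ColorCountVector] = {}
    for pathway_id, members in membership.items():
        resolved = [m for m in members if m in metabolite_vectors]
        missing = set(members) - set(resolved)
        if missing:
            raise KeyError(
                f"pathway {pathway_id!r}: member metabolites without vectors: "
                f"{sorted(missing)}"
            )
        if not resolved:
            raise ValueError(f"pathway {pathway_id!r} has no resolvable members")
        total = metabolite_vectors[resolved[0]]
        for m in resolved[1:]:
            total = total + metabolite_vectors[m]
        out[pathway_id] = total
    return out


def dedupe_columns(m: FeatureMatrix) -> FeatureMatrix:
    """Drop all-zero columns and, within groups of value-identical columns,
    keep only the first (by column order).

    A provenance map dropped-column-index -> kept-column-index is stored on
    the result so dropped features remain traceable.  With few rows (the
    pathway matrix) many columns coincide, which is why pathway feature
    counts come out well below metabolite feature counts.
    """
    values = m.values
    keep: list[int] = []
    provenance: dict[int, int] = {}
    seen: dict[bytes, int] = {}
    for j in range(values.shape[1]):
        col = values[:, j]
        if not np.any(col):
            continue
        sig = col.tobytes()
        if sig in seen:
            provenance[j] = seen[sig]
        else:
            seen[sig] = j
            keep.append(j)
    kept_order = {old: new for new, old in enumerate(keep)}
    vocab = FeatureVocabulary(tuple(m.vocabulary.colors[j] for j in keep))
    out = FeatureMatrix(list(m.row_ids), vocab, values[:, keep].copy())
    out.column_provenance = {j: kept_order[tgt] for j, tgt in provenance.items()}
    return out


def bond_count_normalize(
    row: np.ndarray, radii: np.ndarray, exponential: bool = False
) -> np.ndarray:
    """Normalize one feature row within radius groups.

    Each group (radius 0-3) whose sum is positive is divided by its sum, so
    the group sums to 1; all-zero groups stay zero.  With ``exponential``
    the group is passed through exp() first (a true softmax), provided for
    comparison only.
    """
    row = np.asarray(row, dtype=np.float64)
    if np.any(row < 0):
        raise ValueError("bond_count_normalize requires nonnegative input")
    out = row.copy()
    for r in np.unique(radii):
        mask = radii == r
        group = out[mask]
        if exponential:
            group = np.exp(group)
        total = group.sum()
        if total > 0 and (exponential is False or np.any(row[mask])):
            out[mask] = group / total
        elif exponential:
            out[mask] = 0.0
    return out


def bond_count_normalize_matrix(m: FeatureMatrix, exponential: bool = False) -> FeatureMatrix:
    """Apply :func:`bond_count_normalize` to every row of a matrix."""
    radii = m.vocabulary.radii
    values = np.vstack([
        bond_count_normalize(m.values[i], radii, exponential=exponential)
        for i in range(m.n_rows)
    ]) if m.n_rows else m.values.copy()
    out = FeatureMatrix(list(m.row_ids), m.vocabulary, values)
    out.column_provenance = dict(m.column_provenance)
    return out


def minmax_fit(m: FeatureMatrix) -> ScalingParams:
    """Fit per-column min/max on a matrix with at least one row."""
    if m.n_rows < 1:
        raise ValueError("minmax_fit requires at least one row")
    return ScalingParams(m.vocabulary, m.values.min(axis=0), m.values.max(axis=0))


def minmax_apply(m: FeatureMatrix, p: ScalingParams) -> FeatureMatrix:
    """Scale columns to [0, 1]: (x - min) / (max - min); constant columns
    map to 0; values from matrices other than the fitted one are clipped."""
    if m.vocabulary != p.vocabulary:
        raise ValueError("scaling params vocabulary does not match matrix")
    span = p.col_max - p.col_min
    safe = np.where(span > 0, span, 1.0)
    values = (m.values - p.col_min) / safe
    values = np.where(span > 0, values, 0.0)
    np.clip(values, 0.0, 1.0, out=values)
    out = FeatureMatrix(list(m.row_ids), m.vocabulary, values)
    out.column_provenance = dict(m.column_provenance)
    return out
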
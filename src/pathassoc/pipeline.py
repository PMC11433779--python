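"""End-to-end stages: featurize -> build dataset -> evaluate -> analyze.

All randomness flows from one base seed in the run config; rerunning a
stage with the same config and seed reproduces identical artifacts
(content hashes recorded in the run manifest).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .chemgraph import ColorCountVector, count_colors, parse_molfile, strip_hydrogens
from .dataset import (
    CrossJoinDataset,
    DatasetSpec,
    PathwayHierarchy,
    cross_join,
    filter_by_size,
    select_pathways,
)
from .evaluation import RepeatedCV
from .featurization import (
    aggregate_pathways,
    bond_count_normalize_matrix,
    build_matrix,
    dedupe_columns,
    minmax_apply,
    minmax_fit,
)
from .model import MLPConfig, PathwayAssociationMLP
from .synthetic import SyntheticSpec, write_fixture

logger = logging.getLogger("pathassoc")

__all__ = [
    "featurize_molecules",
    "load_molfile_dir",
    "build_dataset",
    "RunManifest",
    "run_pipeline",
    "load_config",
]


def load_molfile_dir(mol_dir: str | Path) -> dict[str, str]:
    """Read a directory of ``<metabolite_id>.mol`` files."""
    mol_dir = Path(mol_dir)
    if not mol_dir.is_dir():
        raise FileNotFoundError(f"molfile directory not found: {mol_dir}")
    texts = {p.stem: p.read_text() for p in sorted(mol_dir.glob("*.mol"))}
    if not texts:
        raise FileNotFoundError(f"no .mol files under {mol_dir}")
    return texts


def featurize_molecules(
    molfile_texts: Mapping[str, str], max_radius: int = 3
) -> tuple[dict[str, ColorCountVector], dict[str, int]]:
    """Parse, strip hydrogens and color every molecule.

    Returns (color-count vectors, non-hydrogen atom counts) keyed by
    metabolite id.
    """
    vectors: dict[str, ColorCountVector] = {}
    atom_counts: dict[str, int] = {}
    for mid, text in molfile_texts.items():
        g = strip_hydrogens(parse_molfile(text, mid))
        vec = count_colors(g, max_radius)
        vectors[mid] = vec
        atom_counts[mid] = vec.n_atoms()
    return vectors, atom_counts


def build_dataset(
    vectors: Mapping[str, ColorCountVector],
    hierarchy: PathwayHierarchy,
    spec: DatasetSpec,
    atom_counts: Mapping[str, int] | None = None,
    exponential_normalization: bool = False,
) -> CrossJoinDataset:
    """Assemble the cross-join dataset for one level selection.

    Metabolite and pathway matrices keep separate vocabularies; each is
    bond-count normalized entry-wise, then zero/duplicate columns are
    dropped, then (optionally) min/max scaled feature-wise over the full
    assembled dataset.  Metabolites appearing in no selected pathway are
    excluded before the cross-join.
    """
    selected = select_pathways(hierarchy, spec)
    selected, universe = filter_by_size(selected, spec.min_pathway_size)
    missing = universe - set(vectors)
    if missing:
        raise KeyError(f"pathway members without parsed structures: {sorted(missing)[:5]}")

    met_vectors = {m: vectors[m] for m in sorted(universe)}
    met_matrix = dedupe_columns(
        bond_count_normalize_matrix(
            build_matrix(met_vectors), exponential=exponential_normalization
        )
    )
    membership = {p.pathway_id: p.members for p in selected}
    pw_vectors = aggregate_pathways(membership, met_vectors)
    pw_matrix = dedupe_columns(
        bond_count_normalize_matrix(
            build_matrix({p.pathway_id: pw_vectors[p.pathway_id] for p in selected}),
            exponential=exponential_normalization,
        )
    )
    if spec.scaled:
        # min/max over the assembled entries equals min/max over each block's
        # rows: every metabolite row and every pathway row appears in entries
        met_matrix = minmax_apply(met_matrix, minmax_fit(met_matrix))
        pw_matrix = minmax_apply(pw_matrix, minmax_fit(pw_matrix))
    counts = {m: (atom_counts or {}).get(m, vectors[m].n_atoms()) for m in universe}
    return cross_join(met_matrix, pw_matrix, selected, counts)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    n_metabolites: int = 0
    n_pathways_l2: int = 0
    n_pathways_l3: int = 0
    n_entries: int = 0
    metabolite_width: int = 0
    pathway_width: int = 0
    input_width: int = 0
    dataset_hash: str = ""
    stage_seconds: dict = field(default_factory=dict)
    stages_complete: list = field(default_factory=list)

    def validate(self) -> None:
        n_pw = self.n_pathways_l2 + self.n_pathways_l3
        if self.n_entries != self.n_metabolites * n_pw:
            raise ValueError(
                f"manifest entry count {self.n_entries} != "
                f"{self.n_metabolites} x {n_pw}"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": {},
    "dataset": {"level_selection": "combined", "scaled": True, "min_pathway_size": 0},
    "normalization": {"exponential": False},
    "scaling": {"per_fold": False},
    "model": {},
    "evaluation": {"n_iterations": 3, "n_folds": 10},
}


def load_config(path: str | Path | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def run_pipeline(config: dict, out_dir: str | Path, molfiles: Mapping[str, str] | None = None,
                 hierarchy: PathwayHierarchy | None = None) -> RunManifest:
    """Execute featurize -> build-dataset -> evaluate -> analyze.

    When ``molfiles``/``hierarchy`` are not given, the configured synthetic
    universe is generated (or molfile_dir/hierarchy_tsv paths from the
    config are loaded).  Writes metric tables, the pathway report, the
    analysis tables and the run manifest under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(config=config, seed=seed)

    def _stage(name: str):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    def _done(name: str, t0: float) -> None:
        manifest.stage_seconds[name] = round(time.perf_counter() - t0, 3)
        manifest.stages_complete.append(name)
        logger.info("stage %s done in %.2fs", name, manifest.stage_seconds[name])

    try:
        t0 = _stage("inputs")
        if molfiles is None or hierarchy is None:
            paths = config.get("inputs", {})
            if paths.get("molfile_dir"):
                molfiles = load_molfile_dir(paths["molfile_dir"])
                hierarchy = PathwayHierarchy.from_tsv(paths["hierarchy_tsv"])
            else:
                from .synthetic import generate_universe

                spec = SyntheticSpec(**{**config.get("synthetic", {}), "seed": seed})
                molfiles, hierarchy = generate_universe(spec)
        _done("inputs", t0)

        t0 = _stage("featurize")
        vectors, atom_counts = featurize_molecules(molfiles)
        _done("featurize", t0)

        t0 = _stage("build-dataset")
        dspec = DatasetSpec(**config.get("dataset", {}))
        dataset = build_dataset(
            vectors,
            hierarchy,
            dspec,
            atom_counts,
            exponential_normalization=config.get("normalization", {}).get("exponential", False),
        )
        manifest.n_metabolites = dataset.n_metabolites
        manifest.n_pathways_l2 = sum(1 for p in dataset.pathways if p.level.value == "L2")
        manifest.n_pathways_l3 = sum(1 for p in dataset.pathways if p.level.value == "L3")
        manifest.n_entries = dataset.n_entries
        manifest.metabolite_width = dataset.metabolite_matrix.width
        manifest.pathway_width = dataset.pathway_matrix.width
        manifest.input_width = dataset.input_width
        manifest.dataset_hash = dataset.content_hash()
        manifest.validate()
        _done("build-dataset", t0)

        t0 = _stage("evaluate")
        model = PathwayAssociationMLP(
            dataset, MLPConfig(**{**config.get("model", {}), "seed": seed})
        )
        ev_cfg = config.get("evaluation", {})
        cv = RepeatedCV(
            model,
            n_iterations=int(ev_cfg.get("n_iterations", 3)),
            base_seed=seed,
            n_folds=int(ev_cfg.get("n_folds", 10)),
            scale_per_fold=config.get("scaling", {}).get("per_fold", False),
        )
        results = cv.run()
        results.iteration_metrics.to_csv(out_dir / "iteration_metrics.tsv", sep="\t", index=False)
        results.pathway_table().to_csv(out_dir / "pathway_report.tsv", sep="\t", index=False)
        _done("evaluate", t0)

        t0 = _stage("analyze")
        results.size_correlations().to_csv(out_dir / "size_correlations.tsv", sep="\t", index=False)
        sizes = sorted({p.size_metabolites for p in results.pathway_reports})
        thresholds = [0] + sizes
        results.size_threshold_curve(thresholds).to_csv(
            out_dir / "size_threshold_curve.tsv", sep="\t", index=False
        )
        mean, sd = results.mean_mcc()
        summary = {
            "mean_mcc": mean,
            "sd_mcc": sd,
            "overall_mcc": results.overall_mcc(),
            "level_mcc": {
                lvl: results.level_mcc(lvl)
                for lvl in ("L2", "L3")
                if any(p.level == lvl for p in results.pathway_reports)
            },
        }
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        _done("analyze", t0)
    except Exception:
        manifest.to_json(out_dir / "manifest.json")
        logger.exception(
            "pipeline aborted; completed stages: %s", manifest.stages_complete
        )
        raise
    manifest.to_json(out_dir / "manifest.json")
    return manifest
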
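"""The single binary MLP classifier over concatenated metabolite+pathway
features.

`PathwayAssociationMLP` is the model object built from a
:class:`~pathassoc.dataset.CrossJoinDataset`; `fit()` returns an
:class:`MLPFitResult` carrying the trained parameters, the loss history and
prediction methods.  The network is a stack of fully connected ReLU layers
with a single sigmoid output trained on binary cross-entropy with Adam in
mini-batches; training is deterministic given the seed (single-threaded
backend).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.neural_network import MLPClassifier

__all__ = [
    "MLPConfig",
    "PathwayAssociationMLP",
    "MLPFitResult",
    "build_model",
    "train",
    "predict_scores",
    "classify",
    "tune",
]


@dataclass(frozen=True)
class MLPConfig:
    """Desk-scale defaults: 2 hidden ReLU layers of 64 units, Adam with
    mini-batches of 256, at most 100 epochs.  ``early_stop_patience`` > 0
    enables early stopping on a 5% validation slice of the training fold;
    it is off by default because that slice is unreliably small on
    desk-scale datasets.  ``classification_threshold`` converts the sigmoid
    output to a 0/1 label (score >= threshold -> 1)."""

    hidden_size: int = 64
    n_hidden_layers: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 100
    early_stop_patience: int = 0
    classification_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.classification_threshold < 1.0):
            raise ValueError("classification_threshold must lie strictly in (0, 1)")
        if self.hidden_size < 1 or self.n_hidden_layers < 1:
            raise ValueError("hidden_size and n_hidden_layers must be positive")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("learning_rate, batch_size, max_epochs must be positive")
        if self.early_stop_patience < 0:
            raise ValueError("early_stop_patience must be nonnegative")


class TrainingError(RuntimeError):
    pass


def _make_estimator(
    input_width: int, config: MLPConfig, n_samples: int | None = None
) -> MLPClassifier:
    batch = config.batch_size if n_samples is None else min(config.batch_size, n_samples)
    return MLPClassifier(
        hidden_layer_sizes=(config.hidden_size,) * config.n_hidden_layers,
        activation="relu",
        solver="adam",
        learning_rate_init=config.learning_rate,
        batch_size=batch,
        max_iter=config.max_epochs,
        early_stopping=config.early_stop_patience > 0,
        n_iter_no_change=max(config.early_stop_patience, 1),
        validation_fraction=0.05,
        random_state=config.seed,
        alpha=1e-4,
    )


@dataclass
class TrainedModel:
    """Parameter state of one (possibly untrained) network."""

    estimator: MLPClassifier
    input_width: int
    config: MLPConfig
    loss_history: list[float] = field(default_factory=list)
    fitted: bool = False

    def n_parameters(self) -> int:
        """Total weights + biases of the architecture."""
        sizes = (
            [self.input_width]
            + [self.config.hidden_size] * self.config.n_hidden_layers
            + [1]
        )
        return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))


def build_model(input_width: int, config: MLPConfig) -> TrainedModel:
    """Instantiate the architecture (untrained); parameters are initialized
    from config.seed when training starts."""
    if input_width < 1:
        raise ValueError("input_width must be >= 1")
    return TrainedModel(_make_estimator(input_width, config), input_width, config)


def train(
    model: TrainedModel,
    features: np.ndarray,
    labels: np.ndarray,
    config: MLPConfig | None = None,
) -> TrainedModel:
    """Fit the network on (features, labels) minimizing binary cross-entropy.

    The training set must contain both classes.  The per-epoch loss curve is
    recorded; a non-finite loss raises with the epoch index.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels).ravel()
    if features.shape[1] != model.input_width:
        raise ValueError(
            f"feature width {features.shape[1]} does not match model input "
            f"width {model.input_width}"
        )
    if len(np.unique(labels)) < 2:
        raise TrainingError("training set contains a single class")
    cfg = config or model.config
    if cfg != model.config:
        model = build_model(model.input_width, cfg)
    if cfg.batch_size > len(labels):  # sklearn clips with a warning otherwise
        model.estimator = _make_estimator(model.input_width, cfg, n_samples=len(labels))
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        model.estimator.fit(features, labels)
    model.loss_history = [float(x) for x in model.estimator.loss_curve_]
    for epoch, loss in enumerate(model.loss_history):
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite training loss at epoch {epoch}")
    model.fitted = True
    return model


def predict_scores(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Sigmoid output in [0, 1] for each entry row."""
    features = np.asarray(features, dtype=np.float64)
    if not model.fitted:
        raise TrainingError("model has not been trained")
    if features.shape[1] != model.input_width:
        raise ValueError(
            f"feature width {features.shape[1]} does not match model input "
            f"width {model.input_width}"
        )
    pos_col = int(np.flatnonzero(model.estimator.classes_ == 1)[0])
    return model.estimator.predict_proba(features)[:, pos_col]


def classify(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Binary labels from scores; a score exactly at the threshold is 1."""
    return (np.asarray(scores) >= threshold).astype(np.int8)


# ---------------------------------------------------------------------------
# statsmodels-style wrapper
# ---------------------------------------------------------------------------


class PathwayAssociationMLP:
    """Model object: an MLP binary classifier bound to a cross-join dataset.

    Parameters
    ----------
    dataset : CrossJoinDataset
        The assembled metabolite x pathway entries.
    config : MLPConfig, optional
        Architecture and optimization settings.
    """

    def __init__(self, dataset, config: MLPConfig | None = None) -> None:
        self.dataset = dataset
        self.config = config or MLPConfig()

    @classmethod
    def from_dataset(cls, dataset, **config_kwargs) -> "PathwayAssociationMLP":
        return cls(dataset, MLPConfig(**config_kwargs))

    def fit(self, entry_indices: np.ndarray | None = None) -> "MLPFitResult":
        """Train on the given entries (all entries when None)."""
        idx = (
            np.arange(self.dataset.n_entries)
            if entry_indices is None
            else np.asarray(entry_indices)
        )
        tm = build_model(self.dataset.input_width, self.config)
        tm = train(tm, self.dataset.features(idx), self.dataset.labels[idx])
        return MLPFitResult(self, tm, idx)


class MLPFitResult:
    """Results of one training run: trained parameters, loss history, and
    prediction methods over dataset entries."""

    def __init__(self, model: PathwayAssociationMLP, trained: TrainedModel, train_idx: np.ndarray):
        self.model = model
        self.trained = trained
        self.train_indices = train_idx

    @property
    def loss_history(self) -> list[float]:
        return self.trained.loss_history

    def predict_scores(self, entry_indices: np.ndarray) -> np.ndarray:
        return predict_scores(self.trained, self.model.dataset.features(np.asarray(entry_indices)))

    def predict(self, entry_indices: np.ndarray) -> np.ndarray:
        return classify(
            self.predict_scores(entry_indices), self.model.config.classification_threshold
        )

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Pathway association MLP — fit summary",
            "=" * 44,
            f"entries trained        {len(self.train_indices):>12,}",
            f"input width            {self.trained.input_width:>12,}",
            f"hidden layers          {cfg.n_hidden_layers:>12}",
            f"hidden size            {cfg.hidden_size:>12}",
            f"parameters             {self.trained.n_parameters():>12,}",
            f"epochs run             {len(self.loss_history):>12}",
            f"final training loss    {self.loss_history[-1]:>12.5f}",
            f"classification thr.    {cfg.classification_threshold:>12.2f}",
        ]
        return "\n".join(lines)


def tune(
    config_space: Mapping[str, Sequence],
    dataset,
    budget: int,
    seed: int = 0,
    n_folds: int = 10,
) -> tuple[MLPConfig, list[dict]]:
    """Random search over the config space; each trial is scored by MCC on
    one held-out stratified fold.  Returns (best config, trial log)."""
    from .dataset import stratified_split
    from .evaluation import confusion, mcc

    if budget < 1:
        raise ValueError("budget must be >= 1 trials")
    rng = np.random.default_rng(seed)
    plan = stratified_split(dataset.labels, n_folds=n_folds, seed=seed)
    train_idx, test_idx = plan.train_indices(), plan.test_indices()
    trials: list[dict] = []
    best: tuple[float, MLPConfig] | None = None
    for t in range(budget):
        sampled = {k: v[int(rng.integers(len(v)))] for k, v in config_space.items()}
        cfg = replace(MLPConfig(seed=seed + t), **sampled)
        tm = train(
            build_model(dataset.input_width, cfg),
            dataset.features(train_idx),
            dataset.labels[train_idx],
        )
        preds = classify(
            predict_scores(tm, dataset.features(test_idx)), cfg.classification_threshold
        )
        score = mcc(confusion(dataset.labels[test_idx], preds))
        trials.append({"trial": t, "config": sampled, "mcc": score})
        if best is None or score > best[0]:
            best = (score, cfg)
    assert best is not None
    return best[1], trials
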
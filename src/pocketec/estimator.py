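"""Scikit-learn-style classifier over binding-pocket graphs.

:class:`GraphNetClassifier` follows the estimator protocol (``fit`` /
``predict`` / ``predict_proba`` / ``score``, ``get_params`` / ``set_params``)
so it composes with sklearn model selection; ``X`` is a list of
:class:`~pocketec.graph_build.ProteinGraph` rather than a feature matrix.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .eclabel import ECLabel
from .graph_build import ProteinGraph
from .nets import ModelConfig, build_model, save_checkpoint, softmax
from .train_eval import TrainConfig, train_model

__all__ = ["GraphNetClassifier"]


class GraphNetClassifier(BaseEstimator, ClassifierMixin):
    """EC classifier over localized 3D pocket graphs.

    Parameters mirror the underlying architectures: ``architecture`` selects
    distance-only continuous-filter message passing or directional
    (distance + angle) message passing.  Labels may be EC strings,
    :class:`ECLabel` objects, or plain class names; they define ``classes_``.

    Attributes (after ``fit``): ``classes_``, ``vocab_``, ``model_``,
    ``history_``, ``n_features_in_`` (node-type vocabulary size).
    """

    def __init__(
        self,
        architecture: str = "distances",
        embedding_dim: int = 128,
        hidden_dim: int = 128,
        n_filters: int = 128,
        n_interactions: int = 6,
        n_blocks: int = 4,
        n_rbf: int = 50,
        rbf_gamma: float = 10.0,
        cutoff: float = 15.0,
        max_neighbors: int = 32,
        dropout: float = 0.25,
        pooling: str = "sum",
        lr: float = 1e-3,
        batch_size: Optional[int] = None,
        max_epochs: int = 200,
        patience: int = 10,
        augment_amplitude: float = 0.05,
        oversample: bool = False,
        class_weighting: str = "inverse",
        random_state: int = 0,
    ):
        self.architecture = architecture
        self.embedding_dim = embedding_dim
        self.hidden_dim = hidden_dim
        self.n_filters = n_filters
        self.n_interactions = n_interactions
        self.n_blocks = n_blocks
        self.n_rbf = n_rbf
        self.rbf_gamma = rbf_gamma
        self.cutoff = cutoff
        self.max_neighbors = max_neighbors
        self.dropout = dropout
        self.pooling = pooling
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.augment_amplitude = augment_amplitude
        self.oversample = oversample
        self.class_weighting = class_weighting
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _n_node_types(self, X: Sequence[ProteinGraph]) -> int:
        # residue graphs use the 21-class vocabulary, atom graphs the 31-class
        resolution = X[0].resolution
        base = 21 if resolution == "residue" else 31
        return max(base, int(max(g.node_types.max() for g in X if g.n_nodes)) + 1)

    def fit(self, X: Sequence[ProteinGraph], y: Sequence,
            X_val: Optional[Sequence[ProteinGraph]] = None,
            y_val: Optional[Sequence] = None) -> "GraphNetClassifier":
        X = list(X)
        if not X:
            raise ValueError("empty training set")
        y_str = np.array([str(v) for v in y])
        if len(y_str) != len(X):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y_str)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        self.vocab_ = [ECLabel.parse(c) for c in self.classes_]
        self.n_features_in_ = self._n_node_types(X)

        cfg = ModelConfig(
            architecture=self.architecture,
            n_classes=len(self.classes_),
            n_node_types=self.n_features_in_,
            embedding_dim=self.embedding_dim,
            hidden_dim=self.hidden_dim,
            n_filters=self.n_filters,
            n_interactions=self.n_interactions,
            n_blocks=self.n_blocks,
            n_rbf=self.n_rbf,
            rbf_gamma=self.rbf_gamma,
            cutoff=self.cutoff,
            max_neighbors=self.max_neighbors,
            dropout=self.dropout,
            pooling=self.pooling,
        )
        self.model_ = build_model(cfg, seed=self.random_state)

        train_graphs = [
            self._with_label(g, class_index[c]) for g, c in zip(X, y_str)
        ]
        val_graphs = None
        if X_val is not None:
            yv = np.array([str(v) for v in y_val])
            unseen = set(yv) - set(self.classes_)
            if unseen:
                raise ValueError(f"validation labels outside the training vocabulary: {unseen}")
            val_graphs = [self._with_label(g, class_index[c]) for g, c in zip(X_val, yv)]

        tcfg = TrainConfig(
            lr=self.lr,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            augment_amplitude=self.augment_amplitude,
            oversample=self.oversample,
            class_weighting=self.class_weighting,
            seed=self.random_state,
        )
        self.history_ = train_model(self.model_, train_graphs, val_graphs, tcfg)
        return self

    @staticmethod
    def _with_label(g: ProteinGraph, label: int) -> ProteinGraph:
        import dataclasses

        return dataclasses.replace(g, label=label)

    # ------------------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("this GraphNetClassifier instance is not fitted yet")

    def decision_function(self, X: Sequence[ProteinGraph]) -> np.ndarray:
        self._check_fitted()
        return self.model_.logits(list(X))

    def predict_proba(self, X: Sequence[ProteinGraph]) -> np.ndarray:
        return softmax(self.decision_function(X), axis=1)

    def predict(self, X: Sequence[ProteinGraph]) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def predict_with_confidence(self, X: Sequence[ProteinGraph]) -> list[tuple[ECLabel, float]]:
        """Per-graph (EC label, softmax confidence) pairs."""
        proba = self.predict_proba(X)
        idx = np.argmax(proba, axis=1)
        return [(self.vocab_[i], float(p[i])) for i, p in zip(idx, proba)]

    def save(self, path, scheme_version: str = "") -> None:
        self._check_fitted()
        save_checkpoint(path, self.model_, self.vocab_, scheme_version)
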
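"""Training of PRDIS-specific classifiers.

Each specific predictor is a small feed-forward network with sigmoid
units — either a single-layer perceptron (inputs wired directly to one
output unit) or a network with one hidden layer of two nodes — trained
by stochastic gradient descent with momentum on a squared-error loss,
mirroring the classic WEKA MultilayerPerceptron configuration
(L = 0.3, M = 0.2, N = 500 epochs, no validation split).  Inputs are the
raw scores of the predictors whose disagreement defined the PRDIS set,
optionally extended with the three biological features.  Class imbalance
in the training folds is corrected with SMOTE before fitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .io_formats import MISSING, VariantRecord

__all__ = [
    "TrainingConfig",
    "SpecificModel",
    "build_feature_matrix",
    "smote_oversample",
    "train_specific_model",
    "predict",
]

FEATURE_NAMES = ("blosum62", "pssm_nat", "entropy")


@dataclass
class TrainingConfig:
    """Network architecture and optimisation settings.

    Defaults follow the WEKA MultilayerPerceptron conventions used to
    build the original specific predictors: learning rate L = 0.3,
    momentum M = 0.2, N = 500 epochs, validation fraction V = 0 (hence
    early stopping, with patience E, never triggers), seed S = 0.
    ``architecture`` is "no_hidden" (single-layer perceptron) or
    "hidden_2" (one hidden layer, two sigmoid nodes).  ``batch_size``
    groups gradient updates for speed; 1 reproduces per-instance
    updates.
    """

    architecture: str = "no_hidden"
    learning_rate: float = 0.3
    momentum: float = 0.2
    epochs: int = 500
    validation_fraction: float = 0.0
    seed: int = 0
    early_stop_patience: int = 20
    hidden_nodes: int = 0
    feature_set: str = "scores_only"  # or scores_plus_bio
    decision_threshold: float = 0.5
    smote_k: int = 5
    batch_size: int = 32

    def __post_init__(self):
        if self.architecture not in ("no_hidden", "hidden_2"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture == "hidden_2":
            self.hidden_nodes = 2
        elif self.hidden_nodes not in (0, None):
            raise ValueError("no_hidden architecture takes no hidden nodes")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision threshold must be in (0, 1)")
        if self.feature_set not in ("scores_only", "scores_plus_bio"):
            raise ValueError(f"unknown feature set {self.feature_set!r}")


def build_feature_matrix(
    records: Sequence[VariantRecord],
    combination: Sequence[str],
    feature_set: str = "scores_only",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Assemble (X, y, column_names) for a PRDIS record set.

    Columns are the combination's predictor scores in order, then — for
    ``scores_plus_bio`` — the (blosum62, pssm_nat, entropy) triple.
    Labels are 1 for pathogenic, 0 for neutral.  PRDIS membership
    guarantees every predictor produced an output, so a MISSING score is
    an invariant violation and raises.
    """
    names = list(combination) + (
        list(FEATURE_NAMES) if feature_set == "scores_plus_bio" else []
    )
    if not records:
        return np.empty((0, len(names))), np.empty((0,), dtype=int), names
    rows = []
    labels = []
    for rec in records:
        row = []
        for name in combination:
            value = rec.predictor_outputs.get(name, MISSING)
            if value is MISSING or not isinstance(value, (int, float)):
                raise ValueError(
                    f"{rec.replacement}: no numeric {name} score (PRDIS "
                    "records must carry outputs from every predictor)"
                )
            row.append(float(value))
        if feature_set == "scores_plus_bio":
            if rec.features is None:
                raise ValueError(
                    f"{rec.replacement}: biological features missing"
                )
            row.extend(float(v) for v in rec.features)
        rows.append(row)
        if rec.label == "pathogenic":
            labels.append(1)
        elif rec.label == "neutral":
            labels.append(0)
        else:
            raise ValueError(f"{rec.replacement}: unlabeled record")
    return np.asarray(rows, dtype=float), np.asarray(labels, dtype=int), names


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class to parity by convex interpolation.

    Each synthetic row is x + u (x_nn - x) with u ~ U[0, 1], x a minority
    row and x_nn one of its k nearest minority neighbours (Euclidean).
    Majority rows are returned untouched; the input arrays are never
    modified.  Applied to training folds only — never to test data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE needs exactly two classes present")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return X.copy(), y.copy()
    X_min = X[y == minority]
    if k > n_min - 1:
        warnings.warn(
            f"smote_k={k} exceeds minority size - 1; clamped to {max(n_min - 1, 1)}"
        )
        k = max(n_min - 1, 1)
    rng = np.random.default_rng(seed)
    if n_min == 1:
        # Degenerate: a single minority point can only replicate itself.
        synthetic = np.repeat(X_min, n_new, axis=0)
    else:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
        neighbours = nn.kneighbors(X_min, return_distance=False)[:, 1:]
        base = rng.integers(0, n_min, size=n_new)
        pick = rng.integers(0, neighbours.shape[1], size=n_new)
        u = rng.random(n_new)
        x0 = X_min[base]
        x1 = X_min[neighbours[base, pick]]
        synthetic = x0 + u[:, None] * (x1 - x0)
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=int)])
    return X_out, y_out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class SpecificModel:
    """A trained PRDIS-specific predictor.

    ``weights`` holds [W_out, b_out] for the no-hidden network (W_out of
    shape (d,)) or [W_hid, b_hid, W_out, b_out] with W_hid of shape
    (d, 2).  ``normalization`` stores per-feature (min, max) mapping raw
    inputs affinely onto [-1, 1].
    """

    combination: tuple
    feature_names: list
    weights: list
    normalization: tuple  # (mins, maxs) arrays
    config: TrainingConfig

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        mins, maxs = self.normalization
        span = np.where(maxs > mins, maxs - mins, 1.0)
        return 2.0 * (X - mins) / span - 1.0

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Network output in [0, 1] for raw (unnormalised) feature rows."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature columns"
            )
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values")
        Z = self._normalize(X)
        if self.config.architecture == "no_hidden":
            w, b = self.weights
            return _sigmoid(Z @ w + b)
        W_h, b_h, w_o, b_o = self.weights
        H = _sigmoid(Z @ W_h + b_h)
        return _sigmoid(H @ w_o + b_o)

    def predict_records(
        self, records: Sequence[VariantRecord]
    ) -> tuple[np.ndarray, list]:
        """(scores, calls) for variant records carrying the model's inputs."""
        X, _, _ = _matrix_without_labels(
            records, self.combination, self.config.feature_set
        )
        scores = self.predict_scores(X)
        calls = [
            "pathogenic" if s >= self.config.decision_threshold else "neutral"
            for s in scores
        ]
        return scores, calls

    def to_json(self) -> str:
        payload = {
            "combination": list(self.combination),
            "feature_names": list(self.feature_names),
            "weights": [np.asarray(w).tolist() for w in self.weights],
            "normalization": [np.asarray(a).tolist() for a in self.normalization],
            "config": asdict(self.config),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SpecificModel":
        payload = json.loads(text)
        return cls(
            combination=tuple(payload["combination"]),
            feature_names=list(payload["feature_names"]),
            weights=[np.asarray(w, dtype=float) for w in payload["weights"]],
            normalization=tuple(
                np.asarray(a, dtype=float) for a in payload["normalization"]
            ),
            config=TrainingConfig(**payload["config"]),
        )


def _matrix_without_labels(records, combination, feature_set):
    """Like build_feature_matrix but tolerating unlabeled records."""
    labelled = [
        r if r.label in ("pathogenic", "neutral") else r.copy(label="neutral")
        for r in records
    ]
    return build_feature_matrix(labelled, combination, feature_set)


def train_specific_model(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig | None = None,
    combination: Sequence[str] = (),
    feature_names: Sequence[str] | None = None,
) -> SpecificModel:
    """Fit the sigmoid network by mini-batch SGD with momentum.

    Inputs are affinely normalised per feature to [-1, 1] using the
    training ranges; weights start at small seeded uniform values; the
    squared-error loss is minimised for exactly ``config.epochs`` passes
    (no validation split, hence no early stopping).  Deterministic under
    a fixed seed.
    """
    config = config or TrainingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if not np.isfinite(X).all():
        bad = np.where(~np.isfinite(X).all(axis=0))[0]
        names = feature_names or [f"col{j}" for j in range(X.shape[1])]
        raise ValueError(
            f"non-finite values in feature column(s): "
            f"{[names[j] for j in bad]}"
        )
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValueError("need at least two rows per class")
    n, d = X.shape
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    span = np.where(maxs > mins, maxs - mins, 1.0)
    Z = 2.0 * (X - mins) / span - 1.0

    rng = np.random.default_rng(config.seed)
    lr, mom = config.learning_rate, config.momentum
    h = config.hidden_nodes if config.architecture == "hidden_2" else 0

    if h == 0:
        w = rng.uniform(-0.05, 0.05, size=d)
        b = rng.uniform(-0.05, 0.05)
        vw = np.zeros(d)
        vb = 0.0
    else:
        W_h = rng.uniform(-0.05, 0.05, size=(d, h))
        b_h = rng.uniform(-0.05, 0.05, size=h)
        w_o = rng.uniform(-0.05, 0.05, size=h)
        b_o = rng.uniform(-0.05, 0.05)
        vWh = np.zeros_like(W_h)
        vbh = np.zeros_like(b_h)
        vwo = np.zeros_like(w_o)
        vbo = 0.0

    batch = max(1, min(config.batch_size, n))
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            Zb, yb = Z[idx], y[idx]
            m = len(idx)
            if h == 0:
                p = _sigmoid(Zb @ w + b)
                # d(squared error)/dz = (p - y) * p * (1 - p)
                delta = (p - yb) * p * (1.0 - p)
                gw = Zb.T @ delta / m
                gb = delta.mean()
                vw = mom * vw - lr * gw
                vb = mom * vb - lr * gb
                w = w + vw
                b = b + vb
            else:
                A = _sigmoid(Zb @ W_h + b_h)
                p = _sigmoid(A @ w_o + b_o)
                delta_o = (p - yb) * p * (1.0 - p)
                g_wo = A.T @ delta_o / m
                g_bo = delta_o.mean()
                delta_h = np.outer(delta_o, w_o) * A * (1.0 - A)
                g_Wh = Zb.T @ delta_h / m
                g_bh = delta_h.mean(axis=0)
                vwo = mom * vwo - lr * g_wo
                vbo = mom * vbo - lr * g_bo
                vWh = mom * vWh - lr * g_Wh
                vbh = mom * vbh - lr * g_bh
                w_o = w_o + vwo
                b_o = b_o + vbo
                W_h = W_h + vWh
                b_h = b_h + vbh

    weights = [w, b] if h == 0 else [W_h, b_h, w_o, b_o]
    names = list(feature_names) if feature_names is not None else [
        f"col{j}" for j in range(d)
    ]
    return SpecificModel(
        combination=tuple(combination),
        feature_names=names,
        weights=weights,
        normalization=(mins, maxs),
        config=config,
    )


def train_on_records(
    records: Sequence[VariantRecord],
    combination: Sequence[str],
    config: TrainingConfig | None = None,
    apply_smote: bool = True,
) -> SpecificModel:
    """Convenience wrapper: matrix assembly, SMOTE, then fitting."""
    config = config or TrainingConfig()
    X, y, names = build_feature_matrix(records, combination, config.feature_set)
    if apply_smote:
        X, y = smote_oversample(X, y, k=config.smote_k, seed=config.seed)
    return train_specific_model(
        X, y, config, combination=combination, feature_names=names
    )


def predict(
    model: SpecificModel, records: Sequence[VariantRecord]
) -> tuple[np.ndarray, list]:
    """Scores in [0, 1] and binary calls for a record collection."""
    return model.predict_records(records)
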
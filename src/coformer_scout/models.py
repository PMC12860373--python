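"""Feature ranking and the back-propagation suitability classifier.

Two stages of the screen live here. A Random-Forest importance ranking
(mean-decrease-impurity) reduces the descriptor universe to the most
informative features; it wraps scikit-learn's forest, seed-pinned. The
classifier itself is a small feed-forward network trained by error
back-propagation — one hidden layer of logistic units, a sigmoid output and
cross-entropy loss — written out explicitly so its gradients can be checked
against finite differences. With ~160 labeled examples a deeper
architecture would overfit; every hyperparameter is exposed.

Evaluation reports a 2x2 confusion matrix with accuracy, sensitivity and
specificity in percent, rounded half-up to one decimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .descriptors import CoformerFeaturizer, FeatureMatrix

__all__ = [
    "FeatureImportance",
    "RFConfig",
    "rank_features_rf",
    "select_top_features",
    "BPClassifier",
    "TrainingDivergenceError",
    "ConfusionMatrix",
    "evaluate",
    "bp_loss_and_grad",
    "save_model",
    "load_model",
]


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.X
    return np.asarray(X, dtype=float)


def _round1(x: float) -> float:
    """Round half-up to one decimal (87.17948... -> 87.2)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Random-Forest feature ranking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RFConfig:
    """Random-Forest hyperparameters for importance ranking."""

    n_trees: int = 100
    max_depth: int | None = None
    max_features: str | int | float = "sqrt"
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class FeatureImportance:
    """Descending (name, importance) ranking; importances sum to 1."""

    ranking: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        imps = [v for _, v in self.ranking]
        if any(v < 0 for v in imps):
            raise ValueError("importances must be non-negative")
        if imps and abs(sum(imps) - 1.0) > 1e-9:
            raise ValueError(f"importances must sum to 1, got {sum(imps)}")
        if any(imps[i] < imps[i + 1] for i in range(len(imps) - 1)):
            raise ValueError("ranking must be sorted descending")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.ranking)

    def as_dict(self) -> dict[str, float]:
        return dict(self.ranking)


def _base_feature(column: str) -> str:
    # hashed-encoding columns aggregate back to the single 'smiles_enc' feature
    return "smiles_enc" if column.startswith("smiles_enc_") else column


def rank_features_rf(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[int],
    cfg: RFConfig = RFConfig(),
    columns: Sequence[str] | None = None,
    aggregate_encoding: bool = True,
) -> FeatureImportance:
    """Rank features by mean-decrease-impurity importance.

    Importances are normalized to sum to 1 and sorted descending; exact ties
    break toward the lower input column index. With ``aggregate_encoding``
    the per-bucket SMILES-encoding columns are summed into one
    ``smiles_enc`` entry so the ranking speaks the five-variable vocabulary
    of the screen.
    """
    if columns is None:
        if not isinstance(X, FeatureMatrix):
            raise ValueError("columns required when X is a bare array")
        columns = X.columns
    Xa = _as_array(X)
    ya = np.asarray(y, dtype=int)
    if np.unique(ya).size < 2:
        raise ValueError("need at least two classes to rank features")
    if np.isnan(Xa).any():
        raise ValueError("X contains missing values")

    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        max_features=cfg.max_features,
        bootstrap=cfg.bootstrap,
        random_state=cfg.seed,
    )
    forest.fit(Xa, ya)
    raw = forest.feature_importances_
    total = raw.sum()
    if total > 0:
        raw = raw / total

    order_index: dict[str, int] = {}
    agg: dict[str, float] = {}
    for j, col in enumerate(columns):
        name = _base_feature(col) if aggregate_encoding else col
        if name not in agg:
            agg[name] = 0.0
            order_index[name] = j
        agg[name] += float(raw[j])

    ranked = sorted(agg.items(), key=lambda kv: (-kv[1], order_index[kv[0]]))
    return FeatureImportance(ranking=tuple(ranked))


def select_top_features(imp: FeatureImportance, k: int) -> tuple[str, ...]:
    """First ``k`` feature names in importance order."""
    if k > len(imp.ranking):
        raise ValueError(f"k={k} exceeds number of features {len(imp.ranking)}")
    return imp.names[:k]


# ---------------------------------------------------------------------------
# Back-propagation network
# ---------------------------------------------------------------------------


class TrainingDivergenceError(RuntimeError):
    """Training loss became non-finite; carries the loss trace so far."""

    def __init__(self, trace: list[float]):
        super().__init__(f"training diverged at epoch {len(trace)}")
        self.loss_trace = trace


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(weights, biases, X):
    """Return the list of layer activations, input first, output last."""
    acts = [X]
    a = X
    for W, b in zip(weights, biases):
        a = _sigmoid(a @ W + b)
        acts.append(a)
    return acts


def bp_loss_and_grad(weights, biases, X, y):
    """Mean cross-entropy loss and its gradients w.r.t. every weight/bias.

    The network is logistic throughout with a single sigmoid output unit;
    the output-layer delta therefore reduces to ``p - y``. Exposed at module
    level so gradients can be verified against central finite differences.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    n = X.shape[0]
    acts = _forward(weights, biases, X)
    p = acts[-1].reshape(-1)
    eps = 1e-12
    loss = -float(np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))

    grads_w = [np.zeros_like(W) for W in weights]
    grads_b = [np.zeros_like(b) for b in biases]
    delta = (p - y).reshape(-1, 1) / n
    for layer in range(len(weights) - 1, -1, -1):
        grads_w[layer] = acts[layer].T @ delta
        grads_b[layer] = delta.sum(axis=0)
        if layer > 0:
            a_prev = acts[layer]
            delta = (delta @ weights[layer].T) * a_prev * (1 - a_prev)
    return loss, grads_w, grads_b


class BPClassifier:
    """Binary suitability classifier: a small back-propagation network.

    scikit-learn estimator conventions apply: hyperparameters are
    constructor arguments, :meth:`fit` learns ``coefs_``/``intercepts_`` and
    records ``loss_curve_``, and :meth:`predict_proba`/:meth:`predict`
    operate on the (already z-scored) design matrix.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Hidden-layer widths; default one layer of 16 logistic units.
    learning_rate : float
        Gradient-descent step size.
    momentum : float
        Classical momentum coefficient.
    epochs : int
        Maximum number of passes; each epoch is one full-batch gradient step
        unless ``batch_size`` is set.
    batch_size : int or None
        Mini-batch size (``None`` trains full batch). Batches are
        reshuffled each epoch from the estimator's own generator, so
        training stays deterministic under ``random_state``.
    patience : int or None
        If set, hold out ``validation_fraction`` of the training rows and
        stop after this many epochs without validation-loss improvement,
        restoring the best snapshot.
    validation_fraction : float
        Fraction of the training set used for early stopping.
    threshold : float
        Decision threshold on the predicted probability.
    random_state : int
        Seed for weight initialization, shuffling and the validation split.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (16,),
        learning_rate: float = 0.05,
        momentum: float = 0.9,
        epochs: int = 2000,
        batch_size: int | None = 16,
        patience: int | None = None,
        validation_fraction: float = 0.1,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.hidden_layer_sizes = tuple(hidden_layer_sizes)
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.random_state = random_state

    _PARAM_NAMES = (
        "hidden_layer_sizes",
        "learning_rate",
        "momentum",
        "epochs",
        "batch_size",
        "patience",
        "validation_fraction",
        "threshold",
        "random_state",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._PARAM_NAMES}

    def set_params(self, **params) -> "BPClassifier":
        for key, val in params.items():
            if key not in self._PARAM_NAMES:
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, val)
        return self

    # -- fitting -----------------------------------------------------------

    def _init_weights(self, n_features: int, rng: np.random.Generator):
        sizes = (n_features, *self.hidden_layer_sizes, 1)
        weights, biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        # zero output layer: an untrained net predicts exactly 0.5
        weights[-1][:] = 0.0
        return weights, biases

    def fit(self, X, y) -> "BPClassifier":
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        Xa = _as_array(X)
        ya = np.asarray(y, dtype=float).reshape(-1)
        if Xa.ndim != 2 or Xa.shape[0] != ya.shape[0]:
            raise ValueError("X and y shapes disagree")
        if np.isnan(Xa).any():
            raise ValueError("X contains NaN")
        if not set(np.unique(ya)) <= {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")

        rng = np.random.default_rng(self.random_state)
        weights, biases = self._init_weights(Xa.shape[1], rng)
        vel_w = [np.zeros_like(W) for W in weights]
        vel_b = [np.zeros_like(b) for b in biases]

        if self.patience is not None and 0 < self.validation_fraction < 1 and Xa.shape[0] >= 5:
            n_val = max(1, int(round(self.validation_fraction * Xa.shape[0])))
            perm = rng.permutation(Xa.shape[0])
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_tr, y_tr = Xa[tr_idx], ya[tr_idx]
            X_val, y_val = Xa[val_idx], ya[val_idx]
        else:
            X_tr, y_tr = Xa, ya
            X_val = y_val = None

        loss_trace: list[float] = []
        val_trace: list[float] = []
        best_val = np.inf
        best_snapshot = None
        stall = 0

        for _epoch in range(self.epochs):
            if self.batch_size is None:
                batches = [(X_tr, y_tr)]
            else:
                order = rng.permutation(X_tr.shape[0])
                batches = [
                    (X_tr[order[s : s + self.batch_size]], y_tr[order[s : s + self.batch_size]])
                    for s in range(0, X_tr.shape[0], self.batch_size)
                ]
            for Xb, yb in batches:
                _, gw, gb = bp_loss_and_grad(weights, biases, Xb, yb)
                for i in range(len(weights)):
                    vel_w[i] = self.momentum * vel_w[i] - self.learning_rate * gw[i]
                    vel_b[i] = self.momentum * vel_b[i] - self.learning_rate * gb[i]
                    weights[i] = weights[i] + vel_w[i]
                    biases[i] = biases[i] + vel_b[i]
            epoch_loss, _, _ = bp_loss_and_grad(weights, biases, X_tr, y_tr)
            loss_trace.append(epoch_loss)
            if not np.isfinite(epoch_loss):
                raise TrainingDivergenceError(loss_trace)

            if X_val is not None:
                v_loss, _, _ = bp_loss_and_grad(weights, biases, X_val, y_val)
                val_trace.append(v_loss)
                if v_loss < best_val - 1e-12:
                    best_val = v_loss
                    best_snapshot = ([W.copy() for W in weights], [b.copy() for b in biases])
                    stall = 0
                else:
                    stall += 1
                    if stall >= self.patience:
                        break

        if best_snapshot is not None:
            weights, biases = best_snapshot

        self.coefs_ = weights
        self.intercepts_ = biases
        self.loss_curve_ = loss_trace
        self.validation_curve_ = val_trace
        self.best_validation_loss_ = float(best_val) if val_trace else None
        self.n_features_in_ = Xa.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    # -- inference ---------------------------------------------------------

    def _check_fitted_X(self, X) -> np.ndarray:
        if not hasattr(self, "coefs_"):
            raise RuntimeError("classifier is not fitted")
        Xa = _as_array(X)
        if Xa.ndim == 1:
            Xa = Xa.reshape(1, -1)
        if Xa.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {Xa.shape[1]} columns, model was trained with {self.n_features_in_}"
            )
        return Xa

    def predict_proba(self, X) -> np.ndarray:
        """Probability of suitability (class 1) for each row, in [0, 1]."""
        Xa = self._check_fitted_X(X)
        return _forward(self.coefs_, self.intercepts_, Xa)[-1].reshape(-1)

    def predict(self, X) -> np.ndarray:
        """Hard labels: probability >= threshold."""
        return (self.predict_proba(X) >= self.threshold).astype(int)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion counts with percent summaries (one decimal, half-up)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return _round1(100.0 * (self.tp + self.tn) / self.total)

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return _round1(100.0 * self.tp / pos) if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return _round1(100.0 * self.tn / neg) if neg else float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
        }


def evaluate(model: BPClassifier, X, y) -> ConfusionMatrix:
    """Confusion matrix of ``model`` on a labeled held-out set."""
    ya = np.asarray(y, dtype=int).reshape(-1)
    if ya.size == 0:
        raise ValueError("test set is empty")
    pred = model.predict(X)
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (ya == 1))),
        fp=int(np.sum((pred == 1) & (ya == 0))),
        fn=int(np.sum((pred == 0) & (ya == 1))),
        tn=int(np.sum((pred == 0) & (ya == 0))),
    )


# ---------------------------------------------------------------------------
# Persistence (model + featurizer in one JSON document)
# ---------------------------------------------------------------------------


def save_model(path: str | Path, model: BPClassifier, featurizer: CoformerFeaturizer) -> Path:
    """Persist a fitted classifier and its featurizer as a JSON document."""
    doc = {
        "format": "coformer-scout-bp-model",
        "version": 1,
        "config": {k: v for k, v in model.get_params().items()},
        "weights": [W.tolist() for W in model.coefs_],
        "biases": [b.tolist() for b in model.intercepts_],
        "loss_curve": list(model.loss_curve_),
        "featurizer": {
            "features": list(featurizer.features),
            "k": featurizer.k,
            "seed": featurizer.seed,
            "columns": list(featurizer.columns_),
            "means": featurizer.means_.tolist(),
            "sds": featurizer.sds_.tolist(),
        },
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8")
    return path


def load_model(path: str | Path) -> tuple[BPClassifier, CoformerFeaturizer]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format") != "coformer-scout-bp-model":
        raise ValueError(f"{path}: not a coformer-scout model document")
    cfg = dict(doc["config"])
    cfg["hidden_layer_sizes"] = tuple(cfg["hidden_layer_sizes"])
    model = BPClassifier(**cfg)
    model.coefs_ = [np.asarray(W, dtype=float) for W in doc["weights"]]
    model.intercepts_ = [np.asarray(b, dtype=float) for b in doc["biases"]]
    model.loss_curve_ = list(doc["loss_curve"])
    model.validation_curve_ = []
    model.n_features_in_ = model.coefs_[0].shape[0]
    model.classes_ = np.array([0, 1])

    fz_doc = doc["featurizer"]
    featurizer = CoformerFeaturizer(
        features=tuple(fz_doc["features"]), k=fz_doc["k"], seed=fz_doc["seed"]
    )
    featurizer.columns_ = tuple(fz_doc["columns"])
    featurizer.means_ = np.asarray(fz_doc["means"], dtype=float)
    featurizer.sds_ = np.asarray(fz_doc["sds"], dtype=float)
    return model, featurizer
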
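"""Motion estimation from simplified spatial patterns.

Each window's per-channel cluster indices are one-hot encoded
(``n_channels x K`` inputs) and fed to a small single-hidden-layer
feed-forward network trained by mini-batch SGD on cross-entropy
(scikit-learn's ``MLPClassifier`` under the hood, seeded). Per-window
decisions are then smoothed by a causal majority vote over a trailing
span of predictions. A nearest-centroid baseline on the same encoding
is included for sanity comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.neural_network import MLPClassifier

from .layout import ElectrodeLayout


@dataclass
class PatternDataset:
    """Labeled per-window cluster-index rows.

    ``rows``: (n_windows, n_channels) integers in [0, K-1];
    ``labels``: one motion name per window; ``classes``: the declared
    class set, in order (ties and column order follow it).
    """

    rows: np.ndarray
    labels: np.ndarray
    K: int
    classes: list[str] = field(default_factory=list)
    layout: ElectrodeLayout | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        self.labels = np.asarray(self.labels).astype(str)
        if self.rows.ndim != 2:
            raise ValueError(f"rows must be 2-D, got shape {self.rows.shape}")
        if self.labels.shape[0] != self.rows.shape[0]:
            raise ValueError("labels length must match number of rows")
        if np.any((self.rows < 0) | (self.rows >= self.K)):
            raise ValueError(f"cluster indices must lie in [0, {self.K - 1}]")
        if not self.classes:
            seen: dict[str, None] = {}
            for lab in self.labels:
                seen.setdefault(lab, None)
            self.classes = list(seen)
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} outside declared classes")

    @property
    def n_windows(self) -> int:
        return self.rows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.rows.shape[1]


def one_hot_encode(rows: np.ndarray, K: int) -> np.ndarray:
    """(n, n_channels) index rows -> (n, n_channels*K) binary matrix."""
    rows = np.atleast_2d(np.asarray(rows, dtype=int))
    n, c = rows.shape
    out = np.zeros((n, c * K))
    cols = rows + np.arange(c)[None, :] * K
    out[np.arange(n)[:, None], cols] = 1.0
    return out


@dataclass
class ClassifierModel:
    """A trained pattern classifier: one-hot encoding + small MLP.

    Stores the learned weight matrices explicitly so a saved model can
    be reloaded and applied with a plain forward pass. ``coefs`` /
    ``intercepts`` follow layer order (input->hidden..., hidden->out);
    hidden activation is logistic; the output layer is softmax (one
    logistic unit when only two classes are present, mirroring the
    trainer).
    """

    classes: list[str]
    K: int
    n_channels: int
    hidden: list[int]
    coefs: list[np.ndarray]
    intercepts: list[np.ndarray]
    loss_curve: list[float]
    seed: int
    epochs: int
    learning_rate: float

    def save(self, path) -> None:
        doc = {
            "classes": self.classes,
            "K": self.K,
            "n_channels": self.n_channels,
            "hidden": self.hidden,
            "coefs": [w.tolist() for w in self.coefs],
            "intercepts": [b.tolist() for b in self.intercepts],
            "loss_curve": [float(v) for v in self.loss_curve],
            "seed": self.seed,
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            classes=[str(c) for c in d["classes"]], K=int(d["K"]),
            n_channels=int(d["n_channels"]), hidden=[int(h) for h in d["hidden"]],
            coefs=[np.asarray(w, dtype=float) for w in d["coefs"]],
            intercepts=[np.asarray(b, dtype=float) for b in d["intercepts"]],
            loss_curve=[float(v) for v in d["loss_curve"]],
            seed=int(d["seed"]), epochs=int(d["epochs"]),
            learning_rate=float(d["learning_rate"]),
        )


def train_classifier(data: PatternDataset, hidden: list[int] | None = None,
                     epochs: int = 200, learning_rate: float = 0.01,
                     seed: int = 0, alpha: float = 1e-4,
                     batch_size: int = 200) -> ClassifierModel:
    """Train the pattern classifier; seeded, with a recorded loss curve."""
    hidden = list(hidden) if hidden else [20]
    classes = list(data.classes)
    present = sorted(set(data.labels))
    if len(present) < 2:
        raise ValueError("training requires at least 2 classes present in the data")
    counts = {c: int(np.sum(data.labels == c)) for c in present}
    thin = [c for c, n in counts.items() if n < 10]
    if thin:
        raise ValueError(f"need >= 10 examples per class; too few for {thin}")

    X = one_hot_encode(data.rows, data.K)
    clf = MLPClassifier(
        hidden_layer_sizes=tuple(hidden), activation="logistic", solver="sgd",
        alpha=alpha, batch_size=min(batch_size, len(X)),
        learning_rate_init=learning_rate, max_iter=epochs, shuffle=True,
        random_state=seed, tol=0.0, n_iter_no_change=epochs,
        momentum=0.9, nesterovs_momentum=True,
    )
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warning: epochs is a budget
        clf.fit(X, data.labels)
    if not np.all(np.isfinite(clf.loss_curve_)):
        bad = int(np.argmax(~np.isfinite(clf.loss_curve_)))
        raise ArithmeticError(f"non-finite training loss at epoch {bad}")

    # sklearn orders classes lexically; remap columns to the declared order
    model_classes = [c for c in classes if c in clf.classes_]
    return ClassifierModel(
        classes=model_classes, K=data.K, n_channels=data.n_channels,
        hidden=hidden, coefs=[np.asarray(w) for w in clf.coefs_],
        intercepts=[np.asarray(b) for b in clf.intercepts_],
        loss_curve=list(clf.loss_curve_), seed=seed, epochs=epochs,
        learning_rate=learning_rate,
    )


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict(model: ClassifierModel, rows: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Classify pattern rows.

    Returns ``(labels, scores)`` where ``scores`` is (n, n_classes) in
    the model's declared class order, rows summing to 1; the label is
    the argmax with ties toward the earlier class.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=int))
    if rows.shape[1] != model.n_channels:
        raise ValueError(
            f"rows have {rows.shape[1]} channels, model expects {model.n_channels}"
        )
    if np.any((rows < 0) | (rows >= model.K)):
        raise ValueError(f"cluster indices must lie in [0, {model.K - 1}]")
    h = one_hot_encode(rows, model.K)
    for w, b in zip(model.coefs[:-1], model.intercepts[:-1]):
        h = _logistic(h @ w + b)
    z = h @ model.coefs[-1] + model.intercepts[-1]

    sk_classes = sorted(model.classes)  # trainer's internal (lexical) order
    if len(sk_classes) == 2 and z.shape[1] == 1:
        p1 = _logistic(z)[:, 0]
        scores_sk = np.column_stack([1 - p1, p1])
    else:
        scores_sk = _softmax(z)
    # remap columns from lexical order to declared order
    col = {c: i for i, c in enumerate(sk_classes)}
    scores = scores_sk[:, [col[c] for c in model.classes]]
    labels = np.array([model.classes[i] for i in np.argmax(scores, axis=1)])
    return labels, scores


def nearest_centroid_baseline(train: PatternDataset, test_rows: np.ndarray
                              ) -> np.ndarray:
    """Nearest-centroid labels on one-hot encodings; a sanity baseline."""
    from sklearn.neighbors import NearestCentroid

    nc = NearestCentroid()
    nc.fit(one_hot_encode(train.rows, train.K), train.labels)
    return nc.predict(one_hot_encode(np.atleast_2d(test_rows), train.K))


def majority_vote(labels: np.ndarray, vote_span: int = 41,
                  classes: list[str] | None = None) -> np.ndarray:
    """Causal majority-vote smoothing of a per-window label stream.

    ``output[t]`` is the modal label of the trailing ``vote_span``
    predictions (fewer near the start). Ties keep the previous output;
    a tie at t=0 resolves to the earliest class in ``classes`` order
    (input order of first appearance when not given). Output length
    equals input length.
    """
    if vote_span < 1:
        raise ValueError(f"vote_span must be >= 1, got {vote_span}")
    if vote_span % 2 == 0:
        raise ValueError(f"vote_span must be odd, got {vote_span}")
    labels = np.asarray(labels).astype(str)
    if classes is None:
        seen: dict[str, None] = {}
        for lab in labels:
            seen.setdefault(lab, None)
        classes = list(seen)
    order = {c: i for i, c in enumerate(classes)}
    out = np.empty(len(labels), dtype=object)
    prev: str | None = None
    for t in range(len(labels)):
        window = labels[max(0, t - vote_span + 1) : t + 1]
        uniq, counts = np.unique(window, return_counts=True)
        top = counts.max()
        winners = [u for u, n in zip(uniq, counts) if n == top]
        if len(winners) == 1:
            choice = winners[0]
        elif prev is not None and prev in winners:
            choice = prev
        else:
            choice = min(winners, key=lambda c: order.get(c, len(order)))
        out[t] = choice
        prev = choice
    return out.astype(str)


@dataclass
class EvalReport:
    """Confusion matrix (rows = truth, cols = predicted) plus accuracies."""

    classes: list[str]
    confusion: np.ndarray
    accuracy: float
    per_class_accuracy: dict[str, float]

    def summary(self) -> str:
        lines = [f"overall accuracy: {self.accuracy:.4f}", "", "confusion (truth x predicted):"]
        header = " ".join(f"{c:>8}" for c in [""] + self.classes)
        lines.append(header)
        for i, c in enumerate(self.classes):
            lines.append(" ".join([f"{c:>8}"] + [f"{v:>8d}" for v in self.confusion[i]]))
        lines.append("")
        for c in self.classes:
            lines.append(f"accuracy[{c}]: {self.per_class_accuracy[c]:.4f}")
        return "\n".join(lines)


def evaluate(truth: np.ndarray, predicted: np.ndarray,
             classes: list[str] | None = None) -> EvalReport:
    """Confusion matrix and per-class / overall accuracy."""
    truth = np.asarray(truth).astype(str)
    predicted = np.asarray(predicted).astype(str)
    if len(truth) != len(predicted):
        raise ValueError(
            f"truth ({len(truth)}) and predicted ({len(predicted)}) lengths differ"
        )
    if classes is None:
        seen: dict[str, None] = {}
        for lab in np.concatenate([truth, predicted]):
            seen.setdefault(lab, None)
        classes = list(seen)
    else:
        outside = (set(truth) | set(predicted)) - set(classes)
        if outside:
            raise ValueError(f"labels {sorted(outside)} outside declared classes")
    cm = confusion_matrix(truth, predicted, labels=classes)
    acc = float(np.trace(cm)) / max(len(truth), 1)
    per_class = {}
    for i, c in enumerate(classes):
        row = cm[i].sum()
        per_class[c] = float(cm[i, i] / row) if row else float("nan")
    return EvalReport(list(classes), cm, acc, per_class)
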
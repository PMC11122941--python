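"""Prediction-MLP training with BCE or GFE loss, evaluation, and
conventional-classifier baselines.

The MLP halves the input width three times (382 -> 191 -> 95 -> 47 -> 1,
sigmoid output) and is trained with Adam (lr 5e-5, weight decay 1e-4) for
200 epochs on the balanced mixture of observed and generated records. Under
the GFE loss, the frozen GAN discriminator's reference accuracies Acc(D(P))
and Acc(D(N)) are refreshed once per epoch, and the observed-portion weight
W is recomputed per batch as (observed records in the batch) / (total
training records).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import nnet
from .gan import GanBundle, ReferenceSets, discriminator_accuracy
from .losses import GfeContext, gfe_loss_and_grad

__all__ = [
    "MlpSpec",
    "MlpModel",
    "EvalReport",
    "train_mlp",
    "evaluate",
    "train_baseline",
    "BASELINE_FAMILIES",
]


@dataclass
class MlpSpec:
    """Prediction network: input -> /2 -> /4 -> /8 -> 1 (sigmoid)."""

    input_dim: int = 382
    lr: float = 5e-5
    weight_decay: float = 1e-4
    epochs: int = 200
    batch_size: int = 64

    @property
    def hidden(self) -> tuple[int, int, int]:
        d = self.input_dim
        return (max(d // 2, 1), max(d // 4, 1), max(d // 8, 1))

    def build(self, rng: np.random.Generator) -> nnet.Sequential:
        layers: list[nnet.Layer] = []
        w_in = self.input_dim
        for w in self.hidden:
            layers += [nnet.Linear(w_in, w, rng), nnet.ReLU()]
            w_in = w
        layers += [nnet.Linear(w_in, 1, rng), nnet.Sigmoid()]
        return nnet.Sequential(layers)


@dataclass
class MlpModel:
    spec: MlpSpec
    net: nnet.Sequential

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.net.forward(np.asarray(X, dtype=float),
                                training=False).ravel()

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


@dataclass
class EvalReport:
    """Confusion matrix and the per-class / balanced accuracy summary.

    Balanced accuracy is the mean of the two per-class accuracies, i.e. the
    average of sensitivity (positive-class accuracy) and specificity; a
    constant predictor scores 0.5 when both classes are present.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    acc_positive: float | None
    acc_negative: float | None
    balanced_accuracy: float | None
    sensitivity: float | None
    accuracy: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    accP: list[float] = field(default_factory=list)
    accN: list[float] = field(default_factory=list)
    W: list[float] = field(default_factory=list)          # per batch
    accuracy: dict[str, list[float]] = field(default_factory=dict)


def evaluate(model, X: np.ndarray, y: np.ndarray) -> EvalReport:
    """Threshold-0.5 confusion matrix and accuracy summary.

    Works with MlpModel and with sklearn classifiers (anything exposing
    `predict`). A single-class evaluation set yields None for the absent
    class's accuracy and for balanced accuracy.
    """
    y = np.asarray(y).astype(int).ravel()
    if y.size == 0:
        raise ValueError("evaluation set is empty")
    pred = np.asarray(model.predict(X)).astype(int).ravel()
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    acc_pos = tp / n_pos if n_pos else None
    acc_neg = tn / n_neg if n_neg else None
    balanced = ((acc_pos + acc_neg) / 2.0
                if acc_pos is not None and acc_neg is not None else None)
    return EvalReport(tp, fp, tn, fn, acc_pos, acc_neg, balanced,
                      acc_pos, (tp + tn) / y.size)


def train_mlp(X: np.ndarray, y: np.ndarray, observed_mask: np.ndarray,
              loss: str = "bce", bundle: GanBundle | None = None,
              refs: ReferenceSets | None = None,
              spec: MlpSpec | None = None, seed: int = 0,
              eval_sets: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
              acc_override: tuple[float, float] | None = None,
              ) -> tuple[MlpModel, TrainingHistory]:
    """Mini-batch training of the prediction MLP with BCE or GFE loss.

    With `loss='gfe'`, `bundle` (frozen discriminator) and `refs` (observed
    positive/negative reference sets) are required; Acc(D(P)) / Acc(D(N))
    are refreshed at the start of each epoch and W per batch. Per-epoch
    accuracy curves are recorded for the training set and for every set in
    `eval_sets`. Deterministic given the seed; `acc_override` pins
    (accP, accN) for controlled experiments.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    observed_mask = np.asarray(observed_mask, dtype=bool).ravel()
    if loss not in ("bce", "gfe"):
        raise ValueError("loss must be 'bce' or 'gfe'")
    if loss == "gfe" and acc_override is None and (bundle is None or refs is None):
        raise ValueError("loss='gfe' requires a GanBundle and ReferenceSets")

    spec = spec or MlpSpec(input_dim=X.shape[1])
    if spec.input_dim != X.shape[1]:
        raise ValueError("spec input_dim does not match data width")
    rng = np.random.default_rng(seed)
    net = spec.build(rng)
    opt = nnet.Adam(net.params(), spec.lr, spec.weight_decay)
    model = MlpModel(spec, net)

    n = X.shape[0]
    total = float(n)
    hist = TrainingHistory(accuracy={"train": []})
    for name in (eval_sets or {}):
        hist.accuracy[name] = []

    for _ in range(spec.epochs):
        if loss == "gfe":
            if acc_override is not None:
                accP, accN = acc_override
            else:
                accP = discriminator_accuracy(bundle, refs.P, "real")
                accN = discriminator_accuracy(bundle, refs.N, "fake")
            hist.accP.append(accP)
            hist.accN.append(accN)
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            p = net.forward(X[idx], training=True).ravel()
            if loss == "bce":
                batch_loss, grad = nnet.bce_loss_and_grad(p, y[idx])
            else:
                W = float(observed_mask[idx].sum()) / total
                hist.W.append(W)
                ctx = GfeContext(accP, accN, W)
                batch_loss, grad = gfe_loss_and_grad(p, y[idx],
                                                     observed_mask[idx], ctx)
            net.backward(grad[:, None])
            opt.step()
            epoch_loss += batch_loss
            n_batches += 1
        hist.loss.append(epoch_loss / max(n_batches, 1))
        hist.accuracy["train"].append(
            float((model.predict(X) == y.astype(int)).mean()))
        for name, (Xe, ye) in (eval_sets or {}).items():
            hist.accuracy[name].append(
                float((model.predict(Xe) == np.asarray(ye).astype(int)).mean()))

    return model, hist


BASELINE_FAMILIES = ("decision-tree", "random-forest", "svm", "knn")


def train_baseline(family: str, X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Fit a conventional classifier at default settings on observed data.

    Used for the majority-collapse comparison: under severe imbalance with
    no augmentation these families tend to predict only the majority class.
    """
    makers = {
        "decision-tree": lambda: DecisionTreeClassifier(random_state=seed),
        "random-forest": lambda: RandomForestClassifier(random_state=seed),
        "svm": lambda: SVC(random_state=seed),
        "knn": lambda: KNeighborsClassifier(),
    }
    if family not in makers:
        raise ValueError(f"unknown baseline family {family!r}; "
                         f"choose from {BASELINE_FAMILIES}")
    clf = makers[family]()
    clf.fit(np.asarray(X, dtype=float), np.asarray(y).astype(int).ravel())
    return clf
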
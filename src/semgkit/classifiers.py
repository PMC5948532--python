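"""Gesture classification of RMS feature vectors.

Two classifiers are provided:

* a one-hidden-layer perceptron (8 inputs → 8 sigmoid hidden units →
  directional output neurons) trained by full-batch backpropagation on
  squared error, with early stopping on a held-out stream, and
* a linear-discriminant-analysis (LDA) baseline producing hard labels
  for the four basic gestures.

The network's target encoding is *compound*: each basic gesture is
one-hot on its directional output neuron (left, right, up, down), each
compound gesture puts 1/2 on its two parent neurons, and rest is
all-zeros.  The output vector q = (ql, qr, qu, qd) feeds the
proportional control law directly, so classification and cursor
steering share one model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from . import gestures as G
from .features import FeatureStream


def _sigmoid(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-u))


@dataclass
class TargetEncoding:
    """Map gesture id → target output vector u."""

    targets: dict[str, np.ndarray]
    output_names: tuple

    def __post_init__(self) -> None:
        self.targets = {g: np.asarray(u, dtype=float) for g, u in self.targets.items()}
        n = len(self.output_names)
        for g, u in self.targets.items():
            if u.shape != (n,):
                raise ValueError(f"target for {g} must have length {n}")
            if (u < 0).any() or (u > 1).any():
                raise ValueError(f"target for {g} must lie in [0, 1]")

    @property
    def n_out(self) -> int:
        return len(self.output_names)

    def target(self, gesture: str) -> np.ndarray:
        try:
            return self.targets[gesture]
        except KeyError:
            raise ValueError(f"gesture {gesture!r} absent from encoding") from None

    def matrix(self, labels: np.ndarray) -> np.ndarray:
        return np.stack([self.target(g) for g in labels])


def directional_encoding(n_out: int = 4) -> TargetEncoding:
    """Standard encoding on (ql, qr, qu, qd) output neurons.

    ``n_out=4`` (default) uses the four directional neurons only.
    ``n_out=7`` appends fist / palm / rest class neurons; the rest
    gesture then becomes one-hot on the rest neuron instead of
    all-zeros.
    """
    if n_out not in (4, 7):
        raise ValueError("n_out must be 4 or 7")
    axis = {"G1": 0, "G2": 1, "G3": 2, "G4": 3}
    targets = {G.REST: np.zeros(n_out)}
    for g, i in axis.items():
        u = np.zeros(n_out)
        u[i] = 1.0
        targets[g] = u
    for g, (p1, p2) in G.COMPOUND_PARENTS.items():
        u = np.zeros(n_out)
        u[axis[p1]] = 0.5
        u[axis[p2]] = 0.5
        targets[g] = u
    names = ("ql", "qr", "qu", "qd")
    if n_out == 7:
        names = names + ("fist", "palm", "rest")
        targets["G9"] = np.eye(7)[4]
        targets["G10"] = np.eye(7)[5]
        targets[G.REST] = np.eye(7)[6]
    return TargetEncoding(targets=targets, output_names=names)


@dataclass
class AnnModel:
    """One-hidden-layer sigmoid network mapping R^8 features to outputs."""

    w_hidden: np.ndarray
    b_hidden: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray
    scale: np.ndarray | None = None  # per-channel input divisor, optional

    @property
    def n_in(self) -> int:
        return self.w_hidden.shape[0]

    @property
    def n_out(self) -> int:
        return self.w_out.shape[1]

    def forward(self, V: np.ndarray) -> np.ndarray:
        V = np.asarray(V, dtype=float)
        single = V.ndim == 1
        X = np.atleast_2d(V)
        if X.shape[1] != self.n_in:
            raise ValueError(
                f"feature dimension {X.shape[1]} != model input {self.n_in}"
            )
        if self.scale is not None:
            X = X / self.scale
        H = _sigmoid(X @ self.w_hidden + self.b_hidden)
        Q = _sigmoid(H @ self.w_out + self.b_out)
        return Q[0] if single else Q

    def to_json(self, path) -> None:
        payload = {
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "AnnModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            w_hidden=np.asarray(d["w_hidden"]),
            b_hidden=np.asarray(d["b_hidden"]),
            w_out=np.asarray(d["w_out"]),
            b_out=np.asarray(d["b_out"]),
            scale=None if d["scale"] is None else np.asarray(d["scale"]),
        )


@dataclass
class TrainReport:
    epochs_run: int
    train_error_curve: np.ndarray
    test_error_curve: np.ndarray
    stopped_early: bool
    best_epoch: int


DEFAULT_HYPER = {
    "hidden": 8,
    "lr": 1.0,
    "max_epochs": 5000,
    "patience": 50,
    "bias": True,
    "normalize": False,
    "init_scale": 0.5,
}


def ems(outputs, targets) -> float:
    """Mean squared output error over trials and output neurons:

        E_MS = 1/(N M) Σ_n ||q_n − u_n||²
    """
    q = np.asarray(outputs, dtype=float)
    u = np.asarray(targets, dtype=float)
    if q.size == 0:
        raise ValueError("ems of empty output list is undefined")
    if q.shape != u.shape:
        raise ValueError("outputs and targets must have the same shape")
    q = np.atleast_2d(q)
    u = np.atleast_2d(u)
    return float(((q - u) ** 2).sum() / (q.shape[0] * q.shape[1]))


def train_ann(
    features_train: FeatureStream,
    features_test: FeatureStream,
    encoding: TargetEncoding | None = None,
    hyper: dict | None = None,
    seed: int = 0,
) -> tuple[AnnModel, TrainReport]:
    """Train the gesture network by full-batch gradient descent.

    The loss is the per-trial mean squared error between output and the
    compound target; training stops when the held-out E_MS has not
    improved for ``patience`` epochs (or at ``max_epochs``), and the
    weights at the held-out minimum are returned.
    """
    encoding = encoding or directional_encoding()
    hp = dict(DEFAULT_HYPER)
    if hyper:
        hp.update(hyper)

    if features_train.n_frames == 0 or features_test.n_frames == 0:
        raise ValueError("feature streams must be non-empty")
    if features_train.n_channels != 8:
        raise ValueError("ANN expects 8-channel RMS features")

    Xtr, Xte = features_train.V, features_test.V
    Utr = encoding.matrix(features_train.labels)
    Ute = encoding.matrix(features_test.labels)

    scale = None
    if hp["normalize"]:
        scale = np.maximum(Xtr.max(axis=0), 1e-12)
        Xtr = Xtr / scale
        Xte = Xte / scale

    rng = np.random.default_rng(seed)
    n_in, n_hidden, n_out = 8, hp["hidden"], encoding.n_out
    s = hp["init_scale"]
    w1 = rng.uniform(-s, s, (n_in, n_hidden))
    b1 = rng.uniform(-s, s, n_hidden) if hp["bias"] else np.zeros(n_hidden)
    w2 = rng.uniform(-s, s, (n_hidden, n_out))
    b2 = rng.uniform(-s, s, n_out) if hp["bias"] else np.zeros(n_out)

    lr = hp["lr"]
    n = Xtr.shape[0]
    train_curve, test_curve = [], []
    best = None
    best_err = np.inf
    best_epoch = 0
    stopped_early = False

    for epoch in range(hp["max_epochs"]):
        H = _sigmoid(Xtr @ w1 + b1)
        Q = _sigmoid(H @ w2 + b2)
        err = Q - Utr
        train_curve.append(float((err**2).sum() / (n * n_out)))

        dQ = err * Q * (1.0 - Q) / n
        gw2 = H.T @ dQ
        gb2 = dQ.sum(axis=0)
        dH = (dQ @ w2.T) * H * (1.0 - H)
        gw1 = Xtr.T @ dH
        gb1 = dH.sum(axis=0)
        w2 -= lr * gw2
        w1 -= lr * gw1
        if hp["bias"]:
            b2 -= lr * gb2
            b1 -= lr * gb1

        Qte = _sigmoid(_sigmoid(Xte @ w1 + b1) @ w2 + b2)
        te = float(((Qte - Ute) ** 2).sum() / (Qte.shape[0] * n_out))
        test_curve.append(te)
        if te < best_err:
            best_err = te
            best = (w1.copy(), b1.copy(), w2.copy(), b2.copy())
            best_epoch = epoch
        elif epoch - best_epoch >= hp["patience"]:
            stopped_early = True
            break

    w1, b1, w2, b2 = best
    model = AnnModel(w_hidden=w1, b_hidden=b1, w_out=w2, b_out=b2, scale=scale)
    report = TrainReport(
        epochs_run=len(train_curve),
        train_error_curve=np.asarray(train_curve),
        test_error_curve=np.asarray(test_curve),
        stopped_early=stopped_early,
        best_epoch=best_epoch,
    )
    return model, report


def predict_ann(model: AnnModel, V: np.ndarray) -> np.ndarray:
    """Forward pass: output vector q with every component in (0, 1)."""
    return model.forward(V)


def ann_argmax_label(model: AnnModel, V: np.ndarray, encoding: TargetEncoding) -> str:
    """Hard basic-gesture label from the strongest directional neuron."""
    q = np.atleast_2d(model.forward(V))
    idx = q[:, :4].argmax(axis=1)
    basic = np.asarray(G.BASIC)
    out = basic[idx]
    return out[0] if np.asarray(V).ndim == 1 else out


@dataclass
class LdaModel:
    estimator: LinearDiscriminantAnalysis
    classes: np.ndarray = field(default_factory=lambda: np.array([]))


def train_lda(features_train: FeatureStream, regularize: bool = False) -> LdaModel:
    """Fit the LDA baseline on RMS vectors with hard gesture labels."""
    X = features_train.V
    y = features_train.labels
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("LDA needs at least two gesture classes")
    # pooled within-class covariance must be invertible
    pooled = np.zeros((X.shape[1], X.shape[1]))
    for c in classes:
        xc = X[y == c]
        if xc.shape[0] > 1:
            pooled += np.cov(xc.T) * (xc.shape[0] - 1)
    pooled /= max(1, X.shape[0] - len(classes))
    if not regularize and np.linalg.cond(pooled) > 1e10:
        raise ValueError(
            "singular pooled covariance; re-fit with regularize=True "
            "to apply shrinkage"
        )
    if regularize:
        est = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto")
    else:
        est = LinearDiscriminantAnalysis(solver="svd")
    est.fit(X, y)
    return LdaModel(estimator=est, classes=classes)


def predict_lda(model: LdaModel, V: np.ndarray):
    """Hard gesture label(s) for RMS vector(s)."""
    V = np.asarray(V, dtype=float)
    single = V.ndim == 1
    out = model.estimator.predict(np.atleast_2d(V))
    return out[0] if single else out
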
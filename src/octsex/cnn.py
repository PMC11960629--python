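"""CNN sex classifier: sklearn-style estimator around the NumPy network.

The architecture is fixed by design: three 3×3 'same' convolution blocks
(32, 64, 128 filters) each followed by ReLU and 2×2 max-pooling, 25 %
dropout, a 256-unit fully connected ReLU layer, 50 % dropout, and a 2-unit
softmax output (female/male).  Training uses Adam (lr 1e-4), batch size
128, up to 1000 epochs with early stopping on validation loss (patience
50) and best-weight restoration.

A third "not_detect" outcome is produced at prediction time by a softmax
confidence threshold τ: if the winning class probability falls below τ the
frame is rejected rather than sexed.  With two classes the winning
probability is always ≥ 0.5, so τ ≤ 0.5 makes rejection unreachable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .nn import Adam, ConvNet, softmax_xent

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "Prediction",
    "build_model",
    "CNNClassifier",
    "NOT_DETECT",
]

NOT_DETECT = "not_detect"

#: class indexing used everywhere: column 0 = female, column 1 = male
CLASS_ORDER = ("female", "male")


@dataclass(frozen=True)
class ModelSpec:
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    fc_units: int = 256
    conv_dropout: float = 0.25
    fc_dropout: float = 0.50
    output_units: int = 2

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 3:
            raise ValueError("the architecture has exactly three conv+pool blocks")
        for p in (self.conv_dropout, self.fc_dropout):
            if not 0.0 <= p < 1.0:
                raise ValueError("dropout rates must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 1000
    patience: int = 50
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("training parameters must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass(frozen=True)
class Prediction:
    probabilities: tuple[float, float]  # (p_female, p_male)
    label: str
    tau: float


def build_model(
    input_height: int,
    input_width: int,
    spec: ModelSpec | None = None,
    seed: int = 0,
    dtype=np.float32,
) -> ConvNet:
    """Instantiate the network for a given input size.

    Raises if either axis cannot survive three floor-halving pooling
    stages (each input dimension must be at least 8 px).
    """
    spec = spec or ModelSpec()
    return ConvNet(
        input_height=input_height,
        input_width=input_width,
        conv_filters=spec.conv_filters,
        fc_units=spec.fc_units,
        conv_dropout=spec.conv_dropout,
        fc_dropout=spec.fc_dropout,
        n_classes=spec.output_units,
        rng=seed,
        dtype=dtype,
    )


class CNNClassifier(BaseEstimator, ClassifierMixin):
    """Binary chick-sex classifier for 8-bit grayscale B-scan crops.

    Parameters mirror the fixed architecture and training regime; the
    estimator is deterministic given ``random_state`` (weight init, data
    order, dropout masks and the internal validation split all derive from
    it).

    Parameters
    ----------
    input_height, input_width : int
        Expected image shape, rows × columns.  The published input is
        75 wide × 64 high, i.e. ``input_height=64, input_width=75``.
    tau : float
        Softmax confidence threshold of :meth:`predict_with_reject`.
    min_delta : float
        Minimum validation-loss improvement that resets patience.

    Attributes
    ----------
    net_ : ConvNet
        The fitted network (best-validation-loss weights).
    classes_ : ndarray of str
        ``['female', 'male']``.
    history_ : dict of lists
        Per-epoch train/validation loss and accuracy.
    stopped_epoch_ : int
        1-based epoch at which training halted.
    """

    def __init__(
        self,
        input_height: int = 64,
        input_width: int = 75,
        conv_filters: tuple[int, int, int] = (32, 64, 128),
        fc_units: int = 256,
        conv_dropout: float = 0.25,
        fc_dropout: float = 0.50,
        learning_rate: float = 1e-4,
        batch_size: int = 128,
        max_epochs: int = 1000,
        patience: int = 50,
        val_fraction: float = 0.1,
        min_delta: float = 0.0,
        tau: float = 0.6,
        random_state: int = 0,
        verbose: int = 0,
    ):
        self.input_height = input_height
        self.input_width = input_width
        self.conv_filters = conv_filters
        self.fc_units = fc_units
        self.conv_dropout = conv_dropout
        self.fc_dropout = fc_dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.min_delta = min_delta
        self.tau = tau
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------ utils
    def _validate_images(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 2:  # a single image
            X = X[None]
        if X.ndim == 4 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 3:
            raise ValueError("X must be an array of 2-D grayscale images (n, H, W)")
        if X.shape[1] != self.input_height or X.shape[2] != self.input_width:
            raise ValueError(
                f"image shape {X.shape[1]}×{X.shape[2]} (H×W) does not match the "
                f"configured {self.input_height}×{self.input_width}"
            )
        X = X.astype(np.float32)
        if X.max(initial=0.0) > 1.5:  # 8-bit input: bring to [0, 1]
            X = X / 255.0
        return X

    def _encode_labels(self, y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "iub":
            vals = set(np.unique(y).tolist())
            if not vals <= {0, 1}:
                raise ValueError("integer labels must be 0 (female) / 1 (male)")
            return y.astype(np.int64)
        codes = {"female": 0, "male": 1}
        try:
            return np.array([codes[str(v)] for v in y], dtype=np.int64)
        except KeyError as e:
            raise ValueError(
                f"unknown label {e.args[0]!r}; training labels must be binary "
                "('female'/'male'); ambiguous frames are excluded from training"
            ) from None

    # ------------------------------------------------------------------- fit
    def fit(self, X, y):
        TrainConfig(  # re-validate the regime parameters
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            val_fraction=self.val_fraction,
            seed=self.random_state,
        )
        X = self._validate_images(X)
        y = self._encode_labels(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(X) == 0:
            raise ValueError("empty training set")

        rng = np.random.default_rng(self.random_state)
        self.classes_ = np.array(CLASS_ORDER)

        if self.val_fraction > 0 and len(X) >= 10 and len(np.unique(y)) > 1:
            idx_tr, idx_val = train_test_split(
                np.arange(len(X)),
                test_size=self.val_fraction,
                stratify=y,
                random_state=self.random_state,
            )
        else:  # too small to hold data out: monitor training loss instead
            idx_tr = np.arange(len(X))
            idx_val = idx_tr
        Xtr, ytr, Xval, yval = X[idx_tr], y[idx_tr], X[idx_val], y[idx_val]

        net = build_model(
            self.input_height,
            self.input_width,
            ModelSpec(
                conv_filters=tuple(self.conv_filters),
                fc_units=self.fc_units,
                conv_dropout=self.conv_dropout,
                fc_dropout=self.fc_dropout,
            ),
            seed=int(rng.integers(2**31)),
        )
        opt = Adam(net.params(), lr=self.learning_rate)

        history = {k: [] for k in ("train_loss", "val_loss", "train_acc", "val_acc")}
        best_loss = np.inf
        best_weights = net.get_weights()
        epochs_since_improvement = 0
        self.stopped_epoch_ = self.max_epochs

        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(len(Xtr))
            losses, hits, seen = [], 0, 0
            for start in range(0, len(Xtr), self.batch_size):
                sel = order[start : start + self.batch_size]
                logits = net.forward(Xtr[sel], train=True)
                loss, grad = softmax_xent(logits, ytr[sel])
                net.backward(grad)
                opt.step()
                losses.append(loss * len(sel))
                hits += int((logits.argmax(axis=1) == ytr[sel]).sum())
                seen += len(sel)
            train_loss = float(np.sum(losses) / seen)
            train_acc = hits / seen

            val_logits = net.forward(Xval, train=False)
            val_loss, _ = softmax_xent(val_logits, yval)
            val_acc = float((val_logits.argmax(axis=1) == yval).mean())

            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            history["train_acc"].append(train_acc)
            history["val_acc"].append(val_acc)
            if self.verbose:
                print(
                    f"epoch {epoch:4d}  loss {train_loss:.4f}/{val_loss:.4f}"
                    f"  acc {train_acc:.3f}/{val_acc:.3f}"
                )

            if val_loss < best_loss - self.min_delta:
                best_loss = val_loss
                best_weights = net.get_weights()
                epochs_since_improvement = 0
            else:
                epochs_since_improvement += 1
                if epochs_since_improvement >= self.patience:
                    self.stopped_epoch_ = epoch
                    break

        net.set_weights(best_weights)
        self.net_ = net
        self.history_ = history
        self.best_val_loss_ = float(best_loss)
        self.n_features_in_ = self.input_height * self.input_width
        return self

    # --------------------------------------------------------------- predict
    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = self._validate_images(X)
        return self.net_.predict_proba(X, batch_size=max(self.batch_size, 64))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def predict_with_reject(self, X, tau: float | None = None) -> np.ndarray:
        """Labels with the low-confidence frames mapped to 'not_detect'."""
        tau = self.tau if tau is None else tau
        proba = self.predict_proba(X)
        labels = self.classes_[proba.argmax(axis=1)].astype(object)
        labels[proba.max(axis=1).astype(np.float64) < float(tau)] = NOT_DETECT
        return labels.astype(str)

    def predict_one(self, image: np.ndarray, tau: float | None = None) -> Prediction:
        """Single-frame prediction with the τ confidence rule."""
        tau = self.tau if tau is None else tau
        p = self.predict_proba(image[None] if image.ndim == 2 else image)[0]
        label = NOT_DETECT if p.max() < tau else str(self.classes_[int(p.argmax())])
        return Prediction(probabilities=(float(p[0]), float(p[1])), label=label, tau=tau)

    # ------------------------------------------------------------------- i/o
    def save(self, path) -> None:
        """Weights as .npz plus a JSON sidecar with parameters and class order."""
        check_is_fitted(self, "net_")
        path = Path(path)
        weights = self.net_.get_weights()
        np.savez_compressed(path.with_suffix(".npz"), *weights)
        sidecar = {
            "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.get_params().items()},
            "class_order": list(self.classes_),
            "stopped_epoch": int(self.stopped_epoch_),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "CNNClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        params = sidecar["params"]
        params["conv_filters"] = tuple(params["conv_filters"])
        est = cls(**params)
        est.classes_ = np.array(sidecar["class_order"])
        est.net_ = build_model(
            est.input_height,
            est.input_width,
            ModelSpec(
                conv_filters=est.conv_filters,
                fc_units=est.fc_units,
                conv_dropout=est.conv_dropout,
                fc_dropout=est.fc_dropout,
            ),
            seed=0,
        )
        with np.load(path.with_suffix(".npz")) as data:
            est.net_.set_weights([data[k] for k in data.files])
        est.stopped_epoch_ = sidecar["stopped_epoch"]
        est.history_ = {}
        est.n_features_in_ = est.input_height * est.input_width
        return est
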
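"""Small trainable image-patch classifier.

A deliberately compact backbone for desk-scale experiments: RGB patches are
area-averaged down to ``input_size`` x ``input_size``, flattened, and fed to a
single-hidden-layer perceptron.  The hidden layer doubles as the feature
extractor — its post-ReLU activations are the patch embedding used for
pseudo-label refinement and class discovery (default width 512).

Training runs epoch-by-epoch with Adam; the weights with the best
validation weighted-F1 are kept (checkpoint selection).  All randomness is
driven by ``random_state``, so fits are bit-reproducible.
"""

from __future__ import annotations

import copy

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import f1_score
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted


def _block_mean_resize(patches: np.ndarray, out_size: int) -> np.ndarray:
    """Resize (n, H, W, 3) uint8 patches to (n, out, out, 3) by area averaging.

    Fast reshape path when H is a multiple of out_size, otherwise a strided
    nearest-block fallback.
    """
    n, h, w, c = patches.shape
    x = patches.astype(np.float64)
    if h % out_size == 0 and w % out_size == 0:
        bh, bw = h // out_size, w // out_size
        return x.reshape(n, out_size, bh, out_size, bw, c).mean(axis=(2, 4))
    yi = np.linspace(0, h, out_size + 1).astype(int)
    xi = np.linspace(0, w, out_size + 1).astype(int)
    out = np.empty((n, out_size, out_size, c))
    for a in range(out_size):
        for b in range(out_size):
            out[:, a, b] = x[:, yi[a]:yi[a + 1], xi[b]:xi[b + 1]].mean(axis=(1, 2))
    return out


class SmallImageClassifier(ClassifierMixin, BaseEstimator):
    """Multinomial patch classifier over RGB rasters.

    Parameters
    ----------
    input_size : side length patches are downscaled to before the MLP.
    feature_width : hidden-layer width; also the embedding dimension.
    epochs : training epochs; the best-validation checkpoint is returned.
        ``epochs=0`` leaves the network at (near-)initialization, with
        predictions still normalized.
    """

    def __init__(self, input_size: int = 16, feature_width: int = 512,
                 epochs: int = 30, learning_rate: float = 1e-3,
                 batch_size: int = 64, random_state: int = 0):
        self.input_size = input_size
        self.feature_width = feature_width
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.random_state = random_state

    def _featurize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError("X must have shape (n, H, W, 3)")
        small = _block_mean_resize(X, self.input_size)
        return small.reshape(len(X), -1) / 255.0 - 0.5

    def fit(self, X, y, X_val=None, y_val=None):
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError(f"need >= 2 classes, got only {list(classes)}")
        Xf = self._featurize(X)
        lr = self.learning_rate if self.epochs > 0 else 1e-12
        mlp = MLPClassifier(
            hidden_layer_sizes=(self.feature_width,),
            solver="adam", learning_rate_init=lr,
            batch_size=min(self.batch_size, len(Xf)),
            random_state=self.random_state, max_iter=1, warm_start=False,
        )
        rng = np.random.default_rng(self.random_state)
        have_val = X_val is not None and y_val is not None and len(np.asarray(y_val)) > 0
        Xv = self._featurize(X_val) if have_val else None
        best = (-np.inf, None, None)
        history = []
        mlp.partial_fit(Xf, y, classes=classes)  # initialize (first pass)
        for epoch in range(max(self.epochs - 1, 0)):
            order = rng.permutation(len(Xf))
            mlp.partial_fit(Xf[order], y[order], classes=classes)
            if have_val:
                f1 = f1_score(y_val, mlp.predict(Xv), average="weighted")
                history.append(f1)
                if f1 > best[0]:
                    best = (f1, copy.deepcopy(mlp.coefs_),
                            copy.deepcopy(mlp.intercepts_))
        if have_val and best[1] is not None:
            mlp.coefs_, mlp.intercepts_ = best[1], best[2]
            self.best_val_f1_ = float(best[0])
        elif have_val:
            self.best_val_f1_ = float(f1_score(y_val, mlp.predict(Xv),
                                               average="weighted"))
        self.val_history_ = history
        self.mlp_ = mlp
        self.classes_ = mlp.classes_
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "mlp_")
        return self.mlp_.predict_proba(self._featurize(X))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "mlp_")
        return self.mlp_.predict(self._featurize(X))

    def transform(self, X) -> np.ndarray:
        """Patch embeddings: post-ReLU hidden activations, one row per patch."""
        check_is_fitted(self, "mlp_")
        Xf = self._featurize(X)
        hidden = Xf @ self.mlp_.coefs_[0] + self.mlp_.intercepts_[0]
        return np.maximum(hidden, 0.0)

    @property
    def embedding_width_(self) -> int:
        check_is_fitted(self, "mlp_")
        return self.mlp_.coefs_[0].shape[1]
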
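"""Scikit-learn style front end for the texton-dense capsule classifier."""

from __future__ import annotations

import tempfile

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .capsules import MarginLossParams, capsule_lengths
from .model import ModelConfig, TTDCapsNet
from .training import TrainConfig, train_model

__all__ = ["TextonCapsNetClassifier"]


class TextonCapsNetClassifier(BaseEstimator, ClassifierMixin):
    """Capsule-network image classifier with texton + dense-block front ends.

    Parameters
    ----------
    arch : 'full' or 'compact'
        'full' is the reference architecture (12 capsule types, 8-layer dense
        blocks, growth 32); 'compact' is a reduced configuration sized for
        CPU training.
    epochs, batch_size, lr : training schedule (Adam).
    routing_iters : dynamic-routing iterations per class-capsule head.
    recon_weight : weight of the reconstruction sum-squared error.
    val_fraction : share of the training data held out to select the best
        checkpoint.
    random_state : seed for weight initialization, shuffling and the split.

    Fitted attributes end in an underscore: ``model_``, ``classes_``,
    ``history_``, ``config_``.
    """

    def __init__(self, arch="compact", epochs=20, batch_size=50, lr=0.001,
                 routing_iters=3, recon_weight=0.0005, m_plus=0.9,
                 m_minus=0.1, lam=0.5, val_fraction=0.2, random_state=0):
        self.arch = arch
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.routing_iters = routing_iters
        self.recon_weight = recon_weight
        self.m_plus = m_plus
        self.m_minus = m_minus
        self.lam = lam
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _check_images(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[..., None]
        if X.ndim != 4:
            raise ValueError("X must be (n_samples, height, width, channels)")
        if X.max() > 1.0 + 1e-6:
            X = X / 255.0
        return np.clip(X, 0.0, 1.0)

    def _build_config(self, X, n_classes):
        loss = MarginLossParams(self.m_plus, self.m_minus, self.lam)
        kwargs = dict(n_classes=n_classes, channels=X.shape[3],
                      routing_iters=self.routing_iters)
        if self.arch == "full":
            cfg = ModelConfig(height=X.shape[1], width=X.shape[2], **kwargs)
        elif self.arch == "compact":
            cfg = ModelConfig.compact(n_classes=n_classes, channels=X.shape[3])
            cfg.routing_iters = self.routing_iters
            cfg.height, cfg.width = X.shape[1], X.shape[2]
        else:
            raise ValueError("arch must be 'full' or 'compact'")
        cfg.loss = loss
        cfg.recon_weight = self.recon_weight
        return cfg

    # -- estimator API -------------------------------------------------------
    def fit(self, X, y):
        X = self._check_images(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.config_ = self._build_config(X, len(self.classes_))
        self.model_ = TTDCapsNet(self.config_, seed=self.random_state)

        rng = np.random.default_rng(self.random_state)
        val_idx, train_idx = [], []
        for k in range(len(self.classes_)):
            idx = rng.permutation(np.flatnonzero(y_idx == k))
            n_val = max(1, int(np.floor(self.val_fraction * len(idx))))
            val_idx.append(idx[:n_val])
            train_idx.append(idx[n_val:])
        tr = np.concatenate(train_idx)
        va = np.concatenate(val_idx)

        cfg = TrainConfig(lr=self.lr, batch_size=self.batch_size,
                          epochs=self.epochs, seed=self.random_state,
                          recon_weight=self.recon_weight,
                          loss=self.config_.loss)
        with tempfile.TemporaryDirectory() as tmp:
            self.history_, best = train_model(
                self.model_, (X[tr], y_idx[tr]), (X[va], y_idx[va]), cfg,
                checkpoint_dir=tmp)
            self.model_ = TTDCapsNet.load(best)
        return self

    def decision_function(self, X):
        """Per-class scores: Euclidean lengths of the concatenated capsules."""
        self._require_fitted()
        X = self._check_images(X)
        out = self.model_.forward(X)
        return capsule_lengths(out.concat_caps)

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[scores.argmax(axis=1)]

    def reconstruct(self, X):
        """Decoder reconstructions of the argmax class, shaped like X."""
        self._require_fitted()
        X = self._check_images(X)
        out = self.model_.forward(X)
        return out.reconstruction.reshape(X.shape)

    def _require_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    def _more_tags(self):
        return {"X_types": ["3darray"], "non_deterministic": False}
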
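"""scikit-learn estimator facade over the grading network.

``HCCANetClassifier`` composes with sklearn pipelines and model
selection: images are passed as (N, H, W, 3) float arrays (standardized
upstream, e.g. by :class:`hccanet.preprocessing.ImageStandardizer`).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .attention import MCCBAMConfig
from .model import BackboneConfig, HCCANetConfig, build_hccanet
from .training import TrainConfig, train

__all__ = ["HCCANetClassifier"]


class HCCANetClassifier(ClassifierMixin, BaseEstimator):
    """VGG16-backbone grading network with a parallel MCCBAM branch.

    Parameters mirror the backbone, attention and training
    configurations; defaults are the desk-scale settings (width-shrunk
    backbone, small input), with the study's optimizer settings.
    """

    def __init__(self, *, input_size=(64, 64), width_multiplier=0.125,
                 freeze_until="Block_Conv3", reduction_ratios=(4, 8, 16),
                 branch_kernels=(3, 5), spatial_kernel=7,
                 learning_rate=0.005, beta1=0.9, beta2=0.99,
                 epochs=10, batch_size=16, grad_clip_norm=1.0,
                 validation_fraction=0.0, random_state=0):
        self.input_size = input_size
        self.width_multiplier = width_multiplier
        self.freeze_until = freeze_until
        self.reduction_ratios = reduction_ratios
        self.branch_kernels = branch_kernels
        self.spatial_kernel = spatial_kernel
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.epochs = epochs
        self.batch_size = batch_size
        self.grad_clip_norm = grad_clip_norm
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _configs(self, n_classes: int) -> tuple[HCCANetConfig, TrainConfig]:
        model_cfg = HCCANetConfig(
            backbone=BackboneConfig(
                input_size=(*self.input_size, 3),
                freeze_until=self.freeze_until,
                width_multiplier=self.width_multiplier,
                seed=self.random_state,
            ),
            attention=MCCBAMConfig(
                reduction_ratios=tuple(self.reduction_ratios),
                branch_kernels=tuple(self.branch_kernels),
                spatial_kernel=self.spatial_kernel,
            ),
            n_classes=n_classes,
            seed=self.random_state,
        )
        train_cfg = TrainConfig(
            learning_rate=self.learning_rate, beta1=self.beta1, beta2=self.beta2,
            epochs=self.epochs, batch_size=self.batch_size,
            grad_clip_norm=self.grad_clip_norm, seed=self.random_state,
        )
        return model_cfg, train_cfg

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[1:3] != tuple(self.input_size):
            raise ValueError(
                f"X must be (N, {self.input_size[0]}, {self.input_size[1]}, 3), got {X.shape}"
            )
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        model_cfg, train_cfg = self._configs(len(self.classes_))
        self.model_ = build_hccanet(model_cfg)
        val = None
        if self.validation_fraction > 0:
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(X))
            n_val = max(1, int(len(X) * self.validation_fraction))
            vi, ti = order[:n_val], order[n_val:]
            X, y_idx, val = X[ti], y_idx[ti], (X[vi], y_idx[vi])
        self.history_ = train(self.model_, (X, y_idx), val, train_cfg)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=np.float64),
                                         batch_size=self.batch_size)

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
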
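"""Self-supervised protein-identity network and feature-profile extraction.

The pretext task: predict which tagged protein a single-cell crop shows, from
the protein channel alone. The penultimate (second) fully-connected layer of
the classifier is the feature profile; one vector per crop (scFP), averaged
per protein (aFP). Training uses Adam with cosine learning-rate decay,
cross-entropy loss, dihedral augmentation, and an early-stopping rule on the
per-epoch accuracy increments.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .prep import dihedral


def early_stop_select(accuracies, deriv_threshold=0.5, patience=3):
    """Pick the saturation epoch from a per-epoch accuracy curve.

    ``accuracies`` are percentages, one per epoch (epoch numbering is
    1-based). Returns the first epoch at which the per-epoch accuracy
    increment stayed below ``deriv_threshold`` percentage points for
    ``patience`` consecutive epochs; if the curve never saturates, the last
    epoch is returned with a warning.
    """
    acc = np.asarray(accuracies, dtype=float)
    if acc.size == 0:
        raise ValueError("empty accuracy history")
    if acc.size < patience + 1:
        raise ValueError(f"need at least {patience + 1} epochs")
    diffs = np.diff(acc)  # diffs[i] = increment into epoch i+2
    small = diffs < deriv_threshold
    for t in range(patience - 1, len(small)):
        if small[t - patience + 1 : t + 1].all():
            return t + 2  # epoch index of the last increment in the window
    warnings.warn("accuracy never saturated; selecting the last epoch")
    return len(acc)


class ProteinIdentityNetwork(BaseEstimator, TransformerMixin):
    """CNN classifier over protein identities whose penultimate layer is the
    feature profile.

    Parameters mirror the training protocol: eight conv blocks (conv 3x3,
    batch norm, ReLU), three fully-connected layers with a 64-d feature
    layer, dropout 0.05 after it, Adam at 1e-3 with cosine decay over the
    scheduled epochs, batch size 128, weights initialized from a truncated
    normal with standard deviation 0.1. ``transform`` returns scFPs.

    Set ``early_stop_on="val"`` to select the checkpoint on validation rather
    than test accuracy.
    """

    def __init__(
        self,
        n_conv_blocks=8,
        base_channels=16,
        fc1_units=128,
        feature_dim=64,
        dropout=0.05,
        lr=1e-3,
        epochs=30,
        batch_size=128,
        deriv_threshold=0.5,
        patience=3,
        early_stop_on="test",
        augment=True,
        init_std=0.1,
        random_state=0,
        dtype="float32",
    ):
        self.n_conv_blocks = n_conv_blocks
        self.base_channels = base_channels
        self.fc1_units = fc1_units
        self.feature_dim = feature_dim
        self.dropout = dropout
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.deriv_threshold = deriv_threshold
        self.patience = patience
        self.early_stop_on = early_stop_on
        self.augment = augment
        self.init_std = init_std
        self.random_state = random_state
        self.dtype = dtype

    # ------------------------------------------------------------------
    def _coerce(self, X):
        X = np.asarray(X)
        if X.ndim == 3:
            X = X[:, None]
        return X.astype(np.dtype(self.dtype))

    def build_network(self, n_classes, input_shape):
        return nn.build_feature_net(
            n_classes=n_classes,
            input_shape=input_shape,
            n_conv_blocks=self.n_conv_blocks,
            base_channels=self.base_channels,
            fc1_units=self.fc1_units,
            feature_dim=self.feature_dim,
            dropout=self.dropout,
            init_std=self.init_std,
            seed=self.random_state,
            dtype=np.dtype(self.dtype).type,
        )

    def _accuracy(self, X, y_idx):
        probs = self.net_.predict_proba(X, batch_size=self.batch_size)
        return float(np.mean(probs.argmax(axis=1) == y_idx))

    def fit(self, X, y, X_val=None, y_val=None, X_test=None, y_test=None):
        """Train on crops X (N, 1, H, W) with protein-id labels y.

        Validation and test sets feed the accuracy curves; the early-stopping
        checkpoint is chosen on the ``early_stop_on`` curve. Every class must
        be present in the training data.
        """
        X = self._coerce(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 protein classes")
        class_index = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([class_index[v] for v in y])
        counts = np.bincount(y_idx, minlength=len(self.classes_))
        if (counts == 0).any():
            missing = self.classes_[counts == 0]
            raise ValueError(f"classes absent from training data: {list(missing)}")

        self.net_ = self.build_network(len(self.classes_), X.shape[1:])
        rng = np.random.default_rng(self.random_state)
        n = len(X)
        steps_per_epoch = max(1, int(np.ceil(n / self.batch_size)))
        opt = nn.Adam(self.net_, lr=self.lr, total_steps=steps_per_epoch * self.epochs)

        eval_sets = {}
        if X_val is not None:
            eval_sets["val"] = (self._coerce(X_val), np.array([class_index[v] for v in y_val]))
        if X_test is not None:
            eval_sets["test"] = (self._coerce(X_test), np.array([class_index[v] for v in y_test]))

        history = []
        self._checkpoints = []
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(n)
            losses = []
            for b in range(steps_per_epoch):
                idx = order[b * self.batch_size : (b + 1) * self.batch_size]
                xb = X[idx]
                if self.augment:
                    ks = rng.integers(8, size=len(idx))
                    xb = np.stack(
                        [dihedral(im.transpose(1, 2, 0), k).transpose(2, 0, 1)
                         for im, k in zip(xb, ks)]
                    )
                loss, grads = self.net_.loss_and_grads(xb, y_idx[idx], rng=rng)
                opt.step(grads)
                losses.append(loss)
            rec = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            rec["train_accuracy"] = self._accuracy(X, y_idx)
            for name, (Xe, ye) in eval_sets.items():
                rec[f"{name}_accuracy"] = self._accuracy(Xe, ye)
            history.append(rec)
            self._checkpoints.append(self.net_.get_weights())
        self.history_ = pd.DataFrame(history)

        curve_name = f"{self.early_stop_on}_accuracy"
        if curve_name not in self.history_.columns:
            curve_name = "train_accuracy"
        curve = self.history_[curve_name].to_numpy() * 100.0
        if len(curve) >= self.patience + 1:
            self.best_epoch_ = early_stop_select(
                curve, deriv_threshold=self.deriv_threshold, patience=self.patience
            )
        else:
            self.best_epoch_ = len(curve)
        self.net_.set_weights(self._checkpoints[self.best_epoch_ - 1])
        return self

    def initialize(self, input_shape, classes):
        """Build the network without training (randomly initialized weights);
        the untrained-representation baseline for the linear probe."""
        self.classes_ = np.asarray(classes)
        self.net_ = self.build_network(len(self.classes_), tuple(input_shape))
        self.best_epoch_ = 0
        return self

    def load_epoch(self, epoch: int):
        """Restore the checkpoint saved after the given (1-based) epoch."""
        check_is_fitted(self, "net_")
        self.net_.set_weights(self._checkpoints[epoch - 1])
        self.best_epoch_ = epoch
        return self

    def transform(self, X):
        """Single-cell feature profiles: the feature-layer activations
        (dropout disabled, batch norm in inference mode)."""
        check_is_fitted(self, "net_")
        return self.net_.features(self._coerce(X), batch_size=self.batch_size)

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        return self.net_.predict_proba(self._coerce(X), batch_size=self.batch_size)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def input_gradient(self, X, feature_index):
        """Gradient of one feature with respect to the input pixels."""
        check_is_fitted(self, "net_")
        return self.net_.input_gradient(self._coerce(X), feature_index)


def extract_scfps(model, X, crop_ids, protein_ids) -> pd.DataFrame:
    """scFP table: one row per crop, feature columns f0..f{D-1} plus
    ``protein_id``, indexed by crop id."""
    feats = model.transform(X)
    df = pd.DataFrame(
        feats, index=pd.Index(crop_ids, name="crop_id"),
        columns=[f"f{i}" for i in range(feats.shape[1])],
    )
    df.insert(0, "protein_id", protein_ids)
    return df


def average_profiles(scfps: pd.DataFrame) -> pd.DataFrame:
    """aFPs: the per-protein arithmetic mean of scFPs, with cell counts."""
    feature_cols = [c for c in scfps.columns if c.startswith("f")]
    grouped = scfps.groupby("protein_id")[feature_cols]
    afps = grouped.mean()
    afps["n_cells"] = grouped.size()
    afps.index.name = "protein_id"
    return afps


def feature_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """The numeric feature block of an scFP/aFP table."""
    cols = [c for c in profiles.columns if c.startswith("f")]
    return profiles[cols].to_numpy(dtype=float)
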
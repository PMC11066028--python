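"""Single-cell localization heterogeneity and cell-cycle association.

Per protein, the two most frequent localization classes (by mean probability
across its crops) define a per-crop pair (p1, p2). Crops with p1 + p2 below
a confidence threshold are low-confidence; otherwise a crop is primary if
p1 > p2 + beta, secondary if p2 > p1 + beta, and mixed in between. With
category fractions c1, c2, m, k the protein is AND-localizing if
m > c1 + c2, else OR-localizing if min(1, c2) > 0.08, else single; it is
undetermined when too many crops are low-confidence.

Cell-cycle stage is read from the nuclear and cytosolic marker channels by an
ensemble of three CNNs predicting G1 / S / metaphase-anaphase (MA) /
telophase (T); T and G1 are merged for reporting. Stage-localization links
come from a two-sided Mann-Whitney U test on per-crop stage probabilities
between the primary- and secondary-localization crop groups (p < 1e-3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from . import nn

STAGE_CLASSES = ("G1", "S", "MA", "T")
MERGED_CLASSES = ("T/G1", "S/G2", "M/A")


@dataclass
class HeterogeneityParams:
    alpha_conf: float = 0.5
    beta: float = 0.5
    or_threshold: float = 0.08
    undetermined_fraction: float = 0.5
    #: literal reading of the OR rule uses min(1, c2); the alternative
    #: interpretation min(c1, c2) is available as a switch
    or_statistic: str = "min_1_c2"

    def __post_init__(self):
        for name in ("alpha_conf", "beta", "or_threshold", "undetermined_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class HeterogeneityCall:
    protein_id: str
    loc1: str
    loc2: str
    c1: float
    c2: float
    m: float
    k_lc: float
    verdict: str  # single | AND | OR | undetermined


def top2_localizations(probs: pd.DataFrame):
    """Two most frequent localization classes of one protein.

    ``probs`` holds one probability vector per crop (columns = classes).
    Classes are ranked by mean probability (ties broken by column order) and
    the per-crop (p1, p2) pairs for those two classes are returned.
    """
    if probs.shape[1] < 2:
        raise ValueError("need at least 2 localization classes")
    if probs.shape[0] < 1:
        raise ValueError("need at least 1 crop")
    means = probs.mean(axis=0).to_numpy()
    order = np.argsort(-means, kind="stable")
    loc1, loc2 = probs.columns[order[0]], probs.columns[order[1]]
    pairs = probs[[loc1, loc2]].to_numpy(dtype=float)
    return loc1, loc2, pairs


def classify_heterogeneity(
    pairs: np.ndarray,
    params: HeterogeneityParams | None = None,
    protein_id: str = "",
    loc1: str = "loc1",
    loc2: str = "loc2",
) -> HeterogeneityCall:
    """Apply the confidence/heterogeneity rule cascade to (p1, p2) pairs."""
    params = params or HeterogeneityParams()
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 1:
        raise ValueError("pairs must be a non-empty (n, 2) array")
    p1, p2 = pairs[:, 0], pairs[:, 1]
    lowconf = (p1 + p2) < params.alpha_conf
    first = ~lowconf & (p1 > p2 + params.beta)
    second = ~lowconf & (p2 > p1 + params.beta)
    mixed = ~lowconf & ~first & ~second
    n = len(pairs)
    c1, c2 = first.sum() / n, second.sum() / n
    m, k_lc = mixed.sum() / n, lowconf.sum() / n
    if k_lc > params.undetermined_fraction:
        verdict = "undetermined"
    elif m > c1 + c2:
        verdict = "AND"
    else:
        stat = min(c1, c2) if params.or_statistic == "min_c1_c2" else min(1.0, c2)
        verdict = "OR" if stat > params.or_threshold else "single"
    return HeterogeneityCall(
        protein_id=protein_id, loc1=loc1, loc2=loc2,
        c1=c1, c2=c2, m=m, k_lc=k_lc, verdict=verdict,
    )


def call_heterogeneity(
    scfp_probs: pd.DataFrame,
    protein_ids,
    params: HeterogeneityParams | None = None,
) -> pd.DataFrame:
    """Heterogeneity verdicts for every protein.

    ``scfp_probs`` holds per-crop localization probability vectors; rows are
    grouped by ``protein_ids``. Returns one row per protein with the category
    fractions and the verdict.
    """
    params = params or HeterogeneityParams()
    rows = []
    df = scfp_probs.copy()
    df["_pid"] = np.asarray(protein_ids)
    for pid, group in df.groupby("_pid", sort=True):
        probs = group.drop(columns="_pid")
        loc1, loc2, pairs = top2_localizations(probs)
        call = classify_heterogeneity(pairs, params, protein_id=str(pid),
                                      loc1=str(loc1), loc2=str(loc2))
        rows.append(vars(call))
    return pd.DataFrame(rows)


def crop_category_assignment(pairs: np.ndarray, params: HeterogeneityParams):
    """Per-crop category: 0=primary, 1=secondary, 2=mixed, 3=low-confidence."""
    p1, p2 = pairs[:, 0], pairs[:, 1]
    out = np.full(len(pairs), 2, dtype=int)
    out[(p1 + p2) < params.alpha_conf] = 3
    ok = (p1 + p2) >= params.alpha_conf
    out[ok & (p1 > p2 + params.beta)] = 0
    out[ok & (p2 > p1 + params.beta)] = 1
    return out


# --------------------------------------------------------------------------
# cell-cycle classification


def _heavy_augment(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Arbitrary-angle rotation, flips, zoom within 0.02, shifts up to 9 px.

    ``img`` is (C, H, W); channels are transformed jointly.
    """
    out = img
    angle = rng.uniform(0.0, 360.0)
    out = ndimage.rotate(out, angle, axes=(1, 2), reshape=False, order=1, mode="nearest")
    if rng.random() < 0.5:
        out = out[:, :, ::-1]
    if rng.random() < 0.5:
        out = out[:, ::-1, :]
    zoom = 1.0 + rng.uniform(-0.02, 0.02)
    if abs(zoom - 1.0) > 1e-4:
        h, w = out.shape[1:]
        zoomed = ndimage.zoom(out, (1.0, zoom, zoom), order=1, mode="nearest")
        zh, zw = zoomed.shape[1:]
        if zh >= h:
            r0, c0 = (zh - h) // 2, (zw - w) // 2
            out = zoomed[:, r0 : r0 + h, c0 : c0 + w]
        else:
            pad_r, pad_c = h - zh, w - zw
            out = np.pad(zoomed, ((0, 0), (pad_r // 2, pad_r - pad_r // 2),
                                  (pad_c // 2, pad_c - pad_c // 2)), mode="edge")
    shift = rng.integers(-9, 10, size=2)
    out = np.roll(out, shift, axis=(1, 2))
    return np.ascontiguousarray(out)


class CellCycleEnsemble(BaseEstimator, ClassifierMixin):
    """Ensemble of three CNNs predicting the cell-cycle stage from the
    nuclear and cytosolic marker channels.

    Each member is a conv net (4 conv blocks + 2 FC layers by default) over
    64x64x2 crops and 4 stage classes; training uses three-fold
    cross-validation (one fold per member as validation), Adam at 5e-4,
    dropout 0.05, heavy augmentation, and per-member early stopping on
    maximal validation accuracy. The ensemble probability is the mean of the
    member probabilities; T and G1 are merged for reporting.
    """

    def __init__(
        self,
        n_members=3,
        n_conv_blocks=4,
        base_channels=8,
        feature_dim=32,
        dropout=0.05,
        lr=5e-4,
        epochs=150,
        batch_size=64,
        augment=True,
        random_state=0,
        dtype="float32",
    ):
        self.n_members = n_members
        self.n_conv_blocks = n_conv_blocks
        self.base_channels = base_channels
        self.feature_dim = feature_dim
        self.dropout = dropout
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.augment = augment
        self.random_state = random_state
        self.dtype = dtype

    def fit(self, X, y):
        """X: (N, 2, H, W) nuclear+cytosolic crops; y: stage labels."""
        X = np.asarray(X, dtype=np.dtype(self.dtype))
        y = np.asarray(y)
        present = set(np.unique(y))
        missing = [c for c in STAGE_CLASSES if c not in present]
        if missing:
            raise ValueError(f"missing cell-cycle classes: {missing}")
        self.classes_ = np.array(STAGE_CLASSES)
        index = {c: i for i, c in enumerate(STAGE_CLASSES)}
        yi = np.array([index[v] for v in y])
        skf = StratifiedKFold(
            n_splits=self.n_members, shuffle=True, random_state=self.random_state
        )
        self.members_ = []
        self.fold_assignment_ = []
        rng = np.random.default_rng(self.random_state)
        for member, (train_idx, val_idx) in enumerate(skf.split(X, yi)):
            net = nn.build_feature_net(
                n_classes=len(STAGE_CLASSES),
                input_shape=X.shape[1:],
                n_conv_blocks=self.n_conv_blocks,
                base_channels=self.base_channels,
                feature_dim=self.feature_dim,
                dropout=self.dropout,
                n_fc_layers=2,
                seed=self.random_state + 100 + member,
                dtype=np.dtype(self.dtype).type,
            )
            steps = max(1, int(np.ceil(len(train_idx) / self.batch_size)))
            opt = nn.Adam(net, lr=self.lr, total_steps=steps * self.epochs)
            best_acc, best_weights = -1.0, None
            Xv, yv = X[val_idx], yi[val_idx]
            for epoch in range(self.epochs):
                order = rng.permutation(len(train_idx))
                for b in range(steps):
                    idx = train_idx[order[b * self.batch_size : (b + 1) * self.batch_size]]
                    xb = X[idx]
                    if self.augment:
                        xb = np.stack([_heavy_augment(im, rng) for im in xb])
                    _, grads = net.loss_and_grads(xb, yi[idx], rng=rng)
                    opt.step(grads)
                acc = float(np.mean(net.predict_proba(Xv).argmax(1) == yv))
                if acc > best_acc:
                    best_acc, best_weights = acc, net.get_weights()
            net.set_weights(best_weights)
            self.members_.append(net)
            self.fold_assignment_.append((train_idx, val_idx, best_acc))
        return self

    def predict_proba(self, X):
        """Four-class ensemble probabilities (mean over members)."""
        check_is_fitted(self, "members_")
        X = np.asarray(X, dtype=np.dtype(self.dtype))
        if X.shape[1] < 2:
            raise ValueError("cell-cycle prediction needs nuclear and cytosolic channels")
        probs = [m.predict_proba(X, batch_size=self.batch_size) for m in self.members_]
        return np.mean(probs, axis=0)

    def predict_proba_merged(self, X) -> pd.DataFrame:
        """Merged-class probabilities: T/G1 = T + G1, S/G2 = S, M/A = MA."""
        p = self.predict_proba(X)
        i = {c: j for j, c in enumerate(STAGE_CLASSES)}
        merged = np.column_stack(
            [p[:, i["T"]] + p[:, i["G1"]], p[:, i["S"]], p[:, i["MA"]]]
        )
        return pd.DataFrame(merged, columns=list(MERGED_CLASSES))

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def merge_member_probs(member_probs: list[np.ndarray]) -> np.ndarray:
    """Mean of member probability vectors (the ensemble rule)."""
    return np.mean(member_probs, axis=0)


def cellcycle_association(
    pairs: np.ndarray,
    stage_probs: pd.DataFrame,
    params: HeterogeneityParams | None = None,
    p_threshold: float = 1e-3,
    protein_id: str = "",
    loc1: str = "loc1",
    loc2: str = "loc2",
) -> pd.DataFrame:
    """Stage-localization links for one heterogeneous protein.

    Crops assigned to the primary vs secondary localization (by the same
    rule cascade used for heterogeneity calling) are compared per merged
    stage with a two-sided Mann-Whitney U test on the per-crop stage
    probability; links with p below ``p_threshold`` are reported.
    """
    params = params or HeterogeneityParams()
    cats = crop_category_assignment(np.asarray(pairs, dtype=float), params)
    g1 = cats == 0
    g2 = cats == 1
    if g1.sum() == 0 or g2.sum() == 0:
        import warnings

        warnings.warn(f"protein {protein_id}: a localization group is empty; skipped")
        return pd.DataFrame(columns=["protein_id", "stage", "localization", "U", "p"])
    rows = []
    for stage in stage_probs.columns:
        v = stage_probs[stage].to_numpy()
        v1, v2 = v[g1], v[g2]
        U, p = mannwhitneyu(v1, v2, alternative="two-sided")
        if p < p_threshold:
            richer = loc1 if np.median(v1) >= np.median(v2) else loc2
            rows.append(
                {"protein_id": protein_id, "stage": stage, "localization": richer,
                 "U": float(U), "p": float(p)}
            )
    return pd.DataFrame(rows, columns=["protein_id", "stage", "localization", "U", "p"])
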
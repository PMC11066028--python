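"""Whole-panel dendrogram analysis: elbow cutoff selection on the AMI curve,
sub-compartment clustering by silhouette, and 2-D embedding with per-label
density annotation.

The cutoff rule scans correlation thresholds downward from 1 (step 0.01) and
picks the first threshold where the AMI slope over a 20-step window falls
below 0.1 in magnitude — the diminishing-returns elbow of the curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import gaussian_kde
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .benchmarks import ami_score
from .network import feature_matrix


@dataclass
class Dendrogram:
    """Average-linkage merge tree over profiles in correlation distance."""

    Z: np.ndarray
    ids: list[str]

    def cut(self, distance: float) -> np.ndarray:
        """Flat cluster labels at the given correlation-distance height."""
        return fcluster(self.Z, t=distance, criterion="distance")

    @property
    def max_height(self) -> float:
        return float(self.Z[:, 2].max()) if len(self.Z) else 0.0


@dataclass
class CutoffReport:
    standard: str
    threshold: float  # correlation threshold on the evaluated grid
    curve: pd.DataFrame  # columns: threshold (correlation), ami
    clusters: pd.Series  # protein_id -> cluster id at the chosen threshold
    saturated: bool


def build_dendrogram(profiles: pd.DataFrame) -> Dendrogram:
    """Agglomerative clustering of profiles (correlation distance, average
    linkage). Constant profiles have undefined correlation and are refused."""
    X = feature_matrix(profiles)
    if len(X) < 2:
        raise ValueError("need at least 2 profiles")
    stds = X.std(axis=1)
    if (stds < 1e-12).any():
        bad = [str(profiles.index[i]) for i in np.where(stds < 1e-12)[0]]
        raise ValueError(f"constant profile vector(s): {bad}")
    Z = linkage(pdist(X, metric="correlation"), method="average")
    return Dendrogram(Z=Z, ids=list(profiles.index))


def ami_curve(dendrogram: Dendrogram, labels: dict[str, str], step: float = 0.01):
    """AMI between flat clusters and labels across correlation thresholds
    0..1; evaluated on the proteins present in ``labels``."""
    mask = np.array([p in labels for p in dendrogram.ids])
    if mask.sum() < 2:
        raise ValueError("labels must cover at least 2 proteins")
    truth = np.array([labels[p] for p, m in zip(dendrogram.ids, mask) if m])
    thresholds = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    amis = []
    for t in thresholds:
        flat = dendrogram.cut(max(1.0 - t, 0.0))[mask]
        amis.append(ami_score(truth, flat))
    return pd.DataFrame({"threshold": thresholds, "ami": amis})


def apply_derivative_rule(thresholds, ami, step=0.01, window=20, deriv_threshold=0.1):
    """First threshold (scanning down from correlation 1) whose AMI slope
    over ``window`` steps is below ``deriv_threshold`` in magnitude.

    Returns ``(threshold, saturated)``; when the rule never fires, the
    max-AMI threshold is returned with ``saturated=False`` and a warning.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    ami = np.asarray(ami, dtype=float)
    for i in range(len(thresholds) - 1 - window, -1, -1):
        deriv = (ami[i] - ami[i + window]) / (window * step)
        if abs(deriv) < deriv_threshold:
            return float(thresholds[i]), True
    warnings.warn("AMI derivative rule never fired; using max-AMI threshold")
    return float(thresholds[int(np.argmax(ami))]), False


def select_cutoff(
    dendrogram: Dendrogram,
    labels: dict[str, str],
    step: float = 0.01,
    window: int = 20,
    deriv_threshold: float = 0.1,
    standard_name: str = "standard",
) -> CutoffReport:
    """Elbow cutoff by the AMI-derivative rule.

    Scanning correlation thresholds downward from 1, the derivative at t is
    (AMI(t) - AMI(t + window*step)) / (window*step); the first t whose
    derivative magnitude falls below ``deriv_threshold`` is chosen. If the
    rule never fires, the max-AMI threshold is returned with a warning.
    """
    curve = ami_curve(dendrogram, labels, step=step)
    chosen, saturated = apply_derivative_rule(
        curve["threshold"].to_numpy(), curve["ami"].to_numpy(),
        step=step, window=window, deriv_threshold=deriv_threshold,
    )
    flat = dendrogram.cut(max(1.0 - float(chosen), 0.0))
    clusters = pd.Series(flat, index=pd.Index(dendrogram.ids, name="protein_id"))
    return CutoffReport(
        standard=standard_name,
        threshold=float(chosen),
        curve=curve,
        clusters=clusters,
        saturated=saturated,
    )


def silhouette_correlation(X, labels) -> float:
    """Mean silhouette (b - a) / max(a, b) under correlation distance."""
    return float(silhouette_score(X, labels, metric="correlation"))


def subcompartment_clusters(
    afps_by_localization: dict[str, pd.DataFrame],
    grid=None,
    min_group: int = 3,
):
    """Per-localization sub-clustering with a silhouette-selected threshold.

    Each localization group gets its own average-linkage correlation tree;
    the distance threshold maximizing the median silhouette across groups is
    applied to all of them. Groups smaller than ``min_group`` are skipped.
    Returns ``(clusters, table, best_threshold)`` where clusters maps
    localization -> Series(protein_id -> cluster id).
    """
    if grid is None:
        grid = np.round(np.arange(0.25, 0.751, 0.05), 10)
    trees = {}
    for loc, df in afps_by_localization.items():
        if len(df) < min_group:
            warnings.warn(f"localization {loc!r} has <{min_group} profiles; skipped")
            continue
        trees[loc] = (build_dendrogram(df), feature_matrix(df), list(df.index))
    if not trees:
        raise ValueError("no localization group large enough to cluster")
    records = []
    for t in grid:
        sils = []
        for loc, (dend, X, _) in trees.items():
            flat = dend.cut(float(t))
            if len(np.unique(flat)) < 2 or len(np.unique(flat)) >= len(X):
                continue
            sils.append(silhouette_correlation(X, flat))
        records.append(
            {"threshold": float(t), "median_silhouette": float(np.median(sils)) if sils else np.nan}
        )
    table = pd.DataFrame(records)
    valid = table.dropna(subset=["median_silhouette"])
    best = float(valid.loc[valid.median_silhouette.idxmax(), "threshold"]) if not valid.empty else 0.5
    clusters = {
        loc: pd.Series(dend.cut(best), index=pd.Index(ids, name="protein_id"))
        for loc, (dend, _, ids) in trees.items()
    }
    return clusters, table, best


def embed_annotate(
    profiles: pd.DataFrame,
    labels: dict[str, str] | None = None,
    perplexity: float = 40.0,
    kde: bool = True,
    random_state: int = 0,
    grid_size: int = 80,
):
    """t-SNE embedding of profiles with per-label Gaussian KDE annotation.

    Points outside two standard deviations of the mean on either embedded
    axis are dropped before density estimation (Scott's-rule bandwidth).
    Returns ``(coords, densities)``; densities maps label -> dict with the
    evaluation grid and the normalized density surface.
    """
    X = feature_matrix(profiles)
    if len(X) <= perplexity:
        raise ValueError(
            f"{len(X)} profiles cannot support perplexity {perplexity}; lower it"
        )
    emb = TSNE(
        n_components=2, perplexity=perplexity, init="pca", random_state=random_state
    ).fit_transform(X)
    coords = pd.DataFrame(emb, index=profiles.index, columns=["tsne1", "tsne2"])
    if labels is not None:
        coords["label"] = [labels.get(p) for p in profiles.index]
    densities = {}
    if kde and labels is not None:
        inlier = np.ones(len(coords), dtype=bool)
        for col in ("tsne1", "tsne2"):
            v = coords[col].to_numpy()
            inlier &= np.abs(v - v.mean()) <= 2 * v.std()
        kept = coords[inlier]
        # pad the evaluation grid so the kernels' tails are captured
        for_x = coords.tsne1.to_numpy()
        for_y = coords.tsne2.to_numpy()
        mx = 0.3 * (for_x.max() - for_x.min() + 1.0)
        my = 0.3 * (for_y.max() - for_y.min() + 1.0)
        xg = np.linspace(for_x.min() - mx, for_x.max() + mx, grid_size)
        yg = np.linspace(for_y.min() - my, for_y.max() + my, grid_size)
        xx, yy = np.meshgrid(xg, yg)
        for lab in sorted({v for v in kept.get("label", pd.Series()) if v is not None}):
            pts = kept[kept.label == lab][["tsne1", "tsne2"]].to_numpy().T
            if pts.shape[1] < 3:
                continue
            dens = gaussian_kde(pts)(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
            densities[lab] = {"x": xg, "y": yg, "density": dens}
    return coords, densities


def filter_2sd_outliers(points: np.ndarray) -> np.ndarray:
    """Boolean inlier mask: within two SD of the mean on every axis."""
    pts = np.asarray(points, dtype=float)
    keep = np.ones(len(pts), dtype=bool)
    for d in range(pts.shape[1]):
        v = pts[:, d]
        keep &= np.abs(v - v.mean()) <= 2 * v.std()
    return keep
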
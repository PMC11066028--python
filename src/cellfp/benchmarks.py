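"""Feature-profile quality scoring against annotation standards.

Two complementary views: information retrieval (rank all protein pairs by
aFP correlation distance, mark co-annotated pairs positive, score with
average precision and maximal F1) and clustering quality (cut an
average-linkage correlation dendrogram across similarity thresholds and
report the best adjusted mutual information against the standard's labels).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_mutual_info_score

from .network import feature_matrix


@dataclass
class AnnotationStandard:
    """protein_id -> label set, with the positivity rule for co-annotation.

    ``overlap_rule`` is "exact" (identical label sets; used for pathway and
    complex standards) or "half_overlap" (at least half the labels shared;
    used for GO standards, operationalized as |A∩B| >= 0.5 * min(|A|, |B|),
    switchable to Jaccard >= 0.5 via ``half_overlap_denominator="union"``).
    """

    name: str
    mapping: dict[str, frozenset]
    overlap_rule: str = "exact"
    half_overlap_denominator: str = "min"

    def __post_init__(self):
        self.mapping = {
            p: frozenset(ls) for p, ls in self.mapping.items() if len(ls) > 0
        }

    def annotated(self):
        return sorted(self.mapping)

    def single_label(self):
        """Proteins with exactly one label (the AMI evaluation subset)."""
        return {p: next(iter(ls)) for p, ls in self.mapping.items() if len(ls) == 1}

    def is_positive(self, a: str, b: str) -> bool:
        la, lb = self.mapping[a], self.mapping[b]
        if self.overlap_rule == "exact":
            return la == lb
        inter = len(la & lb)
        if self.half_overlap_denominator == "union":
            return inter >= 0.5 * len(la | lb)
        return inter >= 0.5 * min(len(la), len(lb))

    @classmethod
    def from_tsv(cls, path, name=None, overlap_rule="exact"):
        """Read (protein_id, label[, standard_name]) rows from TSV."""
        df = pd.read_csv(path, sep="\t", comment="#")
        mapping: dict[str, set] = {}
        for _, row in df.iterrows():
            mapping.setdefault(str(row.iloc[0]), set()).add(str(row.iloc[1]))
        return cls(name=name or Path(path).stem, mapping=mapping, overlap_rule=overlap_rule)


def correlation_distance(u, v):
    """1 - Pearson correlation between two profile vectors."""
    return 1.0 - float(np.corrcoef(u, v)[0, 1])


def copair_rank(afps: pd.DataFrame, standard: AnnotationStandard) -> pd.DataFrame:
    """Rank annotated aFP pairs by correlation distance, ascending.

    Returns a frame with columns (protein_a, protein_b, distance,
    is_positive); proteins without annotations are left out.
    """
    proteins = [p for p in afps.index if p in standard.mapping]
    if len(proteins) < 2:
        raise ValueError("need at least 2 annotated proteins")
    X = feature_matrix(afps.loc[proteins])
    corr = np.corrcoef(X)
    rows = []
    for i, j in combinations(range(len(proteins)), 2):
        rows.append(
            (proteins[i], proteins[j], 1.0 - corr[i, j],
             standard.is_positive(proteins[i], proteins[j]))
        )
    df = pd.DataFrame(rows, columns=["protein_a", "protein_b", "distance", "is_positive"])
    return df.sort_values("distance", kind="stable", ignore_index=True)


def average_precision(ranked) -> float:
    """AP of a ranked positive/negative sequence (precision averaged at the
    rank of each positive)."""
    rel = _relevance(ranked)
    n_pos = int(rel.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined without positives")
    cum = np.cumsum(rel)
    precision_at = cum / np.arange(1, len(rel) + 1)
    return float((precision_at * rel).sum() / n_pos)


def max_f_score(ranked) -> float:
    """Maximum F1 over all cut points of the ranking."""
    rel = _relevance(ranked)
    n_pos = int(rel.sum())
    if n_pos == 0:
        raise ValueError("F-score undefined without positives")
    tp = np.cumsum(rel)
    k = np.arange(1, len(rel) + 1)
    f1 = 2 * tp / (k + n_pos)  # 2TP / (2TP + FP + FN)
    return float(f1.max())


def f_score_at(ranked, distance_threshold: float) -> float:
    """F1 at a fixed distance cut (override for the max-F1 operating point)."""
    df = ranked if isinstance(ranked, pd.DataFrame) else None
    if df is None:
        raise ValueError("threshold operating point needs the ranked DataFrame")
    pred = df["distance"].to_numpy() <= distance_threshold
    rel = df["is_positive"].to_numpy().astype(bool)
    tp = int((pred & rel).sum())
    if tp == 0:
        return 0.0
    return 2 * tp / (pred.sum() + rel.sum())


def _relevance(ranked) -> np.ndarray:
    if isinstance(ranked, pd.DataFrame):
        return ranked["is_positive"].to_numpy().astype(float)
    return np.asarray(ranked, dtype=float)


def ami_score(labels_true, labels_pred) -> float:
    """Adjusted mutual information (scikit-learn, arithmetic normalization)."""
    return float(adjusted_mutual_info_score(labels_true, labels_pred))


def ami_over_thresholds(
    afps: pd.DataFrame,
    standard: AnnotationStandard,
    thresholds=None,
    min_cluster_size: int = 2,
):
    """Best AMI of dendrogram cuts against the standard's single-label subset.

    Clusters the aFPs (average linkage, correlation distance), cuts at each
    similarity threshold (distance = 1 - threshold), drops clusters smaller
    than ``min_cluster_size``, and scores AMI on proteins that carry exactly
    one label. Returns ``(best_ami, best_threshold, curve)``.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.10, 0.951, 0.05), 10)
    single = standard.single_label()
    proteins = [p for p in afps.index if p in single]
    if len(proteins) < 2:
        raise ValueError("need at least 2 singly-annotated proteins")
    X = feature_matrix(afps.loc[proteins])
    Z = linkage(pdist(X, metric="correlation"), method="average")
    truth = np.array([single[p] for p in proteins])
    records = []
    for t in thresholds:
        labels = fcluster(Z, t=max(1.0 - t, 0.0), criterion="distance")
        sizes = np.bincount(labels)
        keep = sizes[labels] >= min_cluster_size
        if keep.sum() < 2 or len(np.unique(truth[keep])) < 1:
            records.append({"threshold": float(t), "ami": np.nan, "n_clusters": 0})
            continue
        records.append(
            {
                "threshold": float(t),
                "ami": ami_score(truth[keep], labels[keep]),
                "n_clusters": int(len(np.unique(labels[keep]))),
            }
        )
    curve = pd.DataFrame(records)
    valid = curve.dropna(subset=["ami"])
    if valid.empty:
        import warnings

        warnings.warn("degenerate clustering at every threshold")
        return float("nan"), float("nan"), curve
    best = valid.loc[valid.ami.idxmax()]
    return float(best.ami), float(best.threshold), curve


def score_profiles(afps: pd.DataFrame, standards: list[AnnotationStandard]) -> pd.DataFrame:
    """AP, max-F1 and best AMI for each standard (one row per standard)."""
    rows = []
    for std in standards:
        ranked = copair_rank(afps, std)
        best_ami, best_t, _ = ami_over_thresholds(afps, std)
        rows.append(
            {
                "standard": std.name,
                "average_precision": average_precision(ranked),
                "max_f1": max_f_score(ranked),
                "best_ami": best_ami,
                "best_ami_threshold": best_t,
            }
        )
    return pd.DataFrame(rows)
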
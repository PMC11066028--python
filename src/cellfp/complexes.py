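"""Protein-complex discovery from single-cell feature profiles by adaptive
dendrogram thresholding.

The scFP dendrogram (average linkage, correlation distance) is traced from
coarse to fine in steps of 0.05 correlation-distance points. A *root
cluster* is the coarsest cut of a branch whose protein composition persists
(>= 95% Jaccard) to the next evaluated threshold — the level at which the
profiles inside are practically inseparable. Each root is scored by

    s = c * d / k

where c (cell ratio) is the mean fraction of each member protein's cells
captured by the cluster, k (elbow point) is the correlation distance at the
cut, and d (descendant ratio) is the fraction of finer-threshold descendant
clusters that agree with the root. Descendant agreement is made operational
by annotating every protein to the root holding the plurality of its scFPs;
a descendant agrees when at least half of its scFPs belong to proteins
annotated to this root. Roots with s >= 0.6 are high-confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import fisher_exact
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN, KMeans


@dataclass(eq=False)
class RootCluster:
    members: np.ndarray  # scFP row indices
    proteins: frozenset
    elbow_point: float  # correlation distance k at the cut
    cell_ratio: float = float("nan")  # c
    descendant_ratio: float = float("nan")  # d
    score: float = float("nan")  # s = c*d/k
    k_floored: bool = False

    @property
    def size(self):
        return len(self.members)


def trace_dendrogram(Z: np.ndarray, protein_ids, step: float = 0.05):
    """Flat cluster compositions at every division threshold (descending).

    Returns a list of (threshold, labels) from the coarsest evaluated
    threshold (above the tree root) down to 0 in ``step`` increments.
    """
    protein_ids = np.asarray(protein_ids)
    max_h = float(Z[:, 2].max()) if len(Z) else 0.0
    # start strictly below the final merge so the coarsest evaluated level is
    # already divided (plateaus above the tree root are vacuous)
    top = max(np.floor((max_h - 1e-9) / step) * step, step)
    thresholds = np.round(np.arange(top, -step / 2, -step), 10)
    return [(float(t), fcluster(Z, t=max(t, 0.0), criterion="distance")) for t in thresholds]


def _clusters_at(labels: np.ndarray) -> list[np.ndarray]:
    return [np.where(labels == u)[0] for u in np.unique(labels)]


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def find_root_clusters(
    trace,
    protein_ids,
    plateau_tolerance: float = 0.95,
    min_proteins: int = 2,
) -> list[RootCluster]:
    """Identify plateau (root) clusters in a dendrogram trace.

    Scanning coarse to fine, a cluster with at least ``min_proteins``
    distinct proteins becomes a root when the protein composition of its
    largest child at the next evaluated threshold matches its own at Jaccard
    >= ``plateau_tolerance``. Branches below an accepted root are not
    descended into, so roots are disjoint.
    """
    protein_ids = np.asarray(protein_ids)
    roots: list[RootCluster] = []
    claimed = np.zeros(len(protein_ids), dtype=bool)
    seen: set[frozenset] = set()
    for level in range(len(trace) - 1):
        t, labels = trace[level]
        for members in _clusters_at(labels):
            if claimed[members[0]]:
                continue
            key = frozenset(members.tolist())
            if key in seen:  # same cluster already judged at a coarser level
                continue
            seen.add(key)
            prots = frozenset(protein_ids[members])
            if len(prots) < min_proteins:
                continue
            # composition must persist across the branch's next actual
            # division (levels where the cluster does not divide are no-ops)
            child_sets = None
            for j in range(level + 1, len(trace)):
                if trace[j][0] <= 0:
                    break  # the zero-distance cut shatters everything
                sub = trace[j][1][members]
                if len(np.unique(sub)) > 1:
                    child_sets = [
                        frozenset(protein_ids[members[c]]) for c in _clusters_at(sub)
                    ]
                    break
            if child_sets is None:
                best = 1.0  # never divides within the trace: fully stable
            else:
                best = max(_jaccard(prots, cs) for cs in child_sets)
            if best >= plateau_tolerance:
                roots.append(
                    RootCluster(members=members, proteins=prots, elbow_point=float(t))
                )
                claimed[members] = True
    if not roots:
        warnings.warn("no plateau clusters found")
    return roots


def _annotate_proteins_to_roots(roots, protein_ids):
    """protein -> index of the root holding the plurality of its scFPs."""
    protein_ids = np.asarray(protein_ids)
    totals = pd.Series(protein_ids).value_counts()
    table = {}
    for p in totals.index:
        in_roots = [np.isin(np.where(protein_ids == p)[0], r.members).sum() for r in roots]
        table[p] = int(np.argmax(in_roots)) if in_roots and max(in_roots) > 0 else -1
    return table


def score_root_cluster(
    root: RootCluster,
    trace,
    protein_ids,
    root_annotation: dict | None = None,
    roots: list[RootCluster] | None = None,
    descendant_levels: int = 2,
    k_floor: float = 1e-4,
) -> RootCluster:
    """Attach c, d, k and s = c*d/k to a root cluster."""
    protein_ids = np.asarray(protein_ids)
    if len(root.proteins) < 2:
        raise ValueError("root cluster needs at least 2 proteins")
    totals = pd.Series(protein_ids).value_counts()
    member_prots = pd.Series(protein_ids[root.members]).value_counts()
    c = float(np.mean([member_prots[p] / totals[p] for p in root.proteins]))

    if roots is None:
        roots = [root]
    if root_annotation is None:
        root_annotation = _annotate_proteins_to_roots(roots, protein_ids)
    my_index = next(i for i, r in enumerate(roots) if r is root)
    # descendants: flat clusters at the next finer evaluated thresholds that
    # lie inside this root's branch
    levels = [i for i, (t, _) in enumerate(trace) if t < root.elbow_point]
    member_set = set(root.members.tolist())
    agree = total = 0
    for li in levels[:descendant_levels]:
        _, labels = trace[li]
        for cl in _clusters_at(labels):
            if not member_set.issuperset(cl.tolist()):
                continue
            total += 1
            prots = protein_ids[cl]
            in_root = np.array([root_annotation.get(p, -1) == my_index for p in prots])
            if in_root.mean() >= 0.5:
                agree += 1
    d = agree / total if total else 0.0
    k = root.elbow_point
    floored = k < k_floor
    if floored:
        warnings.warn("elbow point below floor; clamping")
        k = k_floor
    root.cell_ratio = c
    root.descendant_ratio = d
    root.score = c * d / k
    root.k_floored = floored
    return root


def high_confidence_clusters(roots: list[RootCluster], cutoff: float = 0.6):
    """Roots with score >= cutoff, sorted by score descending."""
    kept = [r for r in roots if r.score >= cutoff]
    return sorted(kept, key=lambda r: -r.score)


class AdaptiveThresholdClustering(BaseEstimator, ClusterMixin):
    """Adaptive dendrogram thresholding over scFPs (the full pipeline).

    ``fit(X, protein_ids)`` builds the correlation/average-linkage tree,
    traces it in 0.05 steps, finds plateau roots, scores them and keeps the
    high-confidence set. ``labels_`` assigns each scFP its high-confidence
    cluster index, -1 elsewhere.
    """

    def __init__(
        self,
        step=0.05,
        plateau_tolerance=0.95,
        score_cutoff=0.6,
        descendant_levels=2,
        k_floor=1e-4,
    ):
        self.step = step
        self.plateau_tolerance = plateau_tolerance
        self.score_cutoff = score_cutoff
        self.descendant_levels = descendant_levels
        self.k_floor = k_floor

    def fit(self, X, protein_ids):
        X = np.asarray(X, dtype=float)
        protein_ids = np.asarray(protein_ids)
        if len(X) < 10:
            raise ValueError("adaptive thresholding needs at least 10 scFPs")
        Z = linkage(pdist(X, metric="correlation"), method="average")
        self.trace_ = trace_dendrogram(Z, protein_ids, step=self.step)
        roots = find_root_clusters(self.trace_, protein_ids, self.plateau_tolerance)
        annotation = _annotate_proteins_to_roots(roots, protein_ids)
        self.roots_ = [
            score_root_cluster(
                r, self.trace_, protein_ids, root_annotation=annotation, roots=roots,
                descendant_levels=self.descendant_levels, k_floor=self.k_floor,
            )
            for r in roots
        ]
        self.high_confidence_ = high_confidence_clusters(self.roots_, self.score_cutoff)
        self.labels_ = np.full(len(X), -1, dtype=int)
        for ci, root in enumerate(self.high_confidence_):
            self.labels_[root.members] = ci
        return self

    def fit_predict(self, X, protein_ids=None):
        return self.fit(X, protein_ids).labels_

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, r in enumerate(self.high_confidence_):
            for p in sorted(r.proteins):
                rows.append(
                    {"cluster_id": ci, "protein_id": p, "c": r.cell_ratio,
                     "d": r.descendant_ratio, "k": r.elbow_point, "s": r.score}
                )
        return pd.DataFrame(rows, columns=["cluster_id", "protein_id", "c", "d", "k", "s"])


# --------------------------------------------------------------------------
# evaluation against a complex standard


@dataclass
class ComplexStandard:
    """complex_id -> protein set; restricted to complexes with at least
    ``min_members`` imaged members."""

    mapping: dict[str, frozenset]
    min_members: int = 3

    def restrict(self, imaged) -> "ComplexStandard":
        imaged = set(imaged)
        mapping = {
            cid: frozenset(ps & imaged)
            for cid, ps in self.mapping.items()
            if len(ps & imaged) >= self.min_members
        }
        return ComplexStandard(mapping=mapping, min_members=self.min_members)

    def complex_of(self) -> dict[str, str]:
        out = {}
        for cid, ps in self.mapping.items():
            for p in ps:
                out[p] = cid
        return out

    @classmethod
    def from_tsv(cls, path, min_members=3):
        df = pd.read_csv(path, sep="\t", comment="#")
        mapping: dict[str, set] = {}
        for _, row in df.iterrows():
            mapping.setdefault(str(row.iloc[0]), set()).add(str(row.iloc[1]))
        return cls(mapping={k: frozenset(v) for k, v in mapping.items()},
                   min_members=min_members)


def _pair_count(n):
    return n * (n - 1) // 2


def pairwise_f1(labels, protein_ids, standard: ComplexStandard):
    """Global pairwise precision/recall/F1 of a clustering against a complex
    standard.

    Every unordered pair of scFPs of standard-covered proteins is labelled
    positive when the two proteins share a complex; predicted positive when
    the two scFPs share a cluster (label >= 0). Unannotated proteins are
    left out.
    """
    labels = np.asarray(labels)
    protein_ids = np.asarray(protein_ids)
    cof = standard.complex_of()
    keep = np.array([p in cof for p in protein_ids])
    if not keep.any():
        raise ValueError("standard covers no proteins in the data")
    lab = labels[keep]
    comp = np.array([cof[p] for p in protein_ids[keep]])
    n_pos = sum(_pair_count(n) for n in pd.Series(comp).value_counts())
    if n_pos == 0:
        raise ValueError("no co-complex pairs in the standard")
    clustered = lab >= 0
    pp = sum(_pair_count(n) for n in pd.Series(lab[clustered]).value_counts())
    ct = pd.crosstab(pd.Series(lab[clustered]), pd.Series(comp[clustered]))
    tp = int(sum(_pair_count(int(v)) for v in ct.to_numpy().ravel()))
    precision = tp / pp if pp else 0.0
    recall = tp / n_pos
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return f1, precision, recall


def per_cluster_f1(labels, protein_ids, standard: ComplexStandard) -> pd.Series:
    """Pairwise F1 of each predicted cluster.

    For one cluster: predicted positives are its internal pairs; relevant
    truth positives are co-complex pairs touching at least one of its scFPs.
    Only scFPs of standard-covered proteins count.
    """
    labels = np.asarray(labels)
    protein_ids = np.asarray(protein_ids)
    cof = standard.complex_of()
    keep = np.array([p in cof for p in protein_ids])
    lab = np.where(keep, labels, -1)
    comp_all = np.array([cof.get(p, "") for p in protein_ids])
    scores = {}
    for u in np.unique(lab[lab >= 0]):
        members = np.where(lab == u)[0]
        comp = comp_all[members]
        pp = _pair_count(len(members))
        tp = sum(_pair_count(int(n)) for n in pd.Series(comp).value_counts())
        touching = 0
        for cid, n_in in pd.Series(comp).value_counts().items():
            n_total = int(np.sum((comp_all == cid) & keep))
            touching += _pair_count(n_total) - _pair_count(n_total - int(n_in))
        precision = tp / pp if pp else 0.0
        recall = tp / touching if touching else 0.0
        scores[int(u)] = (
            2 * precision * recall / (precision + recall) if precision + recall else 0.0
        )
    return pd.Series(scores, name="f1")


def fold_enrichment(cluster_proteins, standard: ComplexStandard, background):
    """Best-enriched complex for one cluster (one-sided Fisher's exact test).

    fold = (hits / cluster size) / (complex size / background size), with all
    sets intersected with the background. Returns (complex_id, fold, p).
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    if not set(cluster_proteins) <= background:
        raise ValueError("background must contain the cluster proteins")
    cluster = set(cluster_proteins)
    best = (None, 0.0, 1.0)
    for cid, ps in standard.mapping.items():
        comp = set(ps) & background
        if not comp:
            continue
        hits = len(cluster & comp)
        fold = (hits / len(cluster)) / (len(comp) / len(background)) if cluster else 0.0
        table = [
            [hits, len(cluster) - hits],
            [len(comp) - hits, len(background) - len(cluster) - len(comp) + hits],
        ]
        _, p = fisher_exact(table, alternative="greater")
        if fold > best[1] or (fold == best[1] and p < best[2]):
            best = (cid, fold, float(p))
    return best


# --------------------------------------------------------------------------
# baseline clustering families


def baseline_grid(X, protein_ids, standard: ComplexStandard) -> pd.DataFrame:
    """Best-per-family clustering baselines scored by median per-cluster F1.

    Grids: k-means k = 5..500 step 5 (clipped to the sample count), DBSCAN
    eps = 0.1..5 step 0.1 on the precomputed correlation-distance matrix,
    and flat dendrogram cuts at correlation distance 0.05..0.5 step 0.025.
    """
    X = np.asarray(X, dtype=float)
    protein_ids = np.asarray(protein_ids)
    n = len(X)
    D = squareform(pdist(X, metric="correlation"))
    Z = linkage(squareform(D, checks=False), method="average")

    def median_f1(labels):
        s = per_cluster_f1(labels, protein_ids, standard)
        return float(s.median()) if len(s) else 0.0

    rows = []
    kgrid = [k for k in range(5, 501, 5) if k < n]
    if not kgrid:
        raise ValueError("k-means grid empty after clipping")
    best = (None, -1.0)
    for k in kgrid:
        lab = KMeans(n_clusters=k, n_init=3, random_state=0).fit_predict(X)
        f1 = median_f1(lab)
        if f1 > best[1]:
            best = (k, f1)
    rows.append({"method": "kmeans", "param": best[0], "median_f1": best[1]})

    best = (None, -1.0)
    for eps in np.round(np.arange(0.1, 5.01, 0.1), 10):
        lab = DBSCAN(eps=eps, min_samples=5, metric="precomputed").fit_predict(D)
        f1 = median_f1(lab) if (lab >= 0).any() else 0.0
        if f1 > best[1]:
            best = (float(eps), f1)
    rows.append({"method": "dbscan", "param": best[0], "median_f1": best[1]})

    best = (None, -1.0)
    for t in np.round(np.arange(0.05, 0.501, 0.025), 10):
        lab = fcluster(Z, t=float(t), criterion="distance")
        f1 = median_f1(lab)
        if f1 > best[1]:
            best = (float(t), f1)
    rows.append({"method": "hierarchical", "param": best[0], "median_f1": best[1]})
    return pd.DataFrame(rows)
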
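"""Phenotype landscape: clustering attractors into domains.

The deduplicated attractor profiles (attractors x nodes) are reduced by PCA
for visualisation, grouped by hierarchical clustering and by K-means
(k = 3 by default: one normal domain and two tumor subtype domains), and
each cluster is labeled by matching its binarized centroid against
phenotype marker signatures.  Domain size is reported as the share of
unique attractor profiles falling in each cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .attractors import Attractor, AttractorEnsemble
from .netspec import NetworkSpec

logger = logging.getLogger(__name__)

#: Marker signature of the normal gastric epithelium domain: strong
#: adhesion and differentiation markers high; proliferation, inflammation
#: and angiogenesis drivers low.  User-overridable; only markers present in
#: the network are used.
NORMAL_SIGNATURE: dict[str, int] = {
    "E-cadherin": 1,
    "HNF4A": 1,
    "TGF-beta": 1,
    "CyclinD": 0,
    "CyclinE/Cdk2": 0,
    "E2F": 0,
    "NF-kB": 0,
    "VEGF": 0,
}

#: Tumor subtype signatures: intestinal-type (Wnt/beta-catenin-Cdx2 axis)
#: and gastric/diffuse-type (Sox2-Shh axis).
SUBTYPE_SIGNATURES: dict[str, dict[str, int]] = {
    "intestinal (Wnt/beta-catenin-Cdx2)": {"Wnt": 1, "beta-catenin": 1, "Cdx2": 1},
    "gastric (Sox2-Shh)": {"Sox2": 1, "Shh": 1},
}

#: Default functional-module grouping for module-level ON/OFF summaries.
DEFAULT_MODULES: dict[str, list[str]] = {
    "cell cycle": ["CyclinD", "CyclinE/Cdk2", "E2F", "Myc"],
    "apoptosis": ["Caspase3", "p53", "Bax"],
    "growth factors": ["EGF", "AKT", "Ras"],
    "adhesion": ["E-cadherin"],
    "angiogenesis": ["VEGF", "HIF"],
    "metabolism": ["HNF4A", "Glycolysis"],
    "inflammation": ["NF-kB", "IL6"],
    "gastric differentiation": ["Sox2", "Shh", "Cdx2", "HNF1a"],
}


class PhenotypeSignature(dict):
    """Mapping node -> expected binary level (1 high, 0 low)."""

    def restrict(self, spec: NetworkSpec) -> "PhenotypeSignature":
        return PhenotypeSignature({n: v for n, v in self.items() if n in spec})


class ModuleMap(dict):
    """Mapping functional-module name -> member node list."""

    def validate(self, spec: NetworkSpec) -> None:
        for name, members in self.items():
            if not members:
                raise ValueError(f"module {name!r} is empty")
            for m in members:
                spec.index(m)


# -- core operations -------------------------------------------------------


@dataclass
class PCAProjection:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def run_pca(features: np.ndarray, n_components: int | None = None) -> PCAProjection:
    """PCA of the attractor-by-node matrix (full rank unless truncated)."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if np.allclose(X, X[0], atol=1e-15):
        raise ValueError("zero variance: all rows identical")
    k = n_components or min(X.shape)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAProjection(
        scores=scores,
        loadings=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=pca.mean_,
    )


def hier_cluster(
    features: np.ndarray, k: int, method: str = "average", metric: str = "euclidean"
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering; returns (linkage matrix, k-cut labels 0..k-1)."""
    X = np.asarray(features, dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {X.shape[0]}")
    Z = linkage(X, method=method, metric=metric)
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    return Z, labels


@dataclass
class KMeansResult:
    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float
    seed: int | None


def kmeans_cluster(
    features: np.ndarray, k: int, seed: int | None = 0, restarts: int = 10
) -> KMeansResult:
    """Seeded K-means with restarts (best inertia kept)."""
    X = np.asarray(features, dtype=float)
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds number of distinct rows {n_distinct}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(X)
    return KMeansResult(k, labels, km.cluster_centers_, float(km.inertia_), seed)


def proportions(assignments: Sequence[int] | np.ndarray) -> pd.DataFrame:
    """Per-cluster counts and percentages (100 * count / total)."""
    a = np.asarray(assignments)
    if a.size == 0:
        raise ValueError("empty assignments")
    clusters, counts = np.unique(a, return_counts=True)
    pct = 100.0 * counts / a.size
    return pd.DataFrame({"cluster": clusters, "count": counts, "percent": pct})


def signature_from_centroid(
    centroid: np.ndarray, spec: NetworkSpec, threshold: np.ndarray | float | None = None
) -> PhenotypeSignature:
    """Binarize a centroid into a marker signature over all nodes.

    Useful when no curated marker panel applies (e.g. random fixtures or
    exploratory networks): designate one fitted domain as the reference
    phenotype and screen against its binarized centroid.
    """
    c = np.asarray(centroid, dtype=float)
    thr = 0.5 if threshold is None else threshold
    binary = (c >= np.broadcast_to(np.asarray(thr, float), c.shape)).astype(int)
    return PhenotypeSignature({n: int(b) for n, b in zip(spec.nodes, binary)})


def binarize_threshold(features: np.ndarray) -> np.ndarray:
    """Per-node midpoint of the observed range (fallback 0.5 where flat)."""
    X = np.asarray(features, dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    mid = (lo + hi) / 2.0
    flat = (hi - lo) < 1e-12
    mid[flat] = 0.5
    return mid


def label_phenotypes(
    centroids: np.ndarray,
    signature: Mapping[str, int],
    spec: NetworkSpec,
    subtype_signatures: Mapping[str, Mapping[str, int]] | None = None,
    threshold: np.ndarray | float | None = None,
) -> tuple[list[str], np.ndarray]:
    """Label clusters by signature agreement of their binarized centroids.

    The cluster whose binarized centroid agrees best with the normal
    signature is labeled ``"normal"`` (ties: lowest cluster index, logged);
    remaining clusters get the best-matching subtype signature label, or
    ``"abnormal-<i>"`` when no subtype signatures apply.  Returns the label
    list and the per-cluster normal-agreement fractions.
    """
    C = np.atleast_2d(np.asarray(centroids, dtype=float))
    if C.shape[0] < 1:
        raise ValueError("need at least one centroid")
    for node in signature:
        spec.index(node)  # unknown marker -> error
    thr = binarize_threshold(C) if threshold is None else threshold
    binary = (C >= thr).astype(int)

    def agreement(sig: Mapping[str, int]) -> np.ndarray:
        idx = [spec.index(n) for n in sig]
        want = np.array([sig[n] for n in sig])
        if not idx:
            return np.zeros(C.shape[0])
        return (binary[:, idx] == want).mean(axis=1)

    normal_agree = agreement(signature)
    best = int(np.flatnonzero(normal_agree == normal_agree.max())[0])
    if np.sum(normal_agree == normal_agree.max()) > 1:
        logger.info("normal-signature tie; taking lowest cluster index %d", best)
    labels = [""] * C.shape[0]
    labels[best] = "normal"

    rest = [i for i in range(C.shape[0]) if i != best]
    # fallback names are ranked by a permutation-invariant key (agreement
    # with the normal signature, then centroid values), not cluster index
    rest_ranked = sorted(rest, key=lambda i: (-normal_agree[i], tuple(C[i])))
    fallback = {i: f"abnormal-{r + 1}" for r, i in enumerate(rest_ranked)}
    subs = dict(subtype_signatures or {})
    for i in rest:
        chosen = None
        best_score = -1.0
        for name, sig in subs.items():
            sig_known = {n: v for n, v in sig.items() if n in spec}
            if not sig_known:
                continue
            score = agreement(sig_known)[i]
            if score > best_score:
                best_score, chosen = score, name
        labels[i] = chosen if chosen is not None else fallback[i]
    # disambiguate duplicate subtype labels
    seen: dict[str, int] = {}
    for i in rest:
        seen[labels[i]] = seen.get(labels[i], 0) + 1
        if seen[labels[i]] > 1:
            labels[i] = f"{labels[i]} ({seen[labels[i]]})"
    return labels, normal_agree


def module_activity(
    attractor: Attractor | np.ndarray,
    module_map: Mapping[str, Sequence[str]],
    spec: NetworkSpec,
    threshold: np.ndarray | float = 0.5,
) -> dict[str, str]:
    """Summarize an attractor at the functional-module level.

    A module is ON when at least half of its member nodes are above
    threshold, OFF otherwise, and ON|OFF when any member node is flagged
    oscillatory (sustained swings rather than a fixed level).
    """
    if isinstance(attractor, Attractor):
        x = attractor.x
        osc = attractor.node_oscillating
    else:
        x = np.asarray(attractor, dtype=float)
        osc = None
    thr = np.broadcast_to(np.asarray(threshold, dtype=float), x.shape)
    out: dict[str, str] = {}
    for name, members in module_map.items():
        if not members:
            raise ValueError(f"module {name!r} is empty")
        idx = [spec.index(m) for m in members]
        if osc is not None and any(osc[i] for i in idx):
            out[name] = "ON|OFF"
            continue
        on = (x[idx] >= thr[idx]).mean() >= 0.5
        out[name] = "ON" if on else "OFF"
    return out


# -- aggregate landscape ----------------------------------------------------


@dataclass
class LandscapeModel:
    """Clustered phenotype landscape of an attractor ensemble."""

    ensemble: AttractorEnsemble
    features: np.ndarray
    pca: PCAProjection
    linkage: np.ndarray
    hier_labels: np.ndarray
    kmeans: KMeansResult
    proportions: pd.DataFrame
    labels: list[str]
    normal_agreement: np.ndarray
    signature: dict = field(default_factory=dict)

    @property
    def normal_percent(self) -> float:
        tab = self.proportions
        row = tab[tab["label"] == "normal"]
        return float(row["percent"].iloc[0]) if len(row) else 0.0

    def cluster_table(self) -> pd.DataFrame:
        df = self.ensemble.to_frame()
        df = df[~df["oscillatory"].astype(bool)].reset_index(drop=True)
        df.insert(0, "attractor", np.arange(len(df)))
        df["cluster"] = self.kmeans.assignments
        df["label"] = [self.labels[c] for c in self.kmeans.assignments]
        return df

    def plot(self, ax=None):
        """PCA scatter of attractors colored by cluster, centroids marked x."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        S = self.pca.scores
        markers = [".", "*", "+", "o", "s"]
        for c in range(self.kmeans.k):
            sel = self.kmeans.assignments == c
            ax.scatter(
                S[sel, 0],
                S[sel, 1] if S.shape[1] > 1 else np.zeros(sel.sum()),
                marker=markers[c % len(markers)],
                label=f"{c}: {self.labels[c]}",
            )
        cent = (self.kmeans.centroids - self.pca.mean) @ self.pca.loadings.T
        ax.scatter(
            cent[:, 0],
            cent[:, 1] if cent.shape[1] > 1 else np.zeros(len(cent)),
            marker="x",
            c="k",
            s=80,
        )
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend(fontsize=7)
        return ax


def build_landscape(
    ensemble: AttractorEnsemble,
    k: int = 3,
    seed: int | None = 0,
    restarts: int = 10,
    signature: Mapping[str, int] | None = None,
    subtype_signatures: Mapping[str, Mapping[str, int]] | None = None,
    cluster_on_components: float | None = None,
) -> LandscapeModel:
    """Full landscape analysis of an ensemble: PCA, trees, K-means, labels.

    ``k`` degrades gracefully to the number of distinct profiles when the
    ensemble is smaller than requested.  By default K-means runs in full
    node space; pass ``cluster_on_components`` (a variance fraction, e.g.
    0.9) to cluster on the leading principal components instead.
    """
    spec = ensemble.spec
    X = ensemble.feature_matrix()
    if X.shape[0] == 0:
        raise ValueError("ensemble has no fixed-point attractors to cluster")
    n_distinct = np.unique(X, axis=0).shape[0]
    k_eff = min(k, n_distinct)
    if k_eff < k:
        logger.warning("only %d distinct profiles; using k=%d", n_distinct, k_eff)

    if X.shape[0] >= 2 and n_distinct >= 2:
        pca = run_pca(X)
    else:
        pca = PCAProjection(
            scores=np.zeros((X.shape[0], 1)),
            loadings=np.zeros((1, X.shape[1])),
            explained_variance_ratio=np.array([1.0]),
            mean=X.mean(axis=0),
        )
    feats = X
    if cluster_on_components is not None:
        m = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio), cluster_on_components) + 1)
        feats = pca.scores[:, :m]
    if X.shape[0] >= 2:
        Z, hier_labels = hier_cluster(feats, k_eff)
    else:
        Z, hier_labels = np.empty((0, 4)), np.zeros(X.shape[0], dtype=int)
    km = kmeans_cluster(feats, k_eff, seed=seed, restarts=restarts)

    sig = PhenotypeSignature(signature if signature is not None else NORMAL_SIGNATURE)
    sig = sig.restrict(spec)
    centroids_nodes = (
        km.centroids
        if feats is X
        else pca.mean + km.centroids @ pca.loadings[: km.centroids.shape[1]]
    )
    if sig:
        labels, agree = label_phenotypes(
            centroids_nodes,
            sig,
            spec,
            subtype_signatures=subtype_signatures
            if subtype_signatures is not None
            else SUBTYPE_SIGNATURES,
            threshold=binarize_threshold(X),
        )
    else:
        logger.warning("no signature markers present in network; labeling by index")
        labels = [f"cluster-{i}" for i in range(k_eff)]
        agree = np.zeros(k_eff)

    tab = proportions(km.assignments)
    # include empty clusters (possible in principle) as zero rows
    if len(tab) < k_eff:
        missing = sorted(set(range(k_eff)) - set(tab["cluster"]))
        tab = pd.concat(
            [tab, pd.DataFrame({"cluster": missing, "count": 0, "percent": 0.0})],
            ignore_index=True,
        ).sort_values("cluster", ignore_index=True)
    tab["label"] = [labels[c] for c in tab["cluster"]]

    return LandscapeModel(
        ensemble=ensemble,
        features=X,
        pca=pca,
        linkage=Z,
        hier_labels=hier_labels,
        kmeans=km,
        proportions=tab,
        labels=labels,
        normal_agreement=agree,
        signature=dict(sig),
    )
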
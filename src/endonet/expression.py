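"""Model-to-expression comparison.

Expression cohorts (genes x samples) are clustered with the same machinery
used for the attractor landscape (K-means over samples), and a model
centroid is compared with a data centroid by discretizing both profiles
into a small number of levels and counting node-wise agreement.  With
``levels`` categories, two independent random profiles agree on about
100/levels percent of nodes, which is the reported chance baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .landscape import KMeansResult, kmeans_cluster

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes-by-samples table with optional tumor/normal labels."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    labels: pd.Series | None = None  # index: sample ids

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.values.isna().any().any():
            raise ValueError("missing values in expression matrix")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def load_expression(path: str | Path, label_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a genes-in-rows TSV/CSV (and an optional sample,group table)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"non-numeric value at gene {gene!r}, sample {col!r}")
    df = df.astype(float)
    labels = None
    if label_path is not None:
        lab = pd.read_csv(Path(label_path), sep="\t", header=None, names=["sample", "group"])
        labels = lab.set_index("sample")["group"]
    return ExpressionMatrix(df, labels)


def preprocess(
    matrix: ExpressionMatrix, log_transform: bool = False, zscore: bool = False
) -> ExpressionMatrix:
    """Optional log2 transform and per-gene standardization.

    Zero-variance genes cannot be z-scored and are dropped with a warning.
    """
    df = matrix.values.copy()
    if log_transform:
        if (df <= 0).any().any():
            raise ValueError("log transform requires strictly positive values")
        df = np.log2(df)
    if zscore:
        sd = df.std(axis=1, ddof=0)
        flat = sd < 1e-12
        if flat.any():
            dropped = df.index[flat].tolist()
            warnings.warn(f"dropping zero-variance genes: {dropped}", stacklevel=2)
            df = df.loc[~flat]
            sd = sd.loc[~flat]
        df = df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(df, matrix.labels)


def cluster_samples(
    matrix: ExpressionMatrix, k: int, seed: int | None = 0, restarts: int = 10
) -> tuple[np.ndarray, np.ndarray, KMeansResult]:
    """K-means over samples (columns); returns (assignments, centroids, fit).

    Centroids are gene-space mean profiles of each sample cluster, the
    direct analogue of attractor-domain centroids on the data side.
    """
    X = matrix.values.to_numpy().T  # samples x genes
    if X.shape[0] < k:
        raise ValueError(f"k={k} exceeds number of samples {X.shape[0]}")
    km = kmeans_cluster(X, k, seed=seed, restarts=restarts)
    return km.assignments, km.centroids, km


def discretize_profile(
    profile: np.ndarray,
    levels: int = 4,
    oscillatory: np.ndarray | None = None,
) -> np.ndarray:
    """Discretize a profile into ``levels`` categories.

    The numeric categories split the profile's own range into equal bins
    (levels - 1 numeric bins when an oscillatory category is reserved,
    which is the default: low / intermediate / high / oscillatory).
    """
    p = np.asarray(profile, dtype=float)
    n_numeric = levels - 1 if levels >= 2 else levels
    lo, hi = p.min(), p.max()
    if hi - lo < 1e-12:
        cats = np.zeros(p.size, dtype=int)
    else:
        edges = np.linspace(lo, hi, n_numeric + 1)[1:-1]
        cats = np.searchsorted(edges, p, side="right")
    if oscillatory is not None:
        cats = np.where(np.asarray(oscillatory, dtype=bool), levels - 1, cats)
    return cats


def concordance(
    model_profile: np.ndarray,
    data_profile: np.ndarray,
    node_gene_map: Mapping[str, Sequence[str]] | None = None,
    nodes: Sequence[str] | None = None,
    gene_index: Sequence[str] | None = None,
    levels: int = 4,
    model_oscillatory: np.ndarray | None = None,
    data_oscillatory: np.ndarray | None = None,
) -> dict:
    """Percent agreement between two discretized profiles.

    When a node-to-gene map is given, ``model_profile`` is indexed by
    ``nodes`` and ``data_profile`` by ``gene_index``; multi-gene nodes
    aggregate by median.  Only nodes with at least one mapped gene present
    are comparable.  Returns agreement percent, the number of comparable
    nodes, and the chance baseline 100/levels.
    """
    m = np.asarray(model_profile, dtype=float)
    if node_gene_map is not None:
        if nodes is None or gene_index is None:
            raise ValueError("node_gene_map requires nodes and gene_index")
        gpos = {g: i for i, g in enumerate(gene_index)}
        data = np.asarray(data_profile, dtype=float)
        mvals, dvals, mosc = [], [], []
        for j, node in enumerate(nodes):
            genes = [g for g in node_gene_map.get(node, ()) if g in gpos]
            if not genes:
                continue
            mvals.append(m[j])
            dvals.append(float(np.median([data[gpos[g]] for g in genes])))
            if model_oscillatory is not None:
                mosc.append(bool(model_oscillatory[j]))
        m = np.array(mvals)
        d = np.array(dvals)
        model_oscillatory = np.array(mosc, dtype=bool) if mosc else None
        data_oscillatory = None
    else:
        d = np.asarray(data_profile, dtype=float)
        if m.shape != d.shape:
            raise ValueError("profiles must have equal length without a gene map")
    if m.size == 0:
        raise ValueError("zero comparable nodes")
    mc = discretize_profile(m, levels=levels, oscillatory=model_oscillatory)
    dc = discretize_profile(d, levels=levels, oscillatory=data_oscillatory)
    agree = 100.0 * float(np.mean(mc == dc))
    return {
        "agreement_percent": agree,
        "n_comparable": int(m.size),
        "chance_percent": 100.0 / levels,
        "levels": levels,
    }


def write_expression(matrix: ExpressionMatrix, path: str | Path, label_path: str | Path | None = None) -> Path:
    """Write the matrix (TSV) and optional labels; round-trips via load."""
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", float_format="%.10g")
    if label_path is not None and matrix.labels is not None:
        matrix.labels.to_csv(Path(label_path), sep="\t", header=False)
    return path
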
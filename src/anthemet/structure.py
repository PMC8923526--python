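"""PCA of standardized metabolite profiles and hierarchical clustering of
predictor metabolites.

PCA is computed by singular value decomposition of the column-centered
matrix with a deterministic sign convention (the largest-magnitude loading
of each component is made positive).  Clustering uses the correlation
distance 1 - r between metabolite profiles; the linkage method is chosen
data-driven as the one maximizing the cophenetic correlation coefficient,
and clusters are read off by cutting the dendrogram at a height threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _h
from scipy.spatial.distance import squareform

from .preprocess import MetaboliteMatrix

LINKAGE_METHODS = ("single", "complete", "average", "weighted", "centroid", "median", "ward")
#: preference order on cophenetic-coefficient ties (average first, as the
#: study's final dendrogram used average linkage)
LINKAGE_TIE_ORDER = ("average", "complete", "single", "weighted", "centroid", "median", "ward")


class StructureError(ValueError):
    pass


@dataclass
class PcaResult:
    """Scores, loadings and per-component contribution (explained-variance)
    ratios from an SVD-based PCA."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    contribution_ratios: np.ndarray
    singular_values: np.ndarray


def pca(matrix: MetaboliteMatrix, n_components: int | None = None) -> PcaResult:
    """PCA via SVD of the column-centered value matrix.

    Contribution ratio of component c is sigma_c^2 / sum sigma^2 over the
    full spectrum.  Requesting more components than the matrix rank
    truncates with a warning.
    """
    X = matrix.values.to_numpy(dtype=float)
    n, m = X.shape
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(n, m) * np.finfo(float).eps)) if s.size else 0
    if n_components is None:
        n_components = rank
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            RuntimeWarning,
        )
        n_components = rank
    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(n_components):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    total = float((s ** 2).sum())
    ratios = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    comp_names = [f"PC{c + 1}" for c in range(n_components)]
    scores = pd.DataFrame(U[:, :n_components] * s[:n_components],
                          index=matrix.values.index, columns=comp_names)
    loadings = pd.DataFrame(Vt[:n_components].T,
                            index=matrix.values.columns, columns=comp_names)
    return PcaResult(scores, loadings, ratios, s[:n_components])


def correlation_distance_matrix(
    matrix: MetaboliteMatrix, metabolite_ids=None
) -> pd.DataFrame:
    """Pairwise correlation distances 1 - r between metabolite profiles."""
    values = matrix.values if metabolite_ids is None else matrix.values[list(metabolite_ids)]
    sd = values.std(axis=0, ddof=0)
    constant = list(sd.index[sd <= 0])
    if constant:
        raise StructureError(f"constant columns have undefined correlation: {constant}")
    r = np.corrcoef(values.to_numpy(dtype=float), rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, 2.0)
    return pd.DataFrame(d, index=values.columns, columns=values.columns)


@dataclass
class Dendrogram:
    """Agglomerative merge tree: scipy linkage matrix + leaf labels."""

    merges: np.ndarray           # scipy (n-1) x 4 linkage matrix
    leaf_ids: list[str]
    linkage_method: str

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = len(self.leaf_ids)
        height = {i: 0.0 for i in range(n)}
        label = {i: self.leaf_ids[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = f"{label[a]}:{max(h - height[a], 0.0):g}"
            lb = f"{label[b]}:{max(h - height[b], 0.0):g}"
            node = n + k
            label[node] = f"({la},{lb})"
            height[node] = h
        return label[n + len(self.merges) - 1] + ";"

    def to_nested_json(self) -> str:
        n = len(self.leaf_ids)
        node: dict[int, object] = {i: self.leaf_ids[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            node[n + k] = {"height": float(h), "children": [node[int(a)], node[int(b)]]}
        return json.dumps(node[n + len(self.merges) - 1])


def _as_condensed(distances) -> tuple[np.ndarray, list[str]]:
    if isinstance(distances, pd.DataFrame):
        labels = list(distances.columns)
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        labels = [str(i) for i in range(d.shape[0])]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise StructureError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise StructureError("distance matrix must be symmetric")
    return squareform(d, checks=False), labels


def agglomerate(distances, linkage_method: str = "average") -> Dendrogram:
    """Agglomerative clustering of a distance matrix with a classical
    linkage.  Centroid/median linkages may produce height inversions; a
    warning is emitted when merge heights are non-monotone."""
    if linkage_method not in LINKAGE_METHODS:
        raise StructureError(f"unknown linkage {linkage_method!r}")
    condensed, labels = _as_condensed(distances)
    Z = _h.linkage(condensed, method=linkage_method)
    if np.any(np.diff(Z[:, 2]) < -1e-12):
        warnings.warn(
            f"{linkage_method} linkage produced non-monotone merge heights (inversions)",
            RuntimeWarning,
        )
    return Dendrogram(Z, labels, linkage_method)


def cophenetic_correlation(dendrogram: Dendrogram, distances) -> float:
    """Pearson correlation between original pairwise distances and
    cophenetic (first-merge-height) distances over all leaf pairs."""
    condensed, labels = _as_condensed(distances)
    if len(labels) < 3:
        raise StructureError("cophenetic correlation needs at least 3 leaves")
    if len(labels) != len(dendrogram.leaf_ids):
        raise StructureError("dendrogram and distance matrix disagree on leaves")
    coeff, _ = _h.cophenet(dendrogram.merges, condensed)
    return float(coeff)


def select_linkage(
    distances, candidate_methods=LINKAGE_METHODS
) -> tuple[str, Dendrogram, pd.DataFrame]:
    """Evaluate the cophenetic correlation coefficient of every candidate
    linkage and return the argmax (ties resolved by the fixed preference
    order, average first), its dendrogram, and the full coefficient table."""
    candidate_methods = list(candidate_methods)
    if not candidate_methods:
        raise StructureError("need at least one candidate linkage method")
    dendros, rows = {}, []
    for method in candidate_methods:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dend = agglomerate(distances, method)
        coeff = cophenetic_correlation(dend, distances)
        dendros[method] = dend
        rows.append({"method": method, "cophenetic_correlation": coeff})
    table = pd.DataFrame(rows)
    best_coeff = table["cophenetic_correlation"].max()
    tied = set(table.loc[
        np.isclose(table["cophenetic_correlation"], best_coeff, rtol=0, atol=1e-12),
        "method",
    ])
    pref = [m for m in LINKAGE_TIE_ORDER if m in tied] + sorted(tied - set(LINKAGE_TIE_ORDER))
    best = pref[0]
    return best, dendros[best], table


def cut_clusters(dendrogram: Dendrogram, height_threshold: float = 0.5) -> pd.Series:
    """Cluster labels after removing all merges above the height threshold
    (merges at height <= threshold are kept)."""
    if height_threshold < 0:
        raise StructureError("height threshold must be nonnegative")
    labels = _h.fcluster(dendrogram.merges, t=height_threshold, criterion="distance")
    return pd.Series(labels, index=dendrogram.leaf_ids, name="cluster")
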
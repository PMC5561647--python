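"""Hierarchical biclustering and PCA of the spectral-count matrix.

Counts are log-transformed (``log2(count + 0.5)``) and row-standardized so a
protein's profile reads as above/below its own average; proteins (rows) and
animals (columns) are then clustered independently with Euclidean distances
and unweighted pair-group average linkage (UPGMA).  Ordination is a centered
PCA of the animal profiles; per-group score clouds on the first two
components are summarized as bivariate-normal (mean vector, covariance)
densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .errors import ConfigurationError
from .inference import CountMatrix


def _as_frame(matrix) -> tuple[pd.DataFrame, pd.Series | None]:
    if isinstance(matrix, CountMatrix):
        return matrix.counts, matrix.sample_groups
    return pd.DataFrame(matrix), None


def transform_counts(
    counts: pd.DataFrame, standardize: bool = True, log: bool = True
) -> pd.DataFrame:
    """log2(count + 0.5), optionally centered/scaled per protein row.

    Rows with zero spread are centered but left unscaled (no division by
    zero on constant proteins).  ``log=False`` skips the count transform for
    matrices already on an abundance scale.
    """
    x = counts.to_numpy(dtype=float)
    if log:
        x = np.log2(x + 0.5)
    if standardize:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    return pd.DataFrame(x, index=counts.index, columns=counts.columns)


@dataclass
class ClusteringResult:
    """Row and column UPGMA merge trees over the transformed matrix."""

    row_linkage: np.ndarray
    col_linkage: np.ndarray
    matrix: pd.DataFrame

    @property
    def row_order(self) -> list:
        return [self.matrix.index[i] for i in leaves_list(self.row_linkage)]

    @property
    def col_order(self) -> list:
        return [self.matrix.columns[i] for i in leaves_list(self.col_linkage)]


def bicluster(matrix, standardize: bool = True, log: bool = True) -> ClusteringResult:
    """UPGMA clustering of proteins (rows) and animals (columns).

    Merge heights are ultrametric (non-decreasing).  A constant matrix gives
    all-zero distances and merges everything at height 0.  ``log=False``
    clusters the matrix as given (no count transform).
    """
    counts, _ = _as_frame(matrix)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ConfigurationError("biclustering needs at least 2 rows and 2 columns")
    transformed = transform_counts(counts, standardize=standardize, log=log)
    x = transformed.to_numpy()
    row_link = linkage(pdist(x, metric="euclidean"), method="average")
    col_link = linkage(pdist(x.T, metric="euclidean"), method="average")
    return ClusteringResult(row_linkage=row_link, col_linkage=col_link, matrix=transformed)


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a merge tree as a Newick string with merge heights as depths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(link):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + len(link) - 1] + ";"


@dataclass
class OrdinationResult:
    """PCA scores/loadings and per-group bivariate-normal density parameters."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # proteins x components
    explained_variance_ratio: np.ndarray
    group_densities: dict[str, tuple[np.ndarray, np.ndarray]]  # group -> (mean2, cov2x2)


def ordinate(
    matrix,
    groups: Mapping[str, str] | pd.Series | None = None,
    n_components: int | None = None,
    standardize: bool = True,
) -> OrdinationResult:
    """Centered PCA on animal profiles with group density summaries.

    Samples (columns of the count matrix) are the observations.  Per group,
    the mean and covariance of the first two scores parameterize the
    bivariate-normal density used for the score-plot contours; groups with a
    single sample get a zero covariance.
    """
    counts, inferred = _as_frame(matrix)
    if groups is None:
        groups = inferred
    if counts.shape[1] < 3:
        raise ConfigurationError("ordination needs at least 3 samples")
    x = transform_counts(counts, standardize=standardize).to_numpy().T  # samples x proteins
    k = n_components or min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores_df = pd.DataFrame(scores, index=counts.columns, columns=comp_names)
    loadings = pd.DataFrame(pca.components_.T, index=counts.index, columns=comp_names)

    densities: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if groups is not None:
        groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
        for g in sorted(groups.unique()):
            members = [s for s in counts.columns if groups.get(s) == g]
            pts = scores_df.loc[members, comp_names[:2]].to_numpy()
            mean = pts.mean(axis=0)
            cov = np.cov(pts.T) if len(pts) > 1 else np.zeros((2, 2))
            densities[g] = (mean, np.atleast_2d(cov))
    return OrdinationResult(
        scores=scores_df,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        group_densities=densities,
    )
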
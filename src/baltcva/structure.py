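"""Multivariate structure of the species x attribute score matrix.

Hierarchical clustering (Ward linkage on Euclidean distances, columns
standardized) orders species and attributes for heatmap rendering and
cuts the species dendrogram into groups; PCA projects species and
attribute loadings onto the leading dimensions of trait variability.
Both are fully deterministic given the matrix and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from sklearn.decomposition import PCA


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1).replace(0.0, 1.0)  # constant columns carry no signal
    return (df - df.mean()) / sd


@dataclass
class ClusterResult:
    species_groups: pd.Series      # species -> group label 1..k
    attribute_groups: pd.Series | None
    species_order: list[str]       # dendrogram leaf order
    attribute_order: list[str]
    species_linkage: np.ndarray
    attribute_linkage: np.ndarray


def cluster_species_attributes(matrix: pd.DataFrame, k_species: int = 4,
                               k_attributes: int | None = None,
                               method: str = "ward", metric: str = "euclidean",
                               standardize: bool = True) -> ClusterResult:
    """Agglomerative clustering of species (rows) and attributes (columns).

    Cutting the species dendrogram at ``k_species`` (default 4) yields
    the species groups; leaf orders give the heatmap row/column
    orderings.
    """
    if matrix.isna().any().any():
        raise ValueError("score matrix has missing cells; clustering needs a complete matrix")
    if k_species > len(matrix.index):
        raise ValueError(f"k_species={k_species} exceeds the {len(matrix.index)} species")
    if k_attributes is not None and k_attributes > len(matrix.columns):
        raise ValueError(f"k_attributes={k_attributes} exceeds the {len(matrix.columns)} attributes")
    X = _standardize(matrix) if standardize else matrix.copy()
    row_link = linkage(X.to_numpy(), method=method, metric=metric)
    col_link = linkage(X.to_numpy().T, method=method, metric=metric)
    row_labels = fcluster(row_link, t=k_species, criterion="maxclust")
    col_labels = (
        fcluster(col_link, t=k_attributes, criterion="maxclust")
        if k_attributes is not None else None
    )
    row_order = dendrogram(row_link, no_plot=True)["leaves"]
    col_order = dendrogram(col_link, no_plot=True)["leaves"]
    return ClusterResult(
        species_groups=pd.Series(row_labels, index=matrix.index, name="group"),
        attribute_groups=(
            pd.Series(col_labels, index=matrix.columns, name="group")
            if col_labels is not None else None
        ),
        species_order=[matrix.index[i] for i in row_order],
        attribute_order=[matrix.columns[i] for i in col_order],
        species_linkage=row_link,
        attribute_linkage=col_link,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame             # species x components
    loadings: pd.DataFrame           # attributes x components, orthonormal
    explained_variance_ratio: np.ndarray

    def reconstruction(self, mean: np.ndarray) -> np.ndarray:
        return self.scores.to_numpy() @ self.loadings.to_numpy().T + mean


def pca_biplot(matrix: pd.DataFrame, n_components: int = 2,
               standardize: bool = True) -> PCAResult:
    """Principal components of the score matrix for biplot rendering.

    Columns are centered (and by default standardized); the sign of each
    component is fixed so its largest-magnitude attribute loading is
    positive, making biplots reproducible.
    """
    if matrix.isna().any().any():
        raise ValueError("score matrix has missing cells; PCA needs a complete matrix")
    max_rank = min(len(matrix.index), len(matrix.columns))
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds min(n_species, n_attributes)={max_rank}")
    X = _standardize(matrix) if standardize else matrix - matrix.mean()
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X.to_numpy())
    loadings = pca.components_.T  # attributes x components
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    scores = scores * flip
    loadings = loadings * flip
    dims = [f"Dim{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=dims),
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=dims),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
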
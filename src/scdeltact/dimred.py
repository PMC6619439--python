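"""Dimension reduction: PCA composite gene weights and Fisher LDA.

Two complementary views of treatment structure:

* PCA on the gene-standardized -ddCt matrix; the components that cluster
  samples by treatment (empirically PC2 and PC3 here) are summarized per
  gene by the composite weight sqrt(loading_PC2^2 + loading_PC3^2) — a
  rotation-sign-free measure of how much a gene contributes to the
  treatment-separating plane.

* Fisher linear discriminant analysis with an explicit whitening
  convention, because centroid distances depend on it: discriminants are
  eigenvectors of S_W^{-1} S_B scaled to unit pooled within-class variance
  (w' S_W w = 1), S_W the pooled within-class covariance (divisor n - C),
  S_B the between-class scatter of class means weighted by class size
  (divisor C - 1).  Class separation is then reported as Euclidean
  distances between class centroids in the full (C - 1)-dimensional
  discriminant space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


@dataclass
class CompositeWeights:
    table: pd.DataFrame  # per gene: loading_pc2, loading_pc3, composite_weight
    variance_explained: np.ndarray  # fraction per PC


@dataclass
class LdaResult:
    coords: pd.DataFrame  # samples x discriminants (LD1, LD2, ...)
    weights: pd.DataFrame  # genes x discriminants
    eigenvalues: np.ndarray
    labels: pd.Series


@dataclass
class CentroidTable:
    centroids: pd.DataFrame  # classes x discriminants
    distances: pd.DataFrame  # classes x classes, Euclidean


def _complete_genes(values: pd.DataFrame) -> pd.DataFrame:
    incomplete = values.columns[values.isna().any(axis=0)]
    if len(incomplete):
        logger.info("excluding %d genes with missing values: %s",
                    len(incomplete), list(incomplete))
    return values.drop(columns=incomplete)


def pca_composite_weights(
    expr,
    standardize: bool = True,
    pcs: tuple[int, int] = (2, 3),
) -> CompositeWeights:
    """PCA loadings on the treatment-clustering PCs, combined per gene.

    ``pcs`` are 1-based component numbers; the default (2, 3) is the plane
    in which treatments separate most clearly for these data.
    """
    from sklearn.decomposition import PCA

    values = expr.values if hasattr(expr, "analysis_genes") else expr
    if hasattr(expr, "analysis_genes"):
        values = values[expr.analysis_genes()]
    values = _complete_genes(values)
    n, p = values.shape
    if n < 3 or p < 3:
        raise ValueError("PCA composite weights need >= 3 samples and >= 3 complete genes")
    X = values.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            logger.info("dropping %d zero-variance genes from PCA", int((~keep).sum()))
            X, values = X[:, keep], values.loc[:, keep]
        X = X / X.std(axis=0, ddof=1)
    n_comp = min(n - 1, X.shape[1])
    if n_comp < max(pcs):
        raise ValueError(f"rank {n_comp} too low for PCs {pcs}")
    pca = PCA(n_components=n_comp)
    pca.fit(X)
    l2 = pca.components_[pcs[0] - 1]
    l3 = pca.components_[pcs[1] - 1]
    table = pd.DataFrame(
        {
            "loading_pc2": l2,
            "loading_pc3": l3,
            "composite_weight": np.hypot(l2, l3),
        },
        index=values.columns,
    ).sort_values("composite_weight", ascending=False)
    return CompositeWeights(table=table, variance_explained=pca.explained_variance_ratio_)


def lda_project(
    expr,
    labels: pd.Series,
    ridge: float = 1e-6,
) -> LdaResult:
    """Project samples onto Fisher discriminants (documented convention).

    ``ridge`` scales an identity added to S_W as ridge * trace(S_W)/p, which
    keeps the within-class scatter invertible when genes are collinear.
    """
    values = expr.values if hasattr(expr, "analysis_genes") else expr
    if hasattr(expr, "analysis_genes"):
        values = values[expr.analysis_genes()]
    values = _complete_genes(values)
    labels = labels.loc[values.index]
    classes = labels.unique()
    C = len(classes)
    if C < 2:
        raise ValueError("LDA needs >= 2 classes")
    X = values.to_numpy(dtype=float)
    n, p = X.shape
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in classes:
        Xc = X[(labels == c).to_numpy()]
        mu = Xc.mean(axis=0)
        Sw += (Xc - mu).T @ (Xc - mu)
        d = (mu - grand)[:, None]
        Sb += len(Xc) * (d @ d.T)
    Sw /= (n - C)
    Sb /= (C - 1)
    tr = np.trace(Sw)
    Swr = Sw + ridge * (tr / p) * np.eye(p)
    try:
        evals, evecs = linalg.eigh(Sb, Swr)
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError(
            "singular within-class scatter; increase the ridge fraction"
        ) from exc
    order = np.argsort(evals)[::-1][: C - 1]
    evals = evals[order]
    W = evecs[:, order]  # columns satisfy w' Swr w = 1 (unit within-class variance)
    # deterministic sign: largest-magnitude gene loading positive
    for j in range(W.shape[1]):
        k = np.argmax(np.abs(W[:, j]))
        if W[k, j] < 0:
            W[:, j] = -W[:, j]
    coords = (X - grand) @ W
    names = [f"LD{j + 1}" for j in range(W.shape[1])]
    return LdaResult(
        coords=pd.DataFrame(coords, index=values.index, columns=names),
        weights=pd.DataFrame(W, index=values.columns, columns=names),
        eigenvalues=evals,
        labels=labels,
    )


def centroid_distances(coords: pd.DataFrame, labels: pd.Series) -> CentroidTable:
    """Class centroids and pairwise Euclidean distances in discriminant space."""
    labels = labels.loc[coords.index]
    counts = labels.value_counts()
    if (counts < 1).any() or counts.empty:
        raise ValueError("every class needs at least one sample")
    centroids = coords.groupby(labels).mean()
    dist = squareform(pdist(centroids.to_numpy()))
    distances = pd.DataFrame(dist, index=centroids.index, columns=centroids.index)
    return CentroidTable(centroids=centroids, distances=distances)
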
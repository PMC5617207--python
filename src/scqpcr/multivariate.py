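"""Population structure: z-scoring, PCA, hierarchical clustering, ellipses.

PCA operates on per-gene z-scored expression so that highly expressed genes
do not dominate the components; the two neuropeptidergic populations are
expected to separate along PC1, with the discriminatory markers carrying the
largest PC1 loadings.  Agglomerative clustering (Ward by default, complete
linkage as the alternative) provides the unsupervised check that the
populations form distinct clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.stats import chi2

from .core_io import ExpressionMatrix

__all__ = [
    "PCAResult",
    "ClusterTree",
    "EllipseSpec",
    "zscore",
    "run_pca",
    "top_loadings",
    "agglomerative_cluster",
    "cut_tree",
    "cluster_purity",
    "coverage_ellipse",
]


def zscore(x: ExpressionMatrix | pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene standardization to mean 0, sample SD 1 (n-1 divisor).

    Returns the standardized frame and the list of zero-variance genes,
    whose columns are mapped to all zeros rather than NaN.
    """
    df = x.to_dataframe() if isinstance(x, ExpressionMatrix) else x.copy()
    if len(df) < 2:
        raise ValueError("z-scoring needs at least 2 cells")
    sd = df.std(axis=0, ddof=1)
    flagged = [str(s) for s in sd.index[sd == 0]]
    safe_sd = sd.replace(0.0, 1.0)
    out = (df - df.mean(axis=0)) / safe_sd
    out[flagged] = 0.0
    return out, flagged


@dataclass
class PCAResult:
    """Scores (cells x components), unit-norm loadings (genes x components)
    and per-component variance fractions summing to 1."""

    scores: np.ndarray
    loadings: np.ndarray
    variance_fraction: np.ndarray
    cell_ids: list[str]
    genes: list[str]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.cell_ids, columns=cols)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.genes, columns=cols)


def run_pca(z: pd.DataFrame) -> PCAResult:
    """PCA of the centered matrix via singular-value decomposition.

    Variance fractions are the normalized squared singular values.  Sign
    convention: each loading column's largest-magnitude element is made
    positive, so reported poles are reproducible across runs and platforms.
    """
    if len(z) < 2:
        raise ValueError("PCA needs at least 2 cells")
    if z.shape[1] < 2:
        raise ValueError("PCA needs at least 2 genes")
    values = z.to_numpy(dtype=float)
    centered = values - values.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # fix signs so the dominant element of each loading vector is positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    return PCAResult(
        scores=u * s,
        loadings=vt.T,
        variance_fraction=frac,
        cell_ids=[str(i) for i in z.index],
        genes=[str(g) for g in z.columns],
    )


def top_loadings(
    p: PCAResult, component: int = 0, k: int = 5
) -> tuple[list[str], list[str]]:
    """The k most positive and k most negative genes on one component,
    each list ranked by loading magnitude (lists truncate when k exceeds
    the available genes of that sign)."""
    if not 0 <= component < p.loadings.shape[1]:
        raise ValueError(f"component {component} out of range")
    if k < 0:
        raise ValueError("k must be >= 0")
    load = p.loadings[:, component]
    order = np.argsort(load)
    pos = [p.genes[i] for i in order[::-1] if load[i] > 0][:k]
    neg = [p.genes[i] for i in order if load[i] < 0][:k]
    return pos, neg


@dataclass
class ClusterTree:
    """Agglomerative merge tree in scipy linkage-matrix form."""

    merge: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaf_ids: list[str]
    linkage: str
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.merge.shape != (n - 1, 4):
            raise ValueError("linkage matrix must have n-1 merges")


def agglomerative_cluster(
    z: pd.DataFrame, linkage: str = "ward"
) -> ClusterTree:
    """Hierarchical clustering of cells with Euclidean distances.

    Supported linkages are ``ward`` (default) and ``complete``; both yield
    monotone merge heights.  The result is deterministic given input order.
    """
    if linkage not in ("ward", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}; use ward or complete")
    if len(z) < 2:
        raise ValueError("clustering needs at least 2 cells")
    merge = scipy_linkage(z.to_numpy(dtype=float), method=linkage,
                          metric="euclidean")
    return ClusterTree(merge=merge, leaf_ids=[str(i) for i in z.index],
                       linkage=linkage)


def cut_tree(tree: ClusterTree, k: int) -> pd.Series:
    """Cluster labels (1..k) from cutting the tree into k clusters."""
    n = len(tree.leaf_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in [1, {n}]")
    labels = fcluster(tree.merge, t=k, criterion="maxclust")
    return pd.Series(labels, index=tree.leaf_ids, name="cluster")


def cluster_purity(tree: ClusterTree, k: int, labels: dict[str, str] | pd.Series) -> float:
    """Majority-label purity of the k-cluster cut.

    purity = (sum over clusters of the majority population count) / n, so a
    perfectly separated two-population dataset has purity 1.0 at k=2.
    """
    assignments = cut_tree(tree, k)
    labels = pd.Series(labels)
    missing = [i for i in tree.leaf_ids if i not in labels.index]
    if missing:
        raise ValueError(f"labels missing for leaves {missing[:5]}")
    df = pd.DataFrame({"cluster": assignments, "label": labels[tree.leaf_ids]})
    majority = df.groupby("cluster")["label"].agg(lambda s: s.value_counts().iloc[0])
    return float(majority.sum() / len(df))


@dataclass
class EllipseSpec:
    """Coverage ellipse of 2-D component scores.

    The ellipse is ``(p - center)' shape^{-1} (p - center) <= scale`` with
    shape the sample covariance and scale the chi-square(2) quantile at the
    coverage level.
    """

    center: np.ndarray
    shape: np.ndarray
    scale: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        diff = np.atleast_2d(points) - self.center
        inv = np.linalg.inv(self.shape)
        md2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
        return md2 <= self.scale


def coverage_ellipse(scores: np.ndarray, level: float = 0.95) -> EllipseSpec:
    """Normal-theory coverage ellipse for a 2-column score matrix."""
    pts = np.asarray(scores, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    center = pts.mean(axis=0)
    shape = np.cov(pts, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(shape) < 2 or np.linalg.det(shape) <= 0:
        raise ValueError("singular covariance: points are (nearly) collinear")
    return EllipseSpec(center=center, shape=shape,
                       scale=float(chi2.ppf(level, df=2)))
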
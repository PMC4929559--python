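"""Hierarchical clustering with multiscale-bootstrap AU cluster support.

Samples (or accessions) are clustered by average linkage (UPGMA) on the
Pearson correlation distance ``d = 1 - r``.  Cluster support is assessed by
multiscale bootstrap resampling of the features: bootstrap samples of
``ceil(n * r)`` features are drawn with replacement at several scales ``r``,
the data are re-clustered, and the per-scale bootstrap probabilities BP(r)
of each original cluster are extrapolated through the signed-distance /
curvature model

    Phi^-1(1 - BP(r)) = v * sqrt(r) + c / sqrt(r)

fitted by weighted least squares (binomial variance weights), giving the
approximately unbiased p-value AU = 1 - Phi(v - c).  Dendrograms on
correlation distance are cut at a correlation threshold (height
``1 - threshold``) to extract clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .datatypes import FeatureMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ClusterSupport",
    "correlation_distance",
    "average_linkage",
    "multiscale_bootstrap_au",
    "cut_at_correlation",
    "DEFAULT_SCALES",
]

#: pvclust-style default resampling scale grid.
DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        self.d = 0.5 * (self.d + self.d.T)
        np.fill_diagonal(self.d, 0.0)

    def condensed(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.d, checks=False)


@dataclass
class Dendrogram:
    """UPGMA merge tree (SciPy linkage encoding) over labelled leaves."""

    labels: list[str]
    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def clusters(self) -> list[frozenset[int]]:
        """Leaf-index sets of all internal nodes, in merge order."""
        return _internal_clusters(self.linkage, len(self.labels))

    def cluster_labels(self) -> list[frozenset[str]]:
        return [frozenset(self.labels[i] for i in c) for c in self.clusters()]

    def to_newick(self) -> str:
        """Newick string with branch lengths = merge-height differences."""
        import skbio

        tree = skbio.TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree)


@dataclass
class ClusterSupport:
    """Multiscale-bootstrap support for one cluster of the original tree."""

    cluster: frozenset[str]
    bp_per_scale: dict[float, float]
    au: float
    bp1: float  # naive bootstrap probability at scale r = 1
    v: float = np.nan  # fitted signed distance
    c: float = np.nan  # fitted curvature
    fit_quality: float = np.nan  # chi-square of the WLS fit
    degenerate: bool = False


# ---------------------------------------------------------------------------
# distances and linkage
# ---------------------------------------------------------------------------

def correlation_distance(matrix) -> DistanceMatrix:
    """Pearson correlation distance ``1 - r`` between sample columns.

    ``matrix`` is a features x samples DataFrame or FeatureMatrix.
    """
    if isinstance(matrix, FeatureMatrix):
        X = matrix.intensities
    else:
        X = matrix
    arr = X.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least two features to correlate samples")
    sd = arr.std(axis=0)
    if (sd == 0).any():
        bad = [X.columns[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant sample column(s): {bad}")
    d = 1.0 - np.corrcoef(arr, rowvar=False)
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0  # guard tiny negative rounding
    return DistanceMatrix(list(X.columns), d)


def average_linkage(dist: DistanceMatrix) -> Dendrogram:
    """UPGMA (average-linkage) merge tree on a distance matrix."""
    if np.isnan(dist.d).any():
        raise ValueError("distance matrix contains NaN")
    Z = hierarchy.linkage(dist.condensed(), method="average")
    return Dendrogram(list(dist.labels), Z)


def _internal_clusters(Z: np.ndarray, n: int) -> list[frozenset[int]]:
    members: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    out = []
    for a, b, *_ in Z:
        merged = members[int(a)] | members[int(b)]
        members.append(merged)
        out.append(merged)
    return out


def cut_at_correlation(dendrogram: Dendrogram, threshold: float = 0.95) -> pd.Series:
    """Cut a correlation-distance dendrogram at correlation ``threshold``.

    The cut height is ``1 - threshold``; connected subtrees below the cut are
    the clusters.  Returns a Series label -> cluster id (1-based).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    assign = hierarchy.fcluster(dendrogram.linkage, t=1.0 - threshold,
                                criterion="distance")
    return pd.Series(assign, index=dendrogram.labels, name="cluster_id")


# ---------------------------------------------------------------------------
# multiscale bootstrap
# ---------------------------------------------------------------------------

def _fit_au(bp: np.ndarray, scales: np.ndarray, B: int) -> tuple[float, float, float, float, bool]:
    """WLS fit of the signed-distance/curvature model; returns (au, v, c, chi2, degenerate).

    Scales where the raw BP is exactly 0 or 1 carry no information about the
    decay of cluster support and are excluded from the fit.  If fewer than
    two informative scales remain, the AU estimate degenerates to the clipped
    bootstrap probability bound (1 - 1/(B+1) for unanimously supported
    clusters, 1/(B+1) for never-seen ones).
    """
    lo, hi = 1.0 / (B + 1), 1.0 - 1.0 / (B + 1)
    usable = (bp > 0) & (bp < 1)
    if usable.sum() < 2:
        au = hi if bp.mean() >= 0.5 else lo
        return au, np.nan, np.nan, np.nan, True
    r = scales[usable]
    b = np.clip(bp[usable], lo, hi)
    psi = stats.norm.ppf(1.0 - b)
    X = np.stack([np.sqrt(r), 1.0 / np.sqrt(r)], axis=1)
    w = B * stats.norm.pdf(psi) ** 2 / (b * (1.0 - b))
    WX = X * w[:, None]
    try:
        coef = np.linalg.solve(X.T @ WX, WX.T @ psi)
    except np.linalg.LinAlgError:
        au = hi if bp.mean() >= 0.5 else lo
        return au, np.nan, np.nan, np.nan, True
    v, c = float(coef[0]), float(coef[1])
    resid = psi - X @ coef
    chi2 = float((w * resid**2).sum())
    au = float(1.0 - stats.norm.cdf(v - c))
    return au, v, c, chi2, False


def multiscale_bootstrap_au(
    matrix,
    scales=DEFAULT_SCALES,
    B: int = 1000,
    seed: int | None = 0,
    *,
    extra_clusters: list[frozenset[str]] | None = None,
    distance=correlation_distance,
    linkage=average_linkage,
) -> list[ClusterSupport]:
    """Multiscale bootstrap AU support for every cluster of the original tree.

    Features (rows) are resampled with replacement at each scale; the data
    are re-clustered with the same distance/linkage pair and each original
    cluster's per-scale bootstrap probability is recorded, then extrapolated
    to the AU p-value.  ``extra_clusters`` adds user-specified leaf sets
    (e.g. an arbitrary bipartition) whose support is evaluated alongside the
    tree's own clusters.
    """
    if isinstance(matrix, FeatureMatrix):
        X = matrix.intensities
    else:
        X = matrix
    rng = np.random.default_rng(seed)
    n_feat = X.shape[0]
    base = linkage(distance(X))
    labels = base.labels
    own = base.cluster_labels()
    queries = list(dict.fromkeys(own + list(extra_clusters or [])))
    scales = np.asarray(list(scales), dtype=float)
    counts = np.zeros((len(scales), len(queries)), dtype=int)
    arr = X.to_numpy(dtype=float)
    cols = list(X.columns)
    for si, r in enumerate(scales):
        m = max(2, int(np.ceil(n_feat * r)))
        fast = distance is correlation_distance
        for _ in range(B):
            idx = rng.integers(0, n_feat, size=m)
            sub = arr[idx]
            if fast:
                sd = sub.std(axis=0)
                if (sd == 0).any():
                    continue  # degenerate draw: no tree, counts unchanged
                d = 1.0 - np.corrcoef(sub, rowvar=False)
                np.fill_diagonal(d, 0.0)
                d[d < 0] = 0.0
            else:
                try:
                    d = distance(pd.DataFrame(sub, columns=cols)).d
                except ValueError:
                    continue
            Z = hierarchy.linkage(
                DistanceMatrix(cols, d).condensed(), method="average"
            )
            boot_clusters = {
                frozenset(cols[i] for i in c)
                for c in _internal_clusters(Z, len(cols))
            }
            for qi, q in enumerate(queries):
                if q in boot_clusters:
                    counts[si, qi] += 1
    out = []
    for qi, q in enumerate(queries):
        bp = counts[:, qi] / B
        au, v, c, chi2, degen = _fit_au(bp, scales, B)
        r1 = int(np.argmin(np.abs(scales - 1.0)))
        out.append(
            ClusterSupport(
                cluster=q,
                bp_per_scale={float(s): float(p) for s, p in zip(scales, bp)},
                au=au,
                bp1=float(bp[r1]),
                v=v,
                c=c,
                fit_quality=chi2,
                degenerate=degen,
            )
        )
    return out
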
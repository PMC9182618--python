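"""Mahalanobis-D2 germplasm diversity: distance matrix, clustering, PCA.

Genotype divergence is measured on across-location genotype mean vectors
with the squared generalized (Mahalanobis) distance

    D2_ij = (m_i - m_j)' W^{-1} (m_i - m_j)

where W is the pooled error variance-covariance matrix from the per-location
RCBD residuals — the canonical dispersion choice, weighting trait
differences by (inverse) experimental noise and accounting for residual
trait correlation. Clusters come either from Tocher's sequential grouping
(the method classically paired with D2) or from agglomerative hierarchical
clustering on sqrt(D2); intra/inter-cluster mean distances summarise the
diversity structure. PCA of the genotype-mean table (correlation or
covariance mode) gives the variance partition and biplot coordinates, and
the traits themselves are grouped on the 1 - |r| correlation distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .trial_data import TrialDataset, genotype_means

__all__ = [
    "D2Matrix",
    "ClusterAssignment",
    "PCAResult",
    "pooled_error_covariance",
    "mahalanobis_d2",
    "d2_matrix",
    "cluster_tocher",
    "cluster_hierarchical",
    "cluster_distance_summary",
    "pca_traits",
]


def pooled_error_covariance(ds: TrialDataset, traits: list[str] | None = None) -> pd.DataFrame:
    """Pooled error variance-covariance matrix over locations.

    Per location the error SSCP matrix is built from the two-way residuals
    (value - genotype mean - replicate mean + location mean) of each trait,
    then SSCP matrices are summed over locations and divided by the pooled
    error degrees of freedom, sum of (g-1)(r-1). The single-trait case
    reduces to the pooled MSE.
    """
    traits = traits or ds.trait_names
    k = len(traits)
    sscp = np.zeros((k, k))
    df_pooled = 0
    for loc in ds.locations:
        sub = ds.subset_location(loc)
        piv = {
            t: sub.pivot_table(index="genotype", columns="replicate", values=t,
                               aggfunc="first", sort=False).to_numpy(dtype=float)
            for t in traits
        }
        shapes = {m.shape for m in piv.values()}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent layout at {loc!r}")
        g, r = shapes.pop()
        if g < 2 or r < 2:
            raise ValueError(f"need >= 2 genotypes and replicates at {loc!r}")
        resid = {}
        for t, m in piv.items():
            if np.isnan(m).any():
                raise ValueError(f"missing {t!r} values at {loc!r}")
            resid[t] = (m - m.mean(axis=1, keepdims=True)
                        - m.mean(axis=0, keepdims=True) + m.mean())
        for i, ti in enumerate(traits):
            for j, tj in enumerate(traits[i:], start=i):
                s = float((resid[ti] * resid[tj]).sum())
                sscp[i, j] += s
                if j != i:
                    sscp[j, i] += s
        df_pooled += (g - 1) * (r - 1)
    return pd.DataFrame(sscp / df_pooled, index=traits, columns=traits)


def mahalanobis_d2(means_i, means_j, dispersion) -> float:
    """Squared Mahalanobis distance (mi - mj)' W^{-1} (mi - mj).

    Solved as a linear system (no explicit inverse). Reduces to squared
    Euclidean distance for an identity dispersion.
    """
    d = np.asarray(means_i, dtype=float) - np.asarray(means_j, dtype=float)
    W = np.asarray(dispersion, dtype=float)
    if W.shape != (d.size, d.size):
        raise ValueError("dispersion dimension mismatch")
    return float(d @ np.linalg.solve(W, d))


@dataclass
class D2Matrix:
    """Symmetric genotype x genotype matrix of squared Mahalanobis distances."""

    genotypes: list[str]
    values: pd.DataFrame
    dispersion: pd.DataFrame
    singular_dispersion: bool = False

    def pair(self, a: str, b: str) -> float:
        return float(self.values.loc[a, b])


def d2_matrix(
    ds_or_means,
    traits: list[str] | None = None,
    dispersion: pd.DataFrame | None = None,
    allow_pseudo_inverse: bool = False,
) -> D2Matrix:
    """All-pairs D2 over genotypes.

    Pass either a TrialDataset (means and pooled dispersion are computed)
    or a genotype x trait means DataFrame with an explicit ``dispersion``.
    A singular dispersion raises unless ``allow_pseudo_inverse`` is set, in
    which case the Moore-Penrose pseudo-inverse is used and flagged.
    """
    if isinstance(ds_or_means, TrialDataset):
        traits = traits or ds_or_means.trait_names
        means = pd.DataFrame(
            {t: genotype_means(ds_or_means, t) for t in traits}
        )
        if dispersion is None:
            dispersion = pooled_error_covariance(ds_or_means, traits)
    else:
        means = pd.DataFrame(ds_or_means).astype(float)
        traits = list(means.columns)
        if dispersion is None:
            raise ValueError("dispersion required with a means table")
    W = dispersion.loc[traits, traits].to_numpy(dtype=float)

    singular = False
    cond = np.linalg.cond(W)
    if not np.isfinite(cond) or cond > 1e12:
        if not allow_pseudo_inverse:
            raise np.linalg.LinAlgError(
                "pooled dispersion matrix is singular (duplicate or constant "
                "trait?); pass allow_pseudo_inverse=True to proceed"
            )
        singular = True
        Winv = np.linalg.pinv(W)
    else:
        Winv = np.linalg.inv(W)

    X = means.to_numpy(dtype=float)
    diff = X[:, None, :] - X[None, :, :]
    vals = np.einsum("ijk,kl,ijl->ij", diff, Winv, diff)
    vals = np.clip(0.5 * (vals + vals.T), 0.0, None)
    np.fill_diagonal(vals, 0.0)
    idx = list(means.index)
    return D2Matrix(
        genotypes=idx,
        values=pd.DataFrame(vals, index=idx, columns=idx),
        dispersion=pd.DataFrame(W, index=traits, columns=traits),
        singular_dispersion=singular,
    )


@dataclass
class ClusterAssignment:
    """Partition of the genotypes with per-cluster summaries."""

    method: str
    clusters: list[list[str]]
    percentages: list[float]
    intra_d2: list[float]
    inter_d2: pd.DataFrame
    params: dict
    linkage_matrix: np.ndarray | None = None
    newick: str | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, int]:
        return {g: ci for ci, cl in enumerate(self.clusters) for g in cl}

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster": [roman(i + 1) for i in range(self.n_clusters)],
            "n_genotypes": [len(c) for c in self.clusters],
            "percentage": self.percentages,
            "intra_cluster_D2": self.intra_d2,
            "genotypes": [", ".join(c) for c in self.clusters],
        })


def roman(n: int) -> str:
    numerals = [(100, "C"), (90, "XC"), (50, "L"), (40, "XL"), (10, "X"),
                (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    out = ""
    for v, s in numerals:
        while n >= v:
            out += s
            n -= v
    return out


def _finish_assignment(d2: D2Matrix, clusters: list[list[str]], method: str,
                       params: dict, linkage_matrix=None, newick=None) -> ClusterAssignment:
    n = len(d2.genotypes)
    pct = [100.0 * len(c) / n for c in clusters]
    intra, inter = _distance_summaries(d2, clusters)
    return ClusterAssignment(
        method=method, clusters=clusters, percentages=pct,
        intra_d2=intra, inter_d2=inter, params=params,
        linkage_matrix=linkage_matrix, newick=newick,
    )


def _distance_summaries(d2: D2Matrix, clusters: list[list[str]]):
    vals = d2.values
    intra = []
    for c in clusters:
        if len(c) < 2:
            intra.append(0.0)
            continue
        sub = vals.loc[c, c].to_numpy()
        intra.append(float(sub[np.triu_indices(len(c), 1)].mean()))
    k = len(clusters)
    inter = np.zeros((k, k))
    for i in range(k):
        inter[i, i] = intra[i]
        for j in range(i + 1, k):
            block = vals.loc[clusters[i], clusters[j]].to_numpy()
            inter[i, j] = inter[j, i] = float(block.mean())
    labels = [roman(i + 1) for i in range(k)]
    return intra, pd.DataFrame(inter, index=labels, columns=labels)


def tocher_threshold(d2: D2Matrix) -> float:
    """Default Tocher cutoff: max over genotypes of the min off-diagonal D2."""
    vals = d2.values.to_numpy().copy()
    np.fill_diagonal(vals, np.inf)
    return float(vals.min(axis=1).max())


def cluster_tocher(d2: D2Matrix, threshold: float | None = None) -> ClusterAssignment:
    """Tocher's sequential grouping of a D2 matrix.

    Seed each cluster with the closest unassigned pair, then repeatedly add
    the unassigned genotype with the smallest mean D2 to the current
    cluster while that mean stays at or below the threshold (default:
    :func:`tocher_threshold`). Ties break by genotype order; leftover
    genotypes seed further clusters (a final lone genotype becomes a
    singleton cluster).
    """
    n = len(d2.genotypes)
    if n < 2:
        raise ValueError("need at least 2 genotypes")
    thr = tocher_threshold(d2) if threshold is None else float(threshold)
    vals = d2.values.to_numpy()
    order = {g: i for i, g in enumerate(d2.genotypes)}
    unassigned = list(d2.genotypes)
    clusters: list[list[str]] = []
    while unassigned:
        if len(unassigned) == 1:
            clusters.append([unassigned.pop()])
            break
        # closest remaining pair, ties by genotype order
        best = None
        for ai, a in enumerate(unassigned):
            for b in unassigned[ai + 1:]:
                dv = vals[order[a], order[b]]
                if best is None or dv < best[0] - 1e-15:
                    best = (dv, a, b)
        cluster = [best[1], best[2]]
        unassigned.remove(best[1])
        unassigned.remove(best[2])
        while unassigned:
            cand_means = [
                (float(np.mean([vals[order[g], order[m]] for m in cluster])), g)
                for g in unassigned
            ]
            mean_d2, g = min(cand_means, key=lambda t: (t[0], order[t[1]]))
            if mean_d2 <= thr:
                cluster.append(g)
                unassigned.remove(g)
            else:
                break
        clusters.append(cluster)
    return _finish_assignment(d2, clusters, "tocher", {"threshold": thr})


def _tree_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _tree_to_newick(node.get_left(), labels)
    right = _tree_to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_hierarchical(
    d2: D2Matrix, linkage: str = "ward", k: int = 4
) -> ClusterAssignment:
    """Agglomerative clustering on sqrt(D2) distances, cut at k clusters.

    Linkage is one of ward / average / complete; the dendrogram is also
    serialized to Newick. Cluster order follows first appearance in the
    genotype order.
    """
    n = len(d2.genotypes)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if linkage not in ("ward", "average", "complete"):
        raise ValueError("linkage must be ward, average or complete")
    dist = np.sqrt(d2.values.to_numpy())
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    groups: dict[int, list[str]] = {}
    for g, c in zip(d2.genotypes, flat):
        groups.setdefault(int(c), []).append(g)
    # order clusters by first genotype appearance
    clusters = sorted(groups.values(), key=lambda c: d2.genotypes.index(c[0]))
    tree = hierarchy.to_tree(Z)
    newick = _tree_to_newick(tree, d2.genotypes) + ";"
    return _finish_assignment(
        d2, clusters, "hierarchical", {"linkage": linkage, "k": k},
        linkage_matrix=Z, newick=newick,
    )


def cluster_distance_summary(d2: D2Matrix, ca: ClusterAssignment) -> pd.DataFrame:
    """Intra- (diagonal) and inter-cluster (off-diagonal) mean D2 table."""
    members = sorted(g for c in ca.clusters for g in c)
    if members != sorted(d2.genotypes):
        raise ValueError("clusters do not partition the genotype set")
    _, inter = _distance_summaries(d2, ca.clusters)
    return inter


@dataclass
class PCAResult:
    """Eigen decomposition of the genotype-mean correlation/covariance matrix."""

    mode: str
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    scores: pd.DataFrame         # genotype x PC
    loadings: pd.DataFrame       # trait x PC
    trait_linkage: np.ndarray    # average-linkage tree on 1 - |r| distances
    trait_order: list[str]


def pca_traits(means: pd.DataFrame, mode: str = "correlation") -> PCAResult:
    """PCA of a genotype x trait means table.

    ``mode="correlation"`` standardizes traits (unit variance) before the
    eigendecomposition; ``mode="covariance"`` works on raw scales, letting
    large-variance traits dominate. Scores are the (centered, optionally
    scaled) data projected on the eigenvectors; percent variance sums to
    100. The trait dendrogram uses average linkage on 1 - |Pearson r|.
    """
    if mode not in ("correlation", "covariance"):
        raise ValueError("mode must be 'correlation' or 'covariance'")
    tab = pd.DataFrame(means).astype(float)
    if tab.shape[1] < 2 or tab.shape[0] < 3:
        raise ValueError("need >= 2 traits and >= 3 genotypes")
    X = tab.to_numpy()
    Xc = X - X.mean(axis=0)
    if mode == "correlation":
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = [t for t, s in zip(tab.columns, sd) if s == 0]
            raise ValueError(f"constant trait(s) under correlation mode: {bad}")
        Xc = Xc / sd
    S = (Xc.T @ Xc) / (len(tab) - 1)
    w, v = np.linalg.eigh(S)
    idx = np.argsort(w)[::-1]
    w, v = np.clip(w[idx], 0.0, None), v[:, idx]
    # sign convention: largest-magnitude loading positive
    for j in range(v.shape[1]):
        i = np.argmax(np.abs(v[:, j]))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
    pct = 100.0 * w / w.sum()
    pcs = [f"PC{i + 1}" for i in range(len(w))]
    scores = pd.DataFrame(Xc @ v, index=tab.index, columns=pcs)
    loadings = pd.DataFrame(v, index=tab.columns, columns=pcs)

    corr = np.corrcoef(X, rowvar=False)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return PCAResult(
        mode=mode, eigenvalues=w, percent_variance=pct,
        scores=scores, loadings=loadings,
        trait_linkage=Z, trait_order=list(tab.columns),
    )
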
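"""Divergence profiling: correlation matrices, clustering, NJ trees, PCA.

Sample-by-sample Spearman correlation of transcriptome-wide expression (or
PSI) summarizes how conserved a regulatory layer is across samples; the
complementary distance 1 - rho feeds hierarchical clustering and
neighbor-joining expression trees.  PSI correlations use pairwise-complete
observations because PSI missingness is structural (unexpressed genes), not
random — listwise deletion would discard most features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

log = logging.getLogger(__name__)


class ProfilingError(ValueError):
    pass


def spearman_matrix(matrix: pd.DataFrame, min_features: int = 3) -> pd.DataFrame:
    """Pairwise Spearman rho between samples (columns).

    Average ranks for ties; missing entries excluded pairwise.  Raises if
    the matrix has fewer than ``min_features`` rows or if any sample pair
    shares fewer than ``min_features`` non-missing features.
    """
    if matrix.shape[0] < min_features:
        raise ProfilingError(
            f"need >= {min_features} features, got {matrix.shape[0]}"
        )
    X = matrix.to_numpy(dtype=float)
    finite = np.isfinite(X)
    n = X.shape[1]
    if finite.all():
        ranks = stats.rankdata(X, axis=0)
        corr = np.corrcoef(ranks.T)
    else:
        corr = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                common = finite[:, i] & finite[:, j]
                k = int(common.sum())
                if k < min_features:
                    raise ProfilingError(
                        f"samples {matrix.columns[i]!r} and "
                        f"{matrix.columns[j]!r} share only {k} non-missing "
                        f"features (need >= {min_features})"
                    )
                ri = stats.rankdata(X[common, i])
                rj = stats.rankdata(X[common, j])
                corr[i, j] = corr[j, i] = np.corrcoef(ri, rj)[0, 1]
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)


def upper_triangle(corr: pd.DataFrame) -> np.ndarray:
    """Off-diagonal upper-triangle values (no self-pairs, no duplicates)."""
    a = corr.to_numpy()
    iu = np.triu_indices_from(a, k=1)
    return a[iu]


def compare_rho_distributions(
    rho_a: np.ndarray | pd.DataFrame,
    rho_b: np.ndarray | pd.DataFrame,
    n_permutations: int = 0,
    seed: int = 0,
) -> dict:
    """Two-sided Welch t-test between two sets of correlation values.

    Accepts full correlation matrices (their upper triangles are taken) or
    1-D value arrays.  Because correlation values over sample pairs are not
    independent, the t-test is descriptive; an optional label-permutation
    p-value over the pooled values is reported alongside when
    ``n_permutations > 0``.
    """
    a = upper_triangle(rho_a) if isinstance(rho_a, pd.DataFrame) else np.asarray(rho_a)
    b = upper_triangle(rho_b) if isinstance(rho_b, pd.DataFrame) else np.asarray(rho_b)
    if len(a) < 2 or len(b) < 2:
        raise ProfilingError("need at least 2 values per group")
    if len(a) == len(b) and np.allclose(a, b):
        # identical inputs: the difference is exactly zero
        return {
            "t": 0.0, "df": float(len(a) + len(b) - 2), "p": 1.0,
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "difference": 0.0,
        }
    if np.var(a) == 0 or np.var(b) == 0:
        raise ProfilingError("zero-variance group in rho comparison")
    res = stats.ttest_ind(a, b, equal_var=False)
    out = {
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "difference": float(a.mean() - b.mean()),
    }
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        obs = abs(out["difference"])
        hits = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            if abs(pooled[: len(a)].mean() - pooled[len(a):].mean()) >= obs - 1e-15:
                hits += 1
        out["permutation_p"] = (1 + hits) / (n_permutations + 1)
    return out


@dataclass
class ClusterResult:
    """Hierarchical clustering of a correlation matrix on distance 1 - rho."""

    linkage: np.ndarray
    labels: list[str]

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels at k clusters."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")

    def adjusted_rand(self, k: int, factor: pd.Series) -> float:
        """Adjusted Rand index between the k-cut and a metadata factor."""
        flat = self.cut(k)
        fac = factor.reindex(flat.index)
        return float(adjusted_rand_score(fac.astype(str), flat))

    def cophenetic_matrix(self) -> pd.DataFrame:
        d = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(d, index=self.labels, columns=self.labels)


def hcluster(corr: pd.DataFrame, method: str = "average") -> ClusterResult:
    """Agglomerative clustering on distance 1 - rho.

    Merge order is deterministic (scipy breaks distance ties by smallest
    condensed index, i.e. the smallest sample-index pair).
    """
    dist = 1.0 - corr.to_numpy()
    if not np.isfinite(dist).all():
        raise ProfilingError("non-finite distances in correlation matrix")
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    return ClusterResult(linkage=Z, labels=list(corr.columns))


def cophenetic_compare(a: ClusterResult, b: ClusterResult) -> float:
    """Pearson correlation between two dendrograms' cophenetic distances.

    A quantitative surrogate for a tanglegram; requires identical leaf sets.
    """
    if set(a.labels) != set(b.labels):
        raise ProfilingError("leaf sets differ between dendrograms")
    da = a.cophenetic_matrix()
    db = b.cophenetic_matrix().reindex(index=da.index, columns=da.columns)
    va = squareform(da.to_numpy(), checks=False)
    vb = squareform(db.to_numpy(), checks=False)
    return float(np.corrcoef(va, vb)[0, 1])


def expression_nj_tree(
    corr: pd.DataFrame, is_distance: bool = False
) -> str:
    """Neighbor-joining tree (Saitou-Nei) from 1 - rho distances.

    Negative branch lengths produced by NJ on non-additive input are clamped
    to zero with a warning.  Returns a Newick string.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if corr.shape[0] < 4:
        raise ProfilingError("need >= 4 samples for internal NJ structure")
    d = corr.to_numpy().astype(float) if is_distance else 1.0 - corr.to_numpy()
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    tree = nj(DistanceMatrix(d, ids=[str(c) for c in corr.columns]))
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        log.warning("clamped %d negative NJ branch lengths to 0", clamped)
    return str(tree).strip()


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray  # over all components, sums to 1


def pca(
    matrix: pd.DataFrame,
    center: bool = True,
    scale: bool = False,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of samples over features (features are rows of ``matrix``).

    Zero-variance features are dropped (logged).  The variance-explained
    vector covers the full rank and sums to 1.  Sign convention: each
    component's largest-magnitude loading is positive.
    """
    X = matrix.to_numpy(dtype=float).T  # samples x features
    var = X.var(axis=0)
    keep = var > 0
    if not keep.all():
        log.info("dropping %d zero-variance features before PCA", (~keep).sum())
    X = X[:, keep]
    feats = matrix.index[keep]
    if X.shape[1] == 0:
        raise ProfilingError("no features with nonzero variance")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if len(S) else 0
    if n_components is None:
        n_components = rank
    if n_components > rank:
        raise ProfilingError(
            f"requested {n_components} components but rank is {rank}"
        )
    evr = S**2 / (S**2).sum()
    # fix signs: largest-magnitude loading positive
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    comps = [f"PC{k+1}" for k in range(n_components)]
    scores = pd.DataFrame(
        U[:, :n_components] * S[:n_components], index=matrix.columns, columns=comps
    )
    loadings = pd.DataFrame(Vt[:n_components].T, index=feats, columns=comps)
    return PCAResult(
        scores=scores, loadings=loadings, explained_variance_ratio=evr[:rank]
    )
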
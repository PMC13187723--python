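"""Maximum-likelihood OU/BM models of expression evolution on a species tree.

Per feature (gene or isoform), species-mean log2 expression is modeled as a
multivariate normal over the tips of the phylogeny:

* Brownian motion (neutral drift): mean ``root_mean``, covariance
  ``sigma2 * C`` with ``C`` the shared root-to-MRCA path-length matrix.
* Ornstein-Uhlenbeck (stabilizing selection toward an optimum ``theta``
  with strength ``alpha``): two root conventions are supported.
  ``stationary`` draws the root from the stationary law, giving
  ``V_ij = sigma2/(2 alpha) * exp(-alpha * d_ij)`` with ``d_ij`` the
  patristic distance; ``fixed`` pins the root at ``theta``, giving
  ``V_ij = sigma2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha t_ij))``
  with ``t_ij`` the shared time.  The fixed-root form converges to BM as
  ``alpha -> 0``, so the OU family (maximized over both root conventions
  and alpha, including the alpha -> 0 limit point) nests BM exactly; the
  likelihood-ratio statistic is therefore never negative.

The stationary variance ``sigma2 / (2 alpha)`` is reported as the
"evolutionary variance" of a feature: the spread expression maintains
around its optimum at equilibrium, a direct readout of how constrained the
feature's expression evolution is.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .trees import node_depths, phylo_matrices

log = logging.getLogger(__name__)

ALPHA_BOUNDS = (1e-4, 1e3)  # per unit tree height


class PhyloModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# species means


def species_means(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    tissue: str,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Species x feature trait matrix: per-species mean of log2(expr + 1).

    Only samples from ``tissue`` are used.  Species with a single replicate
    are flagged in the log (their mean has no within-species support).
    """
    samples = metadata.index[metadata["tissue"] == tissue]
    samples = samples.intersection(expr.columns)
    if len(samples) == 0:
        raise PhyloModelError(f"no samples for tissue {tissue!r}")
    sub = expr[samples]
    if log_transform:
        sub = np.log2(sub + 1.0)
    species = metadata.loc[samples, "species"]
    absent = sorted(set(metadata["species"]) - set(species))
    if absent:
        raise PhyloModelError(
            f"species absent from tissue {tissue!r}: {absent}"
        )
    counts = species.value_counts()
    lonely = counts.index[counts == 1].tolist()
    if lonely:
        log.info("species with a single replicate in %s: %s", tissue, lonely)
    return sub.T.groupby(species).mean()


# ---------------------------------------------------------------------------
# likelihoods


def _chol(V: np.ndarray) -> np.ndarray:
    """Cholesky with a one-shot jitter fallback for near-singular matrices
    (e.g. zero-length cherries)."""
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        jitter = 1e-10 * float(np.mean(np.diag(V))) + 1e-12
        log.warning("singular covariance; adding diagonal jitter %.2e", jitter)
        return linalg.cholesky(V + jitter * np.eye(len(V)), lower=True)


def _mvn_loglik(y: np.ndarray, mean: np.ndarray, V: np.ndarray) -> float:
    L = _chol(V)
    r = linalg.solve_triangular(L, y - mean, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    n = len(y)
    return float(-0.5 * (n * np.log(2.0 * np.pi) + logdet + r @ r))


def _structure_matrices(
    tree: dendropy.Tree, labels
) -> tuple[np.ndarray, np.ndarray]:
    _, C, D = phylo_matrices(tree, labels)
    return C, D


def _ou_structure(
    alpha: float, C: np.ndarray, D: np.ndarray, root: str
) -> np.ndarray:
    """Unit-variance OU structure matrix: V = (sigma2/(2 alpha)) * R."""
    R = np.exp(-alpha * D)
    if root == "fixed":
        R = R * (1.0 - np.exp(-2.0 * alpha * C))
    elif root != "stationary":
        raise PhyloModelError(f"unknown OU root convention {root!r}")
    return R


def _check_ultrametric(C: np.ndarray) -> None:
    depths = np.diag(C)
    height = depths.max()
    if height > 0 and (depths.max() - depths.min()) > 1e-6 * height:
        log.warning(
            "tree is not ultrametric (tip depth spread %.3g); the OU "
            "covariance is applied to patristic distances as-is",
            depths.max() - depths.min(),
        )


def bm_loglik(
    traits: pd.Series, tree: dendropy.Tree, sigma2: float, root_mean: float
) -> float:
    """Brownian-motion log-likelihood of tip traits."""
    if sigma2 <= 0:
        raise PhyloModelError("BM requires sigma2 > 0")
    C, _ = _structure_matrices(tree, traits.index)
    y = traits.to_numpy(dtype=float)
    return _mvn_loglik(y, np.full(len(y), root_mean), sigma2 * C)


def ou_loglik(
    traits: pd.Series,
    tree: dendropy.Tree,
    sigma2: float,
    alpha: float,
    theta: float,
    root: str = "stationary",
) -> float:
    """Ornstein-Uhlenbeck log-likelihood of tip traits (see module docs)."""
    if alpha <= 0:
        raise PhyloModelError("OU requires alpha > 0")
    if sigma2 <= 0:
        raise PhyloModelError("OU requires sigma2 > 0")
    C, D = _structure_matrices(tree, traits.index)
    _check_ultrametric(C)
    R = _ou_structure(alpha, C, D, root)
    y = traits.to_numpy(dtype=float)
    V = sigma2 / (2.0 * alpha) * R
    return _mvn_loglik(y, np.full(len(y), theta), V)


# ---------------------------------------------------------------------------
# fitting


def _profile_block(Y: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, ...]:
    """Profile the GLS mean and scale of V = v R for all rows of Y.

    Returns (mu_hat, v_hat, loglik) arrays; the ML scale uses the n
    denominator.
    """
    n = R.shape[0]
    L = _chol(R)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ones = np.ones(n)
    Rinv_one = linalg.cho_solve((L, True), ones)
    Rinv_Y = linalg.cho_solve((L, True), Y.T)  # n x F
    one_R_one = ones @ Rinv_one
    one_R_y = ones @ Rinv_Y
    y_R_y = np.einsum("fn,nf->f", Y, Rinv_Y)
    mu = one_R_y / one_R_one
    quad = np.maximum(y_R_y - one_R_y**2 / one_R_one, 1e-300)
    v = quad / n
    loglik = -0.5 * (n * np.log(2.0 * np.pi * v) + logdet + n)
    return mu, v, loglik


def fit_regime(
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    alpha_bounds: tuple[float, float] = ALPHA_BOUNDS,
    n_alpha_grid: int = 25,
    fdr: float = 0.05,
    root_modes: tuple[str, ...] = ("stationary", "fixed"),
) -> pd.DataFrame:
    """Fit BM and OU to every feature and classify its selective regime.

    Parameters
    ----------
    traits
        species x feature matrix (e.g. from :func:`species_means`).
    alpha_bounds
        search bounds for alpha, expressed per unit tree height.

    Per feature: BM is fit in closed form (GLS root mean, ML sigma2); OU
    profiles theta and the scale analytically given alpha and maximizes
    alpha by a log-scale grid plus bounded refinement, over both root
    conventions.  Likelihood-ratio p-values come from chi-squared(1)
    (conservative at the alpha -> 0 boundary), with Benjamini-Hochberg
    correction across features.  Regime is "stabilizing" when OU is
    preferred at q < fdr, "neutral" otherwise, and "unclassified" for
    degenerate features (no variance across species, alpha pinned at the
    upper search bound, or too few tips).
    """
    if traits.shape[0] < 4:
        raise PhyloModelError("need >= 4 species for regime fitting")
    labels = list(traits.index)
    C, D = _structure_matrices(tree, labels)
    height = float(np.max(np.diag(C)))
    if height <= 0:
        raise PhyloModelError("tree has zero height")
    lo, hi = alpha_bounds[0] / height, alpha_bounds[1] / height
    alpha_grid = np.geomspace(lo, hi, n_alpha_grid)

    Y = traits.to_numpy(dtype=float).T  # features x species
    features = list(traits.columns)
    F, n = Y.shape
    variances = Y.var(axis=1)
    ok = np.isfinite(Y).all(axis=1) & (variances > 1e-12)

    out = pd.DataFrame(index=features)
    out.index.name = "feature_id"
    for col in (
        "sigma2_bm", "root_mean_bm", "loglik_bm", "sigma2_ou", "alpha",
        "theta", "loglik_ou", "lrt", "p", "q", "evolutionary_variance",
    ):
        out[col] = np.nan
    out["root_mode"] = ""
    out["regime"] = "unclassified"
    if ok.any():
        sub = Y[ok]
        mu_bm, v_bm, ll_bm = _profile_block(sub, C)

        best_ll = np.full(sub.shape[0], -np.inf)
        best_alpha = np.zeros(sub.shape[0])
        best_mode = np.zeros(sub.shape[0], dtype=int)
        for m, mode in enumerate(root_modes):
            for a in alpha_grid:
                _, _, ll = _profile_block(sub, _ou_structure(a, C, D, mode))
                better = ll > best_ll
                best_ll[better] = ll[better]
                best_alpha[better] = a
                best_mode[better] = m

        # bounded refinement around each feature's best grid point
        grid_pos = {a: i for i, a in enumerate(alpha_grid)}
        final_alpha = best_alpha.copy()
        final_ll = best_ll.copy()
        for f in range(sub.shape[0]):
            i = grid_pos[best_alpha[f]]
            a_lo = alpha_grid[max(i - 1, 0)]
            a_hi = alpha_grid[min(i + 1, len(alpha_grid) - 1)]
            mode = root_modes[best_mode[f]]
            yf = sub[f : f + 1]

            def neg(loga: float) -> float:
                return -_profile_block(
                    yf, _ou_structure(np.exp(loga), C, D, mode)
                )[2][0]

            res = optimize.minimize_scalar(
                neg, bounds=(np.log(a_lo), np.log(a_hi)), method="bounded",
                options={"xatol": 1e-3},
            )
            if res.success and -res.fun > final_ll[f]:
                final_ll[f] = -res.fun
                final_alpha[f] = np.exp(res.x)

        theta_hat = np.empty(sub.shape[0])
        v_hat = np.empty(sub.shape[0])
        for f in range(sub.shape[0]):
            mode = root_modes[best_mode[f]]
            mu, v, _ = _profile_block(
                sub[f : f + 1], _ou_structure(final_alpha[f], C, D, mode)
            )
            theta_hat[f] = mu[0]
            v_hat[f] = v[0]

        # the alpha -> 0 (fixed-root) limit of the OU family is BM itself,
        # so the OU maximum is bounded below by the BM maximum
        clamped = final_ll < ll_bm
        final_ll = np.maximum(final_ll, ll_bm)
        lrt = np.maximum(0.0, 2.0 * (final_ll - ll_bm))
        pvals = stats.chi2.sf(lrt, df=1)

        at_bound = final_alpha >= 0.99 * hi
        idx = np.array(features, dtype=object)[ok]
        out.loc[idx, "sigma2_bm"] = v_bm
        out.loc[idx, "root_mean_bm"] = mu_bm
        out.loc[idx, "loglik_bm"] = ll_bm
        out.loc[idx, "alpha"] = final_alpha
        out.loc[idx, "theta"] = theta_hat
        out.loc[idx, "sigma2_ou"] = 2.0 * final_alpha * v_hat
        out.loc[idx, "loglik_ou"] = final_ll
        out.loc[idx, "root_mode"] = [root_modes[m] for m in best_mode]
        out.loc[idx, "lrt"] = lrt
        out.loc[idx, "p"] = pvals
        out.loc[idx, "evolutionary_variance"] = np.where(clamped, np.nan, v_hat)

        qvals = _bh(pvals)
        out.loc[idx, "q"] = qvals
        regime = np.where(qvals < fdr, "stabilizing", "neutral")
        regime[at_bound] = "unclassified"
        out.loc[idx, "regime"] = regime
    return out


def _bh(p: np.ndarray) -> np.ndarray:
    from .differential import bh_adjust

    return bh_adjust(p)


def evolutionary_variance(fit_row: pd.Series | dict) -> float:
    """Stationary OU variance sigma2 / (2 alpha) from a fitted feature."""
    sigma2 = float(fit_row["sigma2_ou"])
    alpha = float(fit_row["alpha"])
    if alpha <= 0:
        raise PhyloModelError("evolutionary variance requires alpha > 0")
    return sigma2 / (2.0 * alpha)


def compare_evolutionary_variance(
    fits_a: pd.DataFrame, fits_b: pd.DataFrame
) -> dict:
    """Mann-Whitney U comparison of evolutionary-variance distributions
    between two feature sets (e.g. isoform-level vs gene-level fits)."""
    a = fits_a["evolutionary_variance"].dropna().to_numpy()
    b = fits_b["evolutionary_variance"].dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise PhyloModelError("need >= 2 converged OU fits per set")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "U": float(u), "p": float(p),
        "median_a": float(np.median(a)), "median_b": float(np.median(b)),
    }


# ---------------------------------------------------------------------------
# ancestral state reconstruction


def ancestral_states(
    traits: pd.Series,
    tree: dendropy.Tree,
    sigma2: float | None = None,
    root_mean: float | None = None,
) -> pd.DataFrame:
    """ML ancestral state estimates under Brownian motion.

    For each internal node, the conditional expectation and variance of the
    node state given the tip values, with the BM parameters either supplied
    or estimated by ML (GLS root mean, ML sigma2).  The root estimate equals
    the GLS mean.  Variances are conditional on the plugged-in parameters.

    Returns a DataFrame indexed by node label (internal nodes get
    ``node<k>`` labels in preorder if unlabeled) with columns
    ``estimate``, ``variance``, ``depth``, ``n_descendants``.
    """
    labels = list(traits.index)
    C, _ = _structure_matrices(tree, labels)
    y = traits.to_numpy(dtype=float)
    n = len(y)
    L = _chol(C)
    ones = np.ones(n)
    Cinv_one = linalg.cho_solve((L, True), ones)
    Cinv_y = linalg.cho_solve((L, True), y)
    if root_mean is None:
        root_mean = float(ones @ Cinv_y / (ones @ Cinv_one))
    if sigma2 is None:
        r = y - root_mean
        sigma2 = float(r @ linalg.cho_solve((L, True), r) / n)
    resid = linalg.cho_solve((L, True), y - root_mean)

    depths = node_depths(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    # leaf sets and tip-shared-path vectors per internal node
    leafsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = {index[node.taxon.label]} if node.taxon.label in index else set()
        else:
            leafsets[node] = set().union(*(leafsets[c] for c in node.child_nodes()))

    rows = []
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        k += 1
        label = node.label or f"node{k}"
        h = depths[node]
        desc = leafsets[node]
        c = np.empty(n)
        for i in range(n):
            if i in desc:
                c[i] = h
            else:
                anc = node.parent_node
                while anc is not None and i not in leafsets[anc]:
                    anc = anc.parent_node
                c[i] = depths[anc] if anc is not None else 0.0
        estimate = root_mean + c @ resid
        cvar = h - c @ linalg.cho_solve((L, True), c)
        rows.append(
            {
                "node": label,
                "estimate": float(estimate),
                "variance": float(max(sigma2 * cvar, 0.0)),
                "depth": float(h),
                "n_descendants": len(desc),
            }
        )
    return pd.DataFrame(rows).set_index("node")
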
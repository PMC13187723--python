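"""Differential splicing and expression between trophic guilds.

Differential isoform usage is tested with a guild-label permutation test on
the absolute difference of mean PSI: exact enumeration of label splits when
there are at most ``max_exact`` arrangements, seeded random permutations
otherwise.  Gene-level "differentially spliced gene" (DSG) calls aggregate
isoform p-values by minimum-p with a Sidak correction for the gene's
isoform count, then Benjamini-Hochberg across genes.

Differential gene expression (DEG) uses a Welch t-test on log2(CPM + 1)
(default); an optional negative-binomial GLM Wald variant is available.
Overlap and convergence analyses operate on the resulting gene sets.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, FormatError
from .quantify import PSIMatrix, gene_expression, normalize

log = logging.getLogger(__name__)

GUILD_PAIR = ("herbivore", "carnivore")


class DifferentialError(ValueError):
    pass


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise DifferentialError("pvals must be one-dimensional")
    if np.isnan(p).any():
        raise DifferentialError("NaN p-values rejected")
    if ((p < 0) | (p > 1)).any():
        raise DifferentialError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _select_guild_samples(
    metadata: pd.DataFrame,
    radiation: str,
    tissue: str,
    guilds: tuple[str, str] = GUILD_PAIR,
) -> tuple[pd.Index, np.ndarray]:
    """Sample ids of the two guilds within a radiation and tissue; species
    with guild 'other' are excluded from contrasts."""
    sel = metadata[
        (metadata["clade"] == radiation)
        & (metadata["tissue"] == tissue)
        & (metadata["guild"].isin(guilds))
    ]
    if sel.empty:
        raise DifferentialError(
            f"no samples for radiation {radiation!r}, tissue {tissue!r}"
        )
    is_a = (sel["guild"] == guilds[0]).to_numpy()
    if is_a.sum() < 2 or (~is_a).sum() < 2:
        raise DifferentialError(
            f"need >= 2 samples per guild in {radiation}/{tissue}"
        )
    return sel.index, is_a


def _split_matrix(
    n: int, n_a: int, n_perm: int, max_exact: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Boolean (n_splits, n) membership matrix for group A.

    Exact enumeration of all C(n, n_a) splits when feasible (the observed
    labeling is one of them), otherwise the observed labeling plus
    ``n_perm`` random permutations.
    """
    from math import comb

    if comb(n, n_a) <= max_exact:
        rows = [
            np.isin(np.arange(n), idx) for idx in combinations(range(n), n_a)
        ]
        return np.array(rows), True
    perms = np.zeros((n_perm, n), dtype=bool)
    base = np.zeros(n, dtype=bool)
    base[:n_a] = True
    for b in range(n_perm):
        perms[b] = rng.permutation(base)
    return perms, False


def diff_psi(
    psi: PSIMatrix | pd.DataFrame,
    metadata: pd.DataFrame,
    radiation: str,
    tissue: str,
    iso2gene: pd.Series | None = None,
    guilds: tuple[str, str] = GUILD_PAIR,
    n_permutations: int = 1000,
    max_exact: int = 10_000,
    seed: int = 0,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential isoform usage between guilds within one radiation.

    Statistic per isoform: |mean PSI(guild A) - mean PSI(guild B)| over
    non-missing samples.  Only isoforms of multi-isoform genes with at least
    two non-missing values per guild are tested.  Returns
    (isoform-level results, gene-level DSG table).
    """
    if isinstance(psi, PSIMatrix):
        values, genes = psi.multi_isoform(), psi.iso2gene
    else:
        if iso2gene is None:
            raise DifferentialError("iso2gene required with a bare PSI frame")
        genes = iso2gene
        sizes = genes.groupby(genes).transform("size")
        values = psi.loc[sizes.reindex(psi.index) > 1]
    genes = genes.reindex(values.index)

    samples, is_a = _select_guild_samples(metadata, radiation, tissue, guilds)
    X = values[samples].to_numpy(dtype=float)
    finite = np.isfinite(X)
    enough = (finite[:, is_a].sum(axis=1) >= 2) & (
        finite[:, ~is_a].sum(axis=1) >= 2
    )
    if not enough.any():
        raise DifferentialError(
            f"no isoform has >= 2 non-missing PSI values per guild in "
            f"{radiation}/{tissue}"
        )
    dropped = int((~enough).sum())
    if dropped:
        log.info("diff_psi %s/%s: dropped %d low-coverage isoforms",
                 radiation, tissue, dropped)
    X = X[enough]
    finite = finite[enough]
    iso_ids = values.index[enough]
    genes = genes[enough]

    rng = np.random.default_rng(seed)
    W, exact = _split_matrix(
        X.shape[1], int(is_a.sum()), n_permutations, max_exact, rng
    )
    X0 = np.where(finite, X, 0.0)
    Wf = W.T.astype(float)  # n x n_splits
    cf = finite.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = (X0 @ Wf) / (cf @ Wf)
        mean_b = (X0 @ (1.0 - Wf)) / (cf @ (1.0 - Wf))
        stat = np.abs(mean_a - mean_b)  # isoforms x n_splits

    obs_w = is_a.astype(float)
    with np.errstate(invalid="ignore"):
        obs_a = (X0 @ obs_w) / (cf @ obs_w)
        obs_b = (X0 @ (1.0 - obs_w)) / (cf @ (1.0 - obs_w))
    obs = np.abs(obs_a - obs_b)
    delta = obs_a - obs_b  # signed, guild A minus guild B

    ge = stat >= obs[:, None] - 1e-12
    valid = np.isfinite(stat)
    if exact:
        pvals = np.where(
            valid.sum(axis=1) > 0,
            (ge & valid).sum(axis=1) / np.maximum(valid.sum(axis=1), 1),
            1.0,
        )
    else:
        pvals = (1 + (ge & valid).sum(axis=1)) / (valid.sum(axis=1) + 1)

    iso_out = pd.DataFrame(
        {
            "isoform_id": iso_ids,
            "gene_id": genes.to_numpy(),
            "level": "isoform",
            "radiation": radiation,
            "tissue": tissue,
            "effect": delta,
            "p": pvals,
            "direction": np.where(
                delta >= 0, f"higher-in-{guilds[0]}", f"higher-in-{guilds[1]}"
            ),
            "exact_permutation": exact,
        }
    ).set_index("isoform_id", drop=False)

    # gene level: min isoform p, Sidak-corrected for isoform count
    def _aggregate(group: pd.DataFrame) -> pd.Series:
        k = len(group)
        best = group.sort_values(
            ["p", "effect"],
            key=lambda s: s if s.name == "p" else -s.abs(),
            kind="stable",
        ).iloc[0]
        p_gene = 1.0 - (1.0 - best["p"]) ** k
        return pd.Series(
            {
                "p": min(max(p_gene, 0.0), 1.0),
                "effect": best["effect"],
                "direction": best["direction"],
                "top_isoform": best["isoform_id"],
                "n_isoforms": k,
            }
        )

    gene_out = iso_out.groupby("gene_id", sort=True)[
        ["isoform_id", "p", "effect", "direction"]
    ].apply(_aggregate)
    gene_out["q"] = bh_adjust(gene_out["p"].to_numpy())
    gene_out["significant"] = gene_out["q"] < fdr
    gene_out.insert(0, "gene_id", gene_out.index)
    gene_out.insert(1, "level", "gene")
    gene_out.insert(2, "radiation", radiation)
    gene_out.insert(3, "tissue", tissue)
    return iso_out, gene_out


def diff_expr(
    counts: CountMatrix,
    metadata: pd.DataFrame,
    radiation: str,
    tissue: str,
    guilds: tuple[str, str] = GUILD_PAIR,
    fdr: float = 0.05,
    method: str = "welch",
) -> pd.DataFrame:
    """Differential gene expression between guilds within one radiation.

    ``welch`` (default): Welch t-test on per-gene log2(CPM + 1); effect is
    the difference of guild means (a log2 fold change).  ``nb``: per-gene
    negative-binomial GLM Wald test on raw gene counts with a log link and
    a method-of-moments dispersion (slower; clearly labeled in output).
    """
    samples, is_a = _select_guild_samples(metadata, radiation, tissue, guilds)
    cpm = normalize(counts.values[samples], method="cpm")
    genes = gene_expression(cpm, counts.iso2gene)
    if method == "welch":
        logx = np.log2(genes.to_numpy() + 1.0)
        A, B = logx[:, is_a], logx[:, ~is_a]
        effect = A.mean(axis=1) - B.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(A, B, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
        flat = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
        pvals[flat] = 1.0
        flags = np.where(flat, "zero-variance", "")
    elif method == "nb":
        pvals, effect, flags = _nb_wald(
            counts.gene_counts()[samples].to_numpy(), is_a
        )
    else:
        raise DifferentialError(f"unknown method {method!r}")
    out = pd.DataFrame(
        {
            "gene_id": genes.index,
            "level": "gene",
            "radiation": radiation,
            "tissue": tissue,
            "method": method,
            "effect": effect,
            "p": pvals,
            "q": bh_adjust(pvals),
            "direction": np.where(
                effect >= 0, f"higher-in-{guilds[0]}", f"higher-in-{guilds[1]}"
            ),
            "flag": flags,
        }
    ).set_index("gene_id", drop=False)
    out["significant"] = out["q"] < fdr
    return out


def _nb_wald(gene_counts: np.ndarray, is_a: np.ndarray):
    """Per-gene NB-GLM Wald test (guild indicator, log link)."""
    import statsmodels.api as sm

    design = np.column_stack([np.ones(len(is_a)), is_a.astype(float)])
    pvals = np.ones(gene_counts.shape[0])
    effect = np.zeros(gene_counts.shape[0])
    flags = np.array([""] * gene_counts.shape[0], dtype=object)
    for g in range(gene_counts.shape[0]):
        y = gene_counts[g]
        if y.sum() == 0:
            flags[g] = "zero-variance"
            continue
        mu, var = y.mean(), y.var(ddof=1)
        disp = max((var - mu) / max(mu**2, 1e-9), 1e-6)
        try:
            fit = sm.GLM(
                y, design, family=sm.families.NegativeBinomial(alpha=disp)
            ).fit()
            effect[g] = fit.params[1] / np.log(2.0)  # report on log2 scale
            pvals[g] = fit.pvalues[1]
        except Exception:  # non-convergence
            flags[g] = "glm-failure"
    return pvals, effect, flags


def overlap_test(
    set_a: set, set_b: set, universe_size: int
) -> dict:
    """Overlap count and one-sided hypergeometric enrichment p-value.

    p = P(X >= observed overlap) when drawing |b| genes from a universe in
    which |a| are marked.
    """
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise DifferentialError("set larger than the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return {
        "overlap": k,
        "size_a": len(a),
        "size_b": len(b),
        "universe": universe_size,
        "expected": len(a) * len(b) / universe_size,
        "p": min(p, 1.0),
    }


def venn3(sets: dict[str, set]) -> dict[str, int]:
    """Counts of the 7 non-empty regions of a three-set Venn partition."""
    if len(sets) != 3:
        raise DifferentialError("venn3 needs exactly three sets")
    (na, a), (nb, b), (nc, c) = [(k, set(v)) for k, v in sets.items()]
    abc = a & b & c
    return {
        f"{na}_only": len(a - b - c),
        f"{nb}_only": len(b - a - c),
        f"{nc}_only": len(c - a - b),
        f"{na}&{nb}": len((a & b) - c),
        f"{na}&{nc}": len((a & c) - b),
        f"{nb}&{nc}": len((b & c) - a),
        f"{na}&{nb}&{nc}": len(abc),
    }


def convergence(
    results: dict[str, pd.DataFrame],
    min_radiations: int = 2,
    require_same_direction: bool = True,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Features significant in >= min_radiations with a shared direction.

    ``results`` maps radiation label -> gene-level result frame (with
    ``q`` and ``direction`` columns) for a matching tissue.
    """
    if len(results) < 2:
        raise DifferentialError("need results from >= 2 radiations")
    per_rad = {}
    for rad, df in results.items():
        sig = df[df["q"] < fdr]
        if sig["direction"].isna().any() or (sig["direction"] == "").any():
            raise DifferentialError(
                f"significant features without direction in {rad}"
            )
        per_rad[rad] = sig.set_index("gene_id")["direction"]
    all_features = sorted(set().union(*[s.index for s in per_rad.values()]))
    rows = []
    for feat in all_features:
        dirs = {
            rad: s.loc[feat] for rad, s in per_rad.items() if feat in s.index
        }
        if require_same_direction:
            best = pd.Series(dirs).value_counts()
            count = int(best.iloc[0])
            direction = best.index[0]
        else:
            count = len(dirs)
            direction = ";".join(sorted(set(dirs.values())))
        if count >= min_radiations:
            rows.append(
                {
                    "feature_id": feat,
                    "n_radiations": count,
                    "direction": direction,
                    "radiations": ",".join(sorted(dirs)),
                }
            )
    return pd.DataFrame(
        rows, columns=["feature_id", "n_radiations", "direction", "radiations"]
    )


def deg_dsg_overlap(
    deg: pd.DataFrame, dsg: pd.DataFrame, universe_size: int, fdr: float = 0.05
) -> dict:
    """Overlap of DEG and DSG gene sets within one radiation/tissue."""
    deg_set = set(deg.loc[deg["q"] < fdr, "gene_id"])
    dsg_set = set(dsg.loc[dsg["q"] < fdr, "gene_id"])
    out = overlap_test(deg_set, dsg_set, universe_size)
    out["genes"] = sorted(deg_set & dsg_set)
    return out
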
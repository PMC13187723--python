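"""Normalization, PSI computation, presence calling, and clade sharing.

PSI (percent spliced in) is an isoform's abundance divided by the summed
abundance of all isoforms of its gene, computed per sample on normalized
expression (CPM by default, making PSI invariant to library size).  Where a
gene's total abundance in a sample is zero, its isoforms' PSI is *missing*,
not zero — unexpressed and fully skipped are different states and several
downstream analyses depend on the distinction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, FormatError

log = logging.getLogger(__name__)


def normalize(
    counts: CountMatrix | pd.DataFrame,
    method: str = "cpm",
    lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """Normalize an isoform count matrix.

    method
        ``"cpm"`` — counts per million (column sums become 1e6 exactly);
        ``"tpm"`` — length-normalized (requires ``lengths`` in bp);
        ``"none"`` — pass through unchanged.
    """
    values = counts.values if isinstance(counts, CountMatrix) else counts
    method = method.lower()
    if method == "none":
        return values.copy()
    if method == "tpm":
        if lengths is None:
            raise FormatError("TPM normalization requires isoform lengths")
        lengths = lengths.reindex(values.index)
        if lengths.isna().any() or (lengths <= 0).any():
            raise FormatError("missing or nonpositive isoform lengths for TPM")
        values = values.div(lengths / 1e3, axis=0)
    elif method != "cpm":
        raise FormatError(f"unknown normalization method {method!r}")
    totals = values.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise FormatError(f"sample(s) with zero total abundance: {zero}")
    return values.div(totals, axis=1) * 1e6


def gene_expression(expr: pd.DataFrame, iso2gene: pd.Series) -> pd.DataFrame:
    """Gene-level expression = sum of member isoform rows."""
    missing = expr.index.difference(iso2gene.index)
    if len(missing):
        raise FormatError(f"isoforms without gene assignment: {sorted(missing)[:5]}")
    return expr.groupby(iso2gene.reindex(expr.index)).sum()


@dataclass
class PSIMatrix:
    """Isoform x sample PSI values in [0, 1], NaN where the gene is silent."""

    values: pd.DataFrame
    iso2gene: pd.Series
    constitutive: pd.Series | None = None  # bool per isoform

    def multi_isoform(self) -> pd.DataFrame:
        """Rows restricted to isoforms of genes with more than one isoform."""
        sizes = self.iso2gene.groupby(self.iso2gene).transform("size")
        return self.values.loc[sizes > 1]


def compute_psi(expr: pd.DataFrame, iso2gene: pd.Series) -> PSIMatrix:
    """PSI(i, s) = expr(i, s) / sum over gene(i)'s isoforms of expr(., s).

    Missing (NaN), not zero, where the gene's total is zero in a sample.
    """
    arr = expr.to_numpy(dtype=float)
    if (arr < 0).any():
        raise FormatError("negative expression values")
    missing = expr.index.difference(iso2gene.index)
    if len(missing):
        raise FormatError(f"isoforms without gene assignment: {sorted(missing)[:5]}")
    genes = iso2gene.reindex(expr.index)
    totals = expr.groupby(genes).transform("sum").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(totals > 0, arr / totals, np.nan)
    return PSIMatrix(
        values=pd.DataFrame(psi, index=expr.index, columns=expr.columns),
        iso2gene=genes,
    )


def label_isoforms(
    iso2gene: pd.Series,
    primary: dict | pd.Series | None = None,
    expr: pd.DataFrame | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Flag exactly one constitutive (main) isoform per gene.

    The annotation's primary-isoform map takes precedence; genes it does not
    cover fall back to the highest mean abundance in ``expr``, with ties
    broken toward the lexicographically smaller isoform id (logged).

    Returns (constitutive flags, per-gene source labels
    {"annotation", "abundance"}).
    """
    if primary is None and expr is None:
        raise FormatError("label_isoforms needs a primary map or expression")
    primary = dict(primary or {})
    flags = pd.Series(False, index=iso2gene.index)
    sources = {}
    mean_expr = expr.mean(axis=1) if expr is not None else None
    for gene, members in iso2gene.groupby(iso2gene).groups.items():
        members = list(members)
        chosen = primary.get(gene)
        if chosen is not None:
            if chosen not in members:
                raise FormatError(
                    f"annotated primary isoform {chosen!r} not in gene {gene!r}"
                )
            sources[gene] = "annotation"
        else:
            if mean_expr is None:
                raise FormatError(
                    f"gene {gene!r} lacks a primary annotation and no "
                    "expression was given for the fallback"
                )
            m = mean_expr.loc[members]
            best = m.max()
            tied = sorted(m.index[m == best])
            if len(tied) > 1:
                log.info("constitutive tie in gene %s; choosing %s", gene, tied[0])
            chosen = tied[0]
            sources[gene] = "abundance"
        flags.loc[chosen] = True
    return flags, pd.Series(sources, name="constitutive_source")


def call_presence(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    presence_threshold: float = 1.0,
    presence_min_fraction: float = 0.4,
    group_by: str = "clade",
) -> pd.DataFrame:
    """Boolean feature x group presence table.

    A feature is present in a group iff at least ``presence_min_fraction``
    of the group's samples exceed ``presence_threshold`` (strict).  Presence
    is monotone in the threshold: lowering it never removes a presence call.
    """
    if group_by not in metadata.columns:
        raise FormatError(f"metadata has no column {group_by!r}")
    common = expr.columns.intersection(metadata.index)
    if len(common) == 0:
        raise FormatError("no overlap between expression samples and metadata")
    out = {}
    for group, rows in metadata.loc[common].groupby(group_by, sort=True):
        samples = rows.index
        if len(samples) == 0:
            raise FormatError(f"empty group {group!r}")
        frac = (expr[samples] > presence_threshold).sum(axis=1) / len(samples)
        out[group] = frac >= presence_min_fraction
    return pd.DataFrame(out)


def classify_sharing(
    presence: pd.DataFrame,
    radiations: tuple = ("LV", "LM", "LT"),
    nr: str = "NR",
) -> tuple[pd.Series, pd.DataFrame]:
    """Classify each feature's clade-sharing pattern.

    Categories: ``ancestral`` (present in NR and >= 1 radiation),
    ``unique:<radiation>`` (exactly one radiation, not NR),
    ``shared-radiations`` (>= 2 radiations, not NR), ``NR-only``, ``absent``.

    Returns (per-feature category, summary with counts and percentages over
    expressed features).
    """
    for col in radiations + (nr,):
        if col not in presence.columns:
            raise FormatError(f"presence table lacks clade column {col!r}")
    in_nr = presence[nr].to_numpy()
    rad = presence[list(radiations)].to_numpy()
    n_rad = rad.sum(axis=1)
    cats = np.where(
        in_nr & (n_rad >= 1),
        "ancestral",
        np.where(
            in_nr,
            "NR-only",
            np.where(
                n_rad >= 2,
                "shared-radiations",
                np.where(n_rad == 0, "absent", ""),
            ),
        ),
    ).astype(object)
    idx = np.flatnonzero((n_rad == 1) & ~in_nr)
    if len(idx):
        lab = np.array(list(radiations))[np.argmax(rad[idx], axis=1)]
        cats[idx] = [f"unique:{w}" for w in lab]
    categories = pd.Series(cats, index=presence.index, name="sharing")
    expressed = categories != "absent"
    counts = categories[expressed].value_counts()
    summary = pd.DataFrame(
        {
            "count": counts,
            "percent": 100.0 * counts / expressed.sum() if expressed.any() else 0.0,
        }
    )
    return categories, summary


def isoforms_per_gene(
    presence: pd.DataFrame,
    iso2gene: pd.Series,
) -> tuple[pd.DataFrame, dict]:
    """Per-group distribution of isoforms per expressed gene, with tests.

    For each group (presence column), counts present isoforms per gene over
    genes with at least one present isoform.  Reports per-group mean/median,
    Bartlett's homogeneity-of-variance test across groups, and pairwise
    two-sided Mann-Whitney U with Benjamini-Hochberg correction.
    """
    from .differential import bh_adjust

    if presence.shape[1] < 2:
        raise FormatError("need at least two groups")
    genes = iso2gene.reindex(presence.index)
    dists = {}
    for group in presence.columns:
        per_gene = presence[group].groupby(genes).sum()
        per_gene = per_gene[per_gene > 0]
        if len(per_gene) < 2:
            raise FormatError(f"group {group!r} has <2 expressed genes")
        dists[group] = per_gene
    stat, p = stats.bartlett(*[d.to_numpy(dtype=float) for d in dists.values()])
    groups = list(dists)
    pairs, pvals, ustats = [], [], []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            u, pu = stats.mannwhitneyu(
                dists[groups[i]], dists[groups[j]], alternative="two-sided"
            )
            pairs.append((groups[i], groups[j]))
            ustats.append(u)
            pvals.append(pu)
    pairwise = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "U": ustats,
            "p": pvals,
            "q": bh_adjust(np.array(pvals)),
        }
    )
    summary = pd.DataFrame(
        {
            "mean": {g: d.mean() for g, d in dists.items()},
            "median": {g: d.median() for g, d in dists.items()},
            "n_genes": {g: len(d) for g, d in dists.items()},
        }
    )
    return summary, {
        "bartlett_stat": float(stat),
        "bartlett_p": float(p),
        "pairwise": pairwise,
        "distributions": dists,
    }
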
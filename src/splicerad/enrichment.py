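"""Term-set over-representation analysis for DSG/DEG gene sets.

One-sided Fisher's exact (hypergeometric tail) test of each term's genes
against a study set, over a user-supplied term-to-gene map — no live
ontology queries, for reproducibility.  Two algorithms:

``classic``
    every term tested independently on the full study set.
``elim``
    terms are processed children-before-parents through a supplied term
    DAG; genes of a term found significant below ``elim_threshold`` are
    removed from all its ancestors before they are tested, decorrelating
    nested terms (the usual hierarchy-aware refinement).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

log = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


def read_term2gene(path) -> dict[str, set]:
    """Two-column TSV (term_id, gene_id) -> mapping term -> gene set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"], dtype=str)
    return {t: set(g) for t, g in df.groupby("term")["gene"]}


def term_enrichment(
    study_set: set,
    term2gene: Mapping[str, set],
    universe: set,
    algorithm: str = "classic",
    dag: Mapping[str, set] | None = None,
    elim_threshold: float = 0.01,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Fisher over-representation of each term in the study set.

    Parameters
    ----------
    study_set, universe
        study genes must be a subset of the universe (all expressed genes).
    dag
        term DAG as a mapping child -> set of parent terms; required for
        ``elim``.

    Returns a DataFrame sorted by p with one row per tested term.
    """
    study = set(study_set)
    universe = set(universe)
    if not study <= universe:
        raise EnrichmentError("study set is not a subset of the universe")
    if algorithm not in ("classic", "elim"):
        raise EnrichmentError(f"unknown algorithm {algorithm!r}")
    terms = {t: set(g) & universe for t, g in term2gene.items()}
    skipped = sorted(t for t, g in terms.items() if not g)
    if skipped:
        log.info("skipping %d terms with no universe genes", len(skipped))
    terms = {t: g for t, g in terms.items() if g}

    order = sorted(terms)
    if algorithm == "elim":
        if dag is None:
            raise EnrichmentError("elim requires a term DAG")
        g = nx.DiGraph()
        g.add_nodes_from(order)
        for child, parents in dag.items():
            for parent in parents:
                if child in terms and parent in terms:
                    g.add_edge(child, parent)  # edge child -> parent
        order = [t for t in nx.topological_sort(g)]  # children first

    N, n = len(universe), len(study)
    eliminated: dict[str, set] = {t: set() for t in terms}
    rows = []
    for t in order:
        genes = terms[t] - eliminated[t]
        k = len(genes & study)
        K = len(genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "term_id": t,
                "term_size": K,
                "study_hits": k,
                "expected": n * K / N,
                "fold": (k / n) / (K / N) if n and K else np.nan,
                "p": min(p, 1.0),
                "algorithm": algorithm,
            }
        )
        if algorithm == "elim" and p < elim_threshold:
            # remove this term's significant genes from every ancestor
            for anc in nx.descendants(g, t):  # ancestors along child->parent
                eliminated[anc] |= genes & study
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
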
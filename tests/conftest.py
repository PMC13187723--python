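"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import splicerad as sr
from splicerad.trees import read_tree


@pytest.fixture(scope="session")
def study_tree():
    """The default 20-tip study-like species tree."""
    return read_tree(sr.default_study_tree(), is_path=False)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset (60 genes, 200 samples)."""
    return sr.simulate_dataset(sr.SimulationConfig(n_genes=60, rng_seed=7))


@pytest.fixture(scope="session")
def default_dataset():
    """The full default-configuration synthetic dataset (500 genes)."""
    return sr.simulate_dataset(sr.SimulationConfig(rng_seed=0))


@pytest.fixture(scope="session")
def default_expr(default_dataset):
    return sr.normalize(default_dataset.counts, "cpm")


@pytest.fixture(scope="session")
def default_psi(default_dataset, default_expr):
    return sr.compute_psi(default_expr, default_dataset.counts.iso2gene)


@pytest.fixture()
def toy_counts(tmp_path):
    """3-isoform, 2-sample count TSV plus a 2-gene transcript map on disk."""
    counts = tmp_path / "counts.tsv"
    counts.write_text(
        "isoform_id\ts1\ts2\n"
        "t1\t10\t0\n"
        "t2\t30\t5\n"
        "t3\t1\t2\n"
    )
    mapping = tmp_path / "iso2gene.tsv"
    mapping.write_text("t1\tgA\nt2\tgA\nt3\tgB\n")
    return counts, mapping


def truth_classes_long(dataset) -> pd.DataFrame:
    """Planted trajectory classes in long (isoform, radiation) form."""
    long = dataset.iso_truth.melt(
        id_vars=["isoform_id"],
        value_vars=["class_LV", "class_LM", "class_LT"],
        var_name="col",
        value_name="true_class",
    )
    long["radiation"] = long["col"].str[-2:]
    return long.drop(columns="col")


def structural_presence(dataset) -> pd.DataFrame:
    """Clade-level presence from the generator's true proportions."""
    out = {}
    for clade in ("NR", "LV", "LM", "LT"):
        cols = [s for s in dataset.true_psi.columns if s.startswith(clade)]
        out[clade] = dataset.true_psi[cols].sum(axis=1) > 0
    return pd.DataFrame(out)


def true_sample_psi(dataset) -> pd.DataFrame:
    """Noise-free per-sample PSI: each sample carries its species' truth."""
    out = dataset.true_psi[dataset.metadata["species"].values].copy()
    out.columns = dataset.metadata.index
    return out
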
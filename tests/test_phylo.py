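"""OU/BM likelihoods checked against an independently built dense-MVN oracle."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import splicerad as sr
from splicerad.phylo import PhyloModelError
from splicerad.simulate import _tip_matrix
from splicerad.trees import read_tree

ORACLE_TREES = [
    "((A:1.0,B:1.0):1.0,C:2.0);",
    "((A:0.5,B:0.5):1.5,(C:1.2,D:1.2):0.8);",
    "(((A:0.3,B:0.3):0.4,C:0.7):1.3,(D:0.9,E:0.9):1.1);",
    "((((A:0.2,B:0.2):0.2,C:0.4):0.3,D:0.7):0.3,(E:0.5,F:0.5):0.5);",
    # non-ultrametric (BM oracle only)
    "((A:1.0,B:2.0):0.5,(C:0.7,D:1.9):1.1);",
]


def oracle_matrices(newick: str, labels):
    """Shared-path and patristic matrices rebuilt from dendropy primitives,
    independently of the package's own tree code."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    depth = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length
            node = node.parent_node
        depth[leaf.taxon.label] = d
    n = len(labels)
    D = np.zeros((n, n))
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            D[i, j] = pdm.patristic_distance(taxa[a], taxa[b])
            C[i, j] = 0.5 * (depth[a] + depth[b] - D[i, j])
    return C, D


def mvn_logpdf(y, mean, cov):
    return stats.multivariate_normal(mean=mean, cov=cov).logpdf(y)


def is_ultrametric(C):
    d = np.diag(C)
    return np.allclose(d, d[0])


class TestLikelihoodOracle:
    @pytest.mark.parametrize("newick", ORACLE_TREES)
    def test_bm_matches_dense_mvn(self, newick):
        tree = read_tree(newick, is_path=False)
        labels = sr.tip_labels(tree)
        C, _ = oracle_matrices(newick, labels)
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(5, 1, len(labels)), index=labels)
        for sigma2, mu in [(0.5, 4.0), (2.0, 6.5)]:
            ours = sr.bm_loglik(y, tree, sigma2, mu)
            oracle = mvn_logpdf(y.to_numpy(), np.full(len(y), mu), sigma2 * C)
            assert abs(ours - oracle) < 1e-8

    @pytest.mark.parametrize("newick", ORACLE_TREES[:4])
    @pytest.mark.parametrize("root", ["stationary", "fixed"])
    def test_ou_matches_dense_mvn(self, newick, root):
        tree = read_tree(newick, is_path=False)
        labels = sr.tip_labels(tree)
        C, D = oracle_matrices(newick, labels)
        rng = np.random.default_rng(1)
        y = pd.Series(rng.normal(5, 1, len(labels)), index=labels)
        for sigma2, alpha, theta in [(1.0, 0.7, 5.0), (2.5, 3.0, 4.2)]:
            ours = sr.ou_loglik(y, tree, sigma2, alpha, theta, root=root)
            V = sigma2 / (2 * alpha) * np.exp(-alpha * D)
            if root == "fixed":
                V = V * (1.0 - np.exp(-2 * alpha * C))
            oracle = mvn_logpdf(y.to_numpy(), np.full(len(y), theta), V)
            assert abs(ours - oracle) < 1e-8

    def test_single_tip_closed_forms(self):
        tree = read_tree("(A:1.5);", is_path=False)
        y = pd.Series([3.0], index=["A"])
        bm = sr.bm_loglik(y, tree, sigma2=2.0, root_mean=1.0)
        assert np.isclose(bm, stats.norm(1.0, np.sqrt(2.0 * 1.5)).logpdf(3.0))
        ou = sr.ou_loglik(y, tree, sigma2=2.0, alpha=0.5, theta=1.0)
        assert np.isclose(ou, stats.norm(1.0, np.sqrt(2.0 / (2 * 0.5))).logpdf(3.0))

    def test_star_tree_bm_is_independent_normals(self):
        tree = read_tree("(A:2,B:2,C:2,D:2);", is_path=False)
        y = pd.Series([1.0, 2.0, -1.0, 0.5], index=list("ABCD"))
        ours = sr.bm_loglik(y, tree, sigma2=0.7, root_mean=0.3)
        expected = stats.norm(0.3, np.sqrt(0.7 * 2)).logpdf(y).sum()
        assert np.isclose(ours, expected)

    def test_fixed_root_ou_approaches_bm_as_alpha_vanishes(self, study_tree):
        labels = sr.tip_labels(study_tree)
        rng = np.random.default_rng(2)
        y = pd.Series(rng.normal(0, 1, len(labels)), index=labels)
        bm = sr.bm_loglik(y, study_tree, sigma2=1.0, root_mean=0.0)
        gaps = [
            abs(sr.ou_loglik(y, study_tree, 1.0, a, 0.0, root="fixed") - bm)
            for a in (1.0, 0.1, 0.01)
        ]
        assert gaps[0] > gaps[1] > gaps[2]

    def test_invalid_parameters_rejected(self, study_tree):
        y = pd.Series(0.0, index=sr.tip_labels(study_tree))
        with pytest.raises(PhyloModelError):
            sr.ou_loglik(y, study_tree, 1.0, -1.0, 0.0)
        with pytest.raises(PhyloModelError):
            sr.bm_loglik(y, study_tree, 0.0, 0.0)


class TestSpeciesMeans:
    def test_mean_of_replicates(self, small_dataset):
        expr = sr.normalize(small_dataset.counts, "cpm")
        genes = sr.gene_expression(expr, small_dataset.counts.iso2gene)
        traits = sr.species_means(genes, small_dataset.metadata, "OJ")
        assert traits.shape[0] == 20
        # check one entry by hand
        meta = small_dataset.metadata
        samples = meta.index[(meta["species"] == "LV1") & (meta["tissue"] == "OJ")]
        expected = np.log2(genes[samples] + 1).mean(axis=1)
        assert np.allclose(traits.loc["LV1"], expected)

    def test_missing_tissue_is_an_error(self, small_dataset):
        expr = sr.normalize(small_dataset.counts, "cpm")
        meta = small_dataset.metadata
        with pytest.raises(PhyloModelError):
            sr.species_means(expr, meta[meta["tissue"] == "OJ"], "PJ")


class TestFitRegime:
    def test_strong_ou_mostly_stabilizing(self, study_tree):
        rng = np.random.default_rng(10)
        G = 150
        tips = _tip_matrix(
            study_tree, np.array(["OU"] * G), np.full(G, 8.0),
            np.full(G, 16.0), np.full(G, 5.0), rng,
        )
        traits = pd.DataFrame(
            tips.T, index=sr.tip_labels(study_tree),
            columns=[f"f{i}" for i in range(G)],
        )
        fits = sr.fit_regime(traits, study_tree)
        assert (fits["regime"] == "stabilizing").mean() >= 0.8

    def test_bm_rarely_called_stabilizing(self, study_tree):
        rng = np.random.default_rng(11)
        G = 150
        tips = _tip_matrix(
            study_tree, np.array(["BM"] * G), np.ones(G),
            np.full(G, 0.3), np.full(G, 5.0), rng,
        )
        traits = pd.DataFrame(
            tips.T, index=sr.tip_labels(study_tree),
            columns=[f"f{i}" for i in range(G)],
        )
        fits = sr.fit_regime(traits, study_tree)
        assert (fits["regime"] == "stabilizing").mean() <= 0.10
        # nesting invariant
        ok = fits["loglik_ou"].notna()
        assert (fits.loc[ok, "loglik_ou"] >= fits.loc[ok, "loglik_bm"] - 1e-6).all()

    def test_constant_traits_unclassified(self, study_tree):
        traits = pd.DataFrame(
            {"flat": np.full(20, 3.0)}, index=sr.tip_labels(study_tree)
        )
        fits = sr.fit_regime(traits, study_tree)
        assert fits.loc["flat", "regime"] == "unclassified"

    def test_too_few_species_rejected(self):
        tree = read_tree("((A:1,B:1):1,C:2);", is_path=False)
        traits = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=list("ABC"))
        with pytest.raises(PhyloModelError):
            sr.fit_regime(traits, tree)


class TestEvolutionaryVariance:
    def test_arithmetic(self):
        row = {"sigma2_ou": 2.0, "alpha": 1.0}
        assert sr.evolutionary_variance(row) == 1.0

    def test_linear_in_sigma2(self):
        a = sr.evolutionary_variance({"sigma2_ou": 1.0, "alpha": 2.0})
        b = sr.evolutionary_variance({"sigma2_ou": 2.0, "alpha": 2.0})
        assert np.isclose(b, 2 * a)

    def test_distribution_comparison(self, study_tree):
        rng = np.random.default_rng(12)
        G = 60
        mk = lambda s2: pd.DataFrame(
            _tip_matrix(study_tree, np.array(["OU"] * G), np.full(G, 6.0),
                        np.full(G, s2), np.full(G, 5.0), rng).T,
            index=sr.tip_labels(study_tree),
            columns=[f"f{i}" for i in range(G)],
        )
        low = sr.fit_regime(mk(1.2), study_tree)
        high = sr.fit_regime(mk(12.0), study_tree)
        res = sr.compare_evolutionary_variance(high, low)
        assert res["median_a"] > res["median_b"]
        assert res["p"] < 1e-6


class TestAncestralStates:
    def test_star_tree_root_is_tip_mean(self):
        tree = read_tree("(A:1,B:1,C:1,D:1);", is_path=False)
        y = pd.Series([1.0, 2.0, 3.0, 6.0], index=list("ABCD"))
        states = sr.ancestral_states(y, tree)
        assert np.isclose(states["estimate"].iloc[0], 3.0)

    def test_two_tip_midpoint(self):
        tree = read_tree("(A:1.5,B:1.5);", is_path=False)
        y = pd.Series([0.0, 4.0], index=["A", "B"])
        states = sr.ancestral_states(y, tree)
        assert np.isclose(states["estimate"].iloc[0], 2.0)

    def test_matches_gls_oracle_on_four_tip_tree(self):
        newick = "((A:0.5,B:0.5):1.5,(C:1.2,D:1.2):0.8);"
        tree = read_tree(newick, is_path=False)
        labels = sr.tip_labels(tree)
        C, D = oracle_matrices(newick, labels)
        y = pd.Series([1.0, 1.4, -0.2, 0.6], index=labels)
        states = sr.ancestral_states(y, tree, sigma2=1.0, root_mean=None)

        # oracle: GLS mean, then conditional expectation from the explicit
        # joint covariance of (node, tips)
        Cinv = np.linalg.inv(C)
        ones = np.ones(len(y))
        mu = (ones @ Cinv @ y.to_numpy()) / (ones @ Cinv @ ones)
        assert np.isclose(states["estimate"].iloc[0], mu, atol=1e-8)
        # the A-B ancestor sits at depth 1.5; its shared path with A and B
        # is 1.5 and with C, D is 0
        c = np.array([1.5, 1.5, 0.0, 0.0])
        cond = mu + c @ Cinv @ (y.to_numpy() - mu)
        ab = states[np.isclose(states["depth"], 1.5) & (states["n_descendants"] == 2)]
        assert np.isclose(ab["estimate"].iloc[0], cond, atol=1e-8)
        var = 1.5 - c @ Cinv @ c
        assert np.isclose(ab["variance"].iloc[0], var, atol=1e-8)
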
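from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import splicerad as sr
from splicerad.differential import DifferentialError


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        q = sr.bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert sr.bh_adjust(np.array([0.2]))[0] == 0.2

    def test_all_ones(self):
        assert (sr.bh_adjust(np.ones(5)) == 1.0).all()

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(5):
            p = rng.uniform(size=50)
            q = sr.bh_adjust(p)
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(q, q_sm)

    def test_nan_rejected(self):
        with pytest.raises(DifferentialError, match="NaN"):
            sr.bh_adjust(np.array([0.1, np.nan]))


class TestOverlapTest:
    def test_identical_sets_closed_form(self):
        a = set(range(5))
        res = sr.overlap_test(a, a, 100)
        assert res["overlap"] == 5
        assert np.isclose(res["p"], 1.0 / comb(100, 5))

    def test_disjoint_exhausting_universe(self):
        res = sr.overlap_test(set(range(2)), {2, 3}, 4)
        assert res["overlap"] == 0 and np.isclose(res["p"], 1.0)

    def test_matches_brute_force_enumeration(self):
        # |a| = 2, |b| = 2, universe = 4: enumerate all C(4,2) draws of b
        universe = [0, 1, 2, 3]
        a = {0, 1}
        res = sr.overlap_test(a, {0, 2}, 4)
        draws = list(combinations(universe, 2))
        frac = np.mean([len(a & set(d)) >= 1 for d in draws])
        assert np.isclose(res["p"], frac)

    def test_oversized_set_rejected(self):
        with pytest.raises(DifferentialError):
            sr.overlap_test(set(range(10)), set(), 5)


class TestDiffPsi:
    def test_two_vs_two_matches_exhaustive_enumeration(self):
        psi, iso2gene, meta = sr.simulate_psi_experiment(
            n_genes=20, n_per_guild=2, seed=5
        )
        iso, _ = sr.diff_psi(psi, meta, "LV", "OJ", iso2gene=iso2gene, seed=0)
        X = psi.loc[iso.index].to_numpy()
        for row, (_, rec) in enumerate(iso.iterrows()):
            vals = X[row]
            obs = abs(np.nanmean(vals[:2]) - np.nanmean(vals[2:]))
            stats_all = []
            for pick in combinations(range(4), 2):
                a = [vals[i] for i in pick]
                b = [vals[i] for i in range(4) if i not in pick]
                stats_all.append(abs(np.nanmean(a) - np.nanmean(b)))
            expected = np.mean([s >= obs - 1e-12 for s in stats_all])
            assert np.isclose(rec["p"], expected)
            assert rec["exact_permutation"]

    def test_guild_label_swap_flips_direction_not_p(self):
        psi, iso2gene, meta = sr.simulate_psi_experiment(
            n_genes=50, delta_psi=0.25, frac_ds=0.5, seed=6
        )
        iso_a, _ = sr.diff_psi(psi, meta, "LV", "OJ", iso2gene=iso2gene, seed=0)
        swapped = meta.copy()
        swapped["guild"] = swapped["guild"].map(
            {"herbivore": "carnivore", "carnivore": "herbivore"}
        )
        iso_b, _ = sr.diff_psi(psi, swapped, "LV", "OJ", iso2gene=iso2gene, seed=0)
        assert np.allclose(iso_a["p"], iso_b["p"])
        assert np.allclose(iso_a["effect"], -iso_b["effect"])

    def test_library_size_invariance(self, small_dataset):
        expr = sr.normalize(small_dataset.counts, "cpm")
        psi = sr.compute_psi(expr, small_dataset.counts.iso2gene)
        scaled = small_dataset.counts.values * np.linspace(
            0.5, 2.0, small_dataset.counts.values.shape[1]
        )
        psi2 = sr.compute_psi(
            sr.normalize(scaled, "cpm"), small_dataset.counts.iso2gene
        )
        a, _ = sr.diff_psi(
            psi, small_dataset.metadata, "LV", "OJ",
            iso2gene=small_dataset.counts.iso2gene, seed=0, n_permutations=200,
        )
        b, _ = sr.diff_psi(
            psi2, small_dataset.metadata, "LV", "OJ",
            iso2gene=small_dataset.counts.iso2gene, seed=0, n_permutations=200,
        )
        assert np.allclose(a["p"], b["p"])

    def test_sidak_gene_aggregation(self):
        psi, iso2gene, meta = sr.simulate_psi_experiment(
            n_genes=30, n_iso=3, seed=7
        )
        iso, gene = sr.diff_psi(psi, meta, "LV", "OJ", iso2gene=iso2gene, seed=0)
        merged = iso.groupby("gene_id")["p"].min()
        k = iso.groupby("gene_id").size()
        expected = 1 - (1 - merged) ** k
        assert np.allclose(gene.loc[expected.index, "p"], expected)

    def test_requires_two_samples_per_guild(self):
        psi, iso2gene, meta = sr.simulate_psi_experiment(
            n_genes=5, n_per_guild=1, seed=8
        )
        with pytest.raises(DifferentialError, match=">= 2"):
            sr.diff_psi(psi, meta, "LV", "OJ", iso2gene=iso2gene)


class TestDiffExpr:
    def test_all_zero_gene_is_flat(self, small_dataset):
        cm = small_dataset.counts
        values = cm.values.copy()
        values.loc["dead_i1"] = 0.0
        iso2gene = pd.concat(
            [cm.iso2gene, pd.Series({"dead_i1": "dead"})]
        )
        aug = sr.CountMatrix(values=values, iso2gene=iso2gene)
        res = sr.diff_expr(aug, small_dataset.metadata, "LV", "OJ")
        assert res.loc["dead", "p"] == 1.0
        assert res.loc["dead", "effect"] == 0.0
        assert res.loc["dead", "flag"] == "zero-variance"

    def test_planted_fold_change_detected(self):
        # two guilds, 5v5, NB counts, log2FC = 2 at mean 100; the planted
        # set is direction-balanced so CPM composition stays comparable
        rng = np.random.default_rng(9)
        n_genes, fc_genes = 1000, 100
        mu = np.full((n_genes, 10), 100.0)
        mu[: fc_genes // 2, :5] *= 4.0  # up in herbivores
        mu[fc_genes // 2 : fc_genes, 5:] *= 4.0  # up in carnivores
        r = 1 / 0.1
        counts = rng.negative_binomial(r, r / (r + mu))
        values = pd.DataFrame(
            counts, index=[f"g{i}_i1" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(10)],
        )
        iso2gene = pd.Series(
            [f"g{i}" for i in range(n_genes)], index=values.index
        )
        meta = pd.DataFrame(
            {
                "sample_id": values.columns,
                "species": ["H"] * 5 + ["C"] * 5,
                "clade": "LV",
                "tissue": "OJ",
                "guild": ["herbivore"] * 5 + ["carnivore"] * 5,
                "replicate": list(range(1, 6)) * 2,
            }
        ).set_index("sample_id", drop=False)
        cm = sr.CountMatrix(values=values, iso2gene=iso2gene)
        res = sr.diff_expr(cm, meta, "LV", "OJ")
        planted_ids = [f"g{i}" for i in range(fc_genes)]
        planted = res.loc[planted_ids]
        null = res.drop(index=planted_ids)
        assert planted["significant"].mean() >= 0.9
        assert (null["p"] < 0.05).mean() <= 0.08
        up = planted.loc[[f"g{i}" for i in range(fc_genes // 2)]]
        assert up["effect"].median() == pytest.approx(2.0, abs=0.4)
        assert (up["direction"] == "higher-in-herbivore").all()

    def test_nb_variant_agrees_on_direction(self, small_dataset):
        res_w = sr.diff_expr(
            small_dataset.counts, small_dataset.metadata, "LV", "OJ"
        )
        res_nb = sr.diff_expr(
            small_dataset.counts, small_dataset.metadata, "LV", "OJ",
            method="nb",
        )
        strong = res_w[res_w["q"] < 0.01].index
        if len(strong):
            agree = (
                res_w.loc[strong, "direction"] == res_nb.loc[strong, "direction"]
            ).mean()
            assert agree >= 0.9


class TestConvergence:
    @staticmethod
    def _result(radiation, genes_dirs):
        return pd.DataFrame(
            {
                "gene_id": list(genes_dirs),
                "radiation": radiation,
                "q": 0.01,
                "direction": list(genes_dirs.values()),
            }
        )

    def test_two_way_but_not_three_way(self):
        results = {
            "LV": self._result("LV", {"g1": "higher-in-herbivore"}),
            "LM": self._result("LM", {"g1": "higher-in-herbivore"}),
            "LT": self._result("LT", {"g2": "higher-in-carnivore"}),
        }
        two = sr.convergence(results, min_radiations=2)
        assert list(two["feature_id"]) == ["g1"]
        three = sr.convergence(results, min_radiations=3)
        assert three.empty

    def test_opposite_directions_not_convergent(self):
        results = {
            "LV": self._result("LV", {"g1": "higher-in-herbivore"}),
            "LM": self._result("LM", {"g1": "higher-in-carnivore"}),
        }
        assert sr.convergence(results, min_radiations=2).empty
        any_dir = sr.convergence(
            results, min_radiations=2, require_same_direction=False
        )
        assert list(any_dir["feature_id"]) == ["g1"]

    def test_planted_convergent_degs_recovered(self, default_dataset):
        ds = default_dataset
        results = {
            r: sr.diff_expr(ds.counts, ds.metadata, r, "OJ")
            for r in ("LV", "LM", "LT")
        }
        conv = sr.convergence(results, min_radiations=3)
        truth = ds.gene_truth
        planted = set(
            truth.loc[
                truth[["de_LV", "de_LM", "de_LT"]].all(axis=1)
                & (truth["de_dir_LV"] == truth["de_dir_LM"])
                & (truth["de_dir_LM"] == truth["de_dir_LT"]),
                "gene_id",
            ]
        )
        assert len(planted) >= 5
        recovered = set(conv["feature_id"]) & planted
        assert len(recovered) >= 0.8 * len(planted)


class TestDegDsgOverlap:
    def test_disjoint_and_identical(self):
        deg = pd.DataFrame({"gene_id": ["g1", "g2"], "q": [0.01, 0.01]})
        dsg_same = deg.copy()
        dsg_disjoint = pd.DataFrame({"gene_id": ["g3"], "q": [0.01]})
        assert sr.deg_dsg_overlap(deg, dsg_same, 100)["overlap"] == 2
        assert sr.deg_dsg_overlap(deg, dsg_disjoint, 100)["overlap"] == 0
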
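from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ribolens as rl
from ribolens.de import annotate_significance, size_factors


class TestSizeFactors:
    def test_hand_computed_median_of_ratios(self, tiny_design, make_count_matrix):
        # geometric means (4, 2); ratios sample1 (0.5, 1) -> 0.75,
        # sample2 (2, 1) -> 1.5
        cm = make_count_matrix([[2, 8], [2, 2]], ["g1", "g2"],
                               ["Nor_mRNA_1", "Nor_mRNA_2"], tiny_design)
        sf = size_factors(cm)
        assert sf.tolist() == pytest.approx([0.75, 1.5])

    def test_identical_columns_equal_factors(self, tiny_design, make_count_matrix):
        cm = make_count_matrix([[5, 5], [9, 9]], ["g1", "g2"],
                               ["Nor_mRNA_1", "Nor_mRNA_2"], tiny_design)
        assert size_factors(cm).tolist() == pytest.approx([1.0, 1.0])

    def test_scaling_equivariance(self, tiny_design, make_count_matrix):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 200, size=(50, 2))
        scaled = base.copy()
        scaled[:, 1] *= 3
        samples = ["Nor_mRNA_1", "Nor_mRNA_2"]
        f0 = size_factors(make_count_matrix(base, [f"g{i}" for i in range(50)],
                                            samples, tiny_design))
        f1 = size_factors(make_count_matrix(scaled, [f"g{i}" for i in range(50)],
                                            samples, tiny_design))
        # factors are defined up to the geometric-mean reference, so the
        # equivariance holds for factor ratios
        ratio0 = f0["Nor_mRNA_2"] / f0["Nor_mRNA_1"]
        ratio1 = f1["Nor_mRNA_2"] / f1["Nor_mRNA_1"]
        assert ratio1 / ratio0 == pytest.approx(3.0)

    def test_matches_deseq2_reference(self, tiny_design, make_count_matrix):
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(1)
        counts = rng.negative_binomial(10, 0.1, size=(200, 4))
        design = rl.SampleDesign.build(["Nor", "AD"], 2, ["mRNA"])
        cm = make_count_matrix(counts, [f"g{i}" for i in range(200)],
                               design.samples("mRNA"), design)
        ours = size_factors(cm).to_numpy()
        theirs = pydeseq2.deseq2_norm(pd.DataFrame(counts.T))[1]
        np.testing.assert_allclose(ours, np.asarray(theirs), rtol=1e-4)

    def test_all_zero_gene_rows_fall_back_to_totals(self, tiny_design,
                                                    make_count_matrix):
        cm = make_count_matrix([[0, 4], [8, 0]], ["g1", "g2"],
                               ["Nor_mRNA_1", "Nor_mRNA_2"], tiny_design)
        sf = size_factors(cm)
        assert (sf > 0).all()
        # total-count fallback: totals 8 and 4 -> factor ratio 2
        assert sf.iloc[0] / sf.iloc[1] == pytest.approx(2.0)


class TestSignificanceRule:
    @pytest.mark.parametrize("p,lfc,expect", [
        (0.04, 0.60, "up"),        # passes both gates
        (0.04, 0.58, "ns"),        # fold change below 0.585
        (0.06, 3.00, "ns"),        # p above 0.05
        (0.04, -0.60, "down"),
    ])
    def test_gate_boundaries(self, p, lfc, expect, cfg):
        res = pd.DataFrame({"base_mean": [10.0], "log2fc": [lfc],
                            "se": [0.1], "p": [p], "q": [p * 2]},
                           index=pd.Index(["g"], name="gene_id"))
        out = annotate_significance(res, cfg)
        assert out["direction"].iloc[0] == expect

    def test_partition_exhaustive_disjoint(self, de_results):
        res = de_results[("mRNA", ("Nor", "AD"))]
        part = rl.classify_significant(res)
        all_genes = part["up"] | part["down"] | part["ns"]
        assert all_genes == set(res.index)
        assert not (part["up"] & part["down"])
        assert not (part["up"] & part["ns"])


class TestVenn:
    def test_categories(self):
        a = {"up": {"g1", "g3"}, "down": {"g2"}, "ns": {"g4"}}
        b = {"up": {"g1", "g2"}, "down": set(), "ns": {"g3", "g4"}}
        v = rl.venn_intersections(a, b)
        assert v["both_up"] == {"g1"}
        assert v["discordant"] == {"g2"}      # down in A, up in B
        assert v["a_only"] == {"g3"}
        assert v["both_down"] == set()

    def test_disjoint_sets_empty_intersections(self):
        a = {"up": {"g1"}, "down": set(), "ns": set()}
        b = {"up": set(), "down": {"g2"}, "ns": set()}
        v = rl.venn_intersections(a, b)
        assert not v["both_up"] and not v["both_down"] and not v["discordant"]


class TestNBTest:
    def test_bh_q_dominates_p_and_is_monotone(self, de_results):
        res = de_results[("mRNA", ("Nor", "AD"))].dropna(subset=["p"])
        assert (res["q"] >= res["p"] - 1e-12).all()
        s = res.sort_values("p")
        assert (np.diff(np.maximum.accumulate(s["q"].to_numpy())) >= -1e-12).all()

    def test_all_zero_gene_reported_ns_with_na(self, tiny_design,
                                               make_count_matrix):
        counts = np.vstack([np.zeros(4, int),
                            np.random.default_rng(0).integers(5, 50, (30, 4))])
        cm = make_count_matrix(counts, [f"g{i}" for i in range(31)],
                               tiny_design.samples("mRNA"), tiny_design)
        res = rl.nb_test(cm, ("Nor", "AD"))
        assert res.loc["g0", "direction"] == "ns"
        assert np.isnan(res.loc["g0", "p"])

    def test_unknown_group_raises(self, bundle, cfg):
        from ribolens.design import DesignError
        with pytest.raises(DesignError):
            rl.nb_test(bundle.matrices["mRNA"], ("Nor", "nope"), cfg)

    def test_wald_p_tracks_permutation_oracle(self):
        """On a small instance the NB Wald p should rank genes like an
        exact permutation test of the normalized group-mean difference."""
        rng = np.random.default_rng(3)
        n_genes, n = 50, 3
        design = rl.SampleDesign.build(["Nor", "AD"], n, ["mRNA"])
        # graded effects small enough that the 20-relabeling permutation p
        # does not saturate at its 1/20 floor (which would tie most ranks)
        lfc = np.linspace(0, 1.2, n_genes) * np.where(
            np.arange(n_genes) % 2 == 0, 1, -1)
        mu = 200.0
        m = np.empty((n_genes, 2 * n))
        m[:, :n] = mu
        m[:, n:] = mu * np.exp2(lfc)[:, None]
        r = 1 / 0.1
        counts = rng.negative_binomial(r, r / (r + m))
        cm = pd.DataFrame(counts, index=pd.Index(
            [f"g{i}" for i in range(n_genes)], name="gene_id"),
            columns=design.samples("mRNA"))
        cmx = rl.CountMatrix(cm, design, "mRNA")
        res = rl.nb_test(cmx, ("Nor", "AD"))

        # oracle: exact permutation of the log-scale normalized mean
        # difference over all 20 group relabelings
        norm = np.log2((cmx.counts / size_factors(cmx)).to_numpy() + 0.5)
        obs = np.abs(norm[:, n:].mean(1) - norm[:, :n].mean(1))
        perm_p = np.zeros(n_genes)
        idx = list(range(2 * n))
        splits = [set(c) for c in combinations(idx, n)]
        for g in range(n_genes):
            diffs = [abs(norm[g, [i for i in idx if i not in s]].mean()
                         - norm[g, list(s)].mean()) for s in splits]
            perm_p[g] = np.mean([d >= obs[g] - 1e-12 for d in diffs])
        rho = stats.spearmanr(res["p"], perm_p).statistic
        assert rho >= 0.8

    def test_power_not_decreasing_in_effect_size(self):
        """Average detection rate over a 3-point fold-change grid."""
        rng_seed = 5
        powers = []
        for lfc in (0.8, 1.5, 2.5):
            rng = np.random.default_rng(rng_seed)
            n_genes, n = 300, 3
            design = rl.SampleDesign.build(["Nor", "AD"], n, ["mRNA"])
            m = np.full((n_genes, 2 * n), 300.0)
            m[:, n:] *= 2 ** lfc
            r = 1 / 0.1
            counts = rng.negative_binomial(r, r / (r + m))
            cm = rl.CountMatrix(
                pd.DataFrame(counts, index=pd.Index(
                    [f"g{i}" for i in range(n_genes)], name="gene_id"),
                    columns=design.samples("mRNA")), design, "mRNA")
            res = rl.nb_test(cm, ("Nor", "AD"))
            powers.append(res["significant"].mean())
        assert powers[0] <= powers[1] + 0.02 <= powers[2] + 0.04

    def test_planted_lfc_recovery(self, bundle, de_results):
        """Planted |log2FC|=2 estimates land within +-0.5 at the rate NB
        sampling variance permits (sd ~0.37 log2 at 3 reps, alpha 0.1)."""
        res = de_results[("mRNA", ("Nor", "AD"))]
        truth = bundle.truth["de"]["mRNA"]["Nor_vs_AD"]
        est = res.loc[list(truth), "log2fc"]
        err = np.abs(est - pd.Series(truth))
        assert (err < 0.5).mean() >= 0.75
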
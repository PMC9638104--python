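import itertools

import numpy as np
import pandas as pd
import pytest

import ribolens as rl
from ribolens.te import QCError, BOTH_LEVEL_CATEGORIES, joint_category


def de_frame(rows):
    """Minimal DE table from (gene, log2fc, se, p, direction) tuples."""
    idx = [r[0] for r in rows]
    df = pd.DataFrame({
        "base_mean": 100.0,
        "log2fc": [r[1] for r in rows],
        "se": [r[2] for r in rows],
        "p": [r[3] for r in rows],
        "q": [r[3] for r in rows],
        "significant": [r[4] != "ns" for r in rows],
        "direction": [r[4] for r in rows],
    }, index=pd.Index(idx, name="gene_id"))
    return df


class TestRpfQC:
    def test_single_length(self):
        reads = pd.DataFrame({"length": [30] * 10, "region": ["CDS"] * 10})
        qc = rl.rpf_qc(reads)
        assert qc["modal_length"] == 30
        assert len(qc["length_histogram"]) == 1

    def test_constructed_region_fractions(self):
        reads = pd.DataFrame({
            "length": [28] * 100,
            "region": ["CDS"] * 50 + ["UTR5"] * 30 + ["UTR3"] * 20})
        qc = rl.rpf_qc(reads)
        f = qc["region_fractions"]
        assert (f["CDS"], f["UTR5"], f["UTR3"]) == (0.5, 0.3, 0.2)
        assert sum(f.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_table_rejected(self):
        with pytest.raises(QCError):
            rl.rpf_qc(pd.DataFrame({"length": [], "region": []}))


class TestLevelCorrelation:
    def test_identical_layers_give_r_one(self, bundle, cfg):
        rna = bundle.matrices["mRNA"]
        copy = rl.CountMatrix(
            rna.counts.rename(columns=dict(zip(
                rna.samples, bundle.matrices["RPF"].samples))),
            bundle.design, "RPF")
        r = rl.level_correlation(rna, copy, "Nor", cfg)
        assert r["pearson_r"] == pytest.approx(1.0)

    def test_independent_layers_near_zero(self, bundle, cfg):
        # break the gene pairing by shuffling the footprint gene labels
        rpf = bundle.matrices["RPF"]
        rng = np.random.default_rng(0)
        shuffled = rpf.counts.copy()
        shuffled.index = pd.Index(
            rng.permutation(shuffled.index.to_numpy()), name="gene_id")
        ind = rl.CountMatrix(shuffled, bundle.design, "RPF")
        r = rl.level_correlation(bundle.matrices["mRNA"], ind, "Nor", cfg)
        assert abs(r["pearson_r"]) < 0.1

    def test_proportional_layers_recover_latent_correlation(self, bundle, cfg):
        # implied gene-level correlation from the baseline spreads:
        # r = sd_b / sqrt(sd_b^2 + sd_jitter^2)
        c = bundle.config
        expected = c.baseline_log2_sd / np.hypot(c.baseline_log2_sd,
                                                 c.te_baseline_log2_sd)
        r = rl.level_correlation(bundle.matrices["mRNA"],
                                 bundle.matrices["RPF"], "Nor", cfg)
        assert r["pearson_r"] == pytest.approx(expected, abs=0.05)


class TestDTE:
    def test_equal_fold_changes_give_null_delta(self, cfg):
        rna = de_frame([("g", 1.0, 0.3, 0.01, "up")])
        rpf = de_frame([("g", 1.0, 0.4, 0.01, "up")])
        te = rl.dte_test(rna, rpf, cfg)
        assert te.loc["g", "log2_te_fc"] == 0.0
        assert te.loc["g", "p"] == pytest.approx(1.0)

    def test_se_propagation_three_four_five(self, cfg):
        rna = de_frame([("g", 0.0, 0.3, 0.5, "ns")])
        rpf = de_frame([("g", 1.0, 0.4, 0.01, "up")])
        te = rl.dte_test(rna, rpf, cfg)
        assert te.loc["g", "se"] == pytest.approx(0.5)

    def test_missing_gene_gets_na(self, cfg):
        rna = de_frame([("g1", 1.0, 0.3, 0.01, "up")])
        rpf = de_frame([("g2", 1.0, 0.3, 0.01, "up")])
        te = rl.dte_test(rna, rpf, cfg)
        assert np.isnan(te.loc["g1", "p"]) and np.isnan(te.loc["g2", "p"])

    def test_rpf_doubling_shifts_te_fold_change_by_one(self, cfg):
        rna = de_frame([("g", 0.4, 0.3, 0.2, "ns")])
        rpf1 = de_frame([("g", 0.9, 0.3, 0.05, "ns")])
        rpf2 = de_frame([("g", 1.9, 0.3, 0.01, "up")])  # doubled RPF counts
        d1 = rl.dte_test(rna, rpf1, cfg).loc["g", "log2_te_fc"]
        d2 = rl.dte_test(rna, rpf2, cfg).loc["g", "log2_te_fc"]
        assert d2 - d1 == pytest.approx(1.0)


class TestQuadrants:
    def test_category_mapping_exhaustive(self):
        cats = {joint_category(a, b)
                for a, b in itertools.product(("up", "down", "ns"), repeat=2)}
        assert cats == set(rl.te.QUADRANT_CATEGORIES) if hasattr(rl, "te") \
            else len(cats) == 9
        assert joint_category("up", "up") == "homodirectional_up"
        assert joint_category("down", "up") == "opposite_rna_down"
        assert joint_category("ns", "ns") == "unchanged"
        assert joint_category("ns", "down") == "ribo_only_down"

    def test_layer_swap_symmetry(self, de_results):
        rna = de_results[("mRNA", ("Nor", "AD"))]
        rpf = de_results[("RPF", ("Nor", "AD"))]
        j1 = rl.quadrant_classify(rna, rpf)
        j2 = rl.quadrant_classify(rpf, rna)
        for a, b in (("opposite_rna_up", "opposite_rna_down"),
                     ("homodirectional_up", "homodirectional_up"),
                     ("homodirectional_down", "homodirectional_down")):
            s1 = set(j1.index[j1["category"] == a])
            s2 = set(j2.index[j2["category"] == b])
            assert s1 == s2

    def test_both_level_total_sums_four_categories(self, de_results):
        joint = rl.quadrant_classify(de_results[("mRNA", ("Nor", "AD"))],
                                     de_results[("RPF", ("Nor", "AD"))])
        counts = rl.quadrant_counts(joint)
        assert counts["both_levels_total"] == sum(
            counts[c] for c in BOTH_LEVEL_CATEGORIES)


class TestOppositeScreen:
    def test_inclusion_rules(self, cfg):
        te = de_frame([("a", 1.0, 0.1, 0.001, "up"),
                       ("b", 1.0, 0.1, 0.001, "up"),
                       ("c", 1.0, 0.1, 0.5, "ns")]).rename(
            columns={"log2fc": "log2_te_fc"})
        rna = de_frame([("a", -1.0, 0.1, 0.001, "down"),   # opposite -> in
                        ("b", 1.0, 0.1, 0.001, "up"),      # same sign -> out
                        ("c", -1.0, 0.1, 0.001, "down")])  # te ns -> out
        assert rl.te_vs_transcription_opposite(te, rna) == {"a"}
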
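from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ribolens as rl


def brute_force_shared_p(m_a, m_b, s, M):
    """Enumerate all C(M, m_b) draws of RNA b's miRNA set and count how
    often the overlap with a fixed m_a-set reaches s."""
    a_set = set(range(m_a))
    hits = total = 0
    for draw in combinations(range(M), m_b):
        total += 1
        hits += len(a_set & set(draw)) >= s
    return hits / total


class TestHypergeomSharedMirna:
    def test_zero_shared_is_certain(self):
        assert rl.hypergeom_shared_mirna(3, 4, 0, 10) == 1.0

    def test_forced_overlap(self):
        assert rl.hypergeom_shared_mirna(10, 5, 5, 10) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_spot(self):
        p = rl.hypergeom_shared_mirna(4, 5, 3, 10)
        assert p == pytest.approx(brute_force_shared_p(4, 5, 3, 10), abs=1e-12)

    @pytest.mark.parametrize("M", [2, 5, 8, 12])
    def test_matches_enumeration_oracle_all_small_instances(self, M):
        for m_a in range(M + 1):
            for m_b in range(M + 1):
                for s in range(min(m_a, m_b) + 1):
                    p = rl.hypergeom_shared_mirna(m_a, m_b, s, M)
                    assert p == pytest.approx(
                        brute_force_shared_p(m_a, m_b, s, M), abs=1e-12)

    @given(st.integers(1, 40), st.integers(1, 40), st.integers(0, 40),
           st.integers(1, 100))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_and_monotonicity(self, m_a, m_b, s, M):
        m_a, m_b = min(m_a, M), min(m_b, M)
        s = min(s, m_a, m_b)
        p = rl.hypergeom_shared_mirna(m_a, m_b, s, M)
        assert p == pytest.approx(
            rl.hypergeom_shared_mirna(m_b, m_a, s, M), abs=1e-12)
        if s > 0:
            assert p <= rl.hypergeom_shared_mirna(m_a, m_b, s - 1, M) + 1e-12

    def test_invalid_s_rejected(self):
        with pytest.raises(ValueError):
            rl.hypergeom_shared_mirna(2, 3, 4, 10)


def expr_matrices(bundle):
    return {l: bundle.matrices[l] for l in ("mRNA", "lncRNA", "circRNA")}


class TestSpearmanFilter:
    def test_antimonotone_pair_retained_noise_dropped(self, cfg):
        """A perfectly anti-monotone miRNA-target pair passes the filter;
        an independent pair does not; monotone transforms don't matter."""
        design = rl.SampleDesign.build(["AD", "AD_HFD"], 3,
                                       ["miRNA", "mRNA"])
        # constant anchor rows keep the size factors at 1 so the
        # constructed ranks survive normalization
        anchors = np.full((20, 6), 100)
        mi = pd.DataFrame(np.vstack([[[60, 50, 40, 30, 20, 10],
                                      [31, 17, 55, 12, 41, 29]], anchors]),
                          index=pd.Index(["mi_anti", "mi_noise"]
                                         + [f"am{i}" for i in range(20)],
                                         name="gene_id"),
                          columns=design.samples("miRNA"))
        tg = pd.DataFrame(np.vstack([[[10, 20, 30, 40, 50, 60],
                                      [20, 50, 10, 40, 60, 30]], anchors]),
                          index=pd.Index(["t1", "t2"]
                                         + [f"at{i}" for i in range(20)],
                                         name="gene_id"),
                          columns=design.samples("mRNA"))
        targets = pd.DataFrame({
            "mirna_id": ["mi_anti", "mi_noise"],
            "target_id": ["t1", "t2"],
            "target_layer": ["mRNA", "mRNA"]})
        mi_cm = rl.CountMatrix(mi, design, "miRNA")
        tg_cm = rl.CountMatrix(tg, design, "mRNA")
        ret = rl.filter_mirna_target_corr(targets, mi_cm, {"mRNA": tg_cm},
                                          ("AD", "AD_HFD"), cfg)
        assert set(ret["mirna_id"]) == {"mi_anti"}
        # monotone transform of the target leaves the rank filter unchanged
        tg2 = rl.CountMatrix((tg ** 2).astype(int), design, "mRNA")
        ret2 = rl.filter_mirna_target_corr(targets, mi_cm, {"mRNA": tg2},
                                           ("AD", "AD_HFD"), cfg)
        assert set(ret2["mirna_id"]) == {"mi_anti"}


class TestNetwork:
    def test_no_shared_mirna_never_joined(self, cfg):
        retained = pd.DataFrame({
            "mirna_id": ["m1", "m2"], "target_id": ["a", "b"],
            "target_layer": ["mRNA", "mRNA"], "spearman_rho": [-0.9, -0.9]})
        b = rl.simulate(rl.SimulationConfig(seed=1))
        edges, graph = rl.build_cerna_network(
            {"mRNA": {"a", "b"}}, retained, expr_matrices(b),
            ("AD", "AD_HFD"), cfg)
        assert len(edges) == 0
        assert graph.number_of_edges() == 0

    def test_edge_table_symmetric_in_pair_order(self, bundle, cfg,
                                                de_results):
        c = ("AD", "AD_HFD")
        dif = {}
        for layer in ("mRNA", "lncRNA", "circRNA", "miRNA"):
            p = rl.classify_significant(de_results[(layer, c)])
            dif[layer] = p["up"] | p["down"]
        ret = rl.filter_mirna_target_corr(
            bundle.targets, bundle.matrices["miRNA"],
            expr_matrices(bundle), c, cfg)
        edges, _ = rl.build_cerna_network(dif, ret, expr_matrices(bundle),
                                          c, cfg)
        for r in edges.itertuples():
            assert r.rna_a < r.rna_b          # canonical unordered pair
            assert 0 <= r.shared <= min(r.m_a, r.m_b) <= r.M

    def test_planted_triplets_recovered(self, bundle, cfg, de_results):
        c = ("AD", "AD_HFD")
        dif = {}
        for layer in ("mRNA", "lncRNA", "circRNA", "miRNA"):
            p = rl.classify_significant(de_results[(layer, c)])
            dif[layer] = p["up"] | p["down"]
        ret = rl.filter_mirna_target_corr(
            bundle.targets, bundle.matrices["miRNA"],
            expr_matrices(bundle), c, cfg)
        edges, graph = rl.build_cerna_network(dif, ret,
                                              expr_matrices(bundle), c, cfg)
        tri = {tuple(sorted((t["rna_a"], t["rna_b"])))
               for t in bundle.truth["cerna_triplets"]}
        got = {tuple(sorted(e)) for e in graph.edges}
        assert len(tri & got) / len(tri) >= 0.8
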
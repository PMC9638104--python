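"""Parameter-recovery benchmarks against the simulator's planted truth.

Each function simulates under stated conditions, runs the corresponding
pipeline stage from scratch, and scores recovery. These power the
acceptance checks and give users a calibrated view of what the pipeline
can and cannot detect at the default study design (3 replicates, NB
dispersion 0.1, the P < 0.05 & |log2FC| >= 0.585 screening rule).
"""

from __future__ import annotations

import numpy as np

from .cerna import build_cerna_network, filter_mirna_target_corr
from .config import PipelineConfig, SimulationConfig
from .de import classify_significant, nb_test
from .simulate import simulate
from .te import dte_test, te_vs_transcription_opposite
from .trends import profile_significance


def _adjacent_contrasts(groups):
    return [(groups[i], groups[i + 1]) for i in range(len(groups) - 1)]


def null_sim_config(seed: int, **kw) -> SimulationConfig:
    return SimulationConfig(seed=seed, n_de=0, n_te_shift=0,
                            n_trend_genes=0, n_cerna_triplets=0, **kw)


def measure_type_i_error(seeds=(1, 2, 3)) -> float:
    """Fraction of null genes with p < 0.05, averaged over seeds."""
    rates = []
    for seed in seeds:
        b = simulate(null_sim_config(seed))
        res = nb_test(b.matrices["mRNA"], tuple(b.config.groups[:2]),
                      PipelineConfig(seed=seed))
        p = res["p"].dropna()
        rates.append(float((p < 0.05).mean()))
    return float(np.mean(rates))


def measure_de_power(seed: int = 1) -> float:
    """Recall of planted DE genes (|log2FC|=2) under the screening rule,
    averaged over the three adjacent contrasts."""
    b = simulate(SimulationConfig(seed=seed))
    cfg = PipelineConfig(seed=seed)
    recs = []
    for c in _adjacent_contrasts(list(b.config.groups)):
        cname = f"{c[0]}_vs_{c[1]}"
        truth = set(b.truth["de"]["mRNA"][cname])
        res = nb_test(b.matrices["mRNA"], c, cfg)
        sig = set(res.index[res["significant"]])
        recs.append(len(truth & sig) / len(truth))
    return float(np.mean(recs))


def measure_te_recall(seeds=(1, 2)) -> dict:
    """Recall of planted TE shifts (|delta|=1.5) and of the buffered
    subset (mRNA and TE moving in opposite directions)."""
    te_recs, buf_recs = [], []
    for seed in seeds:
        b = simulate(SimulationConfig(seed=seed))
        cfg = PipelineConfig(seed=seed)
        for c in _adjacent_contrasts(list(b.config.groups)):
            cname = f"{c[0]}_vs_{c[1]}"
            rna = nb_test(b.matrices["mRNA"], c, cfg)
            rpf = nb_test(b.matrices["RPF"], c, cfg)
            te = dte_test(rna, rpf, cfg)
            truth = set(b.truth["te"][cname])
            sig = set(te.index[te["significant"]])
            te_recs.append(len(truth & sig) / len(truth))
            buffered = set(b.truth["buffered"][cname])
            opp = te_vs_transcription_opposite(te, rna)
            buf_recs.append(len(buffered & opp) / len(buffered))
    return {"te_recall": float(np.mean(te_recs)),
            "buffered_recall": float(np.mean(buf_recs))}


def _cerna_run(b, cfg):
    # match the truth's contrast name against the config's group pairs
    # (group names may themselves contain underscores)
    contrasts = _adjacent_contrasts(list(b.config.groups))
    c = next(cc for cc in contrasts
             if f"{cc[0]}_vs_{cc[1]}" == b.truth["cerna_contrast"])
    dif = {}
    for layer in ("mRNA", "lncRNA", "circRNA", "miRNA"):
        part = classify_significant(nb_test(b.matrices[layer], c, cfg))
        dif[layer] = part["up"] | part["down"]
    rna_cms = {l: b.matrices[l] for l in ("mRNA", "lncRNA", "circRNA")}
    retained = filter_mirna_target_corr(
        b.targets, b.matrices["miRNA"], rna_cms, c, cfg)
    edges, graph = build_cerna_network(dif, retained, rna_cms, c, cfg)
    return edges, graph, retained, dif


def measure_cerna_recall(seeds=range(1, 11)) -> float:
    """Mean recovered fraction of planted triplet edges."""
    recs = []
    for seed in seeds:
        b = simulate(SimulationConfig(seed=seed))
        edges, graph, _, _ = _cerna_run(b, PipelineConfig(seed=seed))
        tri = {tuple(sorted((t["rna_a"], t["rna_b"])))
               for t in b.truth["cerna_triplets"]}
        got = {tuple(sorted(e)) for e in graph.edges}
        recs.append(len(tri & got) / len(tri))
    return float(np.mean(recs))


def measure_cerna_null_pass_rate(seeds=(1, 2, 3, 4, 5)) -> dict:
    """Fraction of null RNA pairs passing the hypergeometric gate.

    With no planted triplets, the shared-miRNA structure among decoy
    edges is random: across all pairs of differential RNAs in the
    retained table, P(p_hyper < 0.05) should respect the 0.05 level
    (pairs sharing no miRNA count with p = 1).
    """
    passing = total = 0
    for seed in seeds:
        b = simulate(null_sim_config(seed, n_decoy_targets=800))
        edges, _, retained, dif = _cerna_run(b, PipelineConfig(seed=seed))
        dif_all = set().union(*(dif[l] for l in ("mRNA", "lncRNA", "circRNA")))
        in_table = set(retained["target_id"]) & dif_all
        n = len(in_table)
        total += n * (n - 1) // 2
        if len(edges):
            passing += int((edges["p_hyper"] < 0.05).sum())
    rate = passing / total if total else 0.0
    mc_se = np.sqrt(0.05 * 0.95 / total) if total else 0.0
    return {"rate": float(rate), "n_pairs": int(total),
            "bound": float(0.05 + 2 * mc_se)}


def measure_trend_planted_p(seed: int = 2, B: int = 1000) -> dict:
    """Permutation p of the planted trend templates when only trend genes
    are planted (the differential universe is then trend-dominated)."""
    b = simulate(SimulationConfig(seed=seed, n_de=0, n_te_shift=0,
                                  n_cerna_triplets=0))
    cfg = PipelineConfig(seed=seed, permutations=B)
    groups = list(b.config.groups)[:3]
    universe = set()
    for c in _adjacent_contrasts(groups):
        part = classify_significant(nb_test(b.matrices["mRNA"], c, cfg))
        universe |= part["up"] | part["down"]
    prof = profile_significance(b.matrices["mRNA"], sorted(universe),
                                groups, cfg, B=B)
    by_shape = prof.set_index("shape")["p"]
    return {shape: float(by_shape[shape])
            for shape in ("down-up", "up-down")}
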
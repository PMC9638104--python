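"""miRNA-mediated competing-endogenous-RNA network inference.

Pipeline: (1) keep miRNA-target pairs whose expression is anti-correlated
(Spearman rho <= spearman_max, default -0.5) across the contrast's samples;
(2) for every unordered pair of differential non-miRNA RNAs sharing at
least min_shared retained miRNAs, test the shared-miRNA count s against a
hypergeometric null — with M the miRNA universe, m_a and m_b the numbers
of miRNAs targeting each RNA, p = P(X >= s), X ~ Hypergeom(M, m_a, m_b);
(3) require positive co-expression (Pearson r > pearson_min, default 0.7);
(4) assemble passing pairs into a typed network.
"""

from __future__ import annotations

import logging
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .de import size_factors
from .io import CountMatrix

log = logging.getLogger(__name__)


class PairingError(ValueError):
    pass


def hypergeom_shared_mirna(m_a: int, m_b: int, s: int, M: int) -> float:
    """P(X >= s) for the number of miRNAs shared by two RNAs.

    X ~ Hypergeometric(population M, successes m_a, draws m_b); symmetric
    in (m_a, m_b).
    """
    if not (0 <= m_a <= M and 0 <= m_b <= M):
        raise ValueError(f"need 0 <= m_a, m_b <= M; got {m_a}, {m_b}, M={M}")
    if s < 0 or s > min(m_a, m_b):
        raise ValueError(f"s={s} outside [0, min(m_a, m_b)={min(m_a, m_b)}]")
    if s == 0:
        return 1.0
    return float(stats.hypergeom.sf(s - 1, M, m_a, m_b))


def _log2_norm(cm: CountMatrix, samples: list[str]) -> pd.DataFrame:
    norm = (cm.counts / size_factors(cm))[samples]
    return np.log2(norm + 1.0)


def _contrast_samples(cm: CountMatrix, contrast: tuple[str, str]) -> list[str]:
    return cm.group_samples(contrast[0]) + cm.group_samples(contrast[1])


def filter_mirna_target_corr(targets: pd.DataFrame, mirna_cm: CountMatrix,
                             rna_cms: dict[str, CountMatrix],
                             contrast: tuple[str, str],
                             cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Retain miRNA-target pairs with Spearman rho <= spearman_max.

    Correlations are computed on normalized abundances over the contrast's
    matched samples (replicate i of each group pairs across layers).
    """
    cfg = cfg or PipelineConfig()
    mi_samples = _contrast_samples(mirna_cm, contrast)
    if len(mi_samples) < 6:
        raise PairingError(
            f"need >= 6 samples in the contrast, got {len(mi_samples)}")
    mi_expr = _log2_norm(mirna_cm, mi_samples)

    layer_expr = {}
    for layer, cm in rna_cms.items():
        cols = _contrast_samples(cm, contrast)
        if len(cols) != len(mi_samples):
            raise PairingError(
                f"layer {layer!r} has {len(cols)} contrast samples, "
                f"miRNA layer has {len(mi_samples)}; cannot match replicates")
        layer_expr[layer] = _log2_norm(cm, cols)

    rows = []
    for _, row in targets.iterrows():
        layer = row["target_layer"]
        if layer not in layer_expr:
            continue
        expr = layer_expr[layer]
        if row["mirna_id"] not in mi_expr.index or row["target_id"] not in expr.index:
            continue
        x = mi_expr.loc[row["mirna_id"]].to_numpy()
        y = expr.loc[row["target_id"]].to_numpy()
        rho = stats.spearmanr(x, y).statistic
        if np.isnan(rho):
            continue
        if rho <= cfg.spearman_max:
            rows.append({**row, "spearman_rho": float(rho)})
    return pd.DataFrame(
        rows, columns=[*targets.columns, "spearman_rho"])


def build_cerna_network(dif_sets: dict[str, set], retained: pd.DataFrame,
                        cms: dict[str, CountMatrix],
                        contrast: tuple[str, str],
                        cfg: PipelineConfig | None = None,
                        ) -> tuple[pd.DataFrame, nx.Graph]:
    """Score all candidate ceRNA pairs and assemble the passing network.

    dif_sets: layer -> differential gene ids (from the same contrast);
    retained: the Spearman-filtered target table; cms must include every
    target layer. Returns the scored edge table (one row per candidate
    pair, passed True/False) and the graph of passing edges with nodes
    typed by layer and shared miRNAs attached to edges.
    """
    cfg = cfg or PipelineConfig()
    mirna_of: dict[str, set] = {}
    layer_of: dict[str, str] = {}
    dif_all = {g for layer, s in dif_sets.items() if layer != "miRNA" for g in s}
    for _, row in retained.iterrows():
        t = row["target_id"]
        if t not in dif_all:
            continue
        mirna_of.setdefault(t, set()).add(row["mirna_id"])
        layer_of[t] = row["target_layer"]
    M = retained["mirna_id"].nunique()

    expr = {}
    for layer, cm in cms.items():
        if layer == "miRNA":
            continue
        expr[layer] = _log2_norm(cm, _contrast_samples(cm, contrast))

    rows = []
    graph = nx.Graph()
    for a, b in combinations(sorted(mirna_of), 2):
        shared = mirna_of[a] & mirna_of[b]
        s = len(shared)
        if s < cfg.min_shared_mirnas:
            continue
        m_a, m_b = len(mirna_of[a]), len(mirna_of[b])
        p = hypergeom_shared_mirna(m_a, m_b, s, M)
        xa = expr[layer_of[a]].loc[a].to_numpy()
        xb = expr[layer_of[b]].loc[b].to_numpy()
        if np.std(xa) < 1e-12 or np.std(xb) < 1e-12:
            r = np.nan
        else:
            r = float(stats.pearsonr(xa, xb).statistic)
        passed = bool(p < cfg.cerna_p and np.isfinite(r) and r > cfg.pearson_min)
        rows.append({
            "rna_a": a, "rna_b": b, "layer_a": layer_of[a],
            "layer_b": layer_of[b], "shared": s, "m_a": m_a, "m_b": m_b,
            "M": M, "p_hyper": p, "pearson_r": r, "passed": passed,
            "shared_mirnas": ",".join(sorted(shared)),
        })
        if passed:
            graph.add_node(a, layer=layer_of[a])
            graph.add_node(b, layer=layer_of[b])
            graph.add_edge(a, b, shared=s, p_hyper=p, pearson_r=r,
                           shared_mirnas=",".join(sorted(shared)))

    edges = pd.DataFrame(rows, columns=[
        "rna_a", "rna_b", "layer_a", "layer_b", "shared", "m_a", "m_b", "M",
        "p_hyper", "pearson_r", "passed", "shared_mirnas"])
    if len(edges):
        edges["q_hyper"] = multipletests(edges["p_hyper"], method="fdr_bh")[1]
    else:
        log.warning("no candidate ceRNA pairs for contrast %s", contrast)
        edges["q_hyper"] = pd.Series(dtype=float)
    return edges, graph


def bipartite_table(retained: pd.DataFrame, edges: pd.DataFrame) -> pd.DataFrame:
    """miRNA-RNA incidence restricted to RNAs in passing ceRNA pairs."""
    in_net = set(edges.loc[edges["passed"], "rna_a"]) | set(
        edges.loc[edges["passed"], "rna_b"])
    sub = retained[retained["target_id"].isin(in_net)]
    return sub[["mirna_id", "target_id", "target_layer"]].reset_index(drop=True)
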
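"""Gene-set enrichment: hypergeometric over-representation (ORA) and a
permutation GSEA with the weighted running-sum statistic.

GSEA notes: the enrichment score ES is the signed extremum of the running
sum that increments |score|^w / N_R at set members and decrements
1/(n - m) elsewhere. The null permutes gene labels (with only three
replicates per condition a phenotype permutation would have too few
distinct relabelings to be useful). NES = ES / mean |null ES| of the same
sign; the nominal p and FDR come from the sign-matched null.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig, stage_seed

log = logging.getLogger(__name__)


def filter_collection(collection: dict[str, tuple[str, list[str]]],
                      universe: set,
                      min_size: int = 5, max_size: int = 500,
                      ) -> dict[str, tuple[str, list[str]]]:
    """Intersect sets with the universe and apply size bounds."""
    out = {}
    for sid, (desc, members) in collection.items():
        kept = sorted(set(members) & universe)
        if min_size <= len(kept) <= max_size:
            out[sid] = (desc, kept)
        else:
            log.info("gene set %s excluded (size %d after universe "
                     "intersection)", sid, len(kept))
    return out


def ora_single(hit_set: set, gene_set: set, universe: set) -> tuple[int, float]:
    """Overlap count and upper-tail hypergeometric p for one gene set."""
    if not universe:
        raise ValueError("empty universe")
    if not hit_set <= universe or not gene_set <= universe:
        raise ValueError("hit_set and gene_set must be subsets of the universe")
    k = len(hit_set & gene_set)
    if k == 0:
        return 0, 1.0
    p = stats.hypergeom.sf(k - 1, len(universe), len(gene_set), len(hit_set))
    return k, float(p)


def ora(hit_set: set, collection: dict[str, tuple[str, list[str]]],
        universe: set, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Over-representation of a hit set across a gene-set collection."""
    cfg = cfg or PipelineConfig()
    kept = filter_collection(collection, universe,
                             cfg.min_set_size, cfg.max_set_size)
    hit = hit_set & universe
    rows = []
    for sid, (desc, members) in kept.items():
        k, p = ora_single(hit, set(members), universe)
        rows.append({"set_id": sid, "description": desc,
                     "set_size": len(members), "n_hits": len(hit),
                     "overlap": k, "p": p})
    res = pd.DataFrame(rows, columns=[
        "set_id", "description", "set_size", "n_hits", "overlap", "p"])
    res["q"] = multipletests(res["p"], method="fdr_bh")[1] if len(res) else \
        pd.Series(dtype=float)
    return res.sort_values("p", kind="stable").reset_index(drop=True)


def enrichment_score(ranked_genes: np.ndarray, scores: np.ndarray,
                     member_mask: np.ndarray, weight: float) -> float:
    """Signed extremum of the weighted KS-like running sum."""
    n = len(ranked_genes)
    m = int(member_mask.sum())
    if m == 0 or m == n:
        return 0.0
    w = np.abs(scores) ** weight
    hit = np.where(member_mask, w, 0.0)
    denom = hit.sum()
    if denom <= 0:           # all member scores zero at weight > 0
        hit = member_mask.astype(float)
        denom = float(m)
    steps = hit / denom - (~member_mask) / float(n - m)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea(ranking: pd.Series, collection: dict[str, tuple[str, list[str]]],
         cfg: PipelineConfig | None = None,
         B: int | None = None, seed: int | None = None) -> pd.DataFrame:
    """Permutation GSEA of a gene ranking against a gene-set collection.

    ranking: gene -> metric (finite, unique gene ids); sorted descending
    with a stable (metric, gene id) tie-break. Returns es, nes, p, q per
    surviving set.
    """
    cfg = cfg or PipelineConfig()
    B = B or cfg.permutations
    if ranking.index.duplicated().any():
        raise ValueError("duplicate gene ids in ranking")
    if not np.isfinite(ranking).all():
        raise ValueError("ranking metric must be finite")
    order = sorted(ranking.items(), key=lambda kv: (-kv[1], kv[0]))
    genes = np.array([g for g, _ in order])
    scores = np.array([v for _, v in order], dtype=float)
    universe = set(genes)
    kept = filter_collection(collection, universe,
                             cfg.min_set_size, cfg.max_set_size)

    rng = np.random.default_rng(
        stage_seed(cfg.seed if seed is None else seed, "gsea"))
    pos = {g: i for i, g in enumerate(genes)}
    rows = []
    for sid, (desc, members) in kept.items():
        mask = np.zeros(len(genes), dtype=bool)
        mask[[pos[g] for g in members]] = True
        es = enrichment_score(genes, scores, mask, cfg.gsea_weight)
        m = mask.sum()
        null = np.empty(B)
        for b in range(B):
            perm = np.zeros(len(genes), dtype=bool)
            perm[rng.choice(len(genes), size=m, replace=False)] = True
            null[b] = enrichment_score(genes, scores, perm, cfg.gsea_weight)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same_sign) == 0:
            nes, p = np.nan, 1.0 / (B + 1.0)
        else:
            nes = es / np.mean(np.abs(same_sign))
            p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (len(same_sign) + 1.0)
        rows.append({"set_id": sid, "description": desc, "set_size": int(m),
                     "es": es, "nes": nes, "p": p})
    res = pd.DataFrame(rows, columns=[
        "set_id", "description", "set_size", "es", "nes", "p"])
    res["q"] = multipletests(res["p"], method="fdr_bh")[1] if len(res) else \
        pd.Series(dtype=float)
    return res.sort_values("p", kind="stable").reset_index(drop=True)


def ranking_from_de(de: pd.DataFrame, metric: str = "signed_logp") -> pd.Series:
    """Default GSEA ranking metric: sign(log2fc) * -log10(p)."""
    tested = de.dropna(subset=["p", "log2fc"])
    if metric == "log2fc":
        return tested["log2fc"]
    p = np.clip(tested["p"].to_numpy(), 1e-300, 1.0)
    return pd.Series(np.sign(tested["log2fc"]) * -np.log10(p),
                     index=tested.index)
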
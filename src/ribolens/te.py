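"""Ribo-seq QC, translation efficiency, and joint transcriptome-translatome
classification.

Translation efficiency (TE) of a gene is its normalized ribosome-footprint
abundance divided by its normalized mRNA abundance; between two groups the
TE fold change is the difference of the two layers' log2 fold changes,

    delta log2 TE = log2FC(RPF) - log2FC(mRNA),

tested with a two-sided z-test after propagating the two Wald standard
errors (se_delta^2 = se_RPF^2 + se_mRNA^2). Joint quadrant classification
crosses the per-layer up/down/ns calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .de import annotate_significance, size_factors
from .io import CountMatrix

RPF_REGIONS = ("CDS", "UTR5", "UTR3", "other")

QUADRANT_CATEGORIES = (
    "homodirectional_up", "homodirectional_down",
    "opposite_rna_up", "opposite_rna_down",
    "rna_only_up", "rna_only_down",
    "ribo_only_up", "ribo_only_down",
    "unchanged",
)

BOTH_LEVEL_CATEGORIES = (
    "homodirectional_up", "homodirectional_down",
    "opposite_rna_up", "opposite_rna_down",
)


class QCError(ValueError):
    pass


def rpf_qc(reads: pd.DataFrame) -> dict:
    """QC summary of an RPF read-feature table (columns: length, region).

    Returns modal length, a length histogram, and per-region fractions
    (which sum to 1).
    """
    if len(reads) == 0:
        raise QCError("empty RPF read table")
    lengths = reads["length"].astype(int)
    hist = lengths.value_counts().sort_index()
    modal = int(hist.idxmax())
    frac = (reads["region"].value_counts() / len(reads))
    fractions = {r: float(frac.get(r, 0.0)) for r in RPF_REGIONS}
    return {
        "modal_length": modal,
        "length_histogram": hist,
        "region_fractions": fractions,
        "n_reads": int(len(reads)),
    }


def level_correlation(rna: CountMatrix, rpf: CountMatrix, group: str,
                      cfg: PipelineConfig | None = None) -> dict:
    """Pearson R between mRNA and footprint abundance within one group.

    Computed across genes detected (base_mean >= min_base_mean) in both
    layers, on log2(mean normalized abundance + 1).
    """
    cfg = cfg or PipelineConfig()
    shared = rna.counts.index.intersection(rpf.counts.index)
    a = (rna.counts / size_factors(rna))[rna.group_samples(group)].loc[shared]
    b = (rpf.counts / size_factors(rpf))[rpf.group_samples(group)].loc[shared]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    keep = (ma >= cfg.min_base_mean) & (mb >= cfg.min_base_mean)
    if keep.sum() < 10:
        raise QCError(f"only {int(keep.sum())} genes detected in both layers")
    x = np.log2(ma[keep] + 1.0)
    y = np.log2(mb[keep] + 1.0)
    r, _p = stats.pearsonr(x, y)
    return {"group": group, "pearson_r": float(r), "n_genes": int(keep.sum())}


def dte_test(de_rna: pd.DataFrame, de_rpf: pd.DataFrame,
             cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Differential-TE test from matched per-layer DE results.

    Genes missing from either layer (or untested there) carry NA
    statistics. Significance uses the same screening rule as DE applied
    to delta log2 TE.
    """
    cfg = cfg or PipelineConfig()
    genes = de_rna.index.union(de_rpf.index)
    rna = de_rna.reindex(genes)
    rpf = de_rpf.reindex(genes)
    delta = rpf["log2fc"] - rna["log2fc"]
    se = np.sqrt(rpf["se"] ** 2 + rna["se"] ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = delta / se
    p = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=genes)
    p[~np.isfinite(z)] = np.nan
    q = pd.Series(np.nan, index=genes)
    ok = p.notna()
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    res = pd.DataFrame({
        "base_mean": np.minimum(rna["base_mean"], rpf["base_mean"]),
        "log2fc": delta, "se": se, "p": p, "q": q,
    }, index=genes)
    res.index.name = "gene_id"
    res = annotate_significance(res, cfg)
    return res.rename(columns={"log2fc": "log2_te_fc"})


def joint_category(rna_call: str, ribo_call: str) -> str:
    """Quadrant category from the two per-layer calls (pure function)."""
    if rna_call == "ns" and ribo_call == "ns":
        return "unchanged"
    if rna_call == "ns":
        return f"ribo_only_{ribo_call}"
    if ribo_call == "ns":
        return f"rna_only_{rna_call}"
    if rna_call == ribo_call:
        return f"homodirectional_{rna_call}"
    return f"opposite_rna_{rna_call}"


def quadrant_classify(de_rna: pd.DataFrame, de_rpf: pd.DataFrame) -> pd.DataFrame:
    """Cross the transcriptome and translatome calls per gene.

    Genes changed at both levels are the four both-significant categories
    (homodirectional up/down, opposite with RNA up/down).
    """
    genes = de_rna.index.union(de_rpf.index)
    rna_call = de_rna["direction"].reindex(genes).fillna("ns")
    ribo_call = de_rpf["direction"].reindex(genes).fillna("ns")
    cat = [joint_category(a, b) for a, b in zip(rna_call, ribo_call)]
    out = pd.DataFrame({
        "rna_call": rna_call, "ribo_call": ribo_call, "category": cat,
    }, index=genes)
    out.index.name = "gene_id"
    return out


def quadrant_counts(joint: pd.DataFrame) -> pd.Series:
    counts = joint["category"].value_counts()
    counts = counts.reindex(QUADRANT_CATEGORIES, fill_value=0)
    counts.loc["both_levels_total"] = sum(
        counts[c] for c in BOTH_LEVEL_CATEGORIES)
    return counts.astype(int)


def te_vs_transcription_opposite(te: pd.DataFrame, de_rna: pd.DataFrame) -> set:
    """Genes significant in both the TE and transcription screens whose
    TE change opposes the mRNA change (buffered / offset regulation)."""
    genes = te.index.intersection(de_rna.index)
    t = te.loc[genes]
    r = de_rna.loc[genes]
    opp = (t["significant"] & r["significant"]
           & (np.sign(t["log2_te_fc"]) != np.sign(r["log2fc"])))
    return set(genes[opp])
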
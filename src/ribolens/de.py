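"""Normalization and two-group negative-binomial differential expression.

The same machinery is applied to every omics layer (mRNA, RPF, miRNA,
lncRNA, circRNA). Normalization is median-of-ratios; testing is a per-gene
NB Wald test with a method-of-moments dispersion estimate shrunk toward a
lowess mean-dispersion trend. Significance follows the screening rule
P < p_threshold and |log2FC| >= lfc_threshold; BH-adjusted q-values are
reported alongside (and can optionally be the gate).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .design import DesignError
from .io import CountMatrix

log = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-4
LFC_PRIOR_COUNT = 0.5


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (sample_id -> positive scale).

    Each sample's factor is the median, over genes expressed in every
    sample, of its count divided by the gene's geometric mean. Falls back
    to total-count scaling (normalized to geometric mean 1) when no gene
    is positive everywhere.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        log.warning("no gene positive in all samples of layer %s; "
                    "falling back to total-count scaling", cm.layer)
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total counts")
        factors = totals / np.exp(np.mean(np.log(totals)))
    else:
        pos = counts[all_pos]
        log_geo = np.mean(np.log(pos), axis=1, keepdims=True)
        factors = np.median(np.exp(np.log(pos) - log_geo), axis=0)
    return pd.Series(factors, index=cm.samples, name="size_factor")


def normalized_counts(cm: CountMatrix) -> pd.DataFrame:
    return cm.counts / size_factors(cm)


def _dispersion_trend(base_mean: np.ndarray, raw_disp: np.ndarray) -> np.ndarray:
    """Lowess fit of raw dispersion vs log mean, evaluated at every gene."""
    ok = np.isfinite(raw_disp) & (raw_disp > 0) & (base_mean > 0)
    if ok.sum() < 10:
        # too few informative genes: flat trend at the (floored) median
        level = max(float(np.median(raw_disp[ok])) if ok.any() else 0.0,
                    DISPERSION_FLOOR)
        return np.full_like(base_mean, level)
    x = np.log(base_mean[ok])
    fit = lowess(raw_disp[ok], x, frac=0.5, it=2, return_sorted=True)
    xs, ys = fit[:, 0], np.maximum(fit[:, 1], DISPERSION_FLOOR)
    return np.interp(np.log(np.maximum(base_mean, 1e-8)), xs, ys)


def estimate_dispersions(norm: pd.DataFrame, groups: list[list[str]],
                         inv_sf: pd.Series) -> pd.DataFrame:
    """Per-gene NB dispersion: MoM estimate shrunk 50% toward the trend.

    For normalized counts, Var ~ mu * mean(1/s_j) + alpha * mu^2 within a
    group; alpha is solved from pooled within-group moments. Arithmetic
    shrinkage (not geometric) because the n=3 MoM estimate is frequently
    <= 0 and must not collapse the average.
    """
    mats = [norm[g].to_numpy() for g in groups]
    ns = np.array([m.shape[1] for m in mats], dtype=float)
    means = [m.mean(axis=1) for m in mats]
    vars_ = [m.var(axis=1, ddof=1) for m in mats]
    # mean of 1/size_factor per group (Poisson part of normalized variance)
    cs = [float(np.mean(inv_sf[g].to_numpy())) for g in groups]
    num = np.zeros(len(norm))
    den = np.zeros(len(norm))
    for m, v, c, n in zip(means, vars_, cs, ns):
        w = n - 1
        num += w * (v - m * c)
        den += w * m ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / den, np.nan)
    base_mean = norm.to_numpy().mean(axis=1)
    trend = _dispersion_trend(base_mean, raw)
    shrunk = 0.5 * np.clip(np.nan_to_num(raw, nan=0.0), 0.0, None) + 0.5 * trend
    shrunk = np.maximum(shrunk, DISPERSION_FLOOR)
    return pd.DataFrame(
        {"raw": raw, "trend": trend, "dispersion": shrunk}, index=norm.index)


def nb_test(cm: CountMatrix, contrast: tuple[str, str],
            cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Wald test of log2(group2 / group1) per gene.

    Returns a frame indexed by gene with columns base_mean, log2fc, se,
    p, q, significant, direction. Genes failing the independent low-count
    filter (base_mean < cfg.min_base_mean) get NA statistics and 'ns'.
    """
    cfg = cfg or PipelineConfig()
    g1, g2 = contrast
    for g in (g1, g2):
        if g not in cm.design.groups:
            raise DesignError(f"group {g!r} absent from design")
    cm.design.require_replicates(cm.layer, [g1, g2], n_min=2)
    s1, s2 = cm.group_samples(g1), cm.group_samples(g2)

    sf = size_factors(cm)
    norm = cm.counts[s1 + s2] / sf[s1 + s2]
    inv_sf = 1.0 / sf
    base_mean = norm.mean(axis=1).to_numpy()
    tested = base_mean >= cfg.min_base_mean

    mu1 = norm[s1].mean(axis=1).to_numpy()
    mu2 = norm[s2].mean(axis=1).to_numpy()
    log2fc = np.log2(mu2 + LFC_PRIOR_COUNT) - np.log2(mu1 + LFC_PRIOR_COUNT)

    disp = estimate_dispersions(norm, [s1, s2], inv_sf)["dispersion"].to_numpy()

    # delta-method SE of log2 fc from NB variance of each group mean
    c1 = float(np.mean(inv_sf[s1])); c2 = float(np.mean(inv_sf[s2]))
    n1, n2 = len(s1), len(s2)
    var_m1 = (mu1 * c1 + disp * mu1 ** 2) / n1
    var_m2 = (mu2 * c2 + disp * mu2 ** 2) / n2
    ln2sq = np.log(2.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var_m1 / (mu1 + LFC_PRIOR_COUNT) ** 2
                     + var_m2 / (mu2 + LFC_PRIOR_COUNT) ** 2) / np.log(2.0)
    se = np.where(se > 0, se, np.nan)

    # t reference: residual df (n1+n2-2) doubled because the equal-weight
    # dispersion shrinkage contributes prior df equal to the residual df
    # (moderated-statistic logic); a plain normal reference is
    # anticonservative at 3 replicates per group.
    dof = 2 * (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    p = 2.0 * stats.t.sf(np.abs(z), dof)
    p = np.where(tested & np.isfinite(p), p, np.nan)

    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]

    res = pd.DataFrame({
        "base_mean": base_mean,
        "log2fc": np.where(tested, log2fc, np.nan),
        "se": np.where(tested, se, np.nan),
        "df": float(dof),
        "p": p,
        "q": q,
    }, index=norm.index)
    res.index.name = "gene_id"
    return annotate_significance(res, cfg)


def annotate_significance(res: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Apply the screening rule and direction labels to a DE table."""
    gate = res["q"] if cfg.gate_on_q else res["p"]
    sig = (gate < cfg.p_threshold) & (res["log2fc"].abs() >= cfg.lfc_threshold)
    sig = sig.fillna(False)
    res = res.copy()
    res["significant"] = sig
    res["direction"] = np.where(
        ~sig, "ns", np.where(res["log2fc"] > 0, "up", "down"))
    return res


def classify_significant(res: pd.DataFrame) -> dict[str, set]:
    """Exhaustive disjoint partition of genes into {up, down, ns}."""
    idx = res.index
    return {
        "up": set(idx[res["direction"] == "up"]),
        "down": set(idx[res["direction"] == "down"]),
        "ns": set(idx[res["direction"] == "ns"]),
    }


def venn_intersections(part_a: dict[str, set], part_b: dict[str, set]) -> dict[str, set]:
    """Overlap of two DE partitions over the same gene universe.

    Categories: both_up, both_down, discordant (significant in both with
    opposite directions, e.g. a gene reduced in one contrast but increased
    in the other), a_only, b_only.
    """
    sig_a = part_a["up"] | part_a["down"]
    sig_b = part_b["up"] | part_b["down"]
    out = {
        "both_up": part_a["up"] & part_b["up"],
        "both_down": part_a["down"] & part_b["down"],
        "discordant": (part_a["up"] & part_b["down"]) | (part_a["down"] & part_b["up"]),
        "a_only": sig_a - sig_b,
        "b_only": sig_b - sig_a,
    }
    return out
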
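"""STEM-style trend profiling over ordered conditions.

Every step-direction template over k ordered groups (each of the k-1 steps
down/flat/up, the all-flat template excluded) defines a profile; there are
3^(k-1) - 1 of them. Each differential gene's centered log2 group-mean
vector is assigned to the template with maximal Pearson correlation, and
per-profile member counts are tested against a null built by permuting
sample-to-group labels.

Profile ids are dense, ordered by the base-3 encoding of (step+1) digits.
The historical tool-specific numbering of profiles varies; the V-shaped
"callback" template (down then up) and its mirror are best referred to by
their shape tags in the output.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig, stage_seed
from .de import size_factors
from .io import CountMatrix

_STEP_NAME = {-1: "down", 0: "flat", 1: "up"}


class SignificanceError(ValueError):
    pass


def shape_tag(steps: tuple[int, ...]) -> str:
    return "-".join(_STEP_NAME[s] for s in steps)


def _template(steps: tuple[int, ...]) -> np.ndarray:
    v = np.concatenate([[0.0], np.cumsum(steps, dtype=float)])
    return v - v.mean()


def enumerate_profiles(k: int) -> pd.DataFrame:
    """All non-flat step-direction templates over k ordered conditions.

    Returns a frame with profile_id (dense, base-3 order), steps tuple,
    shape tag and centered template vector; exactly 3^(k-1) - 1 rows.
    """
    if k < 2:
        raise ValueError(f"need >= 2 ordered conditions, got k={k}")
    rows = []
    pid = 0
    for steps in itertools.product((-1, 0, 1), repeat=k - 1):
        if all(s == 0 for s in steps):
            continue
        rows.append({
            "profile_id": pid,
            "steps": steps,
            "shape": shape_tag(steps),
            "template": _template(steps),
        })
        pid += 1
    return pd.DataFrame(rows)


def _group_mean_matrix(cm: CountMatrix, genes: list[str],
                       groups: list[str],
                       sample_groups: pd.Series | None = None) -> np.ndarray:
    """genes x groups matrix of log2(mean normalized abundance + 1)."""
    norm = cm.counts / size_factors(cm)
    if sample_groups is None:
        cols = {g: cm.group_samples(g) for g in groups}
    else:
        cols = {g: [s for s in cm.samples if sample_groups[s] == g]
                for g in groups}
    out = np.empty((len(genes), len(groups)))
    sub = norm.loc[genes]
    for j, g in enumerate(groups):
        out[:, j] = np.log2(sub[cols[g]].mean(axis=1).to_numpy() + 1.0)
    return out


def _assign(expr: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Row-wise best-correlated template; -1 for zero-variance rows.

    Ties break to the lowest profile_id (templates are in id order).
    """
    x = expr - expr.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(x, axis=1)
    t = templates - templates.mean(axis=1, keepdims=True)
    tn = np.linalg.norm(t, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (x @ t.T) / np.outer(xn, tn)
    best = np.full(len(expr), -1, dtype=int)
    ok = xn > 1e-12
    if ok.any():
        c = corr[ok]
        mx = c.max(axis=1, keepdims=True)
        best[ok] = np.argmax(c >= mx - 1e-12, axis=1)
    return best


def assign_profiles(cm: CountMatrix, gene_universe, groups: list[str],
                    sample_groups: pd.Series | None = None) -> pd.DataFrame:
    """Assign each universe gene to its best-matching trend template.

    Genes absent from the matrix are skipped; genes with zero variance
    across the ordered group means stay unassigned (profile_id -1).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 ordered groups")
    universe = [g for g in gene_universe if g in cm.counts.index]
    if not universe:
        raise ValueError("empty gene universe after matching the matrix")
    profiles = enumerate_profiles(len(groups))
    templates = np.vstack(profiles["template"].to_numpy())
    expr = _group_mean_matrix(cm, universe, groups, sample_groups)
    best = _assign(expr, templates)
    shape = profiles["shape"].to_numpy()
    return pd.DataFrame({
        "profile_id": best,
        "shape": ["unassigned" if b < 0 else shape[b] for b in best],
    }, index=pd.Index(universe, name="gene_id"))


def profile_significance(cm: CountMatrix, gene_universe, groups: list[str],
                         cfg: PipelineConfig | None = None,
                         B: int | None = None,
                         seed: int | None = None) -> pd.DataFrame:
    """Permutation test of per-profile membership counts.

    The null permutes each gene's sample->group labels independently
    (STEM-style: genes are treated as exchangeable units, so the null
    count of a profile is the number of genes landing on it when their
    condition structure is destroyed), re-assigns the whole universe B
    times, and sets p = (1 + #{perm count >= observed}) / (B + 1),
    BH-adjusted across profiles.
    """
    cfg = cfg or PipelineConfig()
    B = B or cfg.permutations
    if B < 100:
        raise ValueError("need >= 100 permutations")
    samples = [s for g in groups for s in cm.group_samples(g)]
    counts_per_group = [len(cm.group_samples(g)) for g in groups]
    n_distinct = math.factorial(sum(counts_per_group))
    for c in counts_per_group:
        n_distinct //= math.factorial(c)
    if n_distinct < 10:
        raise SignificanceError(
            f"only {n_distinct} distinct group relabelings; "
            "too few samples to permute")

    profiles = enumerate_profiles(len(groups))
    templates = np.vstack(profiles["template"].to_numpy())
    universe = [g for g in gene_universe if g in cm.counts.index]
    labels = np.array([g for g, c in zip(groups, counts_per_group)
                       for _ in range(c)])

    norm = (cm.counts / size_factors(cm)).loc[universe, samples].to_numpy()
    log_norm = np.log2(norm + 1.0)
    group_cols = [np.flatnonzero(labels == g) for g in groups]

    def counts_for(mat: np.ndarray) -> np.ndarray:
        expr = np.column_stack([mat[:, cols].mean(axis=1)
                                for cols in group_cols])
        best = _assign(expr, templates)
        return np.bincount(best[best >= 0], minlength=len(templates))

    observed = counts_for(log_norm)
    rng = np.random.default_rng(
        stage_seed(cfg.seed if seed is None else seed, "trend_permutation"))
    exceed = np.zeros(len(templates), dtype=int)
    null_sum = np.zeros(len(templates), dtype=float)
    for _ in range(B):
        c = counts_for(rng.permuted(log_norm, axis=1))
        exceed += c >= observed
        null_sum += c
    p = (1.0 + exceed) / (B + 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    out = profiles.drop(columns=["template"]).copy()
    out["steps"] = out["steps"].map(lambda s: ",".join(map(str, s)))
    out["n_members"] = observed
    out["expected_count"] = null_sum / B
    out["p"] = p
    out["q"] = q
    return out
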
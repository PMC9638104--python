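"""Planted-truth multi-omics simulator.

Generates negative-binomial count matrices for five layers (mRNA, ribosome
footprints, miRNA, lncRNA, circRNA) over four ordered groups x 3
replicates, with known ground truth planted for every downstream stage:

* DE genes with signed log2 fold changes per adjacent-group contrast
  (effects persist in later groups so each contrast's planting stays out
  of the other contrasts' null);
* TE-shift genes where footprints change relative to mRNA — half of them
  "buffered" (mRNA up while TE moves the opposite way);
* trend genes following the V-shaped (down-up, "callback") and mirrored
  templates across the first three groups;
* ceRNA triplets: a miRNA anti-correlated with two positively co-expressed
  target RNAs that share its response elements, driven by a shared
  per-sample log-normal latent factor with the sign flipped for the miRNA;
* an RPF read-feature table with a modal length of 28 nt and ~88% CDS
  occupancy;
* a gene annotation (GTF) placing lncRNAs cis / antisense / distal to
  coding genes, a miRNA target table with decoy edges, and gene sets (GMT)
  including one set enriched in planted DE genes.

Library sizes are jittered uniformly in [0.7, 1.3] x nominal so size-factor
recovery is non-trivial. Everything is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig, stage_seed
from .design import SampleDesign
from .io import CountMatrix, GenomicFeature

CODING_LAYERS = ("mRNA", "RPF")
TARGET_LAYERS = ("mRNA", "lncRNA", "circRNA")
TREND_SHAPES = ("down-up", "up-down")   # callback V and its mirror

_PREFIX = {"mRNA": "gene", "lncRNA": "lnc", "circRNA": "circ", "miRNA": "mir"}


@dataclass
class SimulationBundle:
    config: SimulationConfig
    design: SampleDesign
    matrices: dict[str, CountMatrix]
    truth: dict
    features: list[GenomicFeature]
    targets: pd.DataFrame
    genesets: dict[str, tuple[str, list[str]]]
    rpf_reads: pd.DataFrame = field(default=None)


class _GenePool:
    """Hands out not-yet-planted gene indices per layer."""

    def __init__(self, n_genes: dict[str, int]):
        self.free = {layer: list(range(n)) for layer, n in n_genes.items()}

    def take(self, layer: str, n: int, rng: np.random.Generator,
             eligible: np.ndarray | None = None) -> list[int]:
        free = self.free[layer]
        if eligible is not None:
            free = [g for g in free if eligible[g]]
        if n > len(free):
            raise ValueError(
                f"planted gene budget exceeds n_genes for layer {layer!r} "
                f"(requested {n}, {len(free)} unplanted left)")
        idx = rng.choice(len(free), size=n, replace=False)
        picked = [free[i] for i in sorted(idx)]
        self.free[layer] = [g for g in self.free[layer] if g not in set(picked)]
        return picked


def _gene_ids(layer: str, n: int) -> list[str]:
    return [f"{_PREFIX[layer]}{i:04d}" for i in range(n)]


def _signs(n: int) -> np.ndarray:
    return np.where(np.arange(n) % 2 == 0, 1.0, -1.0)


def contrast_name(g1: str, g2: str) -> str:
    return f"{g1}_vs_{g2}"


def simulate(cfg: SimulationConfig | None = None) -> SimulationBundle:
    """Full synthetic bundle: counts, truth, annotation, targets, gene sets."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(stage_seed(cfg.seed, "simulate"))
    groups = list(cfg.groups)
    k = len(groups)
    reps = cfg.reps
    n_samples = k * reps
    sample_group = np.repeat(np.arange(k), reps)   # group index per column

    layers = list(cfg.n_genes)                      # mRNA, lncRNA, circRNA, miRNA
    ids = {layer: _gene_ids(layer, n) for layer, n in cfg.n_genes.items()}
    pool = _GenePool(cfg.n_genes)

    # --- baselines -------------------------------------------------------
    base = {}
    for layer in layers:
        rel = np.exp2(rng.normal(0.0, cfg.baseline_log2_sd, cfg.n_genes[layer]))
        base[layer] = rel / rel.sum()
    # footprints mirror mRNA baselines up to a per-gene TE jitter
    te_jitter = rng.normal(0.0, cfg.te_baseline_log2_sd, cfg.n_genes["mRNA"])
    rpf_rel = base["mRNA"] * np.exp2(te_jitter)
    base["RPF"] = rpf_rel / rpf_rel.sum()

    # --- planted effects as per-group log2 multipliers -------------------
    log2mult = {layer: np.zeros((cfg.n_genes[layer], k))
                for layer in layers}
    log2mult["RPF"] = np.zeros((cfg.n_genes["mRNA"], k))

    contrasts = [(groups[i], groups[i + 1]) for i in range(k - 1)]
    cnames = [contrast_name(*c) for c in contrasts]
    truth: dict = {
        "contrasts": cnames,
        "de": {layer: {c: {} for c in cnames} for layer in layers},
        "te": {c: {} for c in cnames},
        "buffered": {c: [] for c in cnames},
        "trends": {},
        "cerna_triplets": [],
    }

    def plant(layer: str, gene: int, start_group: int, lfc: float):
        log2mult[layer][gene, start_group:] += lfc

    # DE genes, scaled per layer size for the small layers
    n_de_layer = {
        layer: (cfg.n_de if layer == "mRNA" else
                max(2, round(cfg.n_de * cfg.n_genes[layer] / cfg.n_genes["mRNA"])))
        for layer in layers}
    for ci, (cname, (_g1, _g2)) in enumerate(zip(cnames, contrasts)):
        for layer in layers:
            n = n_de_layer[layer] if cfg.n_de > 0 else 0
            if n == 0:
                continue
            genes = pool.take(layer, n, rng)
            lfcs = _signs(n) * cfg.de_lfc
            for g, lfc in zip(genes, lfcs):
                plant(layer, g, ci + 1, lfc)
                if layer == "mRNA":      # transcriptional change carries to RPF
                    plant("RPF", g, ci + 1, lfc)
                truth["de"][layer][cname][ids[layer][g]] = float(lfc)

    # TE shifts: first half pure (mRNA flat), second half buffered
    for ci, cname in enumerate(cnames):
        n = cfg.n_te_shift
        if n == 0:
            continue
        genes = pool.take("mRNA", n, rng)
        deltas = _signs(n) * cfg.te_lfc
        half = n // 2
        for j, (g, d) in enumerate(zip(genes, deltas)):
            gid = ids["mRNA"][g]
            if j < half or n == 1:      # pure TE shift
                plant("RPF", g, ci + 1, d)
            else:                        # buffered: RNA moves, TE opposes it
                rna_lfc = -np.sign(d) * cfg.de_lfc
                plant("mRNA", g, ci + 1, rna_lfc)
                plant("RPF", g, ci + 1, rna_lfc + d)
                truth["de"]["mRNA"][cname][gid] = float(rna_lfc)
                truth["buffered"][cname].append(gid)
            truth["te"][cname][gid] = float(d)

    # trend genes over the first three ordered groups
    if cfg.n_trend_genes > 0 and k >= 3:
        shape_steps = {"down-up": (-1, 1), "up-down": (1, -1)}
        for shape in TREND_SHAPES:
            genes = pool.take("mRNA", cfg.n_trend_genes, rng)
            s1, s2 = shape_steps[shape]
            path = [0.0, s1 * cfg.trend_lfc, (s1 + s2) * cfg.trend_lfc]
            for g in genes:
                for gi in range(1, k):   # later groups hold the last level
                    log2mult["mRNA"][g, gi] += path[min(gi, 2)]
                    log2mult["RPF"][g, gi] += path[min(gi, 2)]
                truth["trends"][ids["mRNA"][g]] = shape

    # ceRNA triplets on the middle contrast (AD vs AD_HFD in the default
    # design): targets up, miRNA down, plus a shared per-sample latent
    # factor with the miRNA sign flipped
    latent_adjust = {layer: np.zeros((cfg.n_genes[layer], n_samples))
                     for layer in layers}
    cerna_ci = min(1, k - 2)
    cerna_cname = cnames[cerna_ci]
    pair_layers = [("mRNA", "mRNA"), ("mRNA", "lncRNA"),
                   ("mRNA", "circRNA"), ("lncRNA", "circRNA")]
    # triplet members need enough counts for the planted latent correlation
    # to be expressible above Poisson noise
    expressed = {layer: base[layer] * cfg.library_size[layer] >= 50
                 for layer in layers}
    target_rows = []
    for t in range(cfg.n_cerna_triplets):
        la, lb = pair_layers[t % len(pair_layers)]
        mi = pool.take("miRNA", 1, rng, expressed["miRNA"])[0]
        ga = pool.take(la, 1, rng, expressed[la])[0]
        gb = pool.take(lb, 1, rng, expressed[lb])[0]
        u = rng.normal(0.0, cfg.cerna_latent_log2_sd, n_samples)
        latent_adjust[la][ga] += u
        latent_adjust[lb][gb] += u
        latent_adjust["miRNA"][mi] -= u
        plant(la, ga, cerna_ci + 1, cfg.de_lfc)
        plant(lb, gb, cerna_ci + 1, cfg.de_lfc)
        plant("miRNA", mi, cerna_ci + 1, -cfg.de_lfc)
        if la == "mRNA":
            plant("RPF", ga, cerna_ci + 1, cfg.de_lfc)
        if lb == "mRNA":
            plant("RPF", gb, cerna_ci + 1, cfg.de_lfc)
        mid, aid, bid = ids["miRNA"][mi], ids[la][ga], ids[lb][gb]
        truth["de"][la][cerna_cname][aid] = float(cfg.de_lfc)
        truth["de"][lb][cerna_cname][bid] = float(cfg.de_lfc)
        truth["de"]["miRNA"][cerna_cname][mid] = float(-cfg.de_lfc)
        mre = f"mre{t:03d}"
        truth["cerna_triplets"].append({
            "mirna": mid, "rna_a": aid, "layer_a": la,
            "rna_b": bid, "layer_b": lb, "mre": [mre]})
        target_rows.append((mid, aid, la))
        target_rows.append((mid, bid, lb))
    truth["cerna_contrast"] = cerna_cname

    # decoy miRNA->target edges
    seen = set(target_rows)
    all_mirnas = ids["miRNA"]
    while len(target_rows) - 2 * cfg.n_cerna_triplets < cfg.n_decoy_targets:
        mi = all_mirnas[rng.integers(len(all_mirnas))]
        layer = TARGET_LAYERS[rng.integers(len(TARGET_LAYERS))]
        tg = ids[layer][rng.integers(cfg.n_genes[layer])]
        row = (mi, tg, layer)
        if row not in seen:
            seen.add(row)
            target_rows.append(row)
    targets = pd.DataFrame(target_rows,
                           columns=["mirna_id", "target_id", "target_layer"])

    # --- draw the counts --------------------------------------------------
    all_layers = layers + ["RPF"]
    design = SampleDesign.build(groups, reps, all_layers)
    lib_factors = {layer: rng.uniform(0.7, 1.3, n_samples)
                   for layer in all_layers}
    matrices = {}
    r = 1.0 / cfg.nb_dispersion
    for layer in all_layers:
        src = "mRNA" if layer == "RPF" else layer
        lib = cfg.library_size[layer]
        # footprints inherit the mRNA latent factors (they track mRNA means)
        latent = latent_adjust[src]
        mult = np.exp2(log2mult[layer][:, sample_group] + latent)
        mu = base[layer][:, None] * mult * lib * lib_factors[layer][None, :]
        mu = np.maximum(mu, 1e-8)
        counts = rng.negative_binomial(r, r / (r + mu))
        samples = design.samples(layer)
        df = pd.DataFrame(counts, index=pd.Index(ids[src], name="gene_id"),
                          columns=samples)
        matrices[layer] = CountMatrix(df, design, layer)

    features = _build_features(cfg, ids, truth)
    genesets = _build_genesets(cfg, ids, truth, rng)
    reads = simulate_rpf_reads(cfg, seed=stage_seed(cfg.seed, "rpf_reads"))

    return SimulationBundle(config=cfg, design=design, matrices=matrices,
                            truth=truth, features=features, targets=targets,
                            genesets=genesets, rpf_reads=reads)


def simulate_counts(cfg: SimulationConfig | None = None,
                    ) -> tuple[dict[str, CountMatrix], dict]:
    """(per-layer CountMatrix, planted truth) — see :func:`simulate`."""
    bundle = simulate(cfg)
    return bundle.matrices, bundle.truth


# ---------------------------------------------------------------------------
# RPF read-feature table
# ---------------------------------------------------------------------------

def rpf_region_probs(cds_fraction: float) -> dict[str, float]:
    """Region mix emulating observed footprint occupancy: CDS dominates,
    each UTR stays below 3%, the remainder is other (non-CDS) signal."""
    utr = min(0.025, (1.0 - cds_fraction) / 2.0)
    other = max(0.0, 1.0 - cds_fraction - 2 * utr)
    return {"CDS": cds_fraction, "UTR5": utr, "UTR3": utr, "other": other}


def simulate_rpf_reads(cfg: SimulationConfig | None = None,
                       n_reads: int = 100_000,
                       seed: int | None = None) -> pd.DataFrame:
    """Read length / region table: lengths from a discretized Gaussian on
    [20, 40] nt with mode at ``rpf_modal_length``; regions multinomial."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(
        stage_seed(cfg.seed, "rpf_reads") if seed is None else seed)
    lengths = np.arange(20, 41)
    w = np.exp(-0.5 * ((lengths - cfg.rpf_modal_length) / 1.5) ** 2)
    lens = rng.choice(lengths, size=n_reads, p=w / w.sum())
    probs = rpf_region_probs(cfg.rpf_cds_fraction)
    regions = rng.choice(list(probs), size=n_reads, p=list(probs.values()))
    return pd.DataFrame({"length": lens, "region": regions})


# ---------------------------------------------------------------------------
# annotations: GTF features, gene sets
# ---------------------------------------------------------------------------

_GENE_SPACING = 200_000
_GENE_LEN = 20_000


def _build_features(cfg: SimulationConfig, ids: dict,
                    truth: dict) -> list[GenomicFeature]:
    """Coding genes tiled on chr1; lncRNAs placed cis (50 kb away),
    antisense (opposite-strand overlap), or distal (chr2) in rotation."""
    feats = []
    for i, gid in enumerate(ids["mRNA"]):
        start = i * _GENE_SPACING
        feats.append(GenomicFeature(gid, "chr1", start, start + _GENE_LEN,
                                    "+", "protein_coding"))
    truth["lnc_pairs"] = {"cis": [], "antisense": []}
    for j, lid in enumerate(ids["lncRNA"]):
        partner_idx = j % len(ids["mRNA"])
        pstart = partner_idx * _GENE_SPACING
        mode = j % 3
        if mode == 0:      # cis, 50 kb downstream of its partner
            feats.append(GenomicFeature(
                lid, "chr1", pstart + _GENE_LEN + 50_000,
                pstart + _GENE_LEN + 52_000, "+", "lncRNA"))
            truth["lnc_pairs"]["cis"].append([lid, ids["mRNA"][partner_idx]])
        elif mode == 1:    # antisense, inside the partner on the other strand
            feats.append(GenomicFeature(
                lid, "chr1", pstart + 5_000, pstart + 8_000, "-", "lncRNA"))
            truth["lnc_pairs"]["antisense"].append(
                [lid, ids["mRNA"][partner_idx]])
        else:              # distal, no coding gene on chr2
            feats.append(GenomicFeature(
                lid, "chr2", j * _GENE_SPACING, j * _GENE_SPACING + 2_000,
                "+", "lncRNA"))
    for j, cid in enumerate(ids["circRNA"]):
        feats.append(GenomicFeature(
            cid, "chr3", j * _GENE_SPACING, j * _GENE_SPACING + 1_000,
            "+", "circRNA"))
    for j, mid in enumerate(ids["miRNA"]):
        feats.append(GenomicFeature(
            mid, "chr4", j * 10_000, j * 10_000 + 90, "+", "miRNA"))
    return feats


def _build_genesets(cfg: SimulationConfig, ids: dict, truth: dict,
                    rng: np.random.Generator) -> dict:
    """Random sets plus one set enriched (>= 50%) in planted DE genes of
    the first contrast."""
    sets = {}
    mrna = ids["mRNA"]
    first = truth["contrasts"][0]
    de_genes = sorted(truth["de"]["mRNA"][first])
    if de_genes:
        n_de_in = max(1, min(len(de_genes), 30))
        members = list(rng.choice(de_genes, size=n_de_in, replace=False))
        others = [g for g in mrna if g not in set(members)]
        fill = list(rng.choice(others, size=min(len(members), 20), replace=False))
        sets["set_enriched"] = ("planted DE-enriched set", members + fill)
        truth["enriched_set"] = "set_enriched"
    for i in range(10):
        size = int(rng.integers(20, 51))
        members = list(rng.choice(mrna, size=size, replace=False))
        sets[f"set_random{i:02d}"] = (f"random set {i}", members)
    return sets
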
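"""End-to-end pipeline: simulate or load inputs, then run every stage and
write inspectable TSV / GraphML outputs plus a run manifest.

Outputs are deterministic given (config, seed): identical runs produce
byte-identical statistical result tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .cerna import bipartite_table, build_cerna_network, filter_mirna_target_corr
from .config import PipelineConfig, SimulationConfig
from .de import classify_significant, nb_test
from .enrich import gsea, ora, ranking_from_de
from .io import (write_count_matrix, write_gmt, write_gtf, write_sample_sheet,
                 write_tsv)
from .lncpair import pair_lncrnas
from .simulate import SimulationBundle, contrast_name, simulate
from .te import (dte_test, level_correlation, quadrant_classify,
                 quadrant_counts, rpf_qc, te_vs_transcription_opposite)
from .trends import assign_profiles, profile_significance

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _header(cfg: PipelineConfig, stage: str) -> list[str]:
    return [f"ribolens {__version__} stage={stage}",
            f"config={cfg.to_json()}"]


def write_bundle(bundle: SimulationBundle, outdir) -> None:
    """Write a simulated bundle as the pipeline's on-disk input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for layer, cm in bundle.matrices.items():
        write_count_matrix(cm, outdir / f"counts_{layer}.tsv")
    write_sample_sheet(bundle.design, outdir / "sample_sheet.tsv")
    write_gtf(bundle.features, outdir / "annotation.gtf")
    bundle.targets.to_csv(outdir / "mirna_targets.tsv", sep="\t", index=False)
    write_gmt(bundle.genesets, outdir / "genesets.gmt")
    bundle.rpf_reads.to_csv(outdir / "rpf_reads.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)


def run_pipeline(cfg: PipelineConfig, outdir,
                 bundle: SimulationBundle | None = None,
                 sim_cfg: SimulationConfig | None = None,
                 stages: set[str] | None = None) -> dict:
    """Run all stages on a bundle (simulated if not given); returns a dict
    of in-memory results and writes one subdirectory per stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        sim_cfg = sim_cfg or SimulationConfig(seed=cfg.seed)
        bundle = simulate(sim_cfg)
        write_bundle(bundle, outdir / "inputs")
    stages = stages or {"de", "te", "trend", "enrich", "lncpair", "cerna"}
    mats = bundle.matrices
    design = bundle.design
    groups = design.groups
    contrasts = [(groups[i], groups[i + 1]) for i in range(len(groups) - 1)]
    results: dict = {"contrasts": contrasts}

    # ---- differential expression on every layer -------------------------
    de_res: dict = {}
    if stages & {"de", "te", "trend", "enrich", "cerna"}:
        for layer, cm in mats.items():
            de_res[layer] = {}
            for c in contrasts:
                try:
                    res = nb_test(cm, c, cfg)
                except Exception as e:
                    raise StageError("de", f"layer={layer} contrast={c}: {e}")
                de_res[layer][c] = res
                write_tsv(res, outdir / "de" / f"de_{layer}_{contrast_name(*c)}.tsv",
                          _header(cfg, "de"), index=True)
        results["de"] = de_res

    # ---- translatome ----------------------------------------------------
    if "te" in stages:
        try:
            qc = rpf_qc(bundle.rpf_reads)
            qc_df = pd.DataFrame(
                [{"metric": "modal_length", "value": qc["modal_length"]},
                 {"metric": "n_reads", "value": qc["n_reads"]}]
                + [{"metric": f"fraction_{r}", "value": v}
                   for r, v in qc["region_fractions"].items()])
            write_tsv(qc_df, outdir / "te" / "qc_report.tsv", _header(cfg, "te"))
            corr = [level_correlation(mats["mRNA"], mats["RPF"], g, cfg)
                    for g in groups]
            write_tsv(pd.DataFrame(corr), outdir / "te" / "level_correlation.tsv",
                      _header(cfg, "te"))
            results["qc"] = qc
            results["level_correlation"] = corr
            results["te"] = {}
            results["quadrants"] = {}
            results["opposite"] = {}
            for c in contrasts:
                te = dte_test(de_res["mRNA"][c], de_res["RPF"][c], cfg)
                joint = quadrant_classify(de_res["mRNA"][c], de_res["RPF"][c])
                opp = te_vs_transcription_opposite(te, de_res["mRNA"][c])
                cn = contrast_name(*c)
                write_tsv(te, outdir / "te" / f"te_{cn}.tsv",
                          _header(cfg, "te"), index=True)
                write_tsv(joint, outdir / "te" / f"quadrants_{cn}.tsv",
                          _header(cfg, "te"), index=True)
                write_tsv(quadrant_counts(joint).rename("n").to_frame(),
                          outdir / "te" / f"quadrant_counts_{cn}.tsv",
                          _header(cfg, "te"), index=True)
                results["te"][c] = te
                results["quadrants"][c] = joint
                results["opposite"][c] = opp
        except StageError:
            raise
        except Exception as e:
            raise StageError("te", str(e))

    # ---- trend profiling on the first three ordered groups --------------
    if "trend" in stages and len(groups) >= 3:
        try:
            tg = groups[:3]
            adj = [(tg[0], tg[1]), (tg[1], tg[2])]
            universe = set()
            for c in adj:
                part = classify_significant(de_res["mRNA"][c])
                universe |= part["up"] | part["down"]
            if universe:
                assigned = assign_profiles(mats["mRNA"], sorted(universe), tg)
                prof = profile_significance(mats["mRNA"], sorted(universe),
                                            tg, cfg)
                write_tsv(assigned, outdir / "trend" / "assignments.tsv",
                          _header(cfg, "trend"), index=True)
                write_tsv(prof, outdir / "trend" / "profiles.tsv",
                          _header(cfg, "trend"))
                results["trend"] = {"assignments": assigned, "profiles": prof}
            else:
                log.warning("trend stage: empty differential universe")
        except Exception as e:
            raise StageError("trend", str(e))

    # ---- enrichment ------------------------------------------------------
    if "enrich" in stages and bundle.genesets:
        try:
            c0 = contrasts[0]
            de0 = de_res["mRNA"][c0]
            part = classify_significant(de0)
            universe = set(de0.dropna(subset=["p"]).index)
            hits = part["up"] | part["down"]
            ora_res = ora(hits, bundle.genesets, universe, cfg)
            write_tsv(ora_res, outdir / "enrich" / "ora.tsv",
                      _header(cfg, "enrich"))
            gsea_res = gsea(ranking_from_de(de0), bundle.genesets, cfg,
                            B=min(cfg.permutations, 500))
            write_tsv(gsea_res, outdir / "enrich" / "gsea.tsv",
                      _header(cfg, "enrich"))
            results["ora"] = ora_res
            results["gsea"] = gsea_res
        except Exception as e:
            raise StageError("enrich", str(e))

    # ---- lncRNA pairing --------------------------------------------------
    if "lncpair" in stages and bundle.features:
        try:
            pairs = pair_lncrnas(bundle.features, cfg.cis_window)
            write_tsv(pairs, outdir / "lncpair" / "lnc_pairs.tsv",
                      _header(cfg, "lncpair"))
            results["lnc_pairs"] = pairs
        except Exception as e:
            raise StageError("lncpair", str(e))

    # ---- ceRNA network ---------------------------------------------------
    if "cerna" in stages:
        if bundle.targets is None or len(bundle.targets) == 0:
            raise StageError("cerna", "no miRNA target table supplied")
        try:
            c = contrasts[min(1, len(contrasts) - 1)]
            dif_sets = {
                layer: (lambda p: p["up"] | p["down"])(
                    classify_significant(de_res[layer][c]))
                for layer in ("mRNA", "lncRNA", "circRNA", "miRNA")
                if layer in de_res}
            rna_cms = {l: mats[l] for l in ("mRNA", "lncRNA", "circRNA")
                       if l in mats}
            retained = filter_mirna_target_corr(
                bundle.targets, mats["miRNA"], rna_cms, c, cfg)
            edges, graph = build_cerna_network(dif_sets, retained, rna_cms,
                                               c, cfg)
            cn = contrast_name(*c)
            write_tsv(edges, outdir / "cerna" / f"cerna_edges_{cn}.tsv",
                      _header(cfg, "cerna"))
            write_tsv(bipartite_table(retained, edges),
                      outdir / "cerna" / f"bipartite_{cn}.tsv",
                      _header(cfg, "cerna"))
            nx.write_graphml(graph, outdir / "cerna" / f"cerna_{cn}.graphml")
            passed = edges[edges["passed"]]
            el = passed[["rna_a", "rna_b", "shared"]]
            write_tsv(el, outdir / "cerna" / f"cerna_edgelist_{cn}.tsv",
                      _header(cfg, "cerna"))
            results["cerna"] = {"edges": edges, "graph": graph,
                                "retained_targets": retained}
        except StageError:
            raise
        except Exception as e:
            raise StageError("cerna", str(e))

    manifest = {"version": __version__, "config": cfg.to_dict(),
                "seed": cfg.seed,
                "stages": sorted(stages),
                "groups": groups}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return results
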
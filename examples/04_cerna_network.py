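"""Build the miRNA-mediated ceRNA network for the AD vs AD_HFD contrast.

Differential RNAs sharing miRNA response elements are joined when the
shared-miRNA count beats a hypergeometric null (p < 0.05), the pair is
positively co-expressed (Pearson r > 0.7), and each member is
anti-correlated with the shared miRNA (Spearman rho <= -0.5).
"""

import ribolens as rl

bundle = rl.simulate(rl.SimulationConfig(seed=1))
cfg = rl.PipelineConfig(seed=1)
contrast = ("AD", "AD_HFD")

dif = {}
for layer in ("mRNA", "lncRNA", "circRNA", "miRNA"):
    part = rl.classify_significant(
        rl.nb_test(bundle.matrices[layer], contrast, cfg))
    dif[layer] = part["up"] | part["down"]
print("differential RNAs:", {k: len(v) for k, v in dif.items()})

rna_cms = {l: bundle.matrices[l] for l in ("mRNA", "lncRNA", "circRNA")}
retained = rl.filter_mirna_target_corr(
    bundle.targets, bundle.matrices["miRNA"], rna_cms, contrast, cfg)
print(f"miRNA-target pairs: {len(bundle.targets)} annotated, "
      f"{len(retained)} retained after the Spearman filter")

edges, graph = rl.build_cerna_network(dif, retained, rna_cms, contrast, cfg)
passed = edges[edges["passed"]]
print(f"candidate pairs: {len(edges)}, passing edges: {len(passed)}")
print(passed[["rna_a", "rna_b", "shared", "m_a", "m_b", "M",
              "p_hyper", "pearson_r"]].head(8).round(4).to_string(index=False))

planted = {tuple(sorted((t["rna_a"], t["rna_b"])))
           for t in bundle.truth["cerna_triplets"]}
got = {tuple(sorted(e)) for e in graph.edges}
print(f"\nplanted triplet edges recovered: {len(planted & got)}/{len(planted)}")
# each edge lists how many miRNAs the two RNAs share (s of m_a and m_b
# annotated targets, miRNA universe M) and the co-expression r.
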
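# ribolens

Transcriptome–translatome integration for bulk multi-omics count data.

Paired RNA-seq and Ribo-seq experiments measure, for every gene, how much
mRNA is present and how much of it is being translated. The interesting
biology often lives in the disagreement between the two layers: a gene can
be transcriptionally induced yet translationally buffered, or flat at the
mRNA level while ribosome occupancy shifts. `ribolens` implements the
analysis chain used in whole-transcriptome + ribosome-profiling studies of
disease/intervention designs (e.g. an AD mouse model under a high-fat
diet, with groups ordered Nor < AD < AD_HFD < H_H):

- **Differential expression** on every omics layer (mRNA, ribosome
  footprints, miRNA, lncRNA, circRNA): median-of-ratios normalization, a
  per-gene negative-binomial Wald test with a trend-shrunken
  method-of-moments dispersion, and the screening rule
  *P* < 0.05 and |log₂FC| ≥ 0.585 (1.5-fold), with BH *q* reported.
- **Ribo-seq QC and translation efficiency**: footprint length/region QC
  (modal length 28 nt, CDS-dominated occupancy), per-group mRNA–footprint
  correlation, and the TE contrast
  Δlog₂TE = log₂FC(RPF) − log₂FC(mRNA), tested by a z-test with
  se² = se²_RPF + se²_mRNA.
- **Joint quadrant classification** of transcriptome × translatome calls
  (homodirectional, opposite, single-layer, unchanged) and the
  TE-vs-transcription "opposite" screen.
- **Trend profiling** over ordered conditions: all 3^(k−1) − 1
  step-direction templates (8 for three groups), correlation-based
  assignment, and STEM-style permutation significance of profile
  membership counts.
- **Enrichment**: hypergeometric over-representation and a weighted
  running-sum GSEA with a gene-label permutation null.
- **lncRNA–mRNA pairing** by genomic coordinates: *cis* (≤ 100 kb window)
  and *antisense* (opposite-strand overlap).
- **ceRNA network inference**: miRNA–target anti-correlation filter
  (Spearman ρ ≤ −0.5), shared-MRE hypergeometric test
  P(X ≥ s), X ~ Hypergeom(M, m_a, m_b), positive co-expression filter
  (Pearson r > 0.7), and typed network export (GraphML + TSV).
- **A planted-truth simulator** generating NB count matrices for all five
  layers with known DE genes, TE shifts, trend profiles, ceRNA triplets,
  footprint read features, annotation (GTF), miRNA target table and gene
  sets (GMT) — so every stage can be benchmarked against ground truth.

## Worked example

```python
import ribolens as rl

bundle = rl.simulate(rl.SimulationConfig(seed=1))
cfg = rl.PipelineConfig(seed=1)

res = rl.nb_test(bundle.matrices["mRNA"], ("Nor", "AD"), cfg)
part = rl.classify_significant(res)
truth = set(bundle.truth["de"]["mRNA"]["Nor_vs_AD"])
sig = part["up"] | part["down"]
print(len(part["up"]), len(part["down"]), len(truth & sig) / len(truth))
```

prints `130 120 0.968`: 130 genes called up and 120 down under the
screening rule, recovering 96.8% of the genes planted at |log₂FC| = 2
(3 replicates per group, NB dispersion 0.1). Running
`python examples/02_translation_efficiency.py` continues the analysis:

```
RPF modal length: 28 nt
region fractions: {'CDS': 0.881, 'UTR5': 0.025, 'UTR3': 0.025, 'other': 0.069}
mRNA~footprint Pearson R in Nor: 0.62 (1931 genes)
...
quadrant counts (Nor vs AD):
homodirectional_up        79
homodirectional_down      66
...
both_levels_total        145
```

i.e. footprints peak at 28 nt with ~88% of reads in coding sequence, the
two layers correlate moderately (R ≈ 0.62–0.64 per group), and 145 genes
change at both the transcriptional and translational level in this
simulation. The `examples/` directory has one short script per capability
(DE, TE/quadrants, trends, ceRNA, enrichment, lncRNA pairing); each prints
the numbers it computes and what they mean. A thin CLI covers the same
stages (`ribolens simulate|de|te|trend|cerna|enrich|lncpair|all`).

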
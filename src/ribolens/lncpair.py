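"""lncRNA-coding gene pairing by genomic coordinates.

Two mechanisms: *cis* (same chromosome within a bp window, strand-
agnostic; overlap counts as distance 0) and *antisense* (opposite-strand
interval overlap). Coordinates are 0-based half-open throughout; distance
is the gap between closest ends. Hybridization-energy screening is out of
scope — an optional pass-through column accepts externally computed
energies.
"""

from __future__ import annotations

from collections import defaultdict

import pandas as pd

from .io import GenomicFeature


def _gap(a: GenomicFeature, b: GenomicFeature) -> int:
    """0 when intervals overlap, else the gap between closest ends."""
    if a.start < b.end and b.start < a.end:
        return 0
    return max(a.start, b.start) - min(a.end, b.end)


def _overlap_bp(a: GenomicFeature, b: GenomicFeature) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _by_chrom(features) -> dict[str, list[GenomicFeature]]:
    d = defaultdict(list)
    for f in features:
        d[f.chrom].append(f)
    for fs in d.values():
        fs.sort(key=lambda f: (f.start, f.end, f.feature_id))
    return d


def cis_pairs(lncs, genes, window: int = 100_000) -> pd.DataFrame:
    """lncRNA-gene pairs within `window` bp on the same chromosome.

    Sorted sweep per chromosome; output ordered by (lnc_id, gene_id) so it
    is stable under input permutation.
    """
    gene_idx = _by_chrom(genes)
    rows = []
    for lnc in lncs:
        for g in gene_idx.get(lnc.chrom, ()):
            if g.start - lnc.end > window:
                break
            d = _gap(lnc, g)
            if d <= window:
                rows.append({"lnc_id": lnc.feature_id, "gene_id": g.feature_id,
                             "mode": "cis", "distance": d,
                             "overlap_bp": _overlap_bp(lnc, g)})
    rows.sort(key=lambda r: (r["lnc_id"], r["gene_id"]))
    return pd.DataFrame(rows, columns=[
        "lnc_id", "gene_id", "mode", "distance", "overlap_bp"])


def antisense_pairs(lncs, genes) -> pd.DataFrame:
    """Opposite-strand overlapping lncRNA-gene pairs with overlap length."""
    gene_idx = _by_chrom(genes)
    rows = []
    for lnc in lncs:
        for g in gene_idx.get(lnc.chrom, ()):
            if g.start >= lnc.end:
                break
            if g.end > lnc.start and g.strand != lnc.strand:
                rows.append({"lnc_id": lnc.feature_id, "gene_id": g.feature_id,
                             "mode": "antisense", "distance": 0,
                             "overlap_bp": _overlap_bp(lnc, g)})
    rows.sort(key=lambda r: (r["lnc_id"], r["gene_id"]))
    return pd.DataFrame(rows, columns=[
        "lnc_id", "gene_id", "mode", "distance", "overlap_bp"])


def pair_lncrnas(features, window: int = 100_000) -> pd.DataFrame:
    """Both pairing modes from one mixed feature list.

    lncRNAs are features with biotype 'lncRNA', partners those with
    'protein_coding'.
    """
    lncs = [f for f in features if f.biotype == "lncRNA"]
    genes = [f for f in features if f.biotype == "protein_coding"]
    return pd.concat([cis_pairs(lncs, genes, window),
                      antisense_pairs(lncs, genes)],
                     ignore_index=True)
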
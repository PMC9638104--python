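"""File formats: count matrices (TSV), sample sheets, GTF, GMT, target tables.

All result TSVs may carry ``#`` header comment lines recording config; every
reader here skips them. Genomic intervals are 0-based half-open internally;
GTF I/O converts at the boundary (GTF is 1-based inclusive).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .design import SampleDesign, DesignError


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

class CountMatrix:
    """Non-negative integer gene x sample table tied to one design layer."""

    def __init__(self, counts: pd.DataFrame, design: SampleDesign, layer: str):
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        if counts.isna().any().any():
            raise FormatError("count matrix contains missing entries")
        if (counts.to_numpy() < 0).any():
            r, c = next(zip(*((counts < 0).to_numpy().nonzero())))
            raise FormatError(
                f"negative count at gene {counts.index[r]!r}, "
                f"sample {counts.columns[c]!r}")
        declared = design.samples(layer)
        extra = set(counts.columns) - set(declared)
        if extra:
            raise DesignError(
                f"samples {sorted(extra)} not declared for layer {layer!r}")
        # column order follows the design (hence group order)
        cols = [s for s in declared if s in counts.columns]
        self.counts = counts.loc[:, cols].astype("int64")
        self.design = design
        self.layer = layer

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.counts.columns.tolist()

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples
                if s in set(self.design.samples(self.layer, group))]

    def __repr__(self) -> str:
        return (f"CountMatrix(layer={self.layer!r}, "
                f"shape={self.counts.shape})")


def read_count_matrix(path, design: SampleDesign, layer: str) -> CountMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a gene id column plus >=1 sample")
    gene_col = df.columns[0]
    genes = df[gene_col]
    if genes.duplicated().any():
        dups = genes[genes.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene ids {dups}")
    body = df.drop(columns=[gene_col])
    mat = {}
    for col in body.columns:
        try:
            vals = pd.to_numeric(body[col])
        except (ValueError, TypeError) as e:
            raise FormatError(f"{path}: non-numeric value in column {col!r}: {e}")
        bad = vals[(vals < 0) | (vals != vals.round())]
        if len(bad):
            row = genes.iloc[bad.index[0]]
            raise FormatError(
                f"{path}: invalid count {bad.iloc[0]!r} at gene {row!r}, "
                f"sample {col!r} (must be a non-negative integer)")
        mat[col] = vals.astype("int64")
    counts = pd.DataFrame(mat)
    counts.index = pd.Index(genes, name="gene_id")
    return CountMatrix(counts, design, layer)


def write_count_matrix(cm: CountMatrix, path, header_comments: list[str] | None = None):
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        cm.counts.to_csv(fh, sep="\t")


def read_sample_sheet(path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "replicate" in df.columns:
        df["replicate"] = df["replicate"].astype(int)
    return SampleDesign(df)


def write_sample_sheet(design: SampleDesign, path):
    design.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genomic features / GTF
# ---------------------------------------------------------------------------

BIOTYPES = ("protein_coding", "lncRNA", "circRNA", "miRNA")


@dataclass(frozen=True)
class GenomicFeature:
    """A gene locus; coordinates 0-based half-open."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise FormatError(
                f"{self.feature_id}: invalid interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.feature_id}: strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path) -> list[GenomicFeature]:
    """Parse gene lines from a GTF file (1-based inclusive -> half-open)."""
    feats = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{ln}: expected 9 GTF columns")
            chrom, _src, _ftype, start, end, _score, strand, _frame, attrs = parts
            attrs = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attrs:
                raise FormatError(f"{path}:{ln}: missing gene_id attribute")
            start, end = int(start), int(end)
            if end < start:
                raise FormatError(f"{path}:{ln}: end < start")
            feats.append(GenomicFeature(
                feature_id=attrs["gene_id"],
                chrom=chrom,
                start=start - 1,        # 1-based inclusive -> 0-based half-open
                end=end,
                strand=strand,
                biotype=attrs.get("gene_biotype", "protein_coding"),
            ))
    return feats


def write_gtf(features: list[GenomicFeature], path):
    with open(path, "w") as fh:
        for f in features:
            attrs = f'gene_id "{f.feature_id}"; gene_biotype "{f.biotype}";'
            fh.write("\t".join([
                f.chrom, "ribolens", "gene",
                str(f.start + 1), str(f.end),  # back to 1-based inclusive
                ".", f.strand, ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# gene sets (GMT) and miRNA target tables
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """set_id -> (description, member gene ids)."""
    sets = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT needs id, description, >=1 gene")
            sets[parts[0]] = (parts[1], [g for g in parts[2:] if g])
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path):
    with open(path, "w") as fh:
        for sid, (desc, members) in sets.items():
            fh.write("\t".join([sid, desc, *members]) + "\n")


def read_target_table(path) -> pd.DataFrame:
    """miRNA->target annotation: columns mirna_id, target_id, target_layer."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    need = {"mirna_id", "target_id", "target_layer"}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"{path}: target table missing columns {sorted(missing)}")
    df = df.drop_duplicates(subset=["mirna_id", "target_id"]).reset_index(drop=True)
    return df


def write_tsv(df: pd.DataFrame, path, header_comments: list[str] | None = None,
              index: bool = False):
    """Result table with a ``#`` comment block carrying run metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
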
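"""Readers and writers for the formats the pipeline touches.

Conventions: all coordinates are 0-based half-open in memory; GTF
(1-based inclusive) is converted at the boundary.  Matrices travel as a
10x-style bundle (matrix.mtx + barcodes.tsv + features.tsv + a small
metadata JSON); MTX body indices are 1-based per the format.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges
import scipy.io
import scipy.sparse as sp

__all__ = [
    "Transcript", "GeneModel", "read_gtf", "write_gtf",
    "MatrixBundle", "write_mtx_bundle", "read_mtx_bundle",
    "AlignedRead", "read_alignments_tsv", "write_alignments_tsv",
    "read_alignments_bam", "write_fastq", "read_fastq",
    "RunConfig", "read_config", "write_config",
]


# ---------------------------------------------------------------------------
# gene models / GTF
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    transcript_id: str
    exons: list  # [(start, end)] 0-based half-open, sorted

    def introns(self):
        """Gaps between consecutive exons."""
        ex = sorted(self.exons)
        return [(ex[k][1], ex[k + 1][0]) for k in range(len(ex) - 1)]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list = field(default_factory=list)

    @property
    def span(self):
        lo = min(s for t in self.transcripts for s, _ in t.exons)
        hi = max(e for t in self.transcripts for _, e in t.exons)
        return lo, hi


def read_gtf(path) -> dict:
    """Parse exon features of a GTF into gene models keyed by gene_id."""
    df = pyranges.read_gtf(str(path)).df
    if "Feature" not in df or "gene_id" not in df:
        raise ValueError(f"{path}: not a valid GTF (missing Feature/gene_id)")
    ex = df[df["Feature"] == "exon"]
    bad = int(ex["transcript_id"].isna().sum()) if "transcript_id" in ex else len(ex)
    if bad:
        raise ValueError(f"{path}: {bad} exon lines lack transcript_id")
    genes: dict[str, GeneModel] = {}
    for (gid, tid), grp in ex.groupby(["gene_id", "transcript_id"], sort=False):
        chrom = str(grp["Chromosome"].iloc[0])
        strand = str(grp["Strand"].iloc[0]) if "Strand" in grp else "+"
        gm = genes.setdefault(gid, GeneModel(gene_id=gid, chrom=chrom,
                                             strand=strand))
        exons = sorted(zip(grp["Start"].astype(int), grp["End"].astype(int)))
        for s, e in exons:
            if e <= s:
                raise ValueError(f"{path}: exon with end <= start in {tid}")
        gm.transcripts.append(Transcript(transcript_id=tid, exons=exons))
    return genes


def write_gtf(genes: dict, path) -> None:
    """Emit exon lines, converting back to 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for gm in genes.values():
            for tr in gm.transcripts:
                for s, e in tr.exons:
                    attrs = (f'gene_id "{gm.gene_id}"; '
                             f'transcript_id "{tr.transcript_id}";')
                    fh.write("\t".join([gm.chrom, "regionvelo", "exon",
                                        str(s + 1), str(e), ".", gm.strand,
                                        ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# matrix bundle (MTX + TSV)
# ---------------------------------------------------------------------------

@dataclass
class MatrixBundle:
    matrix: sp.csr_matrix  # cells x genes
    barcodes: list
    features: list
    kind: str = "counts"  # exon|intron|spliced|unspliced|velocity|counts


def write_mtx_bundle(bundle: MatrixBundle, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    m = sp.coo_matrix(bundle.matrix)
    if m.shape != (len(bundle.barcodes), len(bundle.features)):
        raise ValueError("matrix dimensions do not match barcode/feature lists")
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), m)
    with open(os.path.join(outdir, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(map(str, bundle.barcodes)) + ("\n" if bundle.barcodes else ""))
    with open(os.path.join(outdir, "features.tsv"), "w") as fh:
        fh.write("\n".join(map(str, bundle.features)) + ("\n" if bundle.features else ""))
    with open(os.path.join(outdir, "metadata.json"), "w") as fh:
        json.dump({"kind": bundle.kind, "shape": list(m.shape)}, fh)


def read_mtx_bundle(indir) -> MatrixBundle:
    m = sp.csr_matrix(scipy.io.mmread(os.path.join(indir, "matrix.mtx")))
    def _read_list(name):
        p = os.path.join(indir, name)
        with open(p) as fh:
            return [ln.strip() for ln in fh if ln.strip()]
    barcodes = _read_list("barcodes.tsv")
    features = _read_list("features.tsv")
    kind = "counts"
    meta_path = os.path.join(indir, "metadata.json")
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            kind = json.load(fh).get("kind", "counts")
    if m.shape != (len(barcodes), len(features)):
        raise ValueError(f"{indir}: MTX dimensions {m.shape} do not match "
                         f"{len(barcodes)} barcodes x {len(features)} features")
    return MatrixBundle(matrix=m, barcodes=barcodes, features=features, kind=kind)


# ---------------------------------------------------------------------------
# aligned reads (block TSV, or BAM via pysam)
# ---------------------------------------------------------------------------

@dataclass
class AlignedRead:
    """A spliced alignment reduced to its aligned genomic blocks."""

    read_id: str
    cell_label: str
    umi: str
    chrom: str
    strand: str
    blocks: list  # [(start, end)] 0-based half-open, sorted, non-overlapping

    def __post_init__(self):
        bl = sorted(self.blocks)
        for k in range(1, len(bl)):
            if bl[k][0] < bl[k - 1][1]:
                raise ValueError(f"{self.read_id}: overlapping blocks")
        self.blocks = bl


def write_alignments_tsv(reads, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcell\tumi\tchrom\tstrand\tblocks\n")
        for r in reads:
            blocks = ",".join(f"{s}-{e}" for s, e in r.blocks)
            fh.write(f"{r.read_id}\t{r.cell_label}\t{r.umi}\t{r.chrom}"
                     f"\t{r.strand}\t{blocks}\n")


def read_alignments_tsv(path):
    reads = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expect = ["read_id", "cell", "umi", "chrom", "strand", "blocks"]
        if header != expect:
            raise ValueError(f"{path}: expected columns {expect}, got {header}")
        for ln in fh:
            rid, cell, umi, chrom, strand, blocks = ln.rstrip("\n").split("\t")
            bl = []
            for tok in blocks.split(","):
                s, e = tok.split("-")
                bl.append((int(s), int(e)))
            reads.append(AlignedRead(rid, cell, umi, chrom, strand, bl))
    return reads


def read_alignments_bam(path, cell_tag: str = "CB", umi_tag: str = "UB"):
    """Reduce a coordinate BAM of spliced alignments to AlignedRead blocks."""
    import pysam  # optional dependency, only needed for BAM input

    reads = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            try:
                cell = rec.get_tag(cell_tag)
                umi = rec.get_tag(umi_tag)
            except KeyError:
                continue
            blocks = [(int(s), int(e)) for s, e in rec.get_blocks()]
            merged = []
            for s, e in blocks:  # get_blocks splits on I/D too; re-merge abutting
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
                else:
                    merged.append((s, e))
            reads.append(AlignedRead(rec.query_name, cell, umi,
                                     rec.reference_name,
                                     "-" if rec.is_reverse else "+", merged))
    return reads


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def write_fastq(records, path, quality_char: str = "5") -> None:
    """records: iterable of (read_id, sequence); constant Q20 placeholder."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path):
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# run configuration (flat key=value file)
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "fit_quantile": float, "min_corr": float, "min_slope": float,
    "k_cells": int, "delta_t": float, "theta_mode": str,
    "trim_len": int, "max_label_dist": int, "min_margin": int,
    "max_scaffold_dist": int, "seed": int, "n_grid": int,
    "kernel_sigma": float, "n_neighbors": int, "min_intron_len": int,
}


@dataclass
class RunConfig:
    values: dict = field(default_factory=dict)

    def get(self, key, default=None):
        return self.values.get(key, default)


def read_config(path) -> RunConfig:
    values = {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, 1):
            ln = ln.split("#", 1)[0].strip()
            if not ln:
                continue
            if "=" not in ln:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, val = (tok.strip() for tok in ln.split("=", 1))
            if key not in _CONFIG_KEYS:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            values[key] = _CONFIG_KEYS[key](val)
    return RunConfig(values=values)


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        for k, v in cfg.values.items():
            fh.write(f"{k} = {v}\n")
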
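"""Exon/intron/spliced/unspliced quantification and cell calling.

Reads arrive as spliced alignments reduced to genomic blocks.  Per gene,
annotated exons are merged across transcripts and introns are the merged
gaps between consecutive exons; where the merged sets would overlap, exon
wins.  A read is intronic when its intersection with the merged intron
set exceeds ``min_intron_len`` (default 20 bp), and an intronic read is
counted as an unspliced transcript.  Molecules (UMI-deduplicated reads)
increment the spliced or unspliced matrix once each, the exon matrix when
they touch any exon and the intron matrix when their intronic overlap
qualifies.  Cells are called from the barcode-rank curve (knee and
inflection on the log-log curve) with an ambient-profile Monte-Carlo test
at FDR 0.01, the ambient pool being barcodes detecting fewer than 20
genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree
from scipy.interpolate import UnivariateSpline
from scipy.stats import false_discovery_control

from .io import AlignedRead, GeneModel

__all__ = [
    "RegionIndex", "ReadClass", "CountMatrices", "CellCallResult",
    "merge_intervals", "build_region_index", "classify_alignment",
    "accumulate_matrices", "call_cells",
]


def merge_intervals(intervals):
    """Union of half-open intervals, sorted and disjoint."""
    out = []
    for s, e in sorted(intervals):
        if e <= s:
            raise ValueError(f"invalid interval [{s},{e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(e, out[-1][1]))
        else:
            out.append((s, e))
    return out


def _subtract(intervals, cutters):
    """Remove every region of ``cutters`` from ``intervals`` (both merged)."""
    out = []
    for s, e in intervals:
        cur = s
        for cs, ce in cutters:
            if ce <= cur or cs >= e:
                continue
            if cs > cur:
                out.append((cur, cs))
            cur = max(cur, ce)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def _overlap_bp(blocks, intervals):
    """Total intersection of two sorted disjoint interval lists."""
    total = 0
    i = j = 0
    while i < len(blocks) and j < len(intervals):
        bs, be = blocks[i]
        s, e = intervals[j]
        total += max(0, min(be, e) - max(bs, s))
        if be <= e:
            i += 1
        else:
            j += 1
    return total


def _max_single_overlap(blocks, intervals):
    best = 0
    for s, e in intervals:
        o = 0
        for bs, be in blocks:
            if be <= s or bs >= e:
                continue
            o += min(be, e) - max(bs, s)
        best = max(best, o)
    return best


@dataclass
class RegionIndex:
    """Per-gene merged exon/intron intervals with a genomic lookup tree."""

    exons: dict          # gene_id -> [(s,e)]
    introns: dict        # gene_id -> [(s,e)] (introns > min_intron_len only)
    gene_info: dict      # gene_id -> (chrom, strand)
    min_intron_len: int = 20
    _trees: dict = field(default_factory=dict, repr=False)

    def genes_overlapping(self, chrom: str, start: int, end: int):
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end)})


def build_region_index(gene_models: dict, min_intron_len: int = 20) -> RegionIndex:
    """Merge exons and introns per gene and index gene spans by position.

    Introns are the gaps between consecutive exons of each transcript,
    merged across transcripts; merged intron regions that collide with the
    merged exon set are trimmed (exon precedence), and introns whose
    length does not exceed ``min_intron_len`` are dropped from intronic
    calling.
    """
    exons, introns, info = {}, {}, {}
    trees: dict[str, IntervalTree] = {}
    for gid, gm in gene_models.items():
        ex = merge_intervals([iv for tr in gm.transcripts for iv in tr.exons])
        inr = [iv for tr in gm.transcripts for iv in tr.introns()]
        inr = merge_intervals(inr) if inr else []
        inr = _subtract(inr, ex)
        inr = [(s, e) for s, e in inr if (e - s) > min_intron_len]
        exons[gid] = ex
        introns[gid] = inr
        info[gid] = (gm.chrom, gm.strand)
        lo, hi = gm.span
        trees.setdefault(gm.chrom, IntervalTree()).addi(lo, hi, gid)
    return RegionIndex(exons=exons, introns=introns, gene_info=info,
                       min_intron_len=min_intron_len, _trees=trees)


@dataclass
class ReadClass:
    read_id: str
    cell_label: str
    umi: str
    gene: str | None
    exon_overlap_bp: int
    intron_overlap_bp: int
    intronic: bool

    @property
    def spliced_call(self) -> str:
        return "unspliced" if self.intronic else "spliced"


def classify_alignment(read: AlignedRead, index: RegionIndex,
                       per_intron: bool = False,
                       strand_aware: bool = True) -> ReadClass:
    """Assign a read to the gene its blocks overlap most and call its
    splicing state.

    ``per_intron=False`` (default): intronic when the summed overlap with
    the merged intron set exceeds ``min_intron_len``; ``per_intron=True``
    requires a single intron to exceed it.  A tie in gene overlap leaves
    the read unassigned (gene=None), as does no overlap at all.
    """
    lo, hi = read.blocks[0][0], read.blocks[-1][1]
    cands = index.genes_overlapping(read.chrom, lo, hi)
    if strand_aware and read.strand in "+-":
        cands = [g for g in cands if index.gene_info[g][1] == read.strand]
    best_gene = None
    best_tot = 0
    tie = False
    best_ex = best_in = 0
    for gid in cands:
        ex = _overlap_bp(read.blocks, index.exons[gid])
        inb = _overlap_bp(read.blocks, index.introns[gid])
        tot = ex + inb
        if tot > best_tot:
            best_gene, best_tot, tie = gid, tot, False
            best_ex, best_in = ex, inb
        elif tot == best_tot and tot > 0 and gid != best_gene:
            tie = True
    if best_gene is None or tie or best_tot == 0:
        return ReadClass(read.read_id, read.cell_label, read.umi, None,
                         0, 0, False)
    if per_intron:
        intr = _max_single_overlap(read.blocks, index.introns[best_gene]) \
            > index.min_intron_len
    else:
        intr = best_in > index.min_intron_len
    return ReadClass(read.read_id, read.cell_label, read.umi, best_gene,
                     best_ex, best_in, intr)


@dataclass
class CountMatrices:
    """cells x genes integer matrices over one shared axis pair."""

    exon: sp.csr_matrix
    intron: sp.csr_matrix
    spliced: sp.csr_matrix
    unspliced: sp.csr_matrix
    barcodes: list
    gene_ids: list
    n_unassigned_reads: int = 0

    def dense(self, kind: str) -> np.ndarray:
        return np.asarray(getattr(self, kind).todense())


def accumulate_matrices(read_classes, barcodes=None, gene_ids=None,
                        known_cells=None) -> CountMatrices:
    """Collapse classified reads into molecule-level count matrices.

    Reads are grouped into molecules by (cell, gene, UMI); a molecule is
    unspliced if any of its reads is intronic, contributes to the exon
    matrix if any read has exon overlap and to the intron matrix if any
    read qualifies as intronic.  Reads with no gene are tallied, not
    counted.  When ``known_cells`` is given, other barcodes are routed to
    a background tally kept in the result's unassigned count.
    """
    mols: dict[tuple, dict] = {}
    n_unassigned = 0
    for rc in read_classes:
        if rc.gene is None:
            n_unassigned += 1
            continue
        if known_cells is not None and rc.cell_label not in known_cells:
            n_unassigned += 1
            continue
        key = (rc.cell_label, rc.gene, rc.umi)
        m = mols.setdefault(key, {"exon": False, "intron": False})
        m["exon"] = m["exon"] or rc.exon_overlap_bp > 0
        m["intron"] = m["intron"] or rc.intronic
    if barcodes is None:
        barcodes = sorted({k[0] for k in mols})
    if gene_ids is None:
        gene_ids = sorted({k[1] for k in mols})
    bidx = {b: k for k, b in enumerate(barcodes)}
    gidx = {g: k for k, g in enumerate(gene_ids)}
    shape = (len(barcodes), len(gene_ids))
    mats = {k: sp.lil_matrix(shape, dtype=np.int64)
            for k in ("exon", "intron", "spliced", "unspliced")}
    for (cell, gene, _umi), m in mols.items():
        if cell not in bidx or gene not in gidx:
            n_unassigned += 1
            continue
        ci, gi = bidx[cell], gidx[gene]
        if m["exon"]:
            mats["exon"][ci, gi] += 1
        if m["intron"]:
            mats["intron"][ci, gi] += 1
            mats["unspliced"][ci, gi] += 1
        else:
            mats["spliced"][ci, gi] += 1
    return CountMatrices(exon=mats["exon"].tocsr(),
                         intron=mats["intron"].tocsr(),
                         spliced=mats["spliced"].tocsr(),
                         unspliced=mats["unspliced"].tocsr(),
                         barcodes=list(barcodes), gene_ids=list(gene_ids),
                         n_unassigned_reads=n_unassigned)


# ---------------------------------------------------------------------------
# cell calling
# ---------------------------------------------------------------------------

@dataclass
class CellCallResult:
    cells: list
    knee: float
    inflection: float
    fdr: pd.DataFrame  # per-candidate barcode: total, p, q, called
    summary: dict


def _knee_inflection(totals_sorted: np.ndarray):
    """Knee (max negative curvature) and inflection (min first derivative)
    of the smoothed log-log barcode-rank curve."""
    y = np.log10(totals_sorted.astype(float) + 1.0)
    x = np.log10(np.arange(1, y.size + 1, dtype=float))
    xu, iu = np.unique(x, return_index=True)
    yu = y[iu]
    if xu.size < 5:
        return float(totals_sorted[0]), float(totals_sorted[-1])
    spl = UnivariateSpline(xu, yu, k=3, s=max(yu.size * 5e-3, 1e-6))
    d1 = spl.derivative(1)(xu)
    d2 = spl.derivative(2)(xu)
    curvature = d2 / np.power(1.0 + d1 ** 2, 1.5)
    knee_i = int(np.argmin(curvature))
    infl_i = int(np.argmin(d1))
    knee = float(10 ** yu[knee_i] - 1.0)
    infl = float(10 ** yu[infl_i] - 1.0)
    return knee, infl


def call_cells(matrix, barcodes, ambient_gene_threshold: int = 20,
               fdr: float = 0.01, n_mc: int = 1000, seed: int = 0,
               total_counts=None) -> CellCallResult:
    """Call cells from a gene-barcode matrix.

    Barcodes are ranked by total count; knee and inflection are located on
    the smoothed log-log rank curve.  Barcodes detecting fewer than
    ``ambient_gene_threshold`` genes define the ambient expression
    profile; every other barcode is tested against a multinomial draw from
    that profile by Monte-Carlo likelihood p-value, Benjamini-Hochberg
    corrected at ``fdr``.  Barcodes at or above the knee are always
    retained.
    """
    M = sp.csr_matrix(matrix)
    if M.nnz == 0:
        raise ValueError("all-zero matrix: cannot call cells")
    totals = np.asarray(M.sum(axis=1)).ravel()
    if total_counts is not None:
        totals = np.asarray(total_counts, dtype=float).ravel()
    n_genes_det = np.asarray((M > 0).sum(axis=1)).ravel()
    if len(barcodes) == 1:
        import warnings

        warnings.warn("single barcode: knee undefined, returning it as a cell")
        return CellCallResult(cells=list(barcodes), knee=float(totals[0]),
                              inflection=float(totals[0]),
                              fdr=pd.DataFrame(), summary={})
    order = np.argsort(-totals)
    knee, infl = _knee_inflection(totals[order])

    ambient_mask = n_genes_det < ambient_gene_threshold
    rng = np.random.default_rng(seed)
    candidates = np.flatnonzero(~ambient_mask & (totals > 0))
    if ambient_mask.sum() == 0 or candidates.size == 0:
        called = totals >= knee
        cells = [barcodes[k] for k in np.flatnonzero(called)]
        return CellCallResult(cells=cells, knee=knee, inflection=infl,
                              fdr=pd.DataFrame(), summary={})
    profile = np.asarray(M[ambient_mask].sum(axis=0)).ravel().astype(float)
    profile = (profile + 0.1) / (profile + 0.1).sum()
    logp = np.log(profile)

    # Monte-Carlo: simulate the ambient log-likelihood null once per depth
    # bin (5% geometric bins) and compare per-count likelihoods, so near-
    # identical depths share one simulation
    pvals = np.ones(candidates.size)
    def _bin(T):
        return int(np.exp(np.round(np.log(max(T, 1)) / 0.05) * 0.05))
    sims = {}
    for k, ci in enumerate(candidates):
        row = np.asarray(M[ci].todense()).ravel()
        T = int(totals[ci])
        Tb = _bin(T)
        if Tb not in sims:
            draws = rng.multinomial(Tb, profile, size=n_mc)
            sims[Tb] = (draws @ logp) / Tb  # per-count log-likelihood
        obs = float(row @ logp) / T
        pvals[k] = (1.0 + np.sum(sims[Tb] <= obs)) / (1.0 + n_mc)
    qvals = false_discovery_control(pvals, method="bh")
    sig = qvals <= fdr
    called = np.zeros(len(barcodes), dtype=bool)
    called[candidates[sig]] = True
    called |= totals >= knee
    cells = [barcodes[k] for k in np.flatnonzero(called)]
    table = pd.DataFrame({"barcode": [barcodes[k] for k in candidates],
                          "total": totals[candidates],
                          "p": pvals, "q": qvals, "called": sig})
    summary = {
        "n_cells": int(called.sum()),
        "mean_genes_per_cell": float(n_genes_det[called].mean()) if called.any() else 0.0,
        "mean_counts_per_cell": float(totals[called].mean()) if called.any() else 0.0,
        "fraction_counts_in_cells": float(totals[called].sum() / totals.sum()),
    }
    return CellCallResult(cells=cells, knee=knee, inflection=infl, fdr=table,
                          summary=summary)
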
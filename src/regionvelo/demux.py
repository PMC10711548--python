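"""Two-round demultiplexing of long reads carrying a three-part cell label.

The bead cell label is three 9 bp barcodes (each from a pool of 96) joined
by two fixed linkers -- a 52 bp label whose large pairwise edit distance
compensates for nanopore error rates.  The composed reference additionally
carries a 5' anchor, the UMI placeholder and oligo-dT, giving a 98-base
reference padded with Ns at both ends.

Round 1 orients each read by its oligo-dT/oligo-dA run, trims it to the
first 300 bp (the theoretical barcode window), locates the label scaffold
by wildcard edit-distance alignment, and scores the three barcode slots
against their pools; the label is assigned only when the total edit
distance is low enough and every slot's best hit beats its runner-up by a
margin (ties are conservatively unassigned).  Because the label space
factorises over the three slots, scoring 3 x 96 candidates is equivalent
to ranking all 96^3 composed labels while staying fast.  Round 2 rescues
reads the trimming or a defective linker lost: the three pools are aligned
independently against the full read and a read is recovered only when one
barcode per pool occurs in order with inter-barcode gaps matching the
linker lengths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "BarcodePool", "LibraryDesign", "CellLabelReference", "Assignment",
    "DemuxMetrics", "DEFAULT_LINKER1", "DEFAULT_LINKER2", "DEFAULT_ANCHOR5",
    "PRESETS", "levenshtein", "hamming", "build_barcode_pools",
    "load_barcode_pool", "compose_reference", "pool_distance_stats",
    "detect_strand", "demux_first_round", "demux_second_round",
    "demux_reads", "correct_umis", "dedup_umis", "evaluate_demux",
]

# BD Rhapsody-style defaults: 12 bp and 13 bp linkers; anchor and oligo-dT
# lengths chosen so anchor + 3x9 bc + linkers + 8 bp UMI + oligo-dT = 98.
DEFAULT_LINKER1 = "ACTGGCCTGCGA"        # 12 bp
DEFAULT_LINKER2 = "GGTAGCGGTGACA"       # 13 bp
DEFAULT_ANCHOR5 = "ACACGACGCTCTTCCGAT"  # 18 bp
_N_EQUALITIES = [("N", c) for c in "ACGT"]


def levenshtein(a: str, b: str) -> int:
    """Exact edit distance (unit costs)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW")["editDistance"]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# pools, design, reference
# ---------------------------------------------------------------------------

@dataclass
class BarcodePool:
    position: int  # 1 | 2 | 3
    barcodes: list

    def __post_init__(self):
        if self.position not in (1, 2, 3):
            raise ValueError("position must be 1, 2 or 3")
        lens = {len(b) for b in self.barcodes}
        if len(lens) != 1:
            raise ValueError("pool barcodes must share one length")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("pool barcodes must be distinct")
        for b in self.barcodes:
            if any(c not in "ACGT" for c in b):
                raise ValueError("barcodes must be over {A,C,G,T}")

    @property
    def length(self) -> int:
        return len(self.barcodes[0])


@dataclass
class Assignment:
    """One read's demultiplexing outcome (a row of the assignment table)."""

    read_id: str
    bc1: str = ""
    bc2: str = ""
    bc3: str = ""
    umi: str = ""
    strand: str = "none"
    score: float = float("nan")
    round: int = 0  # 0 = unassigned

    @property
    def assigned(self) -> bool:
        return self.round > 0


@dataclass
class LibraryDesign:
    """Fixed read-structure pieces around the three barcodes."""

    anchor5: str = DEFAULT_ANCHOR5
    linker1: str = DEFAULT_LINKER1
    linker2: str = DEFAULT_LINKER2
    umi_len: int = 8
    oligo_dt_len: int = 20
    n_pad: int = 10

    def __post_init__(self):
        if not self.linker1 or not self.linker2:
            raise ValueError("linkers must be nonempty")
        if self.umi_len < 0 or self.oligo_dt_len < 0:
            raise ValueError("umi_len and oligo_dt_len must be >= 0")

    def label_segment_len(self, bc_len: int = 9) -> int:
        return 3 * bc_len + len(self.linker1) + len(self.linker2)


def build_barcode_pools(n: int = 96, length: int = 9,
                        min_pairwise_levenshtein: int = 2,
                        min_pairwise_hamming: int = 4, seed: int = 0,
                        max_tries: int = 200_000):
    """Three pools of distinct barcodes meeting minimum distances within
    and across pools, by seeded rejection sampling.

    The defaults (Levenshtein >= 2, Hamming >= 4 over 9 bp) reproduce the
    separation statistics of the commercial three-pool bead design
    (minimum Hamming 4, minimum Levenshtein 2 across composed labels).
    Set ``min_pairwise_hamming`` to 0 to constrain on edit distance only.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    accepted: list[str] = []
    tries = 0
    while len(accepted) < 3 * n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not build pools (n={n}, length={length}, "
                f"min distance {min_pairwise_levenshtein}) in {max_tries} tries")
        cand = "".join(bases[rng.integers(0, 4, size=length)])
        if all(levenshtein(cand, b) >= min_pairwise_levenshtein
               and (min_pairwise_hamming == 0
                    or hamming(cand, b) >= min_pairwise_hamming)
               for b in accepted):
            accepted.append(cand)
    return [BarcodePool(position=p + 1, barcodes=accepted[p * n:(p + 1) * n])
            for p in range(3)]


def load_barcode_pool(path, position: int) -> BarcodePool:
    """One barcode per line (e.g. a vendor whitelist file)."""
    with open(path) as fh:
        bcs = [ln.strip().upper() for ln in fh if ln.strip()]
    return BarcodePool(position=position, barcodes=bcs)


@dataclass
class CellLabelReference:
    """Composed three-part label space, stored factorised.

    Materialising all |pool1|*|pool2|*|pool3| composed sequences (up to
    96^3) is never needed: alignment scores over the label space decompose
    per slot.  ``all_labels`` enumerates them for small pools.
    """

    pools: list
    design: LibraryDesign = field(default_factory=LibraryDesign)

    def __post_init__(self):
        if len(self.pools) != 3:
            raise ValueError("need exactly three pools")

    @property
    def n_labels(self) -> int:
        return int(np.prod([len(p.barcodes) for p in self.pools]))

    def composed_label(self, bc1: str, bc2: str, bc3: str) -> str:
        d = self.design
        return (d.anchor5 + bc1 + d.linker1 + bc2 + d.linker2 + bc3
                + "N" * d.umi_len + "T" * d.oligo_dt_len)

    def reference_sequence(self, bc1: str, bc2: str, bc3: str) -> str:
        pad = "N" * self.design.n_pad
        return pad + self.composed_label(bc1, bc2, bc3) + pad

    @property
    def reference_length(self) -> int:
        p = self.pools
        d = self.design
        return (len(d.anchor5) + p[0].length + len(d.linker1) + p[1].length
                + len(d.linker2) + p[2].length + d.umi_len + d.oligo_dt_len)

    def all_labels(self):
        return ["".join(t) for t in itertools.product(
            *[p.barcodes for p in self.pools])]

    def scaffold(self):
        """Label template with barcode and UMI slots as N wildcards,
        ending in a short oligo-dT stub that pins the UMI boundary."""
        d = self.design
        p = self.pools
        parts = [d.anchor5, "N" * p[0].length, d.linker1, "N" * p[1].length,
                 d.linker2, "N" * p[2].length, "N" * d.umi_len,
                 "T" * min(6, d.oligo_dt_len)]
        seq = "".join(parts)
        offs = {}
        pos = 0
        names = ["anchor", "bc1", "linker1", "bc2", "linker2", "bc3", "umi",
                 "dt"]
        for name, part in zip(names, parts):
            offs[name] = (pos, pos + len(part))
            pos += len(part)
        return seq, offs


def compose_reference(pools, linker1: str = DEFAULT_LINKER1,
                      linker2: str = DEFAULT_LINKER2,
                      anchor5: str = DEFAULT_ANCHOR5, umi_len: int = 8,
                      oligo_dt_len: int = 20, n_pad: int = 10) -> CellLabelReference:
    design = LibraryDesign(anchor5=anchor5, linker1=linker1, linker2=linker2,
                           umi_len=umi_len, oligo_dt_len=oligo_dt_len,
                           n_pad=n_pad)
    return CellLabelReference(pools=list(pools), design=design)


def pool_distance_stats(sequences) -> dict:
    """Min/mean Hamming (equal-length pairs) and Levenshtein over all
    unordered pairs."""
    seqs = list(sequences)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ham, lev = [], []
    for a, b in itertools.combinations(seqs, 2):
        lev.append(levenshtein(a, b))
        if len(a) == len(b):
            ham.append(hamming(a, b))
    out = {"levenshtein_min": int(min(lev)),
           "levenshtein_mean": float(np.mean(lev))}
    if ham:
        out["hamming_min"] = int(min(ham))
        out["hamming_mean"] = float(np.mean(ham))
    return out


# ---------------------------------------------------------------------------
# strand detection
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _longest_run(seq: str, base: str) -> int:
    best = cur = 0
    for c in seq:
        cur = cur + 1 if c == base else 0
        best = max(best, cur)
    return best


def detect_strand(read: str, run_threshold: int = 6,
                  window: int = 150) -> str:
    """forward / reverse / none by the oligo-dT (dA) run position.

    A forward read carries a poly-T run in its 5' window; its reverse
    complement carries a poly-A run in the 3' window.  The longer of the
    two runs wins; below threshold (or a tie) the read is unresolved.
    """
    if not read:
        raise ValueError("empty read")
    t_run = _longest_run(read[:window], "T")
    a_run = _longest_run(read[-window:], "A")
    if max(t_run, a_run) < run_threshold or t_run == a_run:
        return "none"
    return "forward" if t_run > a_run else "reverse"


# ---------------------------------------------------------------------------
# round 1
# ---------------------------------------------------------------------------

def _map_template_to_read(cigar: str, read_start: int, template_len: int):
    """Read coordinate of every template position, from an edlib path."""
    pos = np.empty(template_len + 1, dtype=int)
    qpos, tpos = 0, read_start
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=XM":
            for _ in range(n):
                pos[qpos] = tpos
                qpos += 1
                tpos += 1
        elif ch == "I":  # consumes template (query) only
            for _ in range(n):
                pos[qpos] = tpos
                qpos += 1
        elif ch == "D":  # consumes read (target) only
            tpos += n
    pos[qpos:] = tpos
    return pos


def _slot_shortlist(window: str, pool: BarcodePool, k: int):
    """Indices of the k pool barcodes closest to a slot window."""
    d = np.fromiter((edlib.align(bc, window, mode="HW")["editDistance"]
                     for bc in pool.barcodes), dtype=int,
                    count=len(pool.barcodes))
    return np.argsort(d, kind="stable")[:k]


# Calibrated operating points (see docs/methods.md): "conservative" is the
# default two-round strategy; "optimized" is the single-round high-recall
# point.  Both use the two-tier rule: a loose distance cap with margin >= 2
# plus a strict cap with margin >= 1.
PRESETS = {
    "conservative": {"max_label_dist": 12, "min_margin": 2,
                     "strict_dist": 7, "max_scaffold_dist": 16,
                     "two_rounds": True, "bc_max_dist": 1,
                     "label_max_dist": 5},
    "optimized": {"max_label_dist": 12, "min_margin": 2,
                  "strict_dist": 7, "max_scaffold_dist": 16,
                  "two_rounds": False, "bc_max_dist": 1,
                  "label_max_dist": 6, "crosscheck_band": (8, 10),
                  "crosscheck_bc_dist": 2},
}


def demux_first_round(records, reference: CellLabelReference,
                      trim_len: int = 300, max_label_dist: int = 12,
                      min_margin: int = 2, strict_dist: int = 7,
                      max_scaffold_dist: int = 16,
                      run_threshold: int = 6, slot_slack: int = 3,
                      shortlist: int = 8) -> pd.DataFrame:
    """Assign each read by scaffold location + label-space alignment.

    The wildcard scaffold locates the label region in the trimmed window;
    each barcode slot's pool is scanned to shortlist candidates (the
    factorised prescreen over the 96^3 label space), and the shortlisted
    composed labels are rescored by a full alignment of
    anchor+bc1+linker1+bc2+linker2+bc3 against the located region.  The
    best label is assigned iff its distance and margin over the best
    differing label clear one of two tiers: distance <= ``max_label_dist``
    with margin >= ``min_margin``, or distance <= ``strict_dist`` with
    margin >= 1 (ties are conservatively unassigned).  Returns one row per
    read: bc1..bc3 ('' when unassigned), umi, strand, score (negative edit
    distance), margin and round (1 or 0).
    """
    if not reference.pools[0].barcodes:
        raise ValueError("empty reference pools")
    scaffold, offs = reference.scaffold()
    d = reference.design
    pools = reference.pools
    rows = []
    for rid, seq in records:
        strand = detect_strand(seq, run_threshold=run_threshold)
        if strand == "none":
            rows.append((rid, "", "", "", "", "none", np.nan, np.nan, 0,
                         "", "", ""))
            continue
        fwd = seq if strand == "forward" else _revcomp(seq)
        window = fwd[:trim_len]
        res = edlib.align(scaffold, window, mode="HW", task="path",
                          additionalEqualities=_N_EQUALITIES)
        if res["editDistance"] < 0 or res["editDistance"] > max_scaffold_dist:
            rows.append((rid, "", "", "", "", strand, np.nan, np.nan, 0,
                         "", "", ""))
            continue
        start = res["locations"][0][0]
        tmap = _map_template_to_read(res["cigar"], start, len(scaffold))
        cands = []
        for slot, pool in zip(("bc1", "bc2", "bc3"), pools):
            s, e = offs[slot]
            win = window[max(tmap[s] - slot_slack, 0): tmap[e] + slot_slack]
            cands.append(_slot_shortlist(win, pool, shortlist))
        a0 = offs["anchor"][0]
        b3 = offs["bc3"][1]
        region = window[max(tmap[a0] - 3, 0): tmap[b3] + 3]
        best = (10 ** 6, None)
        second = 10 ** 6
        for i1 in cands[0]:
            bcs1 = pools[0].barcodes[i1]
            for i2 in cands[1]:
                part = d.anchor5 + bcs1 + d.linker1 + pools[1].barcodes[i2] \
                    + d.linker2
                for i3 in cands[2]:
                    label = part + pools[2].barcodes[i3]
                    dist = edlib.align(label, region, mode="HW",
                                       k=max_label_dist + min_margin + 1
                                       )["editDistance"]
                    if dist < 0:
                        continue
                    key = (int(i1), int(i2), int(i3))
                    if dist < best[0]:
                        if best[1] is not None and best[1] != key:
                            second = best[0]
                        best = (dist, key)
                    elif key != best[1] and dist < second:
                        second = dist
        s, e = offs["umi"]
        umi = window[tmap[s]:tmap[s] + d.umi_len]
        margin = second - best[0]
        ok = best[1] is not None and (
            (best[0] <= max_label_dist and margin >= min_margin)
            or (best[0] <= strict_dist and margin >= 1))
        if best[1] is not None:
            i1, i2, i3 = best[1]
            cand = (pools[0].barcodes[i1], pools[1].barcodes[i2],
                    pools[2].barcodes[i3])
        else:
            cand = ("", "", "")
        if ok:
            rows.append((rid, *cand, umi, strand, -float(best[0]),
                         float(margin), 1, *cand))
        else:
            rows.append((rid, "", "", "", "", strand,
                         -float(best[0]) if best[1] is not None else np.nan,
                         float(margin) if best[1] is not None else np.nan, 0,
                         *cand))
    return pd.DataFrame(rows, columns=["read_id", "bc1", "bc2", "bc3", "umi",
                                       "strand", "score", "margin", "round",
                                       "cand_bc1", "cand_bc2", "cand_bc3"])


# ---------------------------------------------------------------------------
# round 2
# ---------------------------------------------------------------------------

def _pool_hits(seq: str, pool: BarcodePool, k: int):
    """Best-scoring occurrences of each pool barcode within distance k."""
    hits = []
    for bi, bc in enumerate(pool.barcodes):
        r = edlib.align(bc, seq, mode="HW", k=k, task="locations")
        if r["editDistance"] < 0:
            continue
        for s, e in r["locations"]:
            hits.append((r["editDistance"], s, e + 1, bi))
    return hits


def demux_second_round(records, reference: CellLabelReference,
                       linker_len_window: int = 5, bc_max_dist: int = 1,
                       label_max_dist: int = 6, umi_len: int | None = None,
                       require_strand: bool = True) -> pd.DataFrame:
    """Rescue reads by locating one barcode per pool in order.

    The three pools are aligned independently against the full (oriented)
    read; a candidate triple needs one barcode per pool, in order, each
    within ``bc_max_dist`` edits, with the two inter-barcode gaps within
    ``linker_len_window`` of the linker lengths.  Candidates are verified
    by aligning the full 52 bp label (barcodes plus linkers) over the
    spanned region -- at most ``label_max_dist`` edits -- and by an
    oligo-dT run shortly after the third barcode; the best-verifying
    label wins, ambiguity (two candidates at equal distance) leaves the
    read unassigned.  Reads without a strand signature are skipped by
    default.
    """
    d = reference.design
    pools = reference.pools
    umi_len = d.umi_len if umi_len is None else umi_len
    l1, l2 = len(d.linker1), len(d.linker2)
    rows = []
    for rid, seq in records:
        best = None
        tie = False
        best_strand = "none"
        best_umi = ""
        detected = detect_strand(seq)
        if require_strand and detected == "none":
            rows.append((rid, "", "", "", "", "none", np.nan, np.nan, 0))
            continue
        orients = [("forward", seq), ("reverse", _revcomp(seq))]
        if detected != "none":
            orients = [o for o in orients if o[0] == detected]
        for strand, s in orients:
            h1 = _pool_hits(s, pools[0], bc_max_dist)
            if not h1:
                continue
            h2 = _pool_hits(s, pools[1], bc_max_dist)
            if not h2:
                continue
            h3 = _pool_hits(s, pools[2], bc_max_dist)
            if not h3:
                continue
            for d1, s1, e1, b1 in h1:
                for d2_, s2, e2, b2 in h2:
                    if abs((s2 - e1) - l1) > linker_len_window:
                        continue
                    for d3, s3, e3, b3 in h3:
                        if abs((s3 - e2) - l2) > linker_len_window:
                            continue
                        label = (pools[0].barcodes[b1] + d.linker1
                                 + pools[1].barcodes[b2] + d.linker2
                                 + pools[2].barcodes[b3])
                        region = s[max(s1 - 3, 0): e3 + 3]
                        dist = edlib.align(label, region, mode="HW",
                                           k=label_max_dist)["editDistance"]
                        if dist < 0:
                            continue
                        if d.oligo_dt_len > 0 and _longest_run(
                                s[e3: e3 + umi_len + 24], "T") < 6:
                            continue
                        cand = (dist, b1, b2, b3)
                        if best is None or dist < best[0]:
                            best = cand
                            tie = False
                            best_strand = strand
                            best_umi = s[e3:e3 + umi_len]
                        elif dist == best[0] and cand[1:] != best[1:]:
                            tie = True
        if best is not None and not tie:
            rows.append((rid, pools[0].barcodes[best[1]],
                         pools[1].barcodes[best[2]],
                         pools[2].barcodes[best[3]], best_umi, best_strand,
                         -float(best[0]), np.nan, 2))
        else:
            rows.append((rid, "", "", "", "", "none", np.nan, np.nan, 0))
    return pd.DataFrame(rows, columns=["read_id", "bc1", "bc2", "bc3", "umi",
                                       "strand", "score", "margin", "round"])


def demux_reads(records, reference: CellLabelReference,
                preset: str = "conservative", trim_len: int = 300,
                **overrides) -> pd.DataFrame:
    """Full strategy: round 1 plus (for the conservative preset) round 2."""
    cfg = {**PRESETS[preset], **overrides}
    out = demux_first_round(
        records, reference, trim_len=trim_len,
        max_label_dist=cfg["max_label_dist"], min_margin=cfg["min_margin"],
        strict_dist=cfg["strict_dist"],
        max_scaffold_dist=cfg["max_scaffold_dist"])
    band = cfg.get("crosscheck_band")
    if band is not None:
        # borderline candidates (margin 1 at moderate distance) are kept
        # only when the independent per-pool route finds the same label
        lo, hi = band
        dist = -out["score"]
        sel = out.index[(out["round"] == 0) & (out["margin"] >= 1)
                        & dist.between(lo, hi) & (out["cand_bc1"] != "")]
        if len(sel):
            rec_map = dict(records)
            sub = demux_second_round(
                [(out.loc[k, "read_id"], rec_map[out.loc[k, "read_id"]])
                 for k in sel], reference,
                bc_max_dist=cfg.get("crosscheck_bc_dist", 2),
                label_max_dist=cfg["label_max_dist"]).set_index("read_id")
            for k in sel:
                v = sub.loc[out.loc[k, "read_id"]]
                if v["round"] == 2 and (
                        (v["bc1"], v["bc2"], v["bc3"])
                        == tuple(out.loc[k, ["cand_bc1", "cand_bc2",
                                             "cand_bc3"]])):
                    out.loc[k, ["bc1", "bc2", "bc3"]] = \
                        out.loc[k, ["cand_bc1", "cand_bc2", "cand_bc3"]].values
                    out.loc[k, "umi"] = v["umi"]
                    out.loc[k, "round"] = 1
    if cfg["two_rounds"]:
        lost = out[out["round"] == 0]["read_id"]
        rec_map = dict(records)
        rescued = demux_second_round(
            [(rid, rec_map[rid]) for rid in lost], reference,
            bc_max_dist=cfg["bc_max_dist"],
            label_max_dist=cfg["label_max_dist"])
        out = out.set_index("read_id")
        rescued = rescued.set_index("read_id")
        got = rescued[rescued["round"] == 2]
        out.loc[got.index, got.columns] = got
        out = out.reset_index()
    return out


# ---------------------------------------------------------------------------
# UMI correction
# ---------------------------------------------------------------------------

def dedup_umis(umis) -> dict:
    """Directional merge of UMIs within Hamming distance 1.

    Returns {representative: total count}; higher-count UMIs absorb
    lower-count neighbours.
    """
    counts = pd.Series(list(umis)).value_counts()
    reps: dict[str, int] = {}
    for umi, c in counts.items():
        merged = False
        for rep in reps:
            if len(rep) == len(umi) and hamming(rep, umi) <= 1:
                reps[rep] += int(c)
                merged = True
                break
        if not merged:
            reps[umi] = int(c)
    return reps


def correct_umis(assignments: pd.DataFrame, cell_cols=("bc1", "bc2", "bc3"),
                 gene_col: str = "gene") -> pd.DataFrame:
    """Collapse reads to molecules per (cell label, gene) UMI group.

    Rows without a UMI are excluded (their number is reported in the
    frame's ``attrs['n_missing_umi']``).
    """
    df = assignments.copy()
    missing = (df["umi"].isna()) | (df["umi"] == "")
    df = df[~missing]
    rows = []
    for key, grp in df.groupby([*cell_cols, gene_col], sort=False):
        for umi, n_reads in dedup_umis(grp["umi"]).items():
            rows.append((*key, umi, n_reads))
    out = pd.DataFrame(rows, columns=[*cell_cols, gene_col, "umi", "n_reads"])
    out.attrs["n_missing_umi"] = int(missing.sum())
    return out


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class DemuxMetrics:
    tpr: float
    fpr: float
    fnr: float
    precision: float
    demux_rate: float
    n_reads: int
    n_barcoded: int
    tp: int
    fp: int
    fn: int


def evaluate_demux(assignments: pd.DataFrame, truth: pd.DataFrame) -> DemuxMetrics:
    """Confusion metrics against the simulation truth table.

    TP: assigned to the true label; FP: assigned to any wrong label
    (including assignments of structureless reads); FN: truly barcoded but
    unassigned.  TPR/FNR are over truly barcoded reads, FPR over all
    reads; precision = TP/(TP+FP); demux_rate = assigned/total.
    """
    a = assignments.set_index("read_id")
    t = truth.set_index("read_id")
    if set(a.index) != set(t.index):
        raise ValueError("assignments and truth cover different read sets")
    t = t.loc[a.index]
    assigned = a["round"].to_numpy() > 0
    barcoded = t["barcoded"].to_numpy().astype(bool)
    correct = (assigned & barcoded
               & (a["bc1"].to_numpy() == t["bc1"].to_numpy())
               & (a["bc2"].to_numpy() == t["bc2"].to_numpy())
               & (a["bc3"].to_numpy() == t["bc3"].to_numpy()))
    tp = int(correct.sum())
    fp = int((assigned & ~correct).sum())
    fn = int((barcoded & ~assigned).sum())
    n = len(a)
    nb = int(barcoded.sum())
    return DemuxMetrics(
        tpr=tp / nb if nb else 0.0,
        fpr=fp / n if n else 0.0,
        fnr=fn / nb if nb else 0.0,
        precision=tp / (tp + fp) if (tp + fp) else 0.0,
        demux_rate=float(assigned.mean()) if n else 0.0,
        n_reads=n, n_barcoded=nb, tp=tp, fp=fp, fn=fn)
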
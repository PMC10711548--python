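"""Synthetic data with the statistical structure the analyses assume.

Three families of fixtures are generated here, all seedable and fully
truth-tracked so downstream estimators can be scored against ground truth:

* kinetic cell populations -- per-gene rates drawn from priors, per-cell
  latent times uniform on [0, 4*t_switch] (covering induction, the
  approach to steady state, and repression), counts either noiseless
  (equal to the closed-form trajectory) or Poisson around it;
* gene annotations -- random multi-exon gene models emitted as GTF with
  the per-base exon/intron truth retained, plus aligned-block reads drawn
  from truth count matrices for quantification round-trips;
* barcoded long reads -- three-part cell labels with linkers, UMI and
  oligo-dT, written as FASTQ after i.i.d. substitution/insertion/deletion
  errors, with a complete per-read truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AlignedRead, GeneModel, Transcript
from .velocity import (TrajectoryParams, simulate_spliced_trajectory,
                       simulate_trajectory)

__all__ = [
    "ErrorModel", "SyntheticPopulation", "DEFAULT_PRIORS",
    "generate_population", "truncate_counts", "generate_annotation",
    "inject_errors", "generate_reads", "generate_alignments",
    "random_sequence", "reverse_complement",
]

BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# kinetic populations
# ---------------------------------------------------------------------------

# Priors chosen to emulate the study conditions: theta spans typical
# intronic fractions; gamma < beta = 1 because mRNA degradation (hours) is
# slower than splicing (minutes) -- this also keeps the intron signal the
# leading indicator, giving the phase portrait its spindle orientation
# (induction above the steady-state line); t_switch is long enough that
# induction approaches steady state; the expression scale puts peak
# expected counts in the tens (sequencing-depth regime of droplet /
# microwell long-read data).
DEFAULT_PRIORS = {
    "theta": (0.2, 0.6),
    "gamma": (0.2, 0.8),
    "t_switch": (2.0, 4.0),
    "expression_scale": (30.0, 100.0),
}


@dataclass
class SyntheticPopulation:
    """Count matrices (cells x genes) plus complete generation truth."""

    exon: np.ndarray
    intron: np.ndarray
    spliced: np.ndarray
    unspliced: np.ndarray
    expected_exon: np.ndarray
    expected_intron: np.ndarray
    expected_spliced: np.ndarray
    expected_unspliced: np.ndarray
    cell_truth: pd.DataFrame  # latent_time, phase per cell
    params: list  # TrajectoryParams per gene
    barcodes: list
    gene_ids: list


def _draw_params(n_genes: int, priors: dict, rng: np.random.Generator):
    priors = {**DEFAULT_PRIORS, **(priors or {})}
    for key, (lo, hi) in priors.items():
        if lo > hi:
            raise ValueError(f"prior {key}: min {lo} > max {hi}")
        if key != "theta" and lo <= 0:
            raise ValueError(f"prior {key}: rates must be positive")
    out = []
    for _ in range(n_genes):
        th = rng.uniform(*priors["theta"])
        g = rng.uniform(*priors["gamma"])
        ts = rng.uniform(*priors["t_switch"])
        scale = np.exp(rng.uniform(np.log(priors["expression_scale"][0]),
                                   np.log(priors["expression_scale"][1])))
        # alpha set so the steady-state total e+i equals the drawn scale
        alpha = scale / (th / 1.0 + (1.0 - th) / g)
        out.append(TrajectoryParams(alpha=alpha, gamma=g, theta=th,
                                    t_switch=ts))
    return out


def generate_population(n_cells: int, n_genes: int, param_priors: dict | None = None,
                        noise: str = "poisson", seed: int = 0,
                        params: list | None = None,
                        latent_times: np.ndarray | None = None) -> SyntheticPopulation:
    """Simulate a cell population along per-gene kinetic trajectories.

    Every cell has one latent time shared by all genes (a 1-D
    differentiation axis); each gene follows its own closed-form (e, i)
    trajectory, and the matched classic (s, u) trajectories are generated
    from the same rates for baseline comparisons.  ``noise`` is "none"
    (counts equal expectations) or "poisson".
    """
    if n_cells < 1 or n_genes < 1:
        raise ValueError("n_cells and n_genes must be >= 1")
    if noise not in ("none", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")
    rng = np.random.default_rng(seed)
    if params is None:
        params = _draw_params(n_genes, param_priors, rng)
    elif len(params) != n_genes:
        raise ValueError("params length must equal n_genes")

    # common developmental axis scaled per gene to its own switch time
    u01 = rng.uniform(0.0, 1.0, size=n_cells) if latent_times is None \
        else np.asarray(latent_times, dtype=float)
    E = np.empty((n_cells, n_genes))
    I = np.empty((n_cells, n_genes))
    S = np.empty((n_cells, n_genes))
    U = np.empty((n_cells, n_genes))
    for g, p in enumerate(params):
        t = u01 * 4.0 * p.t_switch
        tr = simulate_trajectory(p, t=t)
        E[:, g], I[:, g] = tr.e, tr.i
        sp = simulate_spliced_trajectory(p, t=t)
        S[:, g], U[:, g] = sp.e, sp.i

    if noise == "poisson":
        exon = rng.poisson(E).astype(float)
        intron = rng.poisson(I).astype(float)
        spliced = rng.poisson(S).astype(float)
        unspliced = rng.poisson(U).astype(float)
    else:
        exon, intron, spliced, unspliced = E.copy(), I.copy(), S.copy(), U.copy()

    # phase is taken against the first gene's switch time scaling: by
    # construction every gene switches at the same fraction of the axis
    phase = np.where(u01 <= 0.25, "induction", "repression")
    truth = pd.DataFrame({"latent_fraction": u01, "phase": phase})
    barcodes = [f"cell{k:05d}" for k in range(n_cells)]
    gene_ids = [f"gene{k:04d}" for k in range(n_genes)]
    return SyntheticPopulation(exon=exon, intron=intron, spliced=spliced,
                               unspliced=unspliced, expected_exon=E,
                               expected_intron=I, expected_spliced=S,
                               expected_unspliced=U, cell_truth=truth,
                               params=list(params), barcodes=barcodes,
                               gene_ids=gene_ids)


def truncate_counts(spliced, unspliced, detect_rate=None, seed: int = 0,
                    detectable_fraction: float = 0.25,
                    background_rate: float = 0.02):
    """Emulate 3'-biased short-read detection of unspliced molecules.

    A short 3' window only reveals an intron when one happens to sit near
    the 3' end, so detection is gene-structural and bimodal: a gene either
    has an intron inside the window (detection rate drawn from
    U(0.5, 1)) or it does not (residual rate ``background_rate``).  With a
    quarter of genes detectable this reproduces the aggregate drop of the
    observed unspliced fraction from the ~24% seen by full-length reads to
    the ~8% seen by 3' counting.  Missed unspliced molecules are misread
    as spliced (binomial thinning conserves molecules).  ``detect_rate``
    overrides the per-gene rates directly.
    """
    rng = np.random.default_rng(seed)
    S = np.asarray(spliced, dtype=float)
    U = np.asarray(unspliced, dtype=float)
    n_genes = S.shape[1]
    if detect_rate is None:
        detectable = rng.random(n_genes) < detectable_fraction
        p = np.where(detectable, rng.uniform(0.5, 1.0, n_genes),
                     background_rate)
    else:
        p = np.broadcast_to(np.asarray(detect_rate, dtype=float), (n_genes,))
    U_int = np.round(U).astype(int)
    U_obs = rng.binomial(U_int, p[None, :]).astype(float)
    S_obs = S + (U_int - U_obs)
    return S_obs, U_obs, p


# ---------------------------------------------------------------------------
# annotations and aligned reads
# ---------------------------------------------------------------------------

def generate_annotation(n_genes: int, exons_per_gene_range=(2, 5),
                        exon_len_range=(80, 300), intron_len_range=(30, 500),
                        seed: int = 0, chrom: str = "chr1",
                        gap_between_genes: int = 1000):
    """Random non-overlapping gene models plus per-base region truth.

    Returns (gene_models, truth) where truth maps gene_id to its exact
    exon and intron interval lists (0-based half-open).  Intron lengths of
    1 are allowed so the 20 bp intronic-calling rule can be exercised.
    """
    for name, (lo, hi) in (("exons_per_gene", exons_per_gene_range),
                           ("exon_len", exon_len_range),
                           ("intron_len", intron_len_range)):
        if lo > hi:
            raise ValueError(f"{name} range has min > max")
        if lo < 1:
            raise ValueError(f"{name} range must be >= 1")
    rng = np.random.default_rng(seed)
    genes = {}
    truth = {}
    pos = 1000
    for g in range(n_genes):
        gid = f"gene{g:04d}"
        n_ex = int(rng.integers(exons_per_gene_range[0],
                                exons_per_gene_range[1] + 1))
        exons = []
        introns = []
        cur = pos
        for k in range(n_ex):
            ex_len = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
            exons.append((cur, cur + ex_len))
            cur += ex_len
            if k < n_ex - 1:
                in_len = int(rng.integers(intron_len_range[0],
                                          intron_len_range[1] + 1))
                introns.append((cur, cur + in_len))
                cur += in_len
        strand = "+" if rng.random() < 0.5 else "-"
        gm = GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                       transcripts=[Transcript(f"{gid}.t1", exons)])
        genes[gid] = gm
        truth[gid] = {"exons": exons, "introns": introns}
        pos = cur + gap_between_genes
    return genes, truth


def generate_alignments(spliced, unspliced, gene_models: dict, barcodes,
                        gene_ids, seed: int = 0, umi_len: int = 8,
                        max_duplicates: int = 1):
    """Emit aligned-block reads realising given spliced/unspliced truth.

    Spliced molecules produce one block per exon; unspliced molecules
    produce a single contiguous genomic block spanning the transcript
    (introns retained).  Each molecule gets a unique UMI per (cell, gene)
    and 1..max_duplicates duplicate reads.  Returns (reads, truth_frame).
    """
    rng = np.random.default_rng(seed)
    S = np.round(np.asarray(spliced)).astype(int)
    U = np.round(np.asarray(unspliced)).astype(int)
    reads = []
    rows = []
    rid = 0
    for ci, cell in enumerate(barcodes):
        for gi, gid in enumerate(gene_ids):
            gm = gene_models[gid]
            tr = gm.transcripts[0]
            n_mol = S[ci, gi] + U[ci, gi]
            if n_mol == 0:
                continue
            umis = set()
            while len(umis) < n_mol:
                umis.add(random_sequence(umi_len, rng))
            umis = sorted(umis)
            for m, umi in enumerate(umis):
                is_spliced = m < S[ci, gi]
                if is_spliced or len(tr.exons) == 1:
                    blocks = list(tr.exons)
                else:
                    blocks = [(tr.exons[0][0], tr.exons[-1][1])]
                n_dup = int(rng.integers(1, max_duplicates + 1))
                for _ in range(n_dup):
                    reads.append(AlignedRead(f"read{rid:07d}", cell, umi,
                                             gm.chrom, gm.strand, blocks))
                    rows.append((f"read{rid:07d}", cell, umi, gid,
                                 bool(is_spliced)))
                    rid += 1
    truth = pd.DataFrame(rows, columns=["read_id", "cell", "umi", "gene",
                                        "spliced"])
    return reads, truth


# ---------------------------------------------------------------------------
# barcoded reads with sequencing errors
# ---------------------------------------------------------------------------

@dataclass
class ErrorModel:
    """i.i.d. per-base substitution / insertion / deletion probabilities."""

    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0

    def __post_init__(self):
        rates = (self.sub_rate, self.ins_rate, self.del_rate)
        if any(r < 0 or r > 1 for r in rates):
            raise ValueError("error rates must lie in [0, 1]")
        if sum(rates) > 1:
            raise ValueError("sub+ins+del must be <= 1")

    @property
    def total(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate

    @classmethod
    def uniform(cls, total: float) -> "ErrorModel":
        """Split a total error rate as 50% sub, 25% ins, 25% del."""
        return cls(sub_rate=0.5 * total, ins_rate=0.25 * total,
                   del_rate=0.25 * total)


def inject_errors(sequence: str, error_model: ErrorModel,
                  rng: np.random.Generator) -> str:
    """Apply i.i.d. errors; substitutions uniform over the 3 alternatives,
    insertions uniform over 4 bases (inserted before the current base)."""
    if any(b not in "ACGT" for b in sequence):
        raise ValueError("sequence must be over {A,C,G,T}")
    em = error_model
    if em.total == 0:
        return sequence
    n = len(sequence)
    r = rng.random(n)
    out = []
    for k, base in enumerate(sequence):
        x = r[k]
        if x < em.del_rate:
            continue
        if x < em.del_rate + em.ins_rate:
            out.append(BASES[rng.integers(0, 4)])
            out.append(base)
        elif x < em.del_rate + em.ins_rate + em.sub_rate:
            alts = [b for b in "ACGT" if b != base]
            out.append(alts[rng.integers(0, 3)])
        else:
            out.append(base)
    return "".join(out)


def generate_reads(whitelist, n_reads: int, error_model: ErrorModel,
                   design, seed: int = 0,
                   strand_probs=(0.47, 0.40, 0.13),
                   cdna_len_range=(200, 600)):
    """Simulate barcoded long reads over a composed whitelist.

    Each structured read is 5' anchor + bc1 + linker1 + bc2 + linker2 +
    bc3 + UMI + oligo-dT + reverse-complemented cDNA, emitted forward or
    reverse-complemented; the remaining fraction is structureless random
    sequence (no true label).  Default strand mix 47% forward / 40%
    reverse / 13% structureless, matching the observed library structure.
    Errors are injected over the whole read.  Returns (records, truth).
    """
    whitelist = list(whitelist)
    if not whitelist:
        raise ValueError("whitelist must be nonempty")
    if abs(sum(strand_probs) - 1.0) > 1e-9:
        raise ValueError("strand_probs must sum to 1")
    rng = np.random.default_rng(seed)
    records = []
    rows = []
    for k in range(n_reads):
        rid = f"read{k:06d}"
        u = rng.random()
        cdna = random_sequence(int(rng.integers(*cdna_len_range)), rng)
        if u < strand_probs[0] + strand_probs[1]:
            bc1, bc2, bc3 = whitelist[rng.integers(0, len(whitelist))]
            umi = random_sequence(design.umi_len, rng)
            seq = (design.anchor5 + bc1 + design.linker1 + bc2
                   + design.linker2 + bc3 + umi
                   + "T" * design.oligo_dt_len + reverse_complement(cdna))
            seq = inject_errors(seq, error_model, rng)
            strand = "forward"
            if u >= strand_probs[0]:
                seq = reverse_complement(seq)
                strand = "reverse"
            rows.append((rid, bc1, bc2, bc3, umi, strand, True))
        else:
            seq = random_sequence(int(rng.integers(*cdna_len_range)) + 100, rng)
            rows.append((rid, "", "", "", "", "none", False))
        records.append((rid, seq))
    truth = pd.DataFrame(rows, columns=["read_id", "bc1", "bc2", "bc3",
                                        "umi", "strand", "barcoded"])
    return records, truth
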
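# Methods

## The kinetic model

Each gene follows a two-phase transcription program: induction with
constant rate α until the switch time *t*ₛ, then repression (α = 0),
observed over the window [0, 4·*t*ₛ]. The intronic and exonic signals
evolve as

    di/dt = θ·α(t) − β·i(t)
    de/dt = (1−θ)·α(t) − γ·e(t)

β is fixed at 1, which defines the time unit; all other rates are
per-unit-time relative to splicing. Both equations have closed forms
(saturating exponentials during induction, pure decay after the switch),
implemented in `velocity.simulate_trajectory` and verified in the tests
against an independent fixed-step RK4 integrator at 1e-8 relative error.
The classic spliced/unspliced cascade (du/dt = α − βu,
ds/dt = βu − γs) is implemented alongside as the comparison baseline.

Model assumptions worth keeping in mind:

- **Loop orientation requires γ < β.** The intron and exon pools are
  parallel outputs of transcription, not a cascade. The intron pool
  leads (sits above the steady-state line during induction) only when it
  equilibrates faster than the exon pool decays, i.e. γ < β. This holds
  biologically — splicing takes minutes, mRNA decay hours — and the
  synthetic generator's γ prior (0.2–0.8) reflects it. At γ = β the
  phase portrait degenerates to a straight line and the loop direction,
  and with it the switch time, loses identifiability.
- **The steady-state velocity is a quasi-steady-state estimate.** The
  per-cell velocity vₑ = ((1−θ)/θ)·i − γ·e substitutes α ≈ i/θ, which is
  exact once the intron pool has equilibrated (t ≳ 2/β into induction)
  and biased low before that. The dynamical (EM) velocity does not make
  this substitution and stays unbiased in the transient.

## Steady-state estimation

Counts are first pooled over each cell's k nearest neighbours in PCA
space (k = 10 by default, with a balanced cap of 4k on how often a cell
may serve as neighbour). Per gene:

- slope: zero-intercept least squares of *i* on *e* restricted to the
  top and bottom `fit_quantile` (default 0.05) of exon expression — the
  extreme-quantile fit is robust to cells far from steady state;
- gene filters: Pearson correlation of *i* with *e* ≥ 0.2 and slope
  ≥ 0.2 (defaults);
- θ: three estimators are provided. `quantile_ratio` (default) is the
  count ratio Σi/(Σi+Σe) over the top expression quantile. On
  steady-state data this equals θγ/(θγ + (1−θ)β): it is exact when
  γ = β and biased otherwise, and because the implied γ̂ then collapses
  towards β, the steady-state stage should be read as estimating the
  *slope* (which fully determines velocity directions — θ only rescales
  each gene's velocity by a positive factor). `induction_slope` instead
  fits the origin limb of the portrait, where di/de → θ/(1−θ) as t → 0,
  and does not require γ = β but needs off-steady-state cells.
  `population_ratio` is the whole-population count ratio. When unbiased
  per-gene rates matter, use the dynamical fit.

## Dynamical EM fit

`fit_dynamical_em` treats each cell's latent time as missing data with a
uniform prior on [0, 4·*t*ₛ] (the observation window). The E-step
computes soft responsibilities over a dense time grid; the M-step refits
the steady levels A = θα and C = (1−θ)α/γ, the rate γ, and the Gaussian
noise scales from expected sufficient statistics. The switch time is the
outer profile-likelihood parameter: a coarse log-grid scan over
[0.5, 10], local refinement around the best candidate (each candidate
refitted by the inner EM, warm-started from the running best as a guard
against inner local optima), and a final parabolic interpolation. With
β = 1, (α, γ, θ, *t*ₛ) are identifiable from the two limbs of the
spindle plus the cell density along them: the intron asymptote gives A,
the exon asymptote gives C, the limb curvature gives γ, and
α = A + γC, θ = A/α.

Numerical choices: the latent grid has 200 points for the EM sweeps and
600 for switch-time likelihood evaluations (the finer quadrature is what
makes the *t*ₛ profile unimodal); the noise scales are floored at 2% of
each dimension's spread so the grid sum remains a faithful approximation
of the continuum time integral — with a smaller floor the likelihood
spuriously rewards shrinking the time span; cell sets larger than
`max_cells` (600) are deterministically subsampled, the fit being
sampling-noise limited well below that size. The marginal Gaussian
log-likelihood is returned and ranks driver genes (clean spindles score
high). `dynamical_velocity` combines per-gene fits through a consensus
pseudotime (median of per-gene latent-time fractions), which resolves
the ambiguity of cells near the origin of expression space where a
single gene cannot distinguish the start of induction from the end of
repression.

## Demultiplexing

The cell label is bc1+linker1+bc2+linker2+bc3 (3×9 bp barcodes, 12 and
13 bp linkers → 52 bp), preceded by an 18 bp anchor and followed by an
8 bp UMI and 20 bp oligo-dT — a 98-base composed reference, N-padded at
both ends. Barcode pools are built by seeded rejection sampling at
minimum pairwise Hamming 4 and Levenshtein 2 (within and across pools),
matching the separation statistics of the commercial three-pool bead
design.

Round 1: reads are oriented by their oligo-dT (poly-T run in the 5′
window) or oligo-dA signature, trimmed to 300 bp, and the label region
is located by aligning a wildcard scaffold (anchor + N-slots + linkers +
oligo-dT stub) with edit-distance alignment (edlib). Each barcode slot's
pool is scanned to shortlist candidates — the factorisation of the 96³
label space over the three slots is what keeps this fast — and the
shortlisted composed labels are rescored by a full alignment over the
label region. Assignment uses a two-tier rule on (distance, margin to
the best differing label): distance ≤ 12 with margin ≥ 2, or distance
≤ 7 with margin ≥ 1; borderline candidates (distance 8–10, margin 1) in
the high-recall preset are kept only when an independent per-pool
alignment route finds the same label. Ties are never assigned.

Round 2 (conservative preset) rescues reads that trimming or a defective
linker lost: each pool is aligned against the full read; a read is
recovered only when one barcode per pool occurs in order, gaps within
±5 bp of the linker lengths, the 52 bp label verifies over the spanned
region within 5 edits, and an oligo-dT run follows the third barcode.

The two preset operating points were calibrated once on simulated reads
(10% per-base error, i.i.d. substitution/insertion/deletion at
50/25/25%): "conservative" (two rounds) recovers about two-thirds of
barcoded reads at precision ≈ 0.96; "optimized" (single round) reaches
TPR ≈ 0.70 at FPR ≈ 0.02. UMIs are corrected per (cell, gene) by
directional merging within Hamming distance 1.

## Quantification

Annotated exons are merged per gene across transcripts; introns are the
merged gaps between consecutive exons, trimmed where they would overlap
merged exons (exon precedence) and dropped when not longer than 20 bp. A
read is assigned to the gene its blocks overlap most (ties discarded),
and is intronic — hence an unspliced transcript — when its summed
overlap with the intron set exceeds 20 bp (a per-intron mode is
available). Molecules (UMI-deduplicated read groups) increment spliced
or unspliced once each, exon when any read touches an exon, intron when
any read qualifies as intronic. Cells are called from the log-log
barcode-rank curve (knee = maximum negative curvature of a smoothing
spline, inflection = minimum first derivative); barcodes detecting fewer
than 20 genes define the ambient profile, against which candidates are
tested by Monte-Carlo multinomial likelihood (nulls shared across 5%
depth bins, per-count likelihood compared), Benjamini–Hochberg corrected
at FDR 0.01, with everything at or above the knee retained.

## Embedding projection and evaluation

Transition scores are Pearson correlations between a cell's predicted
expression change and each embedding neighbour's expression offset,
passed through an exponential kernel (σ = 0.05 on the correlation
scale, 50 neighbours by default); arrows are expected unit displacements
minus the neighbourhood null, averaged on a 20×20 grid for display.
Observed directions come from a local principal-axis (total
least-squares) regression over embedding neighbours — the embedding has
no privileged axis — signed by an ordering signal; a prediction succeeds
when the angle to the observed direction is strictly below 90°.
Gene-level tendency matching compares the sign of each gene's predicted
change with the sign of the change toward ordering-forward neighbours.

## What the synthetic data does and does not emulate

`generate_population` draws per-gene rates from priors chosen as
realistic study conditions — θ ∈ (0.2, 0.6), γ ∈ (0.2, 0.8) (degradation
slower than splicing, see above), *t*ₛ ∈ (2, 4), steady-state totals of
30–100 molecules — and places cells uniformly along [0, 4·*t*ₛ] on a
single shared differentiation axis, with optional Poisson count noise.
`truncate_counts` emulates 3′-window short-read detection of unspliced
molecules as gene-structural and bimodal: a quarter of genes have an
intron within the window (detection 0.5–1), the rest only a 2% residual
rate, reproducing the aggregate drop of the observed unspliced fraction
from ~24% (full-length) to ~8% (3′ counting); missed unspliced molecules
are misread as spliced, conserving totals. Barcoded reads carry i.i.d.
per-base errors with a 47/40/13 forward/reverse/structureless strand
mix.

Not emulated: multiple lineages or branching trajectories, gene–gene
correlation beyond the shared latent time, ONT homopolymer- and
signal-level error structure, ambient RNA contamination of called
cells, and isoform diversity within genes. Passing tests therefore show
that the estimators recover the generating kinetic model under
realistic counting noise and barcode corruption — not that they are
robust to everything real data does.

## Benchmark problem sizes

The shipped checks use 10,000 simulated reads for the demultiplexing
operating point; 100 genes × 2,000 cells (Poisson, kNN-pooled, EM on up
to 500 cells per gene) for parameter recovery; 8 noiseless genes on a
regular 700-point time grid for switch-time recovery; and 1,000 cells ×
80 genes for the velocity-field benchmark, with latent times drawn on
the interior [0.04, 0.92] of the unit window so that undecayed early
cells and fully decayed late cells do not coincide at the origin of
expression space (where neither an observed nor a predicted direction
is well defined).

## Known limitations

- The steady-state θ estimator cannot separate θ from γ using
  steady-state cells alone (only the slope is identified); unbiased
  per-gene rates require the dynamical fit.
- The switch time is weakly identified when induction saturates long
  before the switch (*t*ₛ ≫ 1/γ) and unidentified at γ = β; accuracy
  degrades accordingly.
- The demultiplexer assumes the library's fixed read architecture;
  reads with rearranged structure are only reachable by round 2.
- Cell calling assumes the ambient pool is well represented by barcodes
  detecting fewer than 20 genes; very deep ambient contamination would
  need the threshold raised.
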
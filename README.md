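# regionvelo

RNA velocity infers where a cell is heading by comparing precursor and
mature transcript abundances. Short-read single-cell data supports this
only weakly: the unspliced signal is read from a narrow 3′ window and is
missed for most genes. Full-length single-cell platforms (microwell +
nanopore, or droplet + PacBio) see the entire molecule, so every
transcript yields exon *and* intron evidence. **Region velocity** exploits
this: instead of spliced/unspliced molecule counts it models the exonic
count *e(t)* and intronic count *i(t)* of each gene,

```
di/dt = θ·α(t) − β·i(t)
de/dt = (1−θ)·α(t) − γ·e(t)
```

with transcription rate α (on during induction, zero after the switch
time *t*ₛ), splicing rate β (fixed to 1, anchoring the time unit),
degradation rate γ, and θ the intronic fraction of nascent transcription.
At steady state γ = (i/e)·(1−θ)/θ, estimated per gene by extreme-quantile
regression of *i* on *e*; the per-cell velocity is
vₑ = ((1−θ)/θ)·i − γ·e, extrapolated and projected onto a 2-D embedding
as a gridded vector field. A dynamical variant integrates the latent time
out against a uniform prior and fits all four parameters by EM.

The package is aimed at people building or evaluating velocity methods
for full-length single-cell RNA-seq. It covers the full path from raw
long reads to a velocity field:

- `regionvelo.demux` — two-round demultiplexing of reads carrying a
  three-part 52 bp cell label (three 9 bp barcodes from pools of 96,
  joined by two linkers), with UMI correction and confusion metrics;
- `regionvelo.regionquant` — exon/intron/spliced/unspliced count matrices
  from spliced-alignment blocks (a read is unspliced when its overlap
  with annotated introns exceeds 20 bp), plus barcode-rank cell calling;
- `regionvelo.velocity` — steady-state and dynamical (EM) region
  velocity, and the classic spliced/unspliced baseline;
- `regionvelo.flowmap` — embedding projection and the angular-separation
  / tendency-match evaluation metrics;
- `regionvelo.synthkit` — seeded synthetic populations, annotations and
  error-injected barcoded reads with complete ground truth, so the whole
  pipeline is testable without any sequencing data.

## Worked example

```python
import numpy as np
from sklearn.decomposition import PCA
from regionvelo import synthkit as sk, velocity as vel, flowmap

pop = sk.generate_population(n_cells=500, n_genes=40, noise="poisson", seed=0)
pcs = PCA(n_components=10, random_state=0).fit_transform(
    np.log1p(pop.exon + pop.intron))
Ep, Ip = vel.pool_knn([pop.exon, pop.intron], pcs, k=10)

cfg = vel.VelocityConfig(theta_mode="induction_slope")
kin = vel.fit_kinetics(Ep, Ip, cfg)
V, E_next = vel.region_velocity(Ep, Ip, kin)
g = kin.index[kin.passes_filter][0]
res = vel.fit_dynamical_em(Ep[:, g], Ip[:, g])
```

which prints, for the first passing gene of this simulated population:

```
37/40 genes pass the velocity filters
gene 0: slope=0.489  theta=0.430  gamma=0.647  corr=0.833
EM fit:  theta=0.497  gamma=0.369  t_switch=2.01  loglik=-3988.5
truth:   theta=0.455  gamma=0.362  t_switch=2.08
direction success: 90.2% of cells < 90 degrees
```

The steady-state fit recovers the phase-portrait slope and a usable θ;
the dynamical EM fit recovers θ, γ and the transcription switch time of
the generating model. Projecting the extrapolated states onto a (latent
time, noise) embedding and comparing each cell's arrow with the locally
regressed observed direction scores 90% of cells within 90°.

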
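# Methods

## The measurement model

The pipeline assumes the standard isobaric-labeling setup for mutant
libraries: each multiplex experiment ("plex") measures one channel per
sample, and channel intensities are only comparable within a plex.  Because
a typical library screen has no dedicated wild-type channel in every plex,
the across-mutant median of each protein within the plex serves as the
reference — valid as long as most mutants leave a given protein unchanged.
The same logic applies to RNA: per-gene transcript density (strand-summed
coverage / gene length) is referenced to the across-mutant median density.

Two consequences of the median reference are worth keeping in mind:

- Per (protein, plex), the median **linear** fold change is exactly 1 by
  construction.  The median **log** fold change is exactly 0 only for an odd
  number of samples (the median of logs is the mean of the two middle logs
  for even counts).  Tests assert the linear invariant, which is exact in
  both cases.
- A genuine shift shared by more than half the mutants of a plex would be
  absorbed into the reference.  The simulator never creates this situation
  (each deletion affects only its own operon), and in real libraries it
  would require a majority of mutants perturbing the same protein.

## Channel calibration

`normalize_intensities` offers two methods:

- `median_log` rescales each column so the median log2 intensity matches the
  plex's first column.  Simple, rank-preserving, removes pure pipetting /
  loading factors.
- `vsn_like` fits a per-column affine calibration (scale `a > 0`, offset
  `b`) by robustly minimizing the between-column spread of
  `asinh(a*x + b)` (a generalized-log transform) across proteins, iterating
  column fits against the per-protein consensus with a soft-L1 loss.  This
  is a deliberate simplification of variance-stabilizing normalization:
  affine calibration plus glog, without the full maximum-likelihood variance
  model.  The fit warm-starts from the `median_log` scales and the scale is
  bounded within e^±3 of that start, which removes the degenerate zero-scale
  optimum that the robust loss otherwise admits on data with no shared
  row structure.  Each fold-change table records nothing about the method;
  the run log does.

Replicate fold changes are averaged on the log2 scale by default (symmetric
for up/down effects); a linear-scale option exists because the averaging
scale is a genuine free choice.

## Positioning and the operon median correction

Operon tables list genes in transcription order (EcoCyc-style); that order,
not the strand, defines upstream/downstream.  When gene strands contradict
the listed order, a warning is logged and the order wins.  Positions are the
signed index offsets from the deleted gene; position 0 (the deleted gene's
own product) is kept in fold-change tables but excluded from every operon
statistic.  Intergenic distance is

```
d = (first nt of downstream start codon) − (last nt of deleted stop codon) − 1
```

so abutting ORFs give 0 and overlapping ORFs are negative.  Distances use
wild-type coordinates: the cassette preserves the deleted gene's last 21 nt,
so the wild-type stop is the relevant anchor.  Any fixed offset convention
is a monotone transform of any other, so rank statistics are unaffected.

The correction subtracts, per (mutant, side), the median log2 fold change of
that side's genes.  The downstream median **includes** the +1 gene by
default, following the plain reading of "all genes located downstream"; the
alternative (reference over positions ≥ +2 only) is exposed as
`include_p1_in_downstream_median=False`.  The default is the conservative
choice for testing the +1 deficit — the deficit partially drags its own
reference down, shrinking the corrected value — whereas the exclude-+1
variant gives an unshrunk estimate and is what `recovery_report` uses to
estimate the deficit magnitude.  Corrected values are only emitted when at
least `min_genes = 2` genes are quantified on the side, so a side median is
never computed from a single gene.

## Classification and tests

Operon-level classification uses the median of **uncorrected** values at
positions ≥ +2 (the +1 gene is excluded because it carries its own
gene-specific effect): `up` if median > 1 log2 (strictly; "at least 2-fold"
maps to strict > on the log2 median), `down` if < −1, `not_evaluable` with
no such genes.

The +1 test is a two-sample Wilcoxon rank-sum comparing the +1 values (one
per mutant) against the pooled values at positions ≥ +2, on corrected or
uncorrected values per flag.  The exact null enumeration is used when
n1 + n2 ≤ 12 and the data are tie-free, otherwise the normal approximation
with tie and continuity correction (the two branches agree within
|Δp| ≤ 0.02 at n1 = n2 = 6).  A one-sample signed-rank variant against 0 is
available behind `method="signed_rank"`.  The distance relation uses
Spearman correlation with average ranks and the t approximation; RNA/protein
agreement uses Pearson on joined (gene, mutant) pairs.  No multiple-testing
adjustment is applied; outputs label p-values as unadjusted.

## The simulator

`synthetic` generates what the pipeline consumes: annotations, operon
tables, intensity matrices with sample sheets, strand-separated WIG tracks,
and a ground-truth record of every drawn effect.  Default parameters are
chosen to emulate a realistic library of this kind:

| parameter | default | rationale |
|---|---|---|
| operon sizes | uniform 1–6 genes | includes single-gene operons as negative controls |
| gene lengths | 300–1500 nt | typical bacterial ORFs |
| intergenic distances | −20 to 100 nt | operon genes abut, overlap, or sit close |
| P(operon up), P(down) | 0.18 / 0.21 | observed ≥2-fold fractions in this kind of library |
| up / down shifts | (1, 2] / [−3, −1) log2 | up to 4-fold up, 8-fold down; affected operons are the ≥2-fold class |
| +1 deficit | −2.5 log2 at d = 0, exp decay, 30 nt lengthscale | strongest observed deficits near overlap; median deficit ≈ 1.6-fold |
| noise | 0.2 log2 per channel, 2 replicates | duplicate TMT measurements |
| plex size | 10 | TMT10-style multiplexing |
| RNA depth | 5 counts/nt, Poisson | deep enough that the <1 density filter bites only on strong downregulation |

The +1 deficit's exponential decay in distance is a stand-in functional
form: any monotone decreasing function would do, and only the monotonicity
is interpreted.  Negative distances (overlapping ORFs) saturate at the
maximum deficit.  The deficit is applied to **protein only** — that is the
defining signature: on the same simulated library the +1 effect is
detectable in the protein branch and absent in the RNA branch.

Two simulator choices deserve explanation:

- *The deleted locus stays transcribed in RNA tracks.*  The cassette
  replacing the ORF is expressed, so the deleted gene's region keeps
  baseline coverage.  This also keeps the coverage windows of genes that
  overlap the deleted gene comparable across mutants; zeroing the locus
  would leak a small artificial density deficit into overlapping neighbors.
- *Cassette excision* is simulated by zeroing positive operon shifts
  (removing the cassette promoter) while keeping downregulation and the +1
  deficit, which are cassette-independent.

What the simulator does **not** model: sequence (no reads, no RBS motifs,
no mRNA folding), internal promoters/terminators, growth effects, shared
regulation between operons, protein-level noise that correlates across
channels.  Passing recovery tests therefore demonstrates the statistical
machinery is correct under the stated effect structure, not that the
biological inference is valid for any particular real library.

## Problem sizes and numerical choices

The validation suite uses libraries of 15–200 operons: type-I calibration
of the +1 test uses 1000 pure-noise 15-operon libraries (group sizes large
enough for the asymptotic branch); parameter recovery uses a 200-operon
library with 20%/20% up/down operons at fixed ±(1.5, 2) log2 shifts and a
−1 log2 maximal +1 deficit.  The acceptance script runs the 60-operon
default library.  Degenerate inputs are errors, not silent results: plexes
of fewer than 2 samples, all-missing channels, fewer than 3 mutants for a
median reference, fewer than 4 pairs for a correlation, constant inputs to
the rank correlation.  Proteins with a non-positive plex median and genes
covered in fewer than 2 mutants are skipped with logged warnings.  Genes
spanning the origin of a circular chromosome are unsupported.

## Known limitations

- The vsn-like calibration is not the published maximum-likelihood vsn; on
  data with strong intensity-dependent variance the two can differ.  Both
  normalizations are rank-preserving per column, so downstream rank
  statistics are insensitive to the choice.
- The median reference assumes most mutants are unchanged per protein; in
  heavily perturbed plexes fold changes are biased toward zero.
- Classification needs ≥1 gene beyond +1, so deletions of the last or
  second-to-last operon gene are `not_evaluable` — sample sizes per
  position shrink quickly, exactly as the per-position n counts in the run
  log show.
- The Wilcoxon comparison pools downstream genes across mutants and treats
  them as independent; genes within one operon share the mutant's residual
  transcriptional effect, which the correction removes only up to median
  estimation error.
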
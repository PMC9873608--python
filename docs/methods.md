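# Methods

`metacodon` analyzes how the codon and amino-acid usage of whole microbial
communities varies with the environment they were sampled from.  The unit
of observation is a *sample*: a collection of predicted CDS nucleotide
sequences (e.g. from an assembled metagenome), with a biome label and,
optionally, per-gene abundances and feature-abundance matrices (functional
terms, taxa).  This note records the models, estimators, numerical choices
and limitations; everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`.

## Sequence handling

Sequences are normalized to upper-case DNA (`U -> T`) and validated against
the alphabet `ACGTN`.  The default genetic code is NCBI translation table
11 (bacterial/archaeal), configurable by table id.  Sequences whose length
is not divisible by three are dropped rather than trimmed — partial genes
from assemblies carry no reliable frame, and trimming would pick one
arbitrarily.  `N`-containing codons and stop codons are never counted;
internal stop codons are kept in the sequence (flagged in translation as
`*`) but excluded from counts.

## Frequency profiles

* **absCUF** — codon counts normalized by the total over all 61 sense
  codons.  Reflects amino-acid composition and synonymous preference
  jointly.
* **synCUF** — codon counts normalized within each synonymous family.
  Independent of amino-acid usage; isolates synonymous codon usage bias.
* **aa** — residue counts over total protein length (stops excluded).
* **k-mer** — overlapping windows on the coding strand, never crossing
  gene boundaries, `N` windows skipped.  The pipeline convention uses
  k = 2..10 excluding 3 (codon-equivalent); for k >= 6 the top 2000 k-mers
  by frequency are retained before distance computation.

Sample GC content is `(G+C)/(A+C+G+T)` over all CDS nucleotides, and the
GC *distance* between two samples is the absolute difference of these
fractions — the only scalar-consistent choice, since no sample-pair GC
divergence is otherwise defined.

## Distances

Three measures operate on aligned profile vectors: Euclidean, Bray–Curtis
(`1 - 2*C_pq/(S_p+S_q)`; on probability vectors this equals half the L1
distance), and the Endres–Schindelin metric
`d_ES = sqrt(KL(p,m) + KL(q,m))`, `m = (p+q)/2`, with natural logarithms,
so `d_ES <= sqrt(2 ln 2)`.  ES requires probability vectors; synCUF
profiles sum to ~20 (one per family) and are therefore renormalized to a
single distribution before ES — EU and BC are applied to raw synCUFs.
The convention `0*log 0 = 0` is used; no epsilon flooring is needed
because the mixture is positive wherever either argument is.

## Group statistics

**ANOSIM** uses Clarke's rank statistic `R = (rB - rW) / (n(n-1)/4)` with
midranks for ties, and a label-permutation P-value with the add-one
estimator `(1 + hits)/(1 + n_perm)` (default 10,000 permutations).  The
implementation is verified against an exhaustive enumeration oracle for
n <= 8 and against scikit-bio.

**Clustering Index (CI)** for a focal group is the mean within-group
distance divided by the mean distance from the focal group to all other
samples; values below 1 indicate within-group cohesion.  Its significance
test redraws group labels (sizes fixed, default 100 randomizations) and
defines `p = #(CI_random < CI_real) / n_random` — deliberately the literal
count-below definition, so the P-value is one-sided and has granularity
`1/n_random`; an observed CI near or above 1 yields large P-values by
construction.

Ordination is centered (not scaled) PCA via SVD, matching R's `prcomp`
defaults.  Within-vs-between distance lists are compared by a two-sided
Mann–Whitney U test with an explicit Bonferroni factor.

## Codon usage bias indices

**CAI.**  `CAI_g = (prod w_i)^(1/L)` over the gene's countable codons,
computed in log space.  Weights are `w_i = f_i / max(f_i)` within each
synonymous family of a reference set: the top 5% of the sample's genes by
abundance (ties broken by gene id; `ceil` of the fraction).  A +0.5
pseudocount on the pooled reference counts (the classical Sharp–Li
remedy) keeps all weights positive; note it is not scale-invariant, so
tiny references are slightly regularized toward 1.  Single-codon families
(Met, Trp) participate with w = 1; a flag excludes them for comparability
with classical CAI.

**ENC.**  Wright's effective number of codons on pooled sample counts:
per family, `F_hat = (n * sum p_i^2 - 1)/(n - 1)`; per degeneracy class,
the count-weighted mean of its families' `F_hat` (families with n < 2
omitted); then `Nc = n_single + sum_k n_k / F_k`, which for the standard
code is `2 + 9/F2 + 1/F3 + 5/F4 + 3/F6` (the three-fold class is Ile).  A
wholly missing three-fold class is imputed as `(F2 + F4)/2`.  Reported
ENC is capped to [20, 61] since the estimator can exceed 61 on finite
samples; the raw value is available (`cap=False`) and is what enters
Z-scores (see below).

**DCBS.**  With sample-level codon frequencies `f(x,y,z)` and positional
nucleotide frequencies `f1, f2, f3` derived from the same pooled counts,
`d_xyz = f(x,y,z)/(f1(x) f2(y) f3(z)) - 1`; a gene's score is the
arithmetic mean of `d_xyz` over its codons and a sample's score the mean
over genes.  A geometric-mean variant (`exp(mean log ratio) - 1`) is
available behind a flag.

## The randomization null and Z-scores

To ask whether a sample's codon usage is shaped by selection beyond its
nucleotide-level composition, each sample is compared with randomized
versions of itself that preserve every gene's protein exactly and the
sample's dinucleotide content.  The null is the maximum-entropy
distribution over synonymous reconstructions subject to dinucleotide
content: a first-order Markov random field in which a reconstruction's
probability is proportional to the product of a 4x4 weight `W[a,b]` over
all adjacent base pairs.  Sampling is exact — a backward
partition-function recursion over each gene followed by a forward draw.
A left-to-right chain that just normalizes transition probabilities
locally does *not* sample this distribution and measurably distorts
synonymous usage.  `W` is initialized from the sample's observed
dinucleotide transitions and calibrated by deterministic iterative
proportional fitting until the *expected* dinucleotide counts of
randomized sequences match the real counts (tolerance 2e-3 on the log
scale, <= 30 iterations; expected counts are computed exactly by
forward–backward recursion, no sampling noise).  Two consequences:

* with a dinucleotide-neutral sample the calibrated sampler reduces to
  uniform synonymous choice, so the Z-scores below are properly
  calibrated (approximately standard normal) on preference-free data;
* preservation of dinucleotide content is exact in expectation; per
  replicate the deviation is O(1/sqrt(total bases)) and falls well below
  0.01 per dinucleotide on 50-gene samples.

For each index, `z = (real - mean(randoms)) / sd(randoms)` over 20
replicates (sample sd).  CAI/DCBS: positive z = more biased than the
null; ENC: negative z = more biased.  The CAI reference *membership* is
fixed by the real abundance ranking (synonymous substitution does not
change abundance), while reference weights are recomputed per replicate.
ENC enters the Z-score uncapped: at the unbiased boundary the [20, 61]
cap would clip the null distribution one-sidedly and bias z.

A codon-count-preserving within-family shuffle (`method="swap"`) is also
provided; it is unusable as a bias null (sample-level indices are nearly
invariant under it) but serves as a control for distance-level analyses.

## Association layer

All association statistics operate on a pairs-by-variables table of
distances (codon EU/BC, amino-acid, |delta GC|, k-mer, feature-matrix
columns).  Correlation is Spearman's rho; partial correlation
rank-transforms all columns, regresses target and test on the controls
and correlates residuals, with the t-approximation
(`df = n - #controls - 2`) for P — verified against a precision-matrix
oracle and pingouin.  Regression is OLS on z-standardized columns
(standardized betas, R^2).  Pairwise distances are not independent
observations; P-values are descriptive, and a Mantel-style permutation
alternative (`spearman_mantel`) exists for the cautious.  GC-binned
ANOSIM re-runs the test inside GC bins (default: 4 quantile bins, which
guarantee balanced occupancy); a biome signal persisting within narrow
bins cannot be a pure GC artifact.

## Synthetic communities

The generator emulates the structure the analysis is built to detect, and
its defaults are the study conditions of the tests: 7 biomes x 5 samples,
200 genes per sample, lognormal gene lengths (median 300 codons, sigma
0.6, floor 30), lognormal abundances (sigma 1.0).  Biome archetypes are
Dirichlet perturbations of a shared base preference with concentration
`50/effect_size` per family (`400/aa_effect_size` for amino-acid
composition), so effect 0 gives identical archetypes and divergence grows
monotonically with effect.  Per-sample preferences add within-biome noise
(Dirichlet concentration 300).  Codon-level and AA-level effects are
independent dials, so codon signal can be shown not to be an amino-acid
artifact.  A GC dial tilts preferences toward G/C-ending codons either
per biome (confounded) or along a biome-independent gradient assigned
round-robin across samples.  `selection_strength` tilts each gene's codon
draws toward its family's preferred codon in proportion to the gene's
abundance quantile, producing the abundance–CAI correlation a
translational-selection signature requires.  `uniform_preferences` means
*no codon preference at all*: flat families and no per-sample Dirichlet
noise (that noise is itself a small persistent preference, which the
null model correctly detects).  Feature matrices are Dirichlet draws
around biome centroids.  Everything descends from one master seed through
a fixed `SeedSequence` spawn tree, so studies are byte-reproducible.

What the generator does **not** emulate: assembly artifacts and chimeras,
within-sample taxonomic mixture (each synthetic sample has one
preference profile, real communities are mixtures), genome-scale G+C
heterogeneity within a sample, length-biased abundance estimation, and
real GO/taxon sparsity structure.  Passing tests therefore demonstrate
correctness and calibration of the estimators under the stated generative
model, not recovery of any particular real-data effect size.

## Test and acceptance problem sizes

Desk-scale sizes used by the heavier checks (chosen as conditions, fixed
in the tests): signal recovery runs 7 biomes x 5 samples x 200 genes over
20 seeds (ANOSIM with 999 permutations, positive R at p <= 0.05 required
in >= 95% of seeds); ANOSIM null calibration uses 4 biomes x 4 samples x
60 genes over 20 seeds (mean R within +-0.05 of 0); CI-test null
calibration uses 200 replicates of 3 biomes x 4 samples x 40 genes
(Kolmogorov–Smirnov uniformity at alpha = 0.01); Z-score runs use single
samples of 60 genes, median 120 codons, 20 replicates, 20 seeds per
condition.  For a well-calibrated null |z| < 2 holds for ~95% of values;
the calibration check requires >= 90% across runs and indices.

## Known limitations

* The ENC estimator is n-dependent (finite-sample correction), so it is
  not exactly invariant under duplicating a sample's genes; the deviation
  is O(1/n) but amplified near the uniform (61) end by the squared class
  degeneracy.
* The CAI pseudocount (+0.5) is not scale-invariant; with very small
  reference sets weights are shrunk toward 1.
* The CI P-value is one-sided by definition and uninformative for groups
  whose CI is near or above 1.
* Distance-vector correlations and regressions ignore the dependence
  structure of pairwise distances, exactly as the classical analyses do.
* The randomization null conditions on *realized* dinucleotide counts; on
  very small samples that conditioning itself contributes variance to z.
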
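# metacodon

Community-level codon and amino-acid usage analysis for metagenomic CDS
collections.

Microbial communities from similar environments tend to use synonymous
codons in similar ways, even after accounting for amino-acid composition
and GC content.  `metacodon` is a toolkit for quantifying that signal.
Given per-sample multi-FASTA files of predicted coding sequences and a
biome label per sample, it:

* profiles each sample — absolute codon usage frequencies (**absCUF**,
  counts over the 61 sense codons), synonymous codon usage frequencies
  (**synCUF**, normalized within each amino-acid family), amino-acid and
  k-mer frequencies, GC content;
* measures divergence between samples with three distances: Euclidean
  `d_pq = sqrt(Σ (q_i − p_i)²)`, Bray–Curtis `d_BC = 1 − 2C_pq/(S_p+S_q)`,
  and the Endres–Schindelin metric `d_ES = sqrt(KL(p,m) + KL(q,m))`,
  `m = ½(p+q)`;
* tests habitat-level clustering with ANOSIM (Clarke's rank R, permutation
  P) and a Clustering Index (within/between mean-distance ratio) with a
  label-randomization test;
* scores codon usage bias per sample with **CAI** (geometric mean of
  `w_i = f_i/max(f_i)` against a reference of the top 5% most abundant
  genes), Wright's **ENC** (`Nc = 2 + 9/F₂ + 1/F₃ + 5/F₄ + 3/F₆`, range
  20–61), and **DCBS** (mean relative deviation of codon frequencies from
  positional-nucleotide products);
* detects selection on codon usage by comparing each index against
  randomized sequences that preserve every protein exactly and the
  sample's dinucleotide content, via Z-scores
  `z = (real − mean(randoms)) / sd(randoms)`;
* relates codon-usage distances to candidate drivers (GC, amino-acid
  usage, functional/taxonomic composition, k-mers) through Spearman
  correlation, partial correlation, multiple regression and GC-binned
  ANOSIM.

A synthetic community generator (biome-specific codon preferences, GC
gradients, lognormal abundances, abundance-linked selection) makes the
whole pipeline testable without any downloads.  See `docs/methods.md` for
the models, estimators and their assumptions.

## Worked example

```python
import numpy as np
from metacodon import (StudyConfig, generate_study, sample_profiles,
                       distance_matrix, anosim, ci_permutation_test,
                       sample_cub_summary, selection_analysis, standard_code)

config = StudyConfig(n_biomes=3, samples_per_biome=4, genes_per_sample=80,
                     median_gene_length=150, effect_size=1.0, seed=42)
study = generate_study(config)

code = standard_code()
profiles = [sample_profiles(c, code, ("synCUF",))["synCUF"]
            for c in study.collections.values()]
dm = distance_matrix(profiles, "EU")
res = anosim(dm, study.labels, n_permutations=9999, seed=0)
print(f"ANOSIM R = {res.R:.3f}, p = {res.p:.4f}")

ci = ci_permutation_test(dm, study.labels, "soil", n_random=100, seed=1)
print(f"CI(soil) = {ci.ci:.3f}, p = {ci.p:.2f}")

sid = study.sample_ids[0]
scores = sample_cub_summary(study.collections[sid], study.abundances[sid])
print(f"{sid}: mean CAI = {scores.mean_cai:.3f}, ENC = {scores.enc:.2f}, "
      f"mean DCBS = {scores.mean_dcbs:.3f}")

zs = selection_analysis(study.collections[sid], study.abundances[sid],
                        n_replicates=20, seed=2)
for name, r in zs.items():
    print(f"z({name}) = {r.z:+.2f}")
```

prints

```
ANOSIM R = 1.000, p = 0.0001
CI(soil) = 0.487, p = 0.00
soil_s1: mean CAI = 0.688, ENC = 45.95, mean DCBS = 0.562
z(CAI) = -2.50
z(ENC) = -43.79
z(DCBS) = +94.44
```

Reading the numbers: with a clear biome effect (`effect_size=1.0`) the
three simulated biomes separate completely in synonymous codon usage
(R = 1 at the smallest attainable permutation P), and soil samples sit
half as far from each other as from other biomes (CI < 1, no random
relabeling beats it).  Sample `soil_s1` has moderate codon bias
(ENC ≈ 46 on the 20–61 scale).  Against the dinucleotide-preserving null
its ENC is strongly *below* the randomized sequences (z(ENC) ≪ 0) and
DCBS strongly above — this sample's synonymous usage is far more biased
than its nucleotide-level composition explains, the signature the
Z-score analysis is designed to flag.  (The biome preference profile is
drawn once per study, so all genes share it; CAI, which is measured
against the sample's own most-abundant genes, is correspondingly close
to its null here because this simulation adds no abundance-linked
enrichment: `selection_strength=0`.)

There is also a command-line interface:

```bash
metacodon simulate --out study/ --biomes 3 --samples-per-biome 4 --genes 80 --seed 42
metacodon run-all --study-dir study/ --out results/ --seed 0
```

which writes profile, distance, ANOSIM, CI, CUB-index, correlation and
regression tables as TSV plus a reproducibility manifest.

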
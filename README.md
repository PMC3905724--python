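# isoshare

Rare-variant association and haplotype-sharing analysis for population
isolates.

Small, historically isolated populations (founder bottleneck, extensive
relatedness) can carry functional alleles that are vanishingly rare in
outbred populations but have drifted to a frequency of a few percent in the
isolate — putting them within reach of association studies at modest sample
size. Analysing such cohorts needs a chain of machinery: genotype quality
control, phenotype preparation, mixed-model association that accounts for
pervasive kinship, and haplotype-sharing analysis to characterise the origin
and age of a focal allele. `isoshare` implements that chain as a tested,
reusable library plus a thin CLI, driven by a forward simulator so every
stage can be exercised with known ground truth and no external data.

## What is inside

| module | contents |
|---|---|
| `isoshare.simulate` | forward simulation of an isolate: founder bottleneck, random mating, Poisson recombination on a genetic map, a single founder haplotype carrying a rare derived allele, genotyping error/missingness, kinship-structured quantitative traits |
| `isoshare.qc` | staged sample/variant QC: call-rate prefilter, sample call rate, heterozygosity outliers stratified at MAF 1%, variant call rate, Hardy–Weinberg exact filter, singleton-excess samples |
| `isoshare.traits` | Friedewald LDL, mg/dl ↔ mmol/l conversion, 5-SD outlier removal, natural-log and Blom inverse-normal transforms, HDL dichotomisation (≥60 / <40 mg/dl) |
| `isoshare.lmm` | centered-genotype kinship matrix; single-variant linear mixed model `y = Wα + xβ + u + ε`, `u ~ N(0, σ_g²K)`, fitted by ML with the variance ratio profiled on the eigendecomposition of K; likelihood-ratio p-values; conditional and binary-trait fits; variance explained `2f(1−f)β²/Var(y)` |
| `isoshare.sharing` | surrogate-parent Viterbi HMM for maximal haplotype identity, direct opposite-homozygote pair scan, sharing profiles along a chromosome, carrier vs non-carrier Kolmogorov–Smirnov comparison, generations-to-common-ancestor estimator `Ĝ = 1/mean(length in Morgans)` |
| `isoshare.variant_stats` | allele/genotype frequency arithmetic, Hardy–Weinberg exact test, method-of-moments pairwise IBD (π̂), EM two-locus LD (D′, r²), haplotype-span arithmetic, Fisher's-method meta-analysis, power/sample-size and neutral frequency-based allele age |

The haplotype-sharing model: for a target individual, a pair of other cohort
members act as *surrogate parents* — the hidden state of an HMM whose
emission is the probability that the target's genotype arises by Mendelian
transmission from the pair (with ~1% genotyping error), and whose transition
lets each surrogate switch with probability `1 − exp(−d)` per d Morgans of
genetic map. The Viterbi path names, at every position, the genealogical
nearest neighbours of the target's two chromosomes; the run over which the
focal-side surrogate is unchanged is the shared segment. If the common
ancestor of a pair lived G generations ago, the shared segment extends left
and right by independent Exponential(2G)-per-Morgan distances, so segment
lengths estimate G.

## Worked example

```python
import numpy as np
from isoshare import (IsolateConfig, TraitConfig, simulate_isolate,
                      simulate_traits, kinship_centered, lmm_fit, LRPConfig,
                      viterbi_surrogate_parents)
from isoshare.sharing import segments_at

cfg = IsolateConfig(
    n_founders=40, n_generations=8,
    pop_size_trajectory=[60, 94, 147, 231, 362, 567, 888, 1267],
    n_variants=300, chrom_length_bp=10_000_000,
    carrier_target_freq=0.019, freq_tol=0.006, seed=1)
g, truth, gmap = simulate_isolate(cfg)

K = kinship_centered(g)
trait = TraitConfig(trait_name="HDL", variance_explained_target=0.029,
                    polygenic_h2=0.3, mean=1.265, sd=0.35)
ph = simulate_traits(truth, trait, K, seed=2)
res = lmm_fit(ph["HDL"].to_numpy(), truth.carrier_status.astype(float), K)

carrier = g.samples[int(np.flatnonzero(truth.carrier_status > 0)[0])]
vp = viterbi_surrogate_parents(g, carrier, gmap, LRPConfig(error_rate=0.01))
left, right = segments_at(vp, truth.focal_pos)
```

With these seeds the run prints:

```
cohort: 1267 samples x 300 variants
derived-allele frequency: 2.13%  heterozygous: 4.26%
HDL association: beta=0.256 mmol/l per allele, se=0.101, p_LRT=1.19e-02, VE=2.2%
S0049: nearest neighbour S0950, shared segment 3,579,907-9,982,257 (6.40 cM)
```

A rare allele seeded on one founder haplotype drifted to ~2% so that ~4% of
individuals are heterozygous; the mixed model recovers a positive HDL effect
of the right magnitude (true per-allele effect ≈ 0.31 mmol/l). Note the
p-value is far weaker than `n·VE` alone would suggest: with only 300 markers
on one chromosome, deep relatedness means the random effect absorbs part of
the focal signal — in a real exome-wide analysis the kinship matrix is
estimated from tens of thousands of variants and this attenuation largely
disappears. The carrier's longest shared segment spans several cM, the
signature of a recent common ancestor.

Command-line equivalents:

```sh
isoshare simulate --seed 1 --out-prefix sim
isoshare qc --vcf sim.vcf --out-prefix sim
isoshare assoc --vcf sim.qc.vcf --pheno pheno.tsv --trait HDL --out assoc.tsv
isoshare share --vcf sim.vcf --map sim.map.tsv --focal 1:5000000 --out segments.tsv
isoshare stats freq 1219 48 0      # {"alt_allele_freq": 0.01894..., "het_fraction": 0.03788...}
isoshare stats span 116520527 117091609   # {"span_bp": 571082, "span_kb": 571}
```

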
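# traitpred

Quantitative genetic trait prediction with **data-driven genotype
encodings**, ridge-regression BLUP, and mutual-information ranking of
pairwise epistasis effects.

## The problem

Given *n* samples genotyped at *m* biallelic SNPs (*m* ≫ *n*) and a
quantitative phenotype *Y*, genomic prediction fits the linear model

    Y = β₀ + Σᵢ βᵢ Xᵢ + e                          (single-marker model)
    Y = β₀ + Σᵢ βᵢ Xᵢ + Σ_{i<j} α_{ij} XᵢXⱼ + e     (epistasis model)

which requires the three genotype classes (two homozygotes, one
heterozygote) to be *numbers*.  The conventional choices — {0, 1, 2} or
{−1, 0, 1} — are arbitrary, give every marker the same map, and interact
badly with product-style epistasis terms (under {0, 1, 2} the combinations
0·1 and 0·2 are indistinguishable; two heterozygotes multiply to 1 under
one scheme and 0 under the other).

This package implements target-mean alternatives in which the training
phenotype itself chooses the numbers, per marker:

* **pure data-driven** — `E(i, c) = mean trait of training samples with
  code c at marker i`, for all three classes;
* **hybrid data-driven** — class means for the homozygotes,
  the grand training mean for the heterozygote (keeping the heterozygote
  "between" the homozygotes);
* **pairwise grid** — a 3×3 grid per marker pair extending the hybrid idea:
  corner cells are means conditional on both codes, edge cells are marginal
  means given the non-heterozygous code, and the centre cell is the grand
  mean.

Prediction uses **rrBLUP**: ridge regression whose shrinkage is the
variance-component ratio λ = σ²ₑ/σ²_β, estimated by REML through a spectral
decomposition.  Epistasis pairs are screened by the mutual information
between the pair's product feature and the quantile-binned trait, and
rankings under different fixed schemes (E1–E4) are compared by average
overlap.  A k-fold cross-validation harness fits *everything* — encoding
tables, pair rankings, variance components — inside each training fold, and
scores held-out folds by squared Pearson correlation r².

The package is aimed at plant/animal-breeding and statistical-genetics
researchers who want to study how encoding choices affect genomic
prediction, on their own genotype/phenotype files (VCF, sample×marker TSV,
PLINK `.raw`) or on simulated architectures.

## Worked example

```python
from traitpred import (SimulationConfig, generate, fit_hybrid,
                       apply_encoding, reml_fit, predict, r_squared)
```

`examples/encode_and_predict.py` simulates an oligogenic trait (5 causal
markers out of 300), fits the hybrid encoding and an rrBLUP model on 100
training samples, and scores 20 held-out samples:

```
REML variance components: sigma2_beta=0.1347, sigma2_e=0.1611
shrinkage lambda = sigma2_e/sigma2_beta = 1.1961
held-out r^2 = 0.3329
```

The λ printed is the ridge penalty implied by the REML variance ratio; the
r² is the squared correlation between observed and predicted traits on the
held-out samples.

`examples/encoding_sweep.py` runs the encoding comparison across
architectures (mean 10-fold-CV r² over replicate 100×500 datasets):

```
     traditional012    pure  hybrid
s
5            0.1746  0.3684  0.3798
20           0.2444  0.2743  0.3107
200          0.2376  0.1298  0.1425
```

With few causal markers (oligogenic, s = 5) the data-driven encodings beat
the fixed scheme; with many (polygenic, s = 200) the traditional encoding
wins — the central qualitative behaviour the encodings were designed
around.  `examples/rank_epistasis_pairs.py` and
`examples/epistasis_model_cv.py` demonstrate the MI pair screen and the
epistasis-model cross-validation.

## Command line

Three subcommands wrap the library for shell use, each writing its results
plus a `config.json` that reproduces the run bit-for-bit:

```bash
traitpred simulate --n 100 --m 500 --s 5 --seed 1 --out sim/
traitpred cv --genotypes sim/genotypes.tsv --phenotypes sim/phenotypes.tsv \
             --encoding hybrid --model reml --k 10 --seed 1 --out cv/
traitpred rank-pairs --genotypes sim/genotypes.tsv \
             --phenotypes sim/phenotypes.tsv --out rank/
```

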
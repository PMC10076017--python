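# nimkit

Toolkit for assessing the contribution of Neanderthal-introgressed variants to
complex-trait variation: annotation-matched heritability partitioning,
per-variant association with LD clumping, sum-of-single-effects fine-mapping
with credible-NIM post-processing, greedy tag-SNP array design, and a
synthetic genotype generator that emulates introgressed haplotype blocks.

## The problem

Variants inherited from Neanderthal introgression (NIMs — Neanderthal
informative mutations) entered modern human populations ~50,000 years ago on
a small number of haplotypes.  As a consequence they are rare on average,
travel in long blocks of near-perfect LD, and their frequency is decoupled
from local LD — population-genetic properties very different from those of
modern-human (MH) background variants.  Two questions follow:

1. **Aggregate contribution.**  How much phenotypic variance do NIMs explain
   (h²_NIM), and is the per-NIM contribution depleted or enriched relative to
   MH variants *matched for MAF and LD*?  Naive two-class variance-component
   fits are badly miscalibrated precisely because of the MAF/LD contrasts.
2. **Localization.**  Which individual introgressed regions modulate a
   phenotype?  Single-variant association at NIMs is confounded by linked MH
   causal variants riding the same haplotypes, so significant NIMs need
   fine-mapping before they can be believed.

## Model and statistics

Phenotypes follow the additive model on standardized genotypes

    y_j = Σ_i w_ij β_i + ε_j,    w_ij = (x_ij − 2p_i) / √(2p_i(1−p_i)),

with β_i ~ N(0, 1) on causal variants and ε calibrated to a target h².
Heritability is partitioned across annotation bins k (ancestry × MAF quintile
× LD-score quintile, bins under 30 SNPs dropped) with the method-of-moments
normal equations

    E[yᵀK_k y] = Σ_l σ²_l tr(K_k K_l) + σ²_e tr(K_k),    K_k = W_k W_kᵀ / M_k,

solved exactly (streamed trace computation) with a 100-block jackknife for
standard errors and covariances.  The headline statistics are

    ĥ²_NIM = Σ_{NIM bins} ĥ²_k,
    ĥ²_MH  = Σ_i (M_NIM,i / M_MH,i) · ĥ²_MH,i   (matched bins),
    Δĥ²    = ĥ²_NIM − ĥ²_MH,

where a negative Δĥ² means introgressed heritability is depleted relative to
an MAF/LD-matched modern-human background.  Per-phenotype estimates pool
across phenotypes via DerSimonian–Laird random-effects meta-analysis.

The localization arm tests each NIM by linear regression with covariates,
applies a genome-wide threshold and LD clumping (250 kb, r² ≥ 0.5), LD-prunes
the significant NIMs (100 kb, r² > 0.99), and fine-maps every ±100 kb window
with a sum-of-single-effects model (L = 10, 95% credible sets).  Per window
the credible sets are merged; unions with ≥50% MH members are discarded;
overlapping windows merge into **credible NIM regions**, labeled true/false
positives in simulations by whether their credible NIMs include a truly
causal NIM.

## Worked example

```python
import numpy as np
from nimkit import (PanelConfig, simulate_genotypes, qc_filter, compute_ld_scores,
                    build_partition, architecture, select_causal_variants,
                    simulate_phenotype, estimate_components)

cfg = PanelConfig(n_individuals=1000, n_mh_snps=4000, n_segments=8,
                  nims_per_segment=60, linked_mh_per_segment=60,
                  genome_length_bp=40_000_000, seed=11)
panel, variants = simulate_genotypes(cfg)
variants["qc_pass"] = qc_filter(panel, variants)
qc = np.flatnonzero(variants["qc_pass"])
variants["ld_score"] = np.nan
variants.loc[qc, "ld_score"] = compute_ld_scores(
    panel.subset_variants(qc), variants.iloc[qc].reset_index(drop=True))

spec = architecture("RARE", n_causal=60, h2=0.5)      # rare variants enriched
causal = select_causal_variants(variants, spec, seed=1)
truth = simulate_phenotype(panel, variants, causal, h2=0.5, seed=1)

part = build_partition(variants, schemes=(("maf", 5), ("ld_score", 5)),
                       require_matched=True)
est = estimate_components(truth.y, panel, variants, part, n_blocks=50)
print(est.h2_total, est.h2_nim, est.delta_h2)
```

prints (annotated):

```
panel: 1000 individuals, 4938 variants (450 NIMs)
mean MAF: NIM 0.035, MH 0.097          # introgressed variants are rarer
simulated phenotype: h2=0.5, true NIM h2=0.0192
h2_total = 0.502 (SE 0.140)            # recovers the simulated h² of 0.5
h2_NIM   = 0.0893 (SE 0.0777)          # covers the true 0.0192 within 1 SE
delta_h2 = +0.0737 (Z = +0.25, p = 0.80)   # no spurious depletion/enrichment
```

Causal selection here is ancestry-blind, so the matched difference Δh² is
zero in truth; the MAF×LD-matched estimator correctly does not reject, even
though causal variants were deliberately concentrated among rare alleles.

The same pipeline is available from a shell:

```
nimkit simulate --config cfg.yaml --seed 3 --out run/
nimkit annotate --bfile run/panel --out run/variants.tsv
nimkit h2 --bfile run/panel --pheno run/phenotype.tsv --out run/h2/
nimkit assoc --bfile run/panel --pheno run/phenotype.tsv --out run/assoc/
nimkit simstudy --kind calibration --seed 1 --out run/study/
```

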
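# satdepth

**Sequencing-depth saturation analysis for 3′ mRNA-Seq molecular phenotyping.**

`satdepth` answers a practical design question for labs using 3′ mRNA-Seq
(QuantSeq/SMART-Seq-3′-style tag counting) as a cheap, population-scale proxy
phenotype: *how many reads per sample are enough?* Because 3′ libraries
sequence one poly-A-proximal fragment per transcript, gene expression can be
quantified at a fraction of whole-transcriptome depth — but gene detection,
differential expression, and intragenic variant calling each saturate at
different depths. The package quantifies those saturation points by seeded
downsampling of count matrices, benchmarking every subsample against the
full-depth result, and fitting an asymptotic regression curve whose analytic
plateau is the recommended sequencing depth.

## The model

Gene (or variant) detections `y` as a function of sequencing depth `x`
(reads/sample) follow the three-parameter asymptotic regression model

```
y(x) = ymax + (y0 − ymax) · exp(−exp(lrc) · x)
```

with asymptote `ymax`, origin response `y0`, and `lrc` the natural log of the
rate constant. The **saturation depth** is where the marginal gain drops to a
threshold `s` (default `1e-4`, i.e. one more gene per 10,000 extra reads),
with the closed form

```
x_plateau = −( ln( s / (ymax − y0) ) − lrc ) / exp(lrc)
```

Subsamples are scored against full-depth truth with precision = TP/(TP+FP),
recall = TP/(TP+FN), and F = TP/(TP + (FP+FN)/2) (the harmonic mean of
precision and recall).

The analysis stages:

* **Downsampling** — per-sample multivariate-hypergeometric thinning of a
  gene-by-sample count matrix (the count-level equivalent of subsampling
  reads without replacement), over a depth × seed replicate grid.
* **Detection metrics** — *expressed* genes (≥ 1 read) and *informative*
  genes (≥ 10 reads in ≥ 50% of samples), per sample and dataset-level, with
  prevalence distributions (in how many individuals each gene is seen).
* **Differential expression** — a self-contained two-group negative-binomial
  Wald test (median-of-ratios normalisation, moment/trend dispersion
  estimation, IRLS GLM fits vectorised across genes, Benjamini–Hochberg FDR
  at α = 0.05).
* **Variant filtering** — post-calling hard filters (QD < 20, FS > 20,
  MQRankSum < −12.5, ReadPosRankSum < −8, SOR > 5), a lenient record-level
  depth criterion (DP_total ≥ 10 and ALT_AD_total > 0), a stringent
  per-allele criterion ((AD ≥ 2 or (AR ≥ 0.1 and DP > 10)) with recalculated
  depth ≥ 5), intragenic annotation against GFF3/GTF gene models, the
  strand-aware 5′→3′ relative-position histogram, and known-site overlap.
* **Synthetic data** — seeded generators for NB count matrices with known DE
  truth, saturation observations from the model above, and toy VCF/GFF3
  fixtures with 3′-biased variant positions, so every stage can be exercised
  and validated without external downloads.

## Worked example

```python
from satdepth import (ExperimentConfig, ReplicateGrid, SimCountParams,
                      simulate_counts, run_saturation)

matrix, truth, labels = simulate_counts(
    SimCountParams(n_genes=5_000, depth_per_sample=2_000_000,
                   n_de_genes=500, seed=42)
)
config = ExperimentConfig(
    grid=ReplicateGrid(
        depths=(100_000, 250_000, 500_000, 900_000,
                1_200_000, 1_500_000, 1_800_000),
        seeds=(127, 2, 5, 7, 9),
    )
)
report = run_saturation(matrix, config, labels=labels)
print(report.truth_sizes)
for metric in ("expressed", "informative", "deg"):
    p = report.fits[metric]["plateau"]
    print(f"{metric:12s} plateau at {p['x_plateau']:>12,.0f} reads/sample, "
          f"predicted {p['y_at_plateau']:>8,.0f}")
```

prints

```
{'expressed': 4515, 'informative': 2319, 'deg': 310}
expressed    plateau at    1,552,129 reads/sample, predicted    4,418
informative  plateau at    1,606,794 reads/sample, predicted    2,214
deg          plateau at      459,887 reads/sample, predicted      266
```

Reading: of the 5,000 simulated genes, 4,515 are detectable at full depth
(2M reads/sample); the fitted curve says gene detection stops improving
meaningfully (< 1 gene per 10,000 extra reads) at ≈ 1.55M reads/sample, where
≈ 4,418 genes are already captured. The DEG set saturates much earlier.
Mean recall of the expressed set rises from 0.77 at 100k reads to 0.99 at
1.8M reads across replicate seeds.

The same experiment is available from the shell:

```
satdepth simulate --outdir sim --n-genes 5000 --depth 2000000 --seed 42
satdepth saturate --counts sim/counts.tsv --samples sim/samples.tsv \
    --depths 100000,250000,500000,900000,1200000,1500000,1800000 \
    --seeds 127,2,5,7,9 --outdir results
satdepth filter-variants --vcf sim/variants.vcf --gff sim/genes.gff3 \
    --outdir results/variants
```

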
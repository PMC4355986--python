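# methclust

Methyl-capture sequencing (MBD-seq) analysis at gene-cluster scale:
bin-level methylation quantification, differentially methylated region
(DMR) calling between tumor and normal groups, gene-cluster survival
stratification, TSS metagene profiling, and methylation–expression
integration — together with a synthetic cohort generator that plants
known effects so every stage can be validated against ground truth.

It is written for computational epigenomics work where MBD-seq read
density is the methylation proxy: cancer cohort studies asking which
promoter/CGI regions are hypermethylated in tumors, whether
hypermethylation of a cluster of consecutive genes (e.g. a HUGO gene
family like MT1 on 16q13) stratifies patient survival, and how promoter
methylation relates to expression.

## The model

**Quantification.** Each chromosome is tiled with 100-bp bins; a read
credits every bin it overlaps by ≥ 1 bp. Bin counts are normalized by a
library-size mantissa factor,

    N_read,i = U_read,i / (N_U / 10^INT(log10 N_U)),

where `U_read,i` is the unique-read count of bin *i*, `N_U` the
library's total unique reads, and INT rounds toward −∞; the divisor is
the leading mantissa of `N_U` and always lies in [1, 10).

**DMR calling.** CpG islands are classified as promoter (overlapping
TSS ± 2 kb), intragenic, or intergenic; CGI-free promoters form a
fourth class. Each region gets an 8-kb window centered on the TSS (or
CGI midpoint), split into three near-equal segments — left shore, CGI
core, right shore. For every window and segment, per-sample region
means `M_R,G` give group averages `A_R,G`, compared by a two-sided
pooled-variance Student t-test; a segment is an individual DMR when
`p` falls below its class threshold (defaults 0.05 for promoter CGIs,
0.01 elsewhere).

**Survival stratification.** Per-gene promoter methylation is coded
high/low (HM/LM) at the third quartile (strictly above Q3 → HM = 1).
Within a cluster, genes can be screened by univariate Cox direction and
log-rank p (HR > 1, p < 0.3). A patient's HM count over the retained
genes is dichotomized at an integer cutoff chosen by ROC (Youden's
J for classifying dead vs alive, aggregated over 200 bootstrap
resamples); groups are compared by Kaplan-Meier/log-rank and a
multivariable Cox model (methylation group, age, grade, ER status;
Efron ties).

**Profiles and expression.** GC content and conservation are averaged
in 160 × 50-bp bins over TSS ± 4 kb, strand-oriented, per cluster
against an all-genes background. Expression tools cover per-gene
z-scores of log2(RPKM+1), group log2 fold changes on mean RPKM with a
pseudocount, Pearson methylation–expression correlation with optional
percentile trimming, and qPCR relative expression 2^−ΔΔCt.

## Worked example

`examples/` holds one short script per capability. The DMR example
simulates the default study (20 tumors vs 10 normals, 200 analysis
windows, 30 planted 3× hypermethylated windows), quantifies all
samples, and calls DMRs:

```text
$ python examples/02_call_dmrs.py
promoter_CGI       tested  84  differential 29.8%
intragenic_CGI     tested  46  differential 15.2%
intergenic_CGI     tested  34  differential 26.5%
nonCGI_promoter    tested  36  differential 8.3%
segment calls core vs shore: {'core': 35, 'shore': 72}
recovery of the 30 planted windows: sensitivity 1.00, FDR 0.032 over 124 hyper calls
```

Every planted window is recovered and 3.2% of hypermethylation calls
fall outside the planted truth. The survival example plants a hazard
ratio of 2 on one cluster of consecutive genes and leaves a second
cluster null:

```text
$ python examples/03_cluster_survival.py
cluster_1: cutoff 2, high group n=107, log-rank p=9.63e-06, Cox HR 1.81 [1.40, 2.33] (true log HR 0.69)
cluster_2: cutoff 1, high group n=365, log-rank p=9.85e-01, Cox HR 1.14 [0.74, 1.76] (true log HR 0.00)
```

The planted cluster separates survival with a Cox hazard ratio near the
true value of 2; the null cluster does not.

The same stages run from the shell:

```bash
methclust run-all --config cfg.json     # or simulate|quantify|dmr|survival|features|expression
```

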
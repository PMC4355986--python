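# Methods

This note documents the models, conventions and design choices behind
methclust, in the spirit of a statistical software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Quantification model

MBD-capture sequencing measures methylation as enrichment read
density, not per-CpG β-values; all quantities in this package are
(normalized) read counts. Chromosomes are tiled with fixed 100-bp bins
phased at coordinate 0 (the bin size is canonical; the phase is an
arbitrary but reproducible choice). A read increments **every** bin it
overlaps by at least one base, with no fractional attribution — the
literal whole-or-part counting rule. Consequences worth knowing:

* the sum of bin counts exceeds the read count (a 36-bp read can touch
  two bins), so `normalize` warns only when the bin sum falls *below*
  the stated library size;
* `region_mean` includes partially overlapped bins at full weight, for
  consistency with the counting rule.

The normalization factor is the decimal mantissa of the library size,
`N_U / 10^floor(log10 N_U)` ∈ [1, 10). It is computed from the integer
digit count rather than floating `log10`, so exact powers of ten are
never perturbed. An optional exclusion mask (e.g. satellite repeats)
drops whole reads before counting; the library size used for
normalization is the post-mask read count.

## Window construction and the DMR test

Analysis windows are 8 kb — 4 kb either side of the anchor (TSS for
promoter-linked regions, CGI midpoint otherwise) — snapped outward to
the 100-bp grid, and divided into three near-equal segments with
boundaries at `floor(i·L/3)` (2666/2667/2667 bp for an 8,000-bp
window): left shore, CGI core, right shore. A `shore2k` mode
(2000/4000/2000) reflects the alternative convention that shores
extend 2 kb from the island; equal thirds is the default. Windows
crossing a chromosome end are flagged truncated and excluded from
testing rather than padded, keeping segment lengths comparable.

Promoters are TSS ± 2 kb. CGI class precedence is promoter >
intragenic > intergenic, so each island gets exactly one class. Shore
labels are genomic left/right by default; a strand-aware option
relabels them upstream/downstream for minus-strand promoters.

The group comparison is a two-sided pooled-variance Student t-test on
per-sample region means (Welch available by flag), df = S₁ + S₂ − 2.
Degenerate inputs are resolved explicitly: two identical constant
groups give t = 0, p = 1; constant groups with different means give
p = 0 with a degenerate flag rather than NaN. Both the whole window
and each segment are tested and emitted, labeled; only segment tests
below the class threshold (0.05 promoter CGI, 0.01 otherwise, both
configurable) are flagged as individual DMRs. No multiple-testing
correction is applied by default, matching the raw-threshold
convention of the analysis this reimplements; Benjamini–Hochberg
recalibration of the flags is available (`bh_adjust`).

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes,
at desk scale, as a pure function of (config, seed); every stochastic
stage draws from its own named stream of one seed, so changing one
stage's internals cannot shift another's draws.

Layout: entities (genes, intergenic CGIs) occupy disjoint 24-kb slots
so no two 8-kb windows overlap; clustered genes sit in consecutive
slots of one chromosome. Defaults give 200 windows whose class mix
(84 promoter CGI / 46 intragenic / 34 intergenic / 36 non-CGI
promoter) roughly mirrors the proportions of a genome-wide screen.
`background_slots` (default 800) appends window-free genome so that
windows cover ≈ 7% of the genome, close to the share 8-kb CGI/promoter
windows occupy in a mammalian genome.

The background share is not cosmetic. Enrichment sequencing is
compositional: planted tumor signal inflates the tumor libraries'
total read counts, and the library-size normalization then
systematically deflates every tumor bin. With no background (windows =
100% of the genome) the planted defaults shift tumor null bins by
~13% and the group t-test rejects a large fraction of null windows;
at the realistic ~7% window share the residual shift (~2%) is
negligible against sampling noise. The same effect exists in real
MBD-seq at a much smaller magnitude.

Reads: per-bin counts are Poisson with rate `baseline_bin_rate`
(default 0.5 per 100-bp bin, a scaled-down stand-in for ~20M-read
libraries), multiplied by `dmr_effect` (default 3) over planted
windows in tumor samples; 15% of windows are planted, all
hypermethylated. Reads start uniformly within their bin and span 36
bp, so they can cross bin boundaries as real reads do.

Survival: an exponential proportional-hazards model,
`h_i = h₀ · exp(β·risk_i + β_age(age_i − 58) + β_grade(grade_i − 2))`,
with a planted high-risk group (default 25% of patients, log HR =
log 2 attached to the first cluster) and independent uniform censoring
whose upper bound is solved numerically so the expected censored share
equals `censoring_fraction`. The methylation matrix used for
stratification draws per-gene promoter methylation around group means
recorded in the ground truth (risk-cluster genes shifted +4 units for
high-risk patients, sd 1), so detection of the planted group is nearly
noiseless and recovery tests measure the survival machinery, not
detection error.

Expression: `expr_gs = base_g · exp(−γ·(meth_gs − mean_g) + ε)`,
ε ~ N(0, noise_sd). The defaults γ = 1, meth sd = 1, noise_sd = 0.75
give a generative log-scale methylation–expression correlation of
−γ/√(γ² + σ²) = −0.8.

Two layers, one config: the read layer (group-level planted windows,
all tumors elevated) is the ground truth for DMR calling; the
methylation-matrix/expression layer (patient-subgroup effects) is the
ground truth for stratification and coupling. Keeping them separate
means each analysis is scored against an uncontaminated truth —
subgroup effects do not create partial group-level differences that
would count as false positives in the DMR screen.

What the generator does **not** emulate: CpG dinucleotide placement or
any sequence-level realism, fragment-length and GC bias, copy-number
or tumor-purity confounding, correlated noise between neighboring
bins, batch effects. Passing recovery tests therefore demonstrates
correctness of the statistical machinery under the stated model, not
robustness to these real-data phenomena. The synthetic conservation
track is a stand-in shaped like a phastCons track (Beta noise plus a
TSS-proximal bump), not derived from alignments.

## Survival conventions

* Q3 dichotomization uses the linear-interpolation quantile at
  position 0.75·(n − 1) (the numpy/pandas default); HM is *strictly*
  above Q3, guaranteeing ≤ 25% HM per gene for distinct values.
* The gene screen keeps genes with HR > 1 and log-rank p < 0.3
  (borderline genes deliberately retained); the HR < 1 subset is
  reported but unused. **Caveat:** the screen conditions on the same
  survival data that the combined cluster is later tested on. On a
  truly null cluster this circularity inflates the final log-rank
  significance far above its nominal level (measured at roughly 60%
  "significant" at n = 400 in the test conditions). The screen is
  therefore an exploratory ranking device; ground-truth recovery
  evaluations, including the acceptance script, run with
  `select_genes=False`, and published p-values from the screened
  pipeline should be treated as descriptive.
* ROC cutoff: candidates are observed HM counts (floored at 1);
  "best" is Youden's J for classifying dead vs alive; the final
  cutoff is the **lower median** over 200 bootstrap picks. The median
  replaces the more obvious mode because adjacent near-equivalent
  cutoffs split the mode's vote, letting a strictly worse but
  distinctive candidate win (observed in practice as a systematic
  preference for cutoff 1, which dilutes the high group). With
  `n_boot ≤ 1` the cutoff is the exhaustive maximizer on the full
  sample. A fixed cutoff override exists because a cutoff of 1
  ("hypermethylated in at least one gene") is a meaningful clinical
  convention.
* Cox fits use lifelines with Efron tie handling and a tightened
  Newton precision (1e−12) so small-sample estimates agree with a
  brute-force partial-likelihood maximizer to ~1e−8. Age and grade
  enter numerically, ER as binary with unknowns excluded. Monotone
  likelihood is flagged (extreme coefficient) rather than raised;
  univariate per-gene fits fall back to a direction report on
  separation.

## Profiles

160 bins × 50 bp over TSS ± 4 kb, strand-oriented (minus-strand
windows reverse-complemented / reversed so bin 0 is always 4 kb
upstream in transcription sense). GC = (G + C)/50 with ambiguous bases
counted as non-GC — the denominator is fixed. Conservation bins
average only scored bases; fully unscored bins are missing, and
summaries use the sample (n − 1) standard deviation (0 for a single
member), computed over non-missing entries. One profile per gene model
row; genes with truncated windows are skipped with a warning.

## Expression integration

* z-scores standardize log2(RPKM + 1) per gene with the sample (n − 1)
  sd; constant genes yield a zero row plus a flag.
* Group fold change is log2 of group mean RPKM ratios with a
  pseudocount of 1 (not the mean of per-sample logs), antisymmetric
  under group swap by construction.
* Outlier handling in the methylation–expression correlation drops
  samples in the top or bottom `trim_fraction` (default 5%) of either
  variable, then computes Pearson r. Note the estimand changes:
  symmetric 5% trimming of a bivariate normal at r = 0.8 estimates the
  doubly-truncated correlation (≈ 0.70), not the generative 0.8 —
  recovery comparisons against a generative value should use
  `trim_fraction=0`.
* 2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_ref)_treated −
  (Ct_target − Ct_ref)_control; all four Ct values are required.

## Evaluation conventions

DMR recovery against planted truth is scored per direction: the
hypermethylation screen is evaluated on hyper-direction calls (a call
is true iff it overlaps a planted window), and hypo-direction calls —
which have no planted counterpart — are reported separately rather
than folded into the hyper screen's FDR. Counting is at the level of
emitted tests (whole window + three segments), sensitivity at the
level of planted windows (recovered iff ≥ 1 matching call).

## Problem sizes

Default study conditions: 20 tumor / 10 normal samples, one ~23-Mb
chromosome, ~115k reads per sample, 200 windows with 30 planted.
Survival recovery runs 20 independent cohorts of 400 patients
(methylation matrix only — the read layer is not needed there).
The null-calibration check uses 5,000 windows of 10 vs 10 samples.
These sizes were chosen so the full validation cycle completes in a
few minutes on a single core while leaving every estimate's sampling
error well inside its acceptance band.

## Known limitations

* Count models are Poisson; real MBD-seq is overdispersed. The t-test
  on region means is robust to mild overdispersion, but rate-ratio
  effect sizes would be attenuated in real data.
* Raw-threshold DMR calling (no FDR control) mirrors the original
  convention; for genome-scale use the BH option is advisable.
* The gene-selection screen's circularity (above) is the largest
  statistical caveat of the cluster survival procedure.
* The ROC objective (classifying dead/alive at end of follow-up)
  ignores censoring times; it is a heuristic for cutoff choice, not a
  proper survival-model criterion.
* No paired designs, time-dependent covariates, or competing risks.
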
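# Methods

## The problem

Relative quantification of miRNA expression by RT-qPCR divides each target's
abundance by a normalization factor built from endogenous reference genes.
If the "references" are themselves deregulated between the compared groups,
every downstream fold change inherits that bias.  `mirnorm` implements the
standard four-stage workflow for selecting and validating reference miRNAs in
a tumor vs. nonmalignant tissue setting with three sample groups
(nonmalignant, low-grade, high-grade): (1) a microarray invariance screen
produces candidate references; (2) replicate-level Cq data are converted to
efficiency-corrected relative quantities; (3) three stability algorithms rank
the candidates; (4) the practical impact of normalizer choice on target fold
changes is quantified.

## Quantification model

For assay *a* with amplification efficiency `E_a` (fraction of perfect
doubling, `E = 10^(-1/slope) - 1` from a dilution-series slope in cycles per
log10 input), the relative quantity of sample *s* is

```
RQ_as = (1 + E_a) ** (Cqref_a - Cq_as)
```

Replicate wells are averaged first; inter-run offsets are removed by
aligning each run's inter-run-calibrator (IRC) mean Cq to the grand IRC mean
per assay (additive on the Cq scale, idempotent).  `Cqref_a` is the
across-sample mean Cq of the assay ("mean-centering"), chosen over a
minimum-Cq or named-calibrator reference because it is symmetric, robust to
single outliers, and makes every assay's geometric-mean RQ equal 1 — an
arbitrary-units convention under which all fold changes are invariant.  A
named-calibrator mode is available.  qBase-style error propagation
(confidence intervals on RQ) is out of scope.

A useful identity of this model: a per-sample loading shift of `L_s` log2
units moves Cq by `-L_s / log2(1+E_a)` cycles, and converting back to log2 RQ
multiplies by `log2(1+E_a)`; loading therefore enters log2 RQ as `L_s`
exactly, for any efficiency, and cancels exactly in normalized ratios when
references are truly stable.

## Candidate selection from microarrays

Raw intensities are floored at 1.0, log2-transformed and shifted per array so
the 90th percentile of each array's log2 values is zero (percentile-shift
normalization; removes per-array multiplicative factors).  A gene is a
candidate when (a) its detection flag is present in every array, (b) both
tumor-vs-nonmalignant linear fold changes (`max(r, 1/r)` of group-mean
ratios) are below 1.2, and (c) the across-3-group p-value exceeds 0.05.  The
filter runs on normalized (label N) and raw (label R) data; the union (NR for
both) is the candidate panel.  Choices worth noting:

* The across-group test is Kruskal-Wallis by default (`anova` available),
  consistent with the nonparametric statistics used elsewhere in the
  pipeline; the original vendor tool does not document its test.
* Zero-variance genes get p = 1 (equality cannot be rejected); this makes
  selection of exactly invariant genes certain, which is also why recovery
  of planted invariant genes is only guaranteed in the noise → 0 limit — at
  any nonzero noise an invariant gene's p-value is uniform and it fails
  `p > 0.05` with probability alpha.
* No multiple-testing correction: large p is the *pass* condition here, so a
  correction would admit more genes, not fewer.
* Both pairwise tumor-group fold changes must pass (not pooled tumors).

## Pre-screens before stability analysis

Assays whose mean Cq in pooled-RNA pre-screen samples exceeds 35 cycles are
excluded as unquantifiable.  When both mature arms of one pre-miRNA hairpin
(-5p/-3p) are candidates, only the higher-expressed arm (lower mean Cq) is
kept; exact ties keep the lexicographically first name.

## Stability algorithms

**geNorm.**  `M_j` = mean over other candidates *k* of the SD (ddof = 1) of
`log2(RQ_j / RQ_k)` across samples.  The gene with the largest M is removed
and M recomputed until two genes remain (the joint most-stable pair, sharing
rank 1; ties on max M eliminate the lexicographically last gene).  For the
stability-ordered genes, `NF_n` is the per-sample geometric mean of the top
*n*; `V(n/n+1)` = SD of `log2(NF_n / NF_{n+1})`.  The recommended set is the
smallest `n >= 2` with `V < 0.15`; when no V falls below the cutoff the
method recommends nothing — a legitimate outcome on heterogeneous panels.
M and V are invariant to per-gene and per-sample rescaling.

**NormFinder.**  On `y = log2(RQ)`: the per-sample gene mean is subtracted
(removing loading), intragroup variances are bias-corrected by
`sigma2_ig = (s2_ig - sum_i' s2_i'g / (k(k-1))) * k/(k-2)` (truncated at 0;
hence the k >= 3 requirement), intergroup differences `d_ig` are shrunken by
an empirical-Bayes factor `gamma2 / (gamma2 + sigma2_ig/n_g)` with `gamma2 =
max(0, Var(d) - mean(sigma2_ig/n_g))`, and the stability value is
`rho_i = mean_g(|d~_ig| + sqrt(sigma2_ig/n_g))`.  `Var(d)` uses ddof = 1 (the
published model leaves this estimator detail to the implementation).  The
best pair is found by exhaustive search over averaged pseudo-genes with
intragroup variance `(sigma2_i + sigma2_i')/4`.  With a single group the
model reduces to ranking by the corrected variance, `rho_i =
sqrt(sigma2_i)`.  Exact numeric agreement with the original spreadsheet
add-in is not claimed; the formulas above are the contract, validated by
algebraic identities (before truncation, `sum_i sigma2_ig = k/(k-1) sum_i
s2_ig`) and planted-truth ranking recovery.

**BestKeeper.**  Works directly on replicate-mean Cq.  The dispersion
driving ranking and the inconsistency rule is the mean absolute deviation
(MAD) around the arithmetic mean — the original tool's "SD" — with the
classical SD also emitted; `x_fold = (1+E)**MAD`.  Genes with MAD > 1 cycle
are flagged inconsistent and excluded from the BestKeeper index (the
per-sample geometric mean Cq of retained genes) but still reported with
blank ranks.  Genes are ranked by MAD ascending with Pearson r against the
index (descending) as tie-breaker; a constant index yields missing
correlations rather than an error.  The historical 10-gene limit of the
spreadsheet is available as `compat_limit=True` only; natively there is no
limit.

The consensus table merges the three reports one row per gene; geNorm's
joint top pair is displayed with distinct ranks broken lexicographically.

## Associations

Spearman rank correlation (midranks for ties) over all candidate pairs;
pairs with r >= 0.60 are flagged co-expressed.  Clinical tests per
candidate: age by Spearman; sex, malignancy and low-vs-high grade by
two-sided Mann-Whitney U (exact null distribution when the combined n is at
most 20 and tie-free, asymptotic otherwise); stage by Kruskal-Wallis with
Dunn's pairwise z-tests (midranks, tie correction, normal reference) when
the global p < 0.05.  Dunn's p-values are reported raw; Bonferroni/Holm
adjustment is available but off by default, since whether to adjust is an
analyst's choice.  Dunn's test is implemented in-package.

## Normalizer impact

Each target is divided by the scheme's normalization factor (geometric mean
of the scheme's reference RQs); the effect size is the ratio of malignant to
nonmalignant group medians (medians match the boxplot-style presentation of
such experiments; a mean mode exists), with a two-sided Mann-Whitney p.
Concordance across schemes requires agreement on both direction and the
significance verdict.  Closed form used as a test oracle: adding one
reference up-shifted by `delta` log2 units to *n* stable references biases
the estimated target log2 fold change by exactly `-delta/(n+1)` at zero
noise.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
miRNA biology.  A sample well's expected Cq is

```
Cq = base_a - (loading_s + log2fc_a(group_s)) / log2(1 + E_a)
     + run_offset_r + noise
```

Defaults are the study design: 8/8/8 arrays for the screen; 17/20/21 qPCR
samples; triplicate wells; 2 IRC samples measured in triplicate per run;
per-assay efficiencies uniform in [0.81, 0.88]; per-assay base Cq uniform in
[22, 28]; replicate noise Gaussian with SD = CV% x expected Cq / 100, CV per
assay uniform in [0.15, 0.35]%; a 14-assay candidate panel (11 miRNA-like +
3 small-RNA-like names) with 10 planted invariant and 4 planted deregulated
assays at |log2FC| in {0.5, 1}.  Free parameters the design does not pin
down, chosen once as field-realistic values: per-sample loading SD 0.5 log2
units (about 1.4-fold RNA input/quality variation between specimens);
inter-run offset SD 0.3 cycles across 3 runs; microarray per-spot log2 noise
SD 0.25 and 150 deregulated background genes at |log2FC| in [0.5, 3]; a
detection floor placed so that ~14% of background genes are present in all
arrays (the screen's observed yield), capped just below the planted panel's
minimum intensity so the panel models genes that did pass the vendor
present-call everywhere.

What the generator deliberately lacks: per-sample biological heterogeneity
of individual assays (deregulation is a fixed group shift), probe-level
artifacts, partial RNA degradation, and missing wells.  Consequently (a)
group separation of planted effects is sharper than in real tissue, so a
biased normalizer mostly *biases* fold changes rather than destroying
significance unless its deregulation rivals the target's; and (b) passing
recovery tests demonstrates estimator correctness under the assumed noise
model, not robustness to real-tissue pathology.

## Numerical conventions

All SDs use ddof = 1.  RQ values must be strictly positive and finite;
missing Cq propagates to missing RQ, and samples missing any reference RQ
are dropped from normalization factors with a warning (no imputation).
Replicate outlier trimming (drop one well deviating > 0.5 cycles from the
replicate median) exists but is off by default.  Geometric means are
computed in log space.  Deterministic tie-breaks are lexicographic
throughout and documented at each site.  All simulations are driven by a
single integer seed through `numpy.random.default_rng`.

## Problem sizes used in validation

The test-suite and the acceptance script run the full validation design
(58 samples x 14 assays in triplicate): 200 replicate studies for ranking
recovery in the tests (100 in the acceptance script's summary), 100
replicates for fold-change recovery in the tests (50 in the script), 200
random panels for the geNorm oracle sweep — sizes at which the reported
rates are stable to within a few percent.
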
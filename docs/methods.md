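# Methods

This note records the models, conventions and numerical choices behind each
module, what the synthetic generator does and does not emulate, and the known
limitations. Everything stated here is computed by the package's tests or
scripts; nothing is quoted from external analyses.

## Repertoire metrics

A clonotype is identified by `(CDR3aa, V, J)` by default; nucleotide-level keying
(`nt_vj`) and CDR3aa-only keying are available, and paired tables must use the
same key (enforced). Duplicate keys within a table are merged by summing counts
before richness or clonality is computed.

The productive-CDR3 rule retains sequences with no `*`/`_` symbol, length ≥ 5
residues (the rule concerns amino-acid sequences, so "length" is in residues),
starting with `C` and ending with `F` or `W`. The filter is idempotent and
re-normalizes frequencies over the retained records; an all-nonproductive input
yields an empty table with a warning rather than an error.

Clonality uses the natural logarithm and normalizes Shannon entropy by ln(R). A
single-clonotype repertoire has clonality 1 by convention — it is the limit of a
maximally dominated repertoire, and leaving it undefined would drop monoclonal
samples from summaries. Whether clonality is computed before or after productive
filtering is the caller's choice; every pipeline in this package filters first.

## Clonal dynamics

The two-sided Fisher exact p-value is computed as the sum of hypergeometric
probabilities, over the support of the clone's combined count, of all outcomes
whose probability does not exceed the observed one up to a relative tie slack of
1e-7 (the convention of common implementations; an exact-rational oracle in the
test suite reproduces it to 1e-10). Computing over the combined-count support
(rather than the full repertoire depth) keeps the test exact and fast at depths
of 1e5.

Design choices: p-values are unadjusted at α = 0.05 by default, with
Benjamini–Hochberg behind a flag; frequency ties with nonzero counts are
"unchanged"; clones with a zero count on one side are "new"/"lost", tracked as
their own categories and excluded from the Fisher screen (the test is defined
for ITCs). "Strong clonal contraction" is read as differential-contracted.
Clonal-space denominators use productive-only totals.

Frequency rank bins assign a clone with frequency f to the decade bin labelled
`10^floor(log10 f)` (so 1.0 → 10⁰, 0.03 → 10⁻²). The source description of the
binning is internally inconsistent about whether [0.1, 1) belongs to the 10⁰ or
the 10⁻¹ bin; the floor convention is used because it matches both worked
examples and makes the bins a partition.

## Expression signatures

Marker scores are arithmetic means of log2(FPKM+1) over the listed genes;
genes absent from the matrix are dropped with a warning and an all-absent list is
an error. Cytolytic activity converts to the linear scale (2^x − 1) before the
geometric mean and is reported on the linear scale. The loader applies a
documented alias map for typographic variants of gene symbols (CXLC9 → CXCL9).

ssGSEA ranks each sample's genes descending (ties by average rank; tie order is
made deterministic by gene position) and accumulates the difference between the
weighted in-set ECDF (weights rank^0.25, the cited software's default exponent,
normalized over set members) and the uniform out-of-set ECDF; the enrichment
score is the sum of the running difference. Scores are normalized by the global
(max − min) across all sets and samples; for presentation, each hallmark is
z-scored across samples (ddof = 1) and clipped to [−2, 2], with zero-variance
hallmarks set to 0 with a warning. Immune/stromal "ESTIMATE-like" scores are the
same operator over user-supplied immune/stromal GMT sets — a clearly labelled
stand-in, since the published gene lists are external resources.

The IFN/EMT candidate rule keeps members of the EMT / IFN-α / IFN-γ sets whose
group means differ by at least one log2 unit (two-fold linear), boundary
inclusive. The elastic net minimizes

    (1/2n)·Σ(yᵢ − β₀ − xᵢ·β)² + λ·[α·‖β‖₁ + (1−α)/2·‖β‖₂²]

with α = 0.5, λ = 0.24, predictors standardized to unit variance (1/n
convention), an intercept, and y the binary well/poor indicator fitted with a
squared-error objective. Only genes with nonzero coefficients are retained, and
the standardization parameters are frozen in the serialized model so scores are
reproducible on new data. λ = 0 falls back to ordinary least squares; a penalty
that zeroes every coefficient raises an explicit empty-model error. The number
of selected genes is a data-dependent outcome, not a target.

## TME subtypes

Clustering row-scales the hallmark-score matrix (z per hallmark, ddof = 1) and
applies Ward linkage to sample vectors — equivalent to ward.D2 on Euclidean
distances — cut at k = 3. "Half-supervised" subtyping is implemented as this
unsupervised clustering followed by supervised marker-group labelling: each
cluster takes the label of the marker group (IE: IFN-α/IFN-γ/inflammatory;
proliferation: E2F/MYC/DNA-repair/mTORC1; fibroblast: EMT/TGF-β/KRAS/angiogenesis)
with the highest mean scaled score, assigned greedily so that no two clusters
share a label; exact ties resolve by the fixed priority IE > proliferation >
fibroblast with a warning. The default hallmark list is the eleven named marker
hallmarks plus two configurable slots (apoptosis, glycolysis by default) for a
total of 13; the exact list is configurable because it is not canonical.
Clustering uses hallmark scores only; extra feature rows can be appended via
configuration. Degenerate partitions (tiny clusters, near-zero silhouette) are
flagged with a warning rather than an error.

## Neoantigen linkage

The affinity filter is strictly `< 500 nM` as printed; the percentile-rank
filter keeps rank ≤ 2.0 (boundary inclusive — the strictness is not specified at
the boundary, so the inclusive choice is documented and configurable). MHC
binding and TCR–pMHC predictions themselves are out of scope: the module
consumes prediction tables and the generator emits synthetic ones.
"High-affinity ITCs" counts distinct clonotypes (not distinct pairs). TMB divides
the nonsynonymous count by the 33.86 Mb panel size.

## Clinical statistics

Response boundaries: pCR is exactly 0 % residual viable tumor and a subset of
MPR (≤ 10 %); 33 % itself counts as pPR and a *well* responder (the descriptive
texts disagree between "< 33 %" and "33 % or fewer"; the inclusive reading is
used). CPS is capped at 100 per assay convention, with a warning below the
conventional 100-cell denominator.

Kaplan–Meier handles ties with deaths before censorings; the weighted variant
replaces risk/event counts by weighted sums, and Greenwood's formula gives
normal-approximation intervals clipped to [0, 1]. The log-rank statistic uses
the hypergeometric variance with the (Y−d)/(Y−1) correction and a generalized
inverse for K > 2 groups; with IPTW weights the same formulas run on weighted
counts (the usual plug-in adjustment — its variance is approximate, and the
calibration study below shows it errs conservative). OS is clocked from the
first neoadjuvant dose and RFS from surgery via separate time fields.

Propensity scores come from a multinomial logistic model on categorical
covariates (tumor site, clinical stage); a covariate level exclusive to one arm
separates the likelihood and raises an error naming the level. The default
estimand is a stabilized ATE weight (1/P(arm|X) times the marginal arm
frequency; mean ≈ 1), configurable to unstabilized. Balance uses standardized
mean differences on level indicators with the < 0.25 cutoff. Hazard ratios are
delegated to a standard weighted proportional-hazards routine (lifelines) and
reported pass-through; KM, log-rank, SMD and weights are bespoke.

Simon design: stop after stage 1 iff ≤ 4 of 6 successes; success iff ≥ 24 of 27
with continuation; E[N] = 6 + 21·P(continue); all exact binomial sums. The
feasibility/safety *monitoring* probabilities described alongside the design
("probability ≥ 90 % for > 25 % of patients") are ambiguous as printed and are
not implemented; only the exact two-stage rule is.

## The synthetic cohort generator

The generator defines the study conditions. Defaults mirror the trial where the
trial reports them (25 evaluable patients, 11 well / 14 poor responders, stage
and site frequencies, ITC clonotype fractions of 0.44 / 0.20 for well / poor)
and otherwise use values fixed once as realistic: 100,000 templates over 1,000
clonotypes per repertoire (per-sample sequencing depth is not reported and is
fully configurable), a rank-frequency power law with exponent 1, unit-variance
log2 expression noise (all planted shifts are therefore in noise z-units),
signature and subtype effects of 2 log2 units, a 5× / 1.5× expansion factor for
well / poor responders, exponential survival with a stage effect of 0.8 log-HR
per level and stage-confounded arm assignment (log-odds 1.2), and a null arm
effect by default so IPTW recovery is testable against a known truth.

Paired repertoires: persistence is frequency-weighted (dominant clones are more
likely to persist); among persistent clones the *dominant* ones contract and the
*rarest* expand — matching the biology of exhausted dominant clones and rare
tumor-reactive clones, and, by construction, keeping the expanded clonal space
small enough to scale. Stable clones keep exactly their pre-treatment
probability and the contracted set absorbs the renormalization mass in closed
form, so planted-stable clones are an exact null for the Fisher screen and
planted-expanded clones sit at exactly the configured frequency ratio before
multinomial sampling. Every clone is guaranteed ≥ 1 template (one template is
allocated per clone before the multinomial draw), which keeps ground-truth
categories observable; a single master seed is split into named per-component
streams so any table can be regenerated independently and byte-identically.

What the generator does *not* emulate: V(D)J recombination statistics, sequencing
error profiles, read-level data, batch effects, gene–gene correlation beyond the
planted block structure, non-exponential survival, or informative censoring.
Passing recovery tests therefore demonstrates that the analysis recovers planted
effects under clean sampling noise — not that it is robust to the artefacts of
real libraries.

## Test-scale choices

The recovery and calibration suites are sized to run in minutes on one CPU:
expansion-sensitivity uses 200 clones × 100,000 templates × 100 seeds (≈ 1,600
eligible planted-expanded clones pooled); TME clustering uses 13 hallmarks × 30
samples × 100 seeds at the study's subtype shift of 2 z-units; the IPTW study
uses 200 patients × 100 seeds; calibration uses 10,000 null replicates (log-rank
at n = 2×50 exponential, Pearson at n = 17). Measured behaviours at these
conditions: expansion sensitivity 1.00 with a 4.8 % false-call rate on the exact
null; mean clustering ARI 0.92 (the same clustering at a planted shift of 1.5
z-units yields mean ARI 0.70, because row-scaling absorbs part of the
between-group shift — planted separations are diluted by the factor
√(1 + s²·p(1−p)) in the scaled space); weighted log-rank size 0.02 vs 0.54
unweighted under planted confounding, with every post-weighting SMD < 0.25;
log-rank size 0.053 and Pearson size 0.049 at nominal 0.05. The elastic net at
its fixed hyperparameters recovers each planted signature gene in the large
majority of seeds, but recovers *all three* simultaneously in ≈ 73 % of seeds at
unit noise (the three planted predictors correlate through the shared group
shift, so the L1 stage occasionally drops one); the package reports this rather
than quietly easing the conditions.

## Known limitations

* The weighted log-rank and weighted KM use plug-in weighted counts without a
  robust variance; inference under extreme weights is conservative/approximate.
* ssGSEA normalization is global (max − min); scores are comparable within a
  matrix, not across independently processed matrices.
* The elastic-net λ is interpreted in the (1/2n)-loss convention; coefficients
  are not comparable to software using a different scaling without converting λ.
* Clustering at k ≠ 3 is supported, but subtype labelling requires at most one
  cluster per marker group.
* The CPS cap at 100 and the inclusive top-2 % boundary are conventions chosen
  where the source texts are silent; both are configurable.
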
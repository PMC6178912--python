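# Methods

This note documents the statistical models, the estimation choices, and the
scope of the benchmark simulator, in enough detail to judge what a passing
test suite does and does not establish.

## Counts from abundance

Salmon-style quantifiers report, per transcript and sample, the relative
abundance (TPM), the effective length (transcript length adjusted for the
fragment-length distribution), and an estimated fragment count. Expected
fragment yield scales with abundance × effective length, so estimated
counts carry a length dependence that would confound usage proportions: a
switch between isoforms of different lengths changes the gene's total count
even when total expression is constant. The `scaledTPM` mode removes the
length dependence by rescaling TPM per sample to the mapped-read total
(column sum of `NumReads`); `lengthScaledTPM` first multiplies TPM by the
across-sample mean effective length and is appropriate for gene-level
analysis; `raw` counts should be paired with the abundance-weighted average
transcript-length offsets that `summarize_to_gene` computes
(`offset[g,i] = Σ_t w_ti · efflen_ti` with `w` the within-gene TPM weights;
unweighted mean when the gene has zero TPM in a sample). All-zero rows are
dropped at import. A sample with zero total TPM is an error: the rescaling
is undefined, and silently emitting zeros would corrupt every downstream
proportion.

## Pre-modeling filters

Three rules, evaluated in one pass against the pre-removal gene totals:
transcript count ≥ `min_feature_expr` (default 10) in ≥ `n.small` samples;
within-gene proportion ≥ `min_feature_prop` (default 0.1) in ≥ `n.small`
samples; gene total ≥ `min_gene_expr` (default 10) in all `n` samples.
`n.small` defaults to the smallest group size. Genes keeping fewer than two
transcripts are dropped entirely. Proportions use the gene total over all
transcripts present before any removal and are 0 where the gene total is 0;
the filter is idempotent and monotone in each threshold, and both
properties are tested. Whether proportions should be recomputed after
transcript removal is a genuinely open design point; this implementation
does not recompute, and documents that as its contract.

The post-hoc filter computes the standard deviation (n−1 denominator) of
each transcript's per-sample proportions, ignoring group labels, and masks
transcripts with SD < 0.1. Callers set masked p-values and adjusted
p-values to 1 without recomputing the adjustment — the point is to remove
small-effect-size calls, accepting mild conservativeness. It is applied by
default on the Dirichlet-multinomial path only, where it has the most
effect on false discovery control.

## Dirichlet-multinomial model

For a gene with K transcripts, the count vector of sample i (total n_i) is
DM(π, γ) with log-likelihood (multinomial coefficient omitted; it cancels
from every ratio):

    lnΓ(γ) − lnΓ(n_i + γ) + Σ_k [lnΓ(y_ik + γπ_k) − lnΓ(γπ_k)]

γ is the per-gene precision; dispersion = 1/(1+γ). The usage test compares
a full model with one proportion vector per condition group against a
pooled null, LR ∼ χ² on (K−1)(groups−1) df. Proportions are maximized over
the simplex through a softmax parameterization with analytic gradients
(L-BFGS-B); the precision by bounded scalar search on log γ in
[ln 1e-2, ln 1e6]. Counts are rounded to integers first (scaledTPM values
are fractional). Negative LR from numerical ties is floored at 0.

Precision estimation is the one genuinely delicate choice. Profiling out
the proportions biases the raw profile-likelihood estimate upward, so the
profile is penalized by the Cox-Reid adjustment (half the log-determinant
of the observed information of the proportion parameters at their MLE, in
free-logit coordinates), which makes the estimate median-unbiased in
simulations (γ̂ ≈ 20–21 at truth 20, 6 vs 6). Even then, an estimate tuned
on the group-split fit leaves the LR test anticonservative (7–9% rejections
at nominal 5% under a null DM simulation), while an estimate from the
pooled fit is calibrated but collapses under strong switches — the pooled
proportions then misfit grossly, the apparent overdispersion explodes, and
the test loses exactly the strongest signals. The estimator therefore uses
two regimes: the pooled (null-model) CR-adjusted estimate by default, and
the within-group (full-model) estimate when the latter exceeds the former
by more than 1.5 on the log scale. Under the null the log-gap has SD ≈ 0.4,
so the escape fires rarely and the test's size stays at 3–6%; under real
switches the gap is several log units and power is retained. A common
precision (shared γ maximizing the summed within-group adjusted profile on
a seeded 10% gene subset) is computed for initialization and diagnostics;
no moderation/shrinkage toward it is applied.

When one condition group has all-zero counts for a transcript that the
other group expresses, the group-wise proportion MLE sits on the simplex
boundary and no precision is estimable; the gene's p-value (and its
transcript p-values) are reported missing. `sanitize_pvalues` turns missing
into 1 before stage-wise testing. These degenerate genes are typically
total isoform switches — true positives sacrificed for honesty about the
likelihood; the NB path detects them instead.

Per-transcript tests collapse the gene to (this transcript, sum of others)
and run the same LR test as a two-category DM (beta-binomial), reusing the
gene-level γ rather than refitting, with df = 1. For K = 2 the two
transcripts give identical statistics by construction.

## Negative-binomial one-vs-rest test

Each transcript's (this, others) pairs across samples are modeled as NB
(variance μ + αμ²) in a GLM with log link, median-of-ratios size factors
(normalized to geometric mean 1) as offsets, and design
`~sample + feature + condition:feature`; the reduced model drops the single
interaction coefficient, so the LRT has df = 1. Sample effects absorb total
gene expression per sample; the feature effect absorbs baseline usage.
Non-converged fits yield a missing p-value, sanitized downstream.

Dispersion: per-transcript Cox-Reid adjusted profile MLE (mean held at the
current GLM fit, two refinement passes; α bounded in [1e-8, 10]); a
parametric trend α(μ) = a₁/μ + a₀ fitted by gamma-family iteratively
reweighted least squares in which points more than 15× above the current
trend are excluded before each refit (one dispersion outlier must not drag
the curve) and floor-level estimates enter as zeros; final values are the
MAP under a log-normal prior centered at the trend, with prior variance
estimated from the MAD of the log residuals (floored at 0.25). Estimates
more than two prior SDs above the trend are kept at their MLE — shrinking a
genuine outlier down would manufacture false positives.

Gene-level aggregation is the Šidák-corrected minimum,
p_gene = 1 − (1 − min_t p_t)^K, BH-adjusted across genes. It is bounded
between the minimum and the Bonferroni bound K·min p (tested), and BH was
chosen over a q-value estimator for transparency.

## Stage-wise testing and OFDR

Screening: BH over gene p-values (skipped when the caller supplies
already-adjusted values, as the NB path does); genes with adjusted p ≤ α
pass. Confirmation: within each screened gene, Holm with the Shaffer
reduction — the i-th smallest p-value is multiplied by max(K−i, 1), with a
running maximum and cap at 1. The reduction is justified by the simplex
constraint: a usage change in one transcript forces a change in at least
one other, so the global null cannot fail by exactly one hypothesis, and
for K = 2 both transcripts keep their raw p (which coincide for one-vs-rest
tests). Reported transcript values are multiplied by G/|S| (universe size
over screened count) and capped at 1, so comparing them against α enacts
the confirmation level α·|S|/G. α must be fixed before running; the output
is not valid at any other threshold. Identifiers are truncated to 15
characters before joining, which strips Ensembl/GENCODE version suffixes.

The guarantee is on the overall false discovery rate: in expectation at
most α of the screened genes either contain no usage change at all or
contain a falsely confirmed transcript. The evaluation module scores
exactly this definition, with the empty-screen convention OFDR = 0, and
computes sensitivity as confirmed true switching transcripts over all true
switching transcripts in the post-filter universe.

## Benchmark simulator

The generator emulates a two-group bulk RNA-seq benchmark at the count
level. Baseline: isoform counts per gene drawn from a categorical
distribution over 1–7 (thin right tail); log-TPM from N(ln 5, 1.8²);
transcript lengths log-normal (median 2 kb), effective length = length −
200 floored at 25. Transcripts whose expected baseline count falls below 10
have abundance set to 0; abundances are redrawn for any gene left with no
expressed isoform, so every gene is expressed (the real-data analogue is
restricting to expressed genes). Default library sizes are uniform on
[31.4, 38.5] million reads scaled by n_genes/15017, keeping per-gene depth
realistic at any simulation size.

Differential truth: floor(fraction × n_genes) genes per category, remainder
null. DGE multiplies all isoforms of a randomly chosen group by 2^U,
U ~ Uniform(1, 2.58) (fold change 2–6), leaving proportions intact. DTE
applies the fold change to one randomly chosen expressed isoform. DTU
exchanges the TPM of two expressed isoforms with distinct abundances (or
the sole expressed isoform with an unexpressed one), conserving the gene
total exactly. Effective truth labels are derived from the constructed
abundances: a gene is DGE-true iff its total differs, DTE-true iff any
transcript's expression differs, DTU-true iff any within-gene proportion
differs — so DTE genes with other expressed isoforms are DGE- and DTU-true,
a sole-isoform DTE gene is DGE-true only, and DTU genes are DTE- but not
DGE-true. A transcript participates in usage change iff its own proportion
differs between groups, which in a DTE gene includes the untouched isoforms
(the gene total moved under them).

Counts are NB with mean μ_ti ∝ TPM × effective length scaled to the
library size and dispersion α(μ) × log-normal jitter (sdlog 0.3), with
α(μ) = 4/μ + 0.05 — a generic bulk RNA-seq mean–dispersion trend chosen to
span shot-noise-dominated low counts and ~5% biological CV² at high counts;
both the trend and the jitter are overridable. In the `main` regime the
dispersion is per transcript; in `fixed_per_gene` all transcripts of a gene
share one draw matched on the gene-level mean. The emitted TPM matrix is
derived from the realized counts (count/effective-length, normalized to 1e6
per sample), so the counts-from-abundance import path is exercised end to
end and round-trips exactly through the written `quant.sf` files.

What the simulator does *not* emulate: read-level sampling and alignment,
fragment GC bias, and quantification uncertainty (counts are generated
directly, so the extra transcript-level noise a quantifier introduces is
absent). Passing calibration tests on these simulations therefore bounds
the methods' behavior under a correctly specified count model, not under
real quantifier output; observed error rates on real data can be worse.

## Problem sizes and numerical choices

The calibration suite runs at deliberately moderate sizes — 500 genes for
the null type-I check, 1000 genes (6 vs 6) for the end-to-end OFDR and
sensitivity of both paths — which keeps the full test suite and the
acceptance script to a few minutes on one CPU while leaving the binomial
bands tight enough to detect miscalibration. Convergence tolerances:
1e-12 relative on the DM log-likelihood inner optimization, 1e-6 on log γ,
1e-4 on log α; GLM iteration cap 100; dispersion floor 1e-8 and ceiling 10;
proportion floor 1e-12 before log-gamma evaluation. Determinism: every
stochastic step (common-precision gene subset, simulator draws) takes an
explicit seed, and identical configurations produce byte-identical result
tables.

## Known limitations

- Only two-group designs are supported end to end; the DM fit accepts more
  levels but only the single-factor LR test is provided, and the NB design
  builder requires exactly two groups.
- The DM path reports missing p-values for total-switch genes (see above);
  sensitivity comparisons between the DM and NB paths should keep this
  asymmetry in mind.
- The per-gene q-value uses BH; the OFDR guarantee is an expectation, and
  single-run observed OFDR on a few hundred screened genes is noisy.
- The GTF reader extracts only transcript→gene relations; coordinates,
  strand and exon structure are ignored.
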
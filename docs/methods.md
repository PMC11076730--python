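# Methods

This note documents the statistical procedures, the synthetic-data
models behind the tests, the numerical conventions, and the design
choices that were genuinely open.

## Phase-1 epidemiology

**Prevalence tables.** Strata are (age, sex) cells with screened and
radiographically confirmed counts; rates are `100 · positive / screened`.
Each age row carries a 2×2 (sex × positive) Pearson χ² and its p-value;
the total row pools all ages.

**Pearson χ² without continuity correction.** The printed screening
statistics (39.51 for the overall sex difference, 7.439 at age 13, 197.4
for education stage, 0.2466 for BMI category) are reproduced only by the
*uncorrected* statistic Σ(O−E)²/E; Yates-corrected values do not match.
Expected counts must be positive; a zero row/column margin raises.

**Fisher's exact test.** Two-sided p by the point-probability method:
the sum of hypergeometric probabilities, over tables with the observed
margins, not exceeding the observed table's probability. The odds ratio
is the sample odds ratio ad/bc (∞ when bc = 0 with ad > 0). The
implementation delegates to scipy; the test suite holds it to an
independent exact-rational enumeration oracle (agreement < 1e−12 on
every 2×2 table with N ≤ 40). Note the asymptotic χ²–Fisher agreement is
slower than folklore suggests: the gap decays like 1/√N and only falls
below 0.02 with cell counts in the thousands, which is where the
consistency property is asserted.

**Welch *t* from summaries.** Group summaries are (n, mean, SD) as
printed; t = (m₁−m₂)/√(s₁²/n₁+s₂²/n₂) with Welch–Satterthwaite degrees
of freedom. The unequal-variance form is required: the pooled-variance t
on the height summaries gives ≈ 0.629 while the printed value 0.650 is
exactly the Welch statistic. Signs follow the group order; magnitudes
are compared in reports.

**Management classes.** Cobb-angle intervals, closed on the left:
[0,10) negative, [10,20) observation (mild), [20,40) rehabilitation or
bracing (moderate), [40,∞) surgery (severe). Where narrative text
elsewhere writes open bounds ("10° < Cobb < 20°"), the closed-left
convention is used throughout so the classes partition [0,∞) and agree
with the referral rules. Optional record fields are encoded as absent
(None), never 0, so negative screens cannot leak into anthropometric or
morphology summaries.

## Case–control matching

Matching is exact on sex and ethnicity with a greedy nearest-age search
within a caliper (default 1 year), cases processed in sorted-id order and
age ties broken toward the smaller control id; no control is reused.
With three covariates, two categorical, this dominates a fitted
propensity model — there is no model to misspecify, and the result is
deterministic. Logistic propensity scores, optimal matching and balance
diagnostics are out of scope.

## Small-RNA cascade

Stages, in order, with exact read accounting at every step:

1. **3' adapter trimming** — earliest position where an adapter prefix
   (overlap ≥ 8, mismatch rate ≤ 0.1) aligns to the read suffix;
   truncate there. A read that is all adapter is removed.
2. **Length filter** — keep 18–26 nt inclusive (the mature-miRNA range).
3. **Contaminant filter** — ungapped substring/equal-length match
   against named reference sets, attributed to the first matching set in
   fixed order (mrna, rfam, repbase) so removal statistics are
   deterministic.
4. **Counting** — a read is assigned to a mature miRNA iff it matches
   full-length within the mismatch budget (default 0); reads with two or
   more equally good hits stay unassigned. Library size = valid reads.
5. **Normalization** — counts per million valid reads (CPM). The
   vendor pipeline the design emulates does not publish its internal
   normalization; CPM is the standard, documented stand-in.

Conservation holds exactly: raw = trimmed-empty + length-removed +
contaminant-removed + valid, and valid = assigned + unassigned. The
quality-control stage is a structural no-op because simulated reads are
error-free; sequencing error is deliberately out of scope (the cascade
is about adapters, length and contaminants).

## Matched-pair differential screen

Per pair, per miRNA: p from two-sided Fisher's exact on
[[case_count, case_lib − case_count], [control_count, control_lib −
control_count]] — the no-replicates rule — and log₂FC on CPM with a 0.5
pseudocount to keep zeros finite. A call requires both p < α (0.05) and
|log₂FC| ≥ 1 ("2-fold higher or lower", interpreted on normalized
abundance with strict ≥). No multiple-testing correction is applied at
any stage; the six-pair intersection is itself the stringency mechanism.
Candidates = miRNAs differential in **all** pairs; the
direction-consistency filter keeps those moving the same way in every
pair. Exclusive intersection sizes over all non-empty pair subsets
(UpSet counts) are tabulated for reporting. `p_mode="gated"` skips
Fisher where the fold-change gate already fails; the differential set is
provably unchanged (a call needs both conditions), and the replicate
studies use it for speed.

**Reference-miRNA selection.** Eligible = detected in every sample, CPM
coefficient of variation below the 0.25 quantile of detected candidates,
and |log₂ mean case/control ratio| < 1; the most abundant eligible miRNA
wins. This mirrors how a sequencing-based internal reference is chosen:
high abundance, low variability, no group shift.

A pooled 6-vs-6 Welch-t screen on log₂(CPM + 0.5) is provided as a
volcano-style stand-in for group-level comparisons; it is reported but
never drives candidate selection.

## qPCR quantification and ROC

ΔCt = mean(target triplicate) − mean(reference triplicate) per subject;
ΔΔCt subtracts the control-group mean ΔCt (per-group calibration, since
groups rather than a single calibrator sample are compared); RQ =
2^−ΔΔCt, so the control group's geometric-mean RQ is exactly 1 and any
per-subject plate offset cancels. Triplicates are summarized by the
arithmetic mean; outlier-well rejection is not performed.

AUC is computed by concordant-pair counting with ties at ½, i.e. the
Mann–Whitney U statistic divided by n₁n₂. Confidence intervals use the
DeLong placement-value variance (Wald interval clipped to [0,1];
perfect separation degenerates to a zero-width interval, flagged by
construction), cross-checked in tests against a 2000-resample stratified
percentile bootstrap — the agreement is asserted on the median gap over
several instances because bootstrap quantiles carry Monte-Carlo noise of
the same order as the 0.02 comparison. The operating point maximizes
Youden's J over midpoints between adjacent distinct scores, ties broken
toward higher sensitivity. Markers down-regulated in cases are scored
with the `low_predicts_case` orientation (derived from the group means
when not given); AUC is invariant to monotone transformations, so ΔCt
and RQ scales give the same AUC with different threshold units — the
threshold is reported on the input scale.

## Synthetic-data models

The generators encode the study design so the pipeline is testable
against planted truth; distributional *forms* are stand-ins, since the
screening program published only observed frequencies.

**Screening population.** Default strata are the published age × sex
screened counts with their observed positive rates (a `scale` argument
shrinks every stratum proportionally for quick runs). Per stratum,
positives ~ Binomial(n, p). A referral false-positive stream (rate
0.0449, matched to the published gap between the 5.54% referral rate
and the 1.10% + 0.37% confirmed rates) carries ATR ≥ 5° with Cobb < 10°.
Cobb given positive is 10 + LogNormal(2.317, 0.963) degrees — location
and scale solved so that ~49.4% of positives fall in [10,20) and ~13%
at ≥ 40°, the published management mix. Curve morphology is categorical:
P(double) = 0.55, single-curve region probabilities
(thoracolumbar 0.55, thoracic 0.30, lumbar 0.15) and P(right convex) =
0.55, qualitatively matching the reported ordering (double > single;
thoracolumbar most common; right more common overall). The morphology
parameterization is decomposed (pattern, region | single, convexity)
rather than one joint table because double curves carry no single-curve
region. Anthropometrics are normal with the published group means/SDs.
What this generator does *not* emulate: regional/ethnic heterogeneity,
secular trends, measurement error in ATR/Cobb, and any correlation
between anthropometrics and case status beyond the group means — so
passing tests validate the computational pipeline, not those
epidemiological subtleties.

**Matched-pair counts.** Negative binomial in the mean/dispersion
parameterization (variance = m + φm²), φ = 0.05 by default; control
mean = baseline share × library size (10⁶), case mean multiplied by
2^effect for planted miRNAs (5 planted at |log₂ effect| = 2, alternating
signs, by default, in a 300-miRNA catalog over 6 pairs). Case and
control draws are independent — matching aligns demographics, not
molecular baselines. The designated reference miRNA has effect 0 and a
smaller dispersion (0.005): biological stability is precisely the
property that makes a reference miRNA a reference, and with one shared
dispersion every abundant miRNA has near-identical expected CV ≈ √φ, so
a CV-based selector would pick on estimation noise.

**Reads.** Error-free: each counted copy emits mature sequence + 3'
adapter (TruSeq small-RNA prefix), padded to the 50 nt platform read
length; contaminant reads (18–26 nt, drawn from the named sets) are
mixed in at the requested fraction. Catalog sequences are
rejection-sampled so trimming provably returns the exact mature
sequence and no mature sequence is a substring of a contaminant — this
makes the cascade round trip *exact* at mismatch 0, which the tests
assert, and keeps the length mode at 22 nt.

**qPCR.** Ct(target) = target mean + subject plate offset + N(0,
between-subject SD) − effect·[case], in triplicate with N(0, 0.15)
well noise; the reference Ct shares the plate offset and is unaffected
by group. Default validation design: 23 + 23 subjects; three markers
down-shifted by 1.04–1.40 cycles at between-subject SD 1.0 (sized to
put AUCs in the observed high-0.7/low-0.8 regime, since
AUC ≈ Φ(|ΔΔCt effect|/(σ√2))), three null markers.

## Why full planted-set recovery is rare at these noise settings

Per pair, Var(log₂ FC) ≈ 2(1/m + φ)/ln²2 for a miRNA with mean count m,
so at φ = 0.05 the noise floor is SD ≈ 0.46 *regardless of abundance*.
A planted |log₂FC| = 2 therefore clears the ≥ 1 call threshold by only
~2.2 SD per pair, and exact recovery of all 5 planted miRNAs requires
all 30 pair × miRNA calls to pass simultaneously — probability ≈ 0.65
in the Gaussian approximation and ~0.2–0.4 empirically (skewness and
the pseudocount bite further). The observed behaviour — recovered sets
are always *subsets* of the planted set (no false candidates; the null
design yields an empty shared set in ~100% of replicates), with
occasional misses — is the expected operating characteristic of an
intersection-over-six-pairs rule at this dispersion, not an
implementation defect. Recovery becomes near-certain as φ → 0 or the
planted effect grows.

## Problem sizes

Replicate studies (recovery, null control) run at the full count-level
design (300 miRNAs × 12 samples × 10⁶ library, 100 seeds); read-level
runs (FASTQ → cascade → counts) use 20k–30k reads per sample in the
analysis scripts and a few thousand in tests, since the read cascade is
an exact deterministic round trip whose correctness does not depend on
depth. All randomness flows from one `numpy` Generator per run, seeded
explicitly; identical spec + seed reproduces outputs bit-identically.

## Known limitations

* Fisher's exact on counts vs library remainder treats reads as
  independent draws; overdispersion between paired subjects makes the
  per-pair p-values anti-conservative, which is inherent to the
  no-replicates design being modelled (and is why the fold-change gate
  and cross-pair intersection carry the real stringency).
* The contaminant filter is ungapped and attribution is
  precedence-based, not alignment-scored.
* No multiple-testing correction anywhere in the screen (by design,
  preserved from the procedure being modelled).
* The qPCR model omits amplification-efficiency correction and
  inter-plate calibrators beyond the additive offset.
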
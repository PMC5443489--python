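# Methods

`glycometh` implements a blood-and-islet differential-methylation analysis
for hyperglycemia and type 2 diabetes (T2D): discovery of differentially
methylated positions (DMPs) from a paired two-timepoint methylation array
study, association of a target CpG's methylation with glycemic traits, and
single-base windowed differential methylation from whole-genome bisulfite
sequencing (WGBS) of pancreatic islets. This note records the models, the
defaults and why, and what the synthetic data do and do not establish.

## Array beta values

A methylation array probe yields fluorescent intensities M (methylated
allele) and U (unmethylated allele). After subtracting a background
estimate derived from negative-control probes, methylation is summarized
as

    beta = max(M, 0) / (|U| + |M| + 100)

Beta lies in [0, 1) for any real intensities; background subtraction may
drive intensities negative, which the max/abs structure absorbs. The +100
offset is a fixed regularizer, not a parameter. The background statistic
is the mean of the negative-control intensities (median available via
`statistic="median"`); nothing else of array preprocessing (dye bias,
detection p-values, probe-type correction) is modeled.

## DMP discovery cascade

The discovery design measures each subject at two stages roughly a decade
apart, in case/control arms of OGTT-defined subgroups (a 60-minute
glucose-excursion subgroup and a T2D subgroup). Discovery proceeds in three
steps per subgroup:

1. **Longitudinal gate.** Per probe and (subgroup, arm), a two-sided paired
   t-test of stage-5 minus stage-1 beta. Probes whose per-subject
   differences have zero variance get a degenerate flag and NaN p. Probes
   with any missing beta in the group are dropped, not imputed.
2. **Ranking.** Probes with nominal p < alpha (default 0.05; no
   multiple-testing correction, though a Benjamini–Hochberg FDR column is
   attached for information) are ranked by |case − control| mean beta at
   stage 5 and truncated to the top k (default 250). The tie-break is
   deterministic: |delta| descending, p ascending, probe id lexicographic.
   The ranking key uses the absolute difference; the signed value and a
   hypo/hyper direction label are carried in the output.
3. **Set algebra.** Case-specific DMPs are the case-arm selection minus
   the control-arm selection — removing probes that also moved in controls
   strips shared age/time effects. Subgroup-specific sets are intersected
   across subgroups to find shared candidates.

Invariant by construction: |case-specific| = |case set| − |case ∩ control|,
and the whole cascade is invariant to probe order.

## Glycemic traits

Subject classification follows the OGTT rules: the excursion subgroup
assigns control when Glu60 − Glu0 < 20 mg/dL, case when > 100, otherwise
excluded; the diabetic replication rule requires fasting glucose > 126
mg/dL *and* 2-hour glucose > 200 mg/dL (both strict). Derived indices are
HOMA-IR = Ins0·Glu0/405 (Ins0 in µU/mL, Glu0 in mg/dL — the 405 constant
belongs to the mg/dL form) and QUICKI = 1/(log10 Ins0 + log10 Glu0),
base-10 logs, the index's standard definition. Note that a cohort's mean
QUICKI is the mean of per-subject values, not QUICKI of the mean traits;
the two differ in the third decimal on realistic cohorts.

Group comparisons use Welch's unequal-variance t-test with Satterthwaite
degrees of freedom, computable from raw vectors or from published
(mean, SD, n) summaries; the two forms are algebraically identical.
Methylation–trait association is ordinary least squares with the trait as
response and percent methylation as predictor, adjusting for age, sex
(indicator, male reference), BMI, WBC and RBC; when the analyzed trait is
itself a covariate it is removed from the covariate set. The response/
predictor orientation is a genuine choice — correlation-style analyses
could orient either way — and was fixed so the coefficient reads as trait
units per methylation percentage point; it is configurable.

## WGBS methylation calling

Per cytosine, the methylation ratio is (#C reads)/(effective CT count),
where the effective count includes only C and T observations. A call is
*reliable* when the effective CT count is strictly greater than 10
(configurable). Where both mates of a read pair cover a position, only one
mate contributes — mate 1 by default (the choice is arbitrary and
configurable; the point is single-counting). Pairs with mates on different
chromosomes are skipped with a log entry. Contexts are CG/CHG/CHH read
strand-aware on the reference (minus-strand contexts on the reverse
complement); a cytosine with fewer than two downstream bases gets an
`undetermined` context unless the first downstream base already decides CG.
Coordinates are 1-based inclusive throughout; bedGraph export converts to
0-based half-open. The primary input is a methratio-style per-cytosine TSV;
the aligned-read path exists to exercise the counting rules, not to
replace an aligner.

## Windowed DMR statistics

Around a target coordinate (default window ±5 kb), reliable per-donor
calls are assembled into a site × donor percent-methylation matrix; both
strands of a CpG remain separate sites. Per site, control vs case donors
are compared with a two-sided Mann–Whitney U test: the exact permutation
null is used when the data are tie-free and the number of group labelings
C(n1+n2, min n) ≤ 20 000 (this covers both 8-vs-8 and the 16-vs-2 islet
design, whose 153 labelings are enumerable); otherwise the normal
approximation with tie correction. One consequence of exactness worth
knowing: a 6-vs-2 comparison has only 28 labelings, so its smallest
two-sided p is 1/14 and *no* site can reach p < 0.05 — published counts of
significant sites in such designs imply the normal approximation was used.
If every pooled value is identical the test is vacuous and p = 1 with a
tie flag.

The window summary tallies sites by the sign of control mean − case mean
(positive change = cases hypo-methylated), counts sDMPs (p < alpha), and
reports two mean changes: over sDMPs only (the conventional summary-table
figure, averaged over all sDMPs regardless of direction) and over all
sites. Under a uniform planted group difference the sDMP-conditional mean
is upward-biased — with 2 case donors a site only reaches significance
when the case draws land low, so the conditional mean overshoots a
16-point planted difference by roughly 5 points at 30X binomial noise —
while the all-sites mean is unbiased; recovery checks therefore use the
all-sites mean. The confidence interval on the sDMP mean change is a
seeded percentile bootstrap (default 1 000 replicates) resampling donors
within each group over the fixed sDMP site set; resampling donors rather
than sites reflects that donors, not sites, are the sampling units. A
percentile CI under donor resampling may exclude the point estimate.

Donor stratifications: T2D status; age (young < 40 vs old ≥ 40 — exactly
40 is "old"); sex; and sex-matched T2D (controls restricted to the cases'
sex, an error if cases have mixed sex). Sites where a donor lacks a
reliable call use the remaining donors; a site with an empty group is
excluded from all tallies and logged.

## Synthetic data

The generators are pure functions of (config, seed); the master seed is
split with `numpy.random.SeedSequence.spawn` into one child stream per
draw component in a fixed order, so outputs are byte-reproducible and
insensitive to unrelated config changes.

**Array studies.** Per-probe baseline means are Beta-distributed (default
mean 0.5, concentration 50, i.e. SD ≈ 0.07 — a unimodal mid-range
caricature, not the bimodal genome-wide beta distribution). Planted
effects are beta-scale shifts at stage 5: `stage_effect` moves both arms
(a time/age effect the cascade should subtract out), `case_effect` moves
cases only (the signal it should recover). Deltas that push a planted
probe's mean outside [0, 1] are rejected. Noise is logit-normal: the
logit-scale SD is set by the delta method so the beta-scale SD
approximates `noise_sd` (default 0.03) near the mean, keeping draws inside
(0, 1) without clipping; a per-subject logit offset (`subject_sd`, default
0.05 beta-scale) induces within-subject correlation across stages. Default
design: 1 000 probes, 8+8 subjects — desk scale, three orders of magnitude
below a real array; no claim of genome-scale fidelity.

**Traits.** Per-arm normal draws with defaults mirroring an elderly
diabetic replication cohort (e.g. control/case fasting glucose
92.2 ± 7.6 / 165.5 ± 54.3 mg/dL; target-CpG methylation 29.5 ± 3.7 /
26.4 ± 3.3 percent). Two published blood-count rows are not physiological
as printed (WBC 1.313 ± 2.02 × 10³/µL; RBC SD 1.50 × 10⁶/µL would put a
third of draws outside the human range), so the generator uses
physiological defaults there (WBC 6.3 ± 1.7, RBC 4.7 ± 0.45). A planted
methylation→trait slope shifts each trait linearly in cohort-centered
methylation, preserving arm means. Traits that must be positive are
redrawn up to 100 times, then clamped to 0.01 with a warning. Because arm
membership shifts both traits and methylation, a pooled two-arm regression
confounds the arm effect with the planted slope; slope-recovery studies
fit within a single arm.

**WGBS counts.** CpG positions are laid down with geometric gaps (default
mean 34 bp — matching roughly 290 strand-specific sites per 10 kb window),
each CpG emitting a plus-strand record and the complementary minus-strand
record at the next base. Per donor and record, coverage is Poisson (default
30X) and the C count binomial at the donor group's methylation level
(default 0.72 in controls, minus a planted delta of 0.16 in T2D donors at
every site). There is no donor-level overdispersion beyond binomial
sampling, no sequencing-error or conversion-failure model, and the planted
effect is uniform across the window — so passing recovery tests establish
the statistical machinery, not robustness to biological heterogeneity. The
default donor roster is a fixed 18-donor table (2 T2D males, 8 males / 10
females, 5 donors under 40) so the four stratification schemes have
deterministic group sizes.

## Problem sizes and tolerances

Simulation-backed checks use 20 replicate seeds for array and WGBS studies
and 50 for trait-slope recovery, at the desk-scale designs above; these
sizes put Monte-Carlo error comfortably below the asserted margins while
keeping the full suite fast. Null calibration of the paired test is
asserted at 0.05 ± 0.01 over 10 000 probe-tests (binomial error plus an
allowance for t-robustness to the logit-normal noise at n = 8); planted
0.11 case effects must be recovered with mean sensitivity ≥ 0.8 (observed
≈ 0.95, losses dominated by the 5% chance of the same probe passing the
control-arm gate); the planted 16-point islet contrast must be recovered
within ±3 points by the all-sites mean change; planted regression slopes
must fall within 2 SE in ≥ 85% of replicates (nominal 95% coverage with
binomial slack). Exact test equalities (Mann–Whitney vs enumeration, WGBS
counting vs brute-force tally, Welch raw vs summary) are asserted to
floating-point tolerance.

## Known limitations

No multiple-testing control in discovery (by design — the cascade uses
nominal p-values and set algebra as its specificity mechanism); no probe
annotation, pathway analysis, or cell-type deconvolution; no bisulfite
alignment or read QC; synthetic noise models are deliberately simple
(logit-normal, binomial) and homogeneous across probes/sites.
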
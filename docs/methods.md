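# Methods

## Data model

A cohort is a pair of tables. The **mutation table** has one row per variant
(chrom, 1-based pos, ref, alt, gene, SnpEff/VEP-style effect class, a
synonymous flag) and one column per sample (`<patient>_<BL|PD>`); a cell is
`depth:vaf`, with zero depth encoding absence. Positions printed with
grouping spaces (`chr 1: 26 779 439`) are accepted on parse; variant
identity is the exact (chrom, pos, ref, alt) tuple with no
left-normalisation — keys must match the input dialect. The **clinical
table** carries gender, smoking, pathology (LUAD/LUSC), driver-gene status
(EGFR/ALK/ROS1), metastasis count, IDH1 exon-4 status, intolerance, and
right-censored PFS and OS in days.

## Filter chain and burden predictors

Per sample, calls below 100× depth or outside the 168-gene panel are
removed from every retained set (nothing is deleted; records carry labels).
Among survivors — the **G+S** set, whose size is G+S MB — a call is
germline when present in a matched WBC sample if one is given, otherwise
when VAF > 20% (the proxy mode; the mode is recorded in the output
metadata). The **somatic** set additionally requires a MODERATE or HIGH
effect; its size is N+S MB (synonymous + nonsynonymous somatic). The
nonsynonymous HIGH subset feeds the acquired-mutation comparison.

Reading "filtered with VAF > 20%" as *germline-side assignment* (rather
than deletion) keeps 0 ≤ N+S MB ≤ G+S MB and matches the sequential
narrative of the source workflow; whether the study counted the germline
side before or after effect-class filtering is not stated, so the
convention here (effect filtering applies only to the somatic side) is
recorded in metadata and configurable in one place.

## Benefit classes

From PFS: NB (no benefit) = progression ≤ 45 days or drug intolerance;
NDB = progression in (45, 130]; DCB = disease control past 130 days
(censored beyond 130 also qualifies). A patient censored at ≤ 130 days is
*indeterminate*: excluded from DCB/NDB discovery labels but still scored and
classified. The 45/130-day bounds are configuration.

## Acquired mutations and the resistance panel

Acquired = PD \ BL by exact key over nonsynonymous HIGH-effect calls,
post-filter (a call below filters at BL but above them at PD counts as
acquired). Per-gene frequencies divide by the subgroup size. The default
resistance panel is the four published ARID1A/BRCA2 frameshifts
(chr1:26779439 TG/T, chr1:26762190 TC/T, chr13:32379885 CA/C and C/CA);
matching is exact-key, and panels are user-extensible TSVs.

## Unfavorable-mutation screen and UMS

Each baseline mutation carried by at least `min_carriers` (default 3) and
not all patients is tested carrier vs non-carrier on PFS; the default test
is the Gehan–Breslow generalised Wilcoxon (at-risk weighting; Peto–Peto is
a flag), computed from the counting-process representation and vectorised
across mutations. P-values are BH-adjusted across all tested mutations.
Retention applies `alpha` (default 0.01) to the adjusted p-values by
default; the pipeline runs in `p_mode="raw"` because a raw-threshold screen
is the only reading consistent with the scale of the source study's
retained set. Only mutations whose carriers have the *shorter* median PFS
are kept (a direction filter; without it protective mutations would inflate
the score). The minimum-carrier rule exists because near-singleton private
mutations carry no usable survival contrast and would otherwise dilute the
multiple-testing adjustment by the thousands; `min_carriers=1` restores the
fully literal behaviour.

UMS = number of retained unfavorable mutations a baseline profile carries,
each weighted 1. UMS-negative (score 0) vs positive partitions the cohort;
a `positive_min` flag supports the stricter "high-risk ≥ 2" reading.

## Survival machinery

Kaplan–Meier estimation delegates to lifelines; medians use the smallest
time with S(t) ≤ 0.5 (not-reached = ∞). The two-sample tests compute the
weighted observed-minus-expected sum with hypergeometric variance
(chi-square, 1 df); they agree with lifelines to machine precision and with
exhaustive permutation tests to within the chi-square approximation error.
ROC/AUC uses pairwise concordance with half credit for ties (positive class
= non-benefit, so AUC > 0.5 means higher score ↔ worse outcome), a
Hanley–McNeil 95% CI (DeLong optional), and a two-sided z-test against
AUC = 0.5 using the null-hypothesis standard error.

**Cutoff scan ("Ward method").** Candidates are midpoints between
consecutive distinct sorted predictor values leaving ≥ `min_group`
(default 3) per arm; each is scored by the configured test and the minimal
p wins (ties → smallest candidate). The scan's p-values are reported
unadjusted, as in the source workflow; note two honest caveats measured on
synthetic data: the minimum-p choice is optimistically biased, and the
chosen cutoff tends to sit near — not exactly at — a planted boundary,
because adjacent splits differ by single patients and the argmin follows
noise among nearly equivalent candidates. The scan is direction-free, so a
strongly significant *inverted* split is possible and is surfaced by the
reported group medians.

## TMI scoring

Per predictor, a patient on the responder side (burden strictly below its
cutoff; UMS-negative) earns 50 baseline points, plus subgroup points: the
sum, over the five demographic subgroups the patient belongs to (gender,
smoking, pathology, driver status, ≤3 vs >3 metastases), of the
Kaplan–Meier significance points for PFS and OS (1/2/3 below 0.05/0.01/
0.001) and the ROC points (1 for AUC > 0.7 plus significance-style points
on the null-test p) of that predictor in that subgroup. Design choices the
source text leaves open, fixed here as one consistent reading: subgroup
points go only to predictor-responders ("responder" is per-predictor, not
clinical benefit, which would leak outcomes into the score), and each
predictor's subgroup sum is capped at 50 — the only reading under which the
maximum total is the printed normalisation constant 300 = 3×50 + 3×50.
Not-evaluable subgroups (arms below `min_group`, or a single benefit class)
contribute 0. TMI = 100 × (300 − total) / 300, reported to one decimal;
classification uses the unrounded value, with `tmi < cutoff` = low
(boundary classifies high). Combined classifier: unfavorable iff high TMI
*and* IDH1 exon-4 mutant.

OS-benefit labels for the ROC components are OS beyond the discovery-cohort
KM median OS (censored before the median = indeterminate); PFS-benefit
labels are DCB vs NDB.

## Pipeline

Discovery: exclusion of NB patients (by clinical benefit class; the
resistance-panel screen is computed and reported alongside, and
`exclude_by="panel"` switches to prospective panel-based exclusion), a
seeded random discovery/validation split at 62/85, the UMS screen, cutoff
scans, predictor evaluations, score cards, the TMI cutoff scan. All frozen
artifacts (cutoffs, unfavorable keys, subgroup tables, split) are hashed
into the run manifest; validation recomputes from the manifest, verifies
the hash (no re-estimation leaks into validation) and stratifies the
held-out and pooled cohorts by log-rank. If the TMI scan has no admissible
candidate the published default cutoff 60 is used and flagged as such.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, not
the sequencing process (no reads, no error model, no tumor fraction).
Per patient: a burden stratum (low/high, default means 60/200 calls at 30%
high — scaled down from the study's thousands-scale burdens to keep tables
desk-sized; every analysis is scale-free), germline-like VAFs ~ Beta(30,30)
and somatic VAFs ~ Beta(2,18) so the 20% proxy separates the classes
imperfectly on purpose, ~3% shallow (<100×) calls except at the four
clinically assured resistance-panel loci, shared background mutations with
uniform prevalences, and private singletons.

Unfavorable carriage is *clustered*: a patient-level propensity
u ~ Beta(πκ, (1−π)κ) with marginal prevalence π (default 0.15) and
concentration κ (default 4) drives Bernoulli carriage of each of the
default 12 planted mutations. Clustering reproduces the long-tailed,
strongly co-occurring unfavorable loads of real cohorts; with independent
carriage the compounding hazard (below) creates so much cross-mutation
frailty that no rank test can recover per-mutation effects — measured
sensitivity plateaus near 0.7 even in noise-free configurations, versus
≈1.0 under clustering.

PFS is exponential (Weibull shape exposed) with hazard
base × hr_burden^[high] × hr_unfav^(#carried) × hr_idh1^[IDH1+];
baseline median 210 days, hr_burden 1.65 (the 210 vs 127-day medians of the
source discovery cohort), hr_unfav 2.0, hr_idh1 1.8. Censoring is
independent exponential at rate censor_rate/(1−censor_rate) × hazard
(20% censoring). OS = PFS × a patient-level lognormal factor (median 2.4 ≈
505/210, floor 1.05). NB-stratum patients (23.4% = 26/111) progress
uniformly in 7–45 days and carry ≥1 resistance-panel mutation with
probability 0.92 (= 24/26); others carry one at a 3% background rate.
Durable responders get a PD sample: baseline plus Poisson(4) acquired
HIGH-effect mutations, drawn preferentially (70%) from ARID1A/BRCA2 for the
~60% planted as resistance-driven acquirers. Times are rounded up to whole
days. One seeded generator drives everything; identical configs give
byte-identical fixtures, and the truth block stores the full configuration
so a fixture can be regenerated from its own `truth.json`.

What passing tests on these cohorts do **not** show: performance under
sequencing artefacts, subclonal VAF dynamics, non-exponential hazards,
informative censoring, or the study's absolute burden scale. The compounding
hazard also sends heavily loaded patients into the NB class, so simulated
analysis fractions (~50–60%) run below the study's 85/111.

## Problem sizes and numerical choices

Statistical checks run at desk scale: 50-replicate null calibration at
n=100 with ~200 testable mutations; screen sensitivity at n=200 with 20
planted HR-3 mutations at 20% prevalence; cutoff-recovery and TMI
stratification over 50 replicates at n=120/200. Exhaustive oracles
(permutation tests at n=8, brute-force step-up BH, pair-counting AUC,
full-scan equivalence) bound the approximations. Ties in the scan resolve
to the smallest candidate; zero-variance tests return p=1; BH is capped at
1 and monotone; all randomness flows from explicit integer seeds.

## Known limitations

Single-mutation screening only (no gene-level collapsing, no multivariate
adjustment); no Cox models, competing risks or time-varying covariates; the
minimum-p scan's multiplicity is reported, not corrected (a permutation
"honest mode" is a natural extension); ROC CIs are asymptotic; the
subgroup-point reading, while the only one consistent with the 300-point
normalisation, remains one interpretation of an under-specified rule.
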
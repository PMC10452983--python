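# Methods

## Harmonization

Input is long-format lesion data (trial, arm, patient, lesion,
assessment day, longest diameter) plus one row per patient with
covariates and overall survival. Diameters are held in millimetres;
readers convert from a declared unit (`mm` or `cm`) on ingest. The
harmonizer reduces each patient to at most five target lesions — the
largest at baseline, diameter ties broken by ascending lesion id so the
choice is deterministic and order-independent — and one restaging scan:
among post-baseline scans on days in (0, 84] (12 weeks = 84 days; an
optional tolerance extends the upper bound, default 0), the day closest
to 84, equidistant ties resolved to the later scan since it reflects
more treatment exposure.

Patients that cannot be harmonized get exactly one exclusion reason,
evaluated as a fixed cascade: no baseline measurement → only one target
lesion → no restaging scan in the window → retained lesions not all
measured at the chosen scan → non-target-progression flag set → no
survival beyond the restaging day. The non-target flag is a pass-through
input: non-target progression cannot be derived from target-lesion
diameters, so it is accepted only as an explicit per-patient indicator.
A restaging diameter recorded as 0 means the lesion disappeared (a valid
response); a lesion absent from the chosen scan means "not evaluated"
and excludes the patient. Malformed rows (negative diameters, duplicate
patient/lesion/day keys) abort with the offending row named, on the
view that silent repair of measurement data is worse than failure.

## Classification

Per-lesion classes use the fractional change from baseline only (the
baseline is the nadir by construction — exactly two timepoints exist).
Thresholds default to +0.20 (progression) and −0.30 (response) with
inclusive comparisons, matching the convention that "a 20% increase"
qualifies; a flag switches to strict inequalities because usage varies
on whether the boundary itself counts. The patient-level pattern is a
pure function of the (best, worst) pair of lesion classes; with 2–5
lesions exactly six patterns are reachable. The prevalence subclass
within RL/PL compares counts of RL versus PL lesions, ignoring stable
ones.

RECIST 1.1 is recomputed from the harmonized sums: CR requires every
retained lesion to measure exactly 0 (diameters are exact inputs, so no
tolerance is used); PD requires a ≥ 20% sum increase and, by default,
the ≥ 5 mm absolute increase of RECIST 1.1 (toggleable, since two-
timepoint recomputations sometimes omit it); then PR at ≤ −30%; else
SD. Precedence CR, PD, PR, SD. Because the sum's percent change is a
baseline-weighted mean of per-lesion changes, uniform patterns imply
their RECIST counterparts (RL only ⇒ CR/PR, SL only ⇒ SD, PL only ⇒ PD
whenever the 5 mm condition is met, e.g. baseline sum ≥ 25 mm); this is
enforced by property tests.

The sensitivity grid re-classifies a cohort under the six alternative
threshold pairs (progression at ≥ 20/15/10%, response at ≥ 30/25/20%
decrease, in the six published combinations) and reports the fraction
of patients whose pattern is unchanged relative to the default
thresholds.

## Survival evaluation

Overall survival is measured from the restaging scan (landmark), so
classification and follow-up do not overlap; patients dying on or
before the scan are excluded during harmonization. Days are the
internal unit; months = days / 30.4375 for reporting.

- **Kaplan–Meier** per group via lifelines, log-log pointwise CIs;
  the median CI is read off the confidence band (Brookmeyer–Crowley
  style). A median the curve never reaches is reported "NE".
- **Stratified log-rank**: per-stratum observed-minus-expected score
  vectors and hypergeometric covariances are summed over strata and
  event times; the statistic is the quadratic form with #groups − 1
  degrees of freedom. With one stratum this reduces exactly to the
  ordinary log-rank (verified against lifelines).
- **Cox models** via lifelines with Efron tie handling, stratified by
  trial × arm (configurable — the stratification factors of pooled
  analyses vary), adjusting for age (linear), sex, and ECOG (indicator
  coded, 0 as reference). Missing covariates are handled complete-case
  with the dropped count reported. The global p-value is the
  likelihood-ratio test of the group factor against the covariate-only
  model on identical rows. Non-reference levels with fewer than a
  minimum number of events (1 for direct fits; 5 inside the subgroup
  report, where a level spread thin across many strata yields a
  singular partial likelihood) are flagged non-estimable and left out
  of the fit rather than allowed to destabilize it.
- **Harrell's C**: ordered pairs are comparable when the earlier time
  is an event; predictor ties count ½; tied times are not comparable.
  Computed by chunked vectorized pair counting; the default 95% CI is
  an exact leave-one-subject-out jackknife obtained from per-subject
  pair sums (a patient-level percentile bootstrap is available by
  flag). Equivalence with naive pair counting and with
  scikit-survival's implementation is tested.

The report builder produces the pattern-level fits overall and per
treatment-regimen subgroup, the prevalence-subclass fit among RL/PL
patients (unstratified: the subgroup is small and stratification by
trial × arm would shred it), within-RECIST fits (PR subset with RL-only
reference, SD subset with RL/SL reference), and a side-by-side
concordance table for the two classification systems. Subgroups with
fewer than two usable levels, or whose fit fails, are skipped with a
warning rather than failing the bundle.

## Synthetic cohort generator

No lesion-level multi-trial mCRC dataset is publicly deposited, so the
generator emulates one: its defaults are the published cohort's
marginals — growth-pattern proportions (16.7 / 42.0 / 31.0 / 3.3 / 6.3 /
0.7 % for RL only / RL-SL / SL only / RL-PL / SL-PL / PL only),
regimen mix (37.7 / 41.4 / 13.7 / 7.3 % chemo / VEGFi / EGFRi / both),
age ≈ N(60, 11) clipped to 18–89, 60% male, ECOG 0/1/2 at
56.2/42.2/1.6% with 0.7% missing, 2–5 lesions per patient (mean 3.5),
log-normal baseline diameters with median 30 mm (σ = 0.55), and scan
days uniform on 70–84.

Each patient's growth pattern is drawn first; lesion classes then
realize it constructively (one lesion forced to the best class, one to
the worst, the rest uniform over the classes in between), so
harmonizing and classifying the output recovers the drawn pattern for
every patient — an exact round-trip used throughout the tests. Percent
changes are uniform over each class region shrunk by ε = 10⁻⁶ so no
lesion lies on a boundary, and diameters are never rounded. Responding
lesions disappear completely with probability 0.05; additionally 5% of
RL-only patients have *all* lesions disappear, modelling patient-level
complete response (without it CR would require independent per-lesion
disappearances and be vanishingly rare, leaving the RECIST CR level
empty or separated in Cox fits).

Survival from the landmark is exponential per pattern with the rate set
from the published per-pattern median OS (25.8 / 19.9 / 16.8 / 15.4 /
9.0 / 8.0 months); a Weibull shape parameter is exposed for robustness
checks. Censoring is an independent exponential (median 40 months)
truncated by an administrative cutoff at 72 months, giving roughly 30%
censoring. Covariates are independent of survival, so adjusted and
unadjusted fits estimate the same group effects.

What the generator does **not** emulate: correlation between lesion
count and pattern (the source reports only marginals; independence is
assumed), measurement error and reader variability, non-proportional
hazards, covariate–survival association, informative censoring, and
new-lesion progression (out of scope throughout). Passing tests
therefore demonstrate correctness of the pipeline's logic and
estimators under the assumed data-generating process, not robustness to
these real-data features.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale by design:
shared fixtures use 4,000-patient cohorts, the reference
parameter-recovery run 10,000, closed-form Kaplan–Meier checks 50,000
uncensored draws, and the replicate log-HR recovery study 8 cohorts of
3,000. lifelines fits use Newton–Raphson precision 1e-9 so closed-form
toy solutions are reproduced to four decimals. The log-rank covariance
uses a pseudoinverse for the quadratic form, which handles a redundant
group level gracefully. Percent-change comparisons are exact float
comparisons — classification thresholds are meaningful at boundary
values, so no tolerance is injected.

## Known limitations

- Only target-lesion longest diameters are used: no lymph-node
  short-axis rules, no non-target assessment (beyond the pass-through
  exclusion flag), no new-lesion progression, no confirmation scans,
  no multi-timepoint best overall response.
- The concordance CI is asymptotic (jackknife); for very small groups
  the bootstrap option is preferable.
- The generator's exponential survival makes the per-pattern hazard
  ratios time-constant; published adjusted hazard ratios from real
  cohorts will differ from the ratio of median-implied rates whenever
  covariates correlate with group membership.
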
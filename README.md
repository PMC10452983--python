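# lbr12

Lesion-based tumor response classification at 12 weeks, with RECIST 1.1
recomputation and landmark survival evaluation.

## The problem

RECIST 1.1 grades a patient's response from the *sum* of target-lesion
longest diameters, so a patient whose liver metastasis shrinks by half
while a lung nodule doubles can look "stable". In metastatic colorectal
cancer such mixed (varied) responses are common, and pooling them with
genuinely stable disease blurs prognosis. This package implements a
lesion-based criterion that keeps the per-lesion information, for
biostatisticians and trialists working with lesion-level measurement
data from (possibly multi-trial) cohorts.

## The criterion

For lesion *i* with baseline longest diameter L0ᵢ > 0 and restaging
diameter L12ᵢ at the scan closest to 12 weeks, let Δᵢ = (L12ᵢ − L0ᵢ)/L0ᵢ.
Each lesion is classified

- **RL** (responding): Δᵢ ≤ −0.30 (including complete disappearance),
- **PL** (progressing): Δᵢ ≥ +0.20,
- **SL** (stable): otherwise,

and the patient is summarized by the best and worst lesion class into
one of six growth patterns: *RL only*, *RL/SL*, *SL only*, *RL/PL*,
*SL/PL*, *PL only*. Patterns mixing classes are "varied responses";
RL/PL patients are further split by whether responding or progressing
lesions are more numerous. Boundaries are inclusive by default and can
be made strict (`CutoffConfig(inclusive_boundaries=False)`).

RECIST 1.1 is recomputed from the same harmonized two-timepoint data
(CR: all lesions disappear; PD: sum up ≥ 20% and ≥ 5 mm; PR: sum down
≥ 30%; SD otherwise; no new-lesion information), so the two systems can
be cross-tabulated and compared on identical inputs.

Prognostic value is assessed by landmark analysis — overall survival
measured from the restaging scan — with Kaplan–Meier curves, stratified
log-rank tests, stratified multivariable Cox models (Efron ties,
adjusting for age, sex, ECOG performance status; strata = trial × arm),
and Harrell's concordance index with jackknife confidence intervals.

## Worked example

```python
import lbr12 as L

lesions = [(50.0, 35.0), (40.0, 40.0), (30.0, 36.0)]  # (baseline, restaging) mm
classes = [L.classify_lesion(l0, l12) for l0, l12 in lesions]
print([c.name for c in classes])                  # ['RL', 'SL', 'PL']
print(L.classify_patient(classes).value)          # RL_PL
print(L.prevalence_subclass(classes).value)       # equal_RL_PL
print(L.classify_recist(120, 111).value)          # SD
```

The three lesions change by −30%, 0% and +20% — one responding, one
stable, one progressing — so the patient has the most heterogeneous
pattern (RL/PL), while the sum moves only −7.5% and RECIST calls the
same scan stable disease.

On a simulated 4,000-patient cohort (`examples/03_simulate_and_survival.py`)
the landmark evaluation prints:

```
growth pattern   n     median OS (mo)   HR vs SL only
   SL_only   1212       14.9        reference
     RL_SL   1659       19.6        0.80 (0.73-0.87)
   RL_only    686       23.6        0.65 (0.58-0.74)
     SL_PL    257        8.3        1.91 (1.64-2.23)
     RL_PL    125       12.6        1.20 (0.97-1.48)
   PL_only     32       10.3        1.45 (0.97-2.16)

global likelihood-ratio p = 2.68e-35
concordance: lesion-based 0.564 (0.558-0.570)  vs RECIST 0.548 (0.542-0.554)
```

Hazard ratios are against the SL-only reference: more responding
lesions mean lower hazard, progressing lesions roughly double it, and
the lesion-based grouping ranks survival slightly better than RECIST
(higher concordance) because it separates the heterogeneous patients
RECIST pools into SD.

More narrative scripts live in `examples/`; a thin CLI wraps the same
pipeline for shell use:

```sh
lbr12 simulate --n 2000 --seed 1 --out data/
lbr12 classify --lesions data/lesions.csv --patients data/patients.csv --out out/
lbr12 analyze  --lesions data/lesions.csv --patients data/patients.csv --out out/
lbr12 sensitivity --lesions data/lesions.csv --patients data/patients.csv --out out/
```

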
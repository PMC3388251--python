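# cfscreen

Simulation and evaluation of multi-tier neonatal cystic fibrosis (CF)
screening, built around the Dutch four-step protocol:
**IRT → PAP → CFTR mutation panel → extended gene analysis (EGA)** with a
failsafe, plus the autosomal-recessive carrier-risk calculus used in
genetic counselling.

## Who this is for

Screening-program analysts and biostatisticians who want to reason about
multi-tier newborn-screening decision trees: how cutoffs, panel coverage
and a sequencing failsafe trade off sensitivity, specificity, referral
counts and incidental carrier findings — on synthetic cohorts whose
genotype structure and biomarker distributions are under full control.

## The model in brief

- **Cohorts.** Newborns carry two CFTR alleles sampled under
  Hardy–Weinberg within ancestry strata (general population: carrier
  frequency 1:30; Turkish and North-African strata: ≈1:50 with panel
  detectabilities of only 0.44 and 0.69 per disease allele — the reason
  the failsafe exists). Two disease alleles give classical or
  non-classical CF, one a healthy carrier.
- **Biomarkers.** IRT and PAP are log-normal given the phenotype class.
  The unaffected IRT distribution is *calibrated exactly* to two published
  population quantiles (2.43% ≥ 50 µg/l, 1.03% ≥ 60 µg/l) by solving
  `log t = μ + zσ` for both constraints.
- **Protocol.** IRT < 60 µg/l → negative; PAP < 3.0 µg/l (IRT 60–100) or
  < 1.6 µg/l (IRT ≥ 100) → negative; panel: 2 mutations refer, 1 goes to
  sequencing, 0 is negative unless IRT ≥ 100 and PAP ≥ 1.6 (failsafe);
  sequencing: 2 disease alleles refer, 1 is a carrier report (opt-out).
  Pilot-era strategies (IRT/PAP, IRT/DNA-EGA, combined) and the exact 5/3
  PAP kit-recalibration are included.
- **Risk calculus.** Carrier frequency *c* → allele frequency *q = c/2*,
  birth prevalence *q²*, and next-pregnancy risk after a carrier child
  *q/4* (for *c* = 1/30: 1/60, 1/3600 and 1/240 as exact rationals), with
  Bayes residual-risk updates after negative parental tests.

## Worked example

```python
from cfscreen import (PopulationConfig, ProtocolConfig, default_biomarker_model,
                      generate_cohort, generate_affected_cohort, screen_cohort, summarize)

model = default_biomarker_model()
cohort = generate_cohort(PopulationConfig(cohort_size=200_000, seed=1), model)
s = summarize(cohort, screen_cohort(cohort, ProtocolConfig()))
print(s.abnormal_results, s.false_positive_referrals, round(s.specificity, 6))

affected = generate_affected_cohort(PopulationConfig(cohort_size=1, seed=2), 4_000, model)
sa = summarize(affected, screen_cohort(affected, ProtocolConfig()))
print(round(sa.sensitivity, 3))
```

prints

```
62 0 1.0
0.939
```

meaning: of 200,000 simulated newborns, 62 were referred for CF — every
one a true two-disease-allele case, so the specificity is 1.0 (the
published program claim is > 99.99%; with perfect sequencing a referral
requires a confirmed genotype, so false-positive referrals cannot occur
in the model). On a CF-enriched cohort of 4,000 affected newborns the
four-step protocol detects 93.9% — in line with the expected ≈95%
sensitivity, the losses coming from CF cases whose IRT or PAP sits below
the cutoffs and from rare non-panel genotypes the failsafe does not catch.

The `examples/` scripts walk through each capability (calibration,
national screening, strategy comparison, risk counselling), and the
`cfscreen` command exposes the same operations from the shell:

```bash
cfscreen simulate --n 100000 --seed 1 --out cohort.tsv
cfscreen screen --cohort cohort.tsv --strategy national --out results.tsv
cfscreen evaluate --cohort cohort.tsv --results results.tsv
cfscreen risk --carrier-freq 1/30 --parent-test panel --test-sensitivity 0.95
cfscreen run --out-dir run1           # end-to-end with a manifest
cfscreen config --out config.yaml     # annotated default configuration
```

## Documentation

`docs/methods.md` describes the model, the calibration of the biomarker
defaults, numerical conventions and limitations.
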
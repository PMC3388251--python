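# Methods

`cfscreen` models a four-step neonatal cystic fibrosis (CF) screening
protocol — immunoreactive trypsinogen (IRT), pancreatitis-associated
protein (PAP), a CFTR mutation panel, and extended gene analysis (EGA,
sequencing) with a failsafe — together with the synthetic newborn cohorts
needed to study its test properties and the autosomal-recessive risk
calculus used in counselling after a carrier finding. This note records
the model, its assumptions, the numerical choices, and what passing tests
do and do not demonstrate.

## Population model

CF is autosomal recessive. Within an ancestry stratum with carrier
frequency *c*, each of a newborn's two CFTR alleles is independently a
disease allele with probability *q = c/2* (Hardy–Weinberg sampling), so
genotype classes occur at *q²*, *2q(1−q)*, *(1−q)²*. Each disease allele
is independently panel-detectable with the stratum's panel detectability;
patient-level panel sensitivity therefore *emerges* from allele-level
detection, which is how mutation panels actually operate. Users who read
the published 44%/69% migrant figures as patient-level sensitivities can
invert this by adjusting the detectability.

Shipped strata (all configurable):

| stratum | birth fraction | carrier frequency | panel detectability |
|---|---|---|---|
| dutch_general | 0.90 | 1/30 | 0.95 |
| turkish | 0.05 | 1/50 | 0.44 |
| north_african | 0.05 | 1/50 | 0.69 |

The 1/30 general carrier frequency and the 44%/69% migrant panel
sensitivities are published figures; the ~1/50 migrant carrier frequency
is a published rough estimate, applied to both migrant strata. The 0.95
general-panel detectability is an assumption (the panel is described as
covering all common Dutch mutations without a number), as is the 0.90/0.05/0.05
birth split.

Two-disease-allele genotypes are classical CF with probability 0.72 and
non-classical (milder) CF with probability 0.28; no genotype-level rule
for this split is published, so it is a configurable assumption.
Meconium ileus — neonatal bowel obstruction that leads to a clinical CF
diagnosis before screening results — affects CF newborns at rate 4/29
(four such diagnoses per 25 screened patients per year). Flagged newborns
stay in the cohort but are excluded from sensitivity denominators by
default, since they are diagnosed outside screening.

### Randomness and determinism

All randomness in a cohort descends from one root seed. Each newborn owns
a fixed-width private sub-stream: row *i* of a 7-column uniform matrix and
a 2-column standard-normal matrix, drawn from two stage streams spawned
from the root `SeedSequence`. Cohort content is therefore bit-reproducible,
invariant to processing order, and prefix-stable (growing the cohort never
changes earlier newborns).

## Biomarker model

Both markers are log-normal within each phenotype class, conditionally
independent given the class (a configurable log-scale correlation, default
0, is exposed because PAP-step performance depends on it). Log-normals
were chosen for positive support, the right skew typical of analyte
concentrations, and closed-form quantile calibration; the family is
isolated behind the model interface.

**Calibrated component.** The unaffected IRT distribution is solved
exactly from two published population quantiles — 2.43% of newborns at or
above 50 µg/l and 1.03% at or above 60 µg/l — via
`log(t_i) = μ + z_i σ` with `z_i = Φ⁻¹(1 − p_i)`, giving
μ ≈ 2.8642, σ ≈ 0.5313 (median ≈ 17.5 µg/l). Non-monotone or degenerate
constraint pairs are rejected. The published quantiles are read as
referring to unaffected newborns; at a prevalence of ~1/3600 the
distinction perturbs the tail negligibly.

**Default class parameters.** No published population quantiles exist for
PAP or for the affected classes, so these are the package's own
calibration, fixed analytically before any simulation was scored, to make
the shipped defaults reproduce the protocol's two published aggregate
properties (specificity > 99.99%, sensitivity ≈ 95%):

| class | IRT median (σ_log) | PAP median (σ_log) |
|---|---|---|
| unaffected / carrier | calibrated (carrier ×1.15) | 0.4 (0.85) |
| classical CF | 130 (0.40) | 14.0 (0.60) |
| non-classical CF | 105 (0.45) | 10.0 (0.60) |

The reasoning: with classical IRT median 130 µg/l, 97.3% of classical
cases exceed the 60 µg/l cutoff and 74% exceed 100 µg/l; a classical PAP
median of 14 µg/l makes the PAP step nearly transparent to them
(pass ≈ 0.995–0.9999 per branch), so ≈ 97% of classical cases survive
steps 1–2. Non-classical parameters are set so that ≈ 89% survive;
with the 0.72/0.28 class mix and small panel/failsafe losses
(concentrated in the low-detectability migrant strata) the four-step
sensitivity over all CF lands at ≈ 94–95% analytically, which simulation
confirms. The carrier IRT median sits 15% above unaffected (carriers are
known to run mildly elevated IRT). The unaffected PAP σ of 0.85 yields a
realistic, small IRT/PAP false-positive rate at the pilot thresholds
(order 2–3 per 10,000 screened) without affecting the national protocol's
specificity.

These defaults are assumptions, not published values; only the calibrated
unaffected IRT tail and the two aggregate claims are anchored.

## Protocol engine

The national four-step tree (all thresholds inclusive for positivity,
strict for negativity; the 60–100 band is half-open so IRT = 100 takes the
high-IRT branch):

1. IRT < 60 µg/l → negative.
2. PAP < 3.0 µg/l (60 ≤ IRT < 100) or < 1.6 µg/l (IRT ≥ 100) → negative.
3. Mutation panel: 2 panel mutations → CF referral (sequencing adds
   nothing when the diagnosis is already genotypically certain);
   1 → sequencing; 0 → negative unless the failsafe fires
   (IRT ≥ 100 and PAP ≥ 1.6 → sequencing anyway, because an extreme
   biomarker signal with a negative panel suggests a rare mutation,
   typically in a migrant-ancestry newborn).
4. Sequencing: 2 disease alleles → CF referral; 1 → carrier report
   (relabelled negative-after-sequencing when carrier reporting is opted
   out); 0 → negative after sequencing.

EGA is modelled as detecting every disease allele; a per-allele
sensitivity hook (default 1.0) exists for sensitivity analyses and
requires an explicit RNG when below 1. Referral is the terminal event —
sweat-test confirmation is out of scope.

Pilot-era strategies: pure IRT/PAP (positive iff IRT ≥ 50 & PAP ≥ 1.8, or
IRT ≥ 100 & PAP ≥ 1.0 — thresholds on the pre-correction kit scale);
IRT ≥ 50 followed by panel + sequencing (no PAP, no failsafe); and the
combined scenario, which pushes exactly the IRT/PAP positives through the
DNA tiers — its referral set is by construction the intersection of the
two pilot strategies' referral sets. Because the historical PAP kit
calibrators assumed a 5 µl punch volume that is actually 3 µl, historical
PAP concentrations must be multiplied by exactly 5/3; by default the pilot
thresholds are mapped through this correction so they can screen cohorts
simulated on the modern scale (1.8 → 3.0, 1.0 → 5/3).

## Evaluation conventions

Disease-positive defaults to any CF class, switchable to classical-only
(both are computed since the published aggregate figures do not state
which definition they use). Carriers count as non-diseased; a carrier
report is a secondary finding, never a false-positive referral.
Sensitivity = referred CF / all CF not flagged meconium-ileus;
specificity = true negatives / (true negatives + false-positive
referrals); PPV = true-positive referrals / all referrals. Empty
denominators are reported as NaN with an explicit flag, never silently as
0 or 1.

A structural consequence worth stating plainly: with perfect EGA a CF
referral requires two confirmed disease alleles, so unaffected and carrier
newborns *cannot* be referred under the national protocol and its
simulated specificity is exactly 100% — consistent with, and stronger
than, the > 99.99% claim. Real programs sit below this because of
laboratory error and sweat-test borderline cases, which are outside the
model.

## Risk calculus

With carrier frequency *c*: allele frequency *q = c/2*; birth prevalence
*q²*; risk of an affected child in the next pregnancy once a child is
known to be a carrier: *q/4* in the Punnett-square formulation used in
counselling practice (1/240 at *c* = 1/30, fifteen times the 1/3600
prevalence). A fully conditioned derivation (one parent is a proven
carrier and transmits with probability ½; the partner transmits a mutant
allele with probability *q*) gives *q/2*; both operations exist under
distinct names and are never silently substituted. After a negative
parental test with sensitivity *s*, the partner's carrier probability
updates by the standard Bayes rule *p(1−s)/(p(1−s)+1−p)* and the
next-pregnancy risk is recomposed through the same *q/4* rule on the
residual. All operations preserve exact rationals (`fractions.Fraction`)
and degrade gracefully to floats.

## Problem sizes and numerical choices

The shipped analyses use 200,000 newborns for specificity, the pilot's
72,874 for strategy comparisons, 4,000 CF-genotype newborns (sampled
conditionally on two disease alleles, strata weighted by
fraction × q²) for sensitivity, and 10⁶ direct draws for biomarker-tail
checks. These sizes put Monte-Carlo error well inside the tolerances of
interest (binomial SE of the sensitivity estimate ≈ 0.35 pp at n = 4,000)
while a full run stays in the seconds range. Stochastic assertions in the
test suite use 4-standard-error bands. Tie-breaks at thresholds are exact
(`>=` positivity); concentrations are serialized with 10 significant
digits for lossless round-trips.

## Limitations

- Biomarker parameters for affected classes are calibrated assumptions;
  the model cannot be used to re-estimate real cutoff performance, only
  the logic and relative behaviour of strategies.
- Under the shipped defaults the national protocol reports essentially no
  carriers (carriers rarely clear the PAP step when IRT and PAP are
  conditionally independent); the real program expects a dozen per year.
  A positive log-correlation between markers or a higher carrier PAP
  median moves this count up without touching the headline properties.
- Empirical pilot cell counts (119/20/12 referrals, carrier tallies) are
  qualitative targets only: the underlying individual-level data are not
  available, and the published table is not fully self-consistent.
  The engine reproduces their orderings, not their values.
- No assay measurement-error layer distinct from biological variation, no
  age-at-sampling effects, no second-heel-prick recall policy, no sweat
  test, no real mutation nomenclature, no consanguinity or haplotype
  structure.
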
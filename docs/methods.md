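# Methods

`pgxtraj` implements a longitudinal pharmacoepidemiological analysis: do
CYP2D6 and CYP2C19 metabolizer phenotypes predict whether patients with
depressive/anxiety disorders switch or discontinue antidepressant (AD)
treatment, and do they perceive different side-effect burdens?  The package
covers the whole chain — genotype translation, drug substrate
classification, trajectory definitions, side-effect aggregation, the
statistical layer and a synthetic cohort generator — as a reusable, tested
library with a thin CLI.

## Genotype translation

Star alleles carry a functional class.  Defaults: CYP2D6 *1,*2 fully
functional; *3,*4,*6 inactive; *10,*17,*41 reduced.  CYP2C19 *1 fully
functional; *2,*3 inactive; *17 increased.

* **CYP2D6** is scored by gene dose (activity score): 1 / 0.5 / 0 per
  full / reduced / inactive allele, binned PM = 0, IM = 0.5–1,
  NM = 1.5–2.5.  The reachable doses form a closed set
  {0, 0.5, 1, 1.5, 2, 2.5}; any other value signals a corrupt allele table
  and raises instead of being binned silently.
* **CYP2C19** uses combination rules: two inactive/reduced alleles → PM;
  exactly one → IM; FULL/FULL → NM; FULL/INCREASED → NM under DPWG (the
  default) and UM under CPIC; INCREASED/INCREASED → UM.  The two
  conventions differ on exactly the FULL/INCREASED (*1/*17) diplotypes.
  REDUCED CYP2C19 alleles are accepted by the rule engine although no
  default allele carries that label, keeping user-supplied tables
  extensible.

Unidentifiable alleles (the *5 whole-gene deletion, duplications) cannot be
distinguished by the array-plus-imputation genotyping this pipeline models.
`paper_compat` mode (default) maps any allele missing from the function
table to *1 before translation — reproducing the known NM-inflation bias of
that choice — while `strict` mode translates such diplotypes to UNKNOWN.
Diplotypes whose imputation quality flag is unset always translate to
UNKNOWN and are excluded from association analyses.

## Substrate table and trajectories

Antidepressants are classified by 7-character ATC code into CYP2C19-only
(5 drugs), CYP2D6-only (12), both (4) or neither; the table ships as
packaged CSV data keyed by ATC code.  NEITHER drugs (e.g. tryptophan,
tranylcypromine) stay in timelines and may serve as index drugs (they count
toward eligibility and switch detection) but never define subsample
membership; a flag can exclude them from eligibility.

Medication use is discretized into 11 ordered periods (intervals between
visits and current-use assessments, from three years pre-baseline to the
9-year follow-up).  A patient is an *eligible index user* if period 1 shows
exactly one AD, or the first period of use in 2..10 shows exactly one AD
with all earlier assessed periods AD-free.  Successive AD-use periods are
compared pairwise; two use periods separated only by AD-free periods form a
gap-spanning comparison that supersedes consecutive comparisons inside the
gap.  A comparison is a *switch* when the two periods share no drug —
replacement, not augmentation; carrying the original AD forward next to an
added drug is not a switch.  Labels:

* SWITCHED — some comparison is a switch (this takes precedence, since the
  other two definitions require that no switch took place).  A return to
  the original drug after an intermediate different drug is still SWITCHED.
* DISCONTINUED — use confined to periods 1–4, no use in any assessed
  period 5–11, and at least one period ≥ 5 assessed.
* NOT_CLASSIFIABLE — use confined to 1–4 with no assessment ≥ 5;
  continuation is unknowable and the patient is excluded, with the
  exclusion logged in the flow counts.
* MAINTAINED — otherwise.

Unassessed periods are skipped, never imputed as AD-free.  Period 11
participates in switch detection and the 5–11 emptiness test, but
eligibility for MAINTAINED is governed by use in periods 1–10.  Subsample
membership (CYP2D6 / CYP2C19 analysis arms) is fixed by the index drug even
if a patient later switches to a different substrate class.

Discontinuation reasons (symptom-free / ineffective / side-effects) attach
to the visit transitions 5→6, 7→8 and 9→10: a stop event is a prior-period
drug set that empties or is fully replaced, and reason records are matched
on the visit period and a prior-period drug's ATC; unmatched records are
logged and excluded.  Counts are tabulated by enzyme and collapsed group
(NM vs IM/PM for CYP2D6; NM vs IM/PM/UM for CYP2C19).

## Side effects

The ASEC-12 checklist is binary per item, collected per drug at periods 3,
5, 7, 9.  Categories: serotonergic (insomnia, restlessness, muscle
spasms/twitching, profuse sweating, sexual disorders, nausea, diarrhoea),
cholinergic (dry mouth, constipation), histaminergic (daytime sleepiness,
weight gain); dizziness counts in the 12-item total only.  Aggregation is
strictly two-stage: mean count over qualifying drugs (substrates of the
enzyme under analysis) within a period, then the mean of the available
period means — missing periods are dropped from the denominator, not
zero-imputed.  Source files may code 1 = reported (canonical) or
0 = reported (the questionnaire's printed convention); a config flag
converts on read, because a count of *perceived* side effects must count
reported items.

## Statistical layer

All models are crude (unadjusted): the published odds ratios equal the raw
cross-products, so no covariates are modelled.

* **Odds ratios**: OR = ad/bc on the (group, reference-group) ×
  (event, maintained) subtable, with the Woolf/Wald interval
  exp(ln OR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d)); z₀.₉₇₅ = 1.959964.  Zero cells
  raise an explicit error; a Haldane 0.5 correction is opt-in only.
* **Logistic regression**: plain Newton/IRLS from β = 0, converging when
  max |score| < 1e-8 or max |Δβ| < 1e-10, at most 50 iterations; fitted
  log-odds exceeding ±30 or a singular information matrix are reported as
  perfect separation.  On a saturated 2×2 expansion the exponentiated
  coefficient equals the closed-form OR to ≈ 1e-12, which the test suite
  exploits as an independent oracle (with statsmodels as a second
  cross-check).
* **Mann–Whitney U**: midrank-based U, tie-corrected normal variance, no
  continuity correction by default (matching the defaults of the major
  statistics packages at these sample sizes); continuity correction by
  flag, and an exact-enumeration mode for n₁+n₂ ≤ 12.  When all pooled
  values tie, the variance is zero and p is reported as 1.  Exhaustive
  enumeration shows the *uncorrected* approximation can deviate from the
  exact two-sided p by more than 0.05 at every size pair with
  n₁+n₂ ≤ 12 (worst case 0.089 at n₁ = n₂ = 5); with the continuity
  correction the deviation stays below 0.05 for all min(n₁,n₂) ≥ 3, which
  the suite verifies exhaustively.
* **Power**: Cohen's arcsine effect size h = 2·asin√p₂ − 2·asin√p₁ with
  the two-sided z-test, power = Φ(z−z_crit) + Φ(−z−z_crit),
  z = |h|/√(1/n₁+1/n₂) — the "two independent proportions" z-family.  On
  the published CYP2D6 comparisons this reproduces the reported 0.27–0.29
  power range.

The association analysis is exposed statsmodels-style:
`MetabolizerAssociation` (built `from_counts` or `from_dataframe`) with
`fit()` returning `AssociationResults` carrying the estimates table,
post-hoc power per contrast and a `summary()` that prints percentages at
1 decimal and ORs/CIs/power at 2, the precision of the source report.

## Synthetic cohort generator

The real cohort is access-restricted, so the generator emulates its
structure; its defaults are the study conditions and are not tuned per
test.

* **Diplotypes** are drawn under Hardy–Weinberg equilibrium, independently
  per gene.  Defaults are HWE inversions of the study's phenotype
  prevalences (see `scripts/calibrate_frequencies.py`).  Two constraints
  matter: HWE has only two free class frequencies per gene, and collapsing
  unidentifiable alleles to *1 preserves HWE, so the study's CYP2D6
  PM 2.4% / IM 14.2% split is not jointly attainable (PM = i² = 0.024
  forces IM ≥ 2i−2i² ≈ 0.26).  The defaults therefore match the CYP2D6 NM
  share — hence the NM vs IM/PM analysis split — exactly (83.0% of
  established phenotypes) with a small realistic reduced-allele mass
  (3%), yielding PM 0.8% / IM 16.2%; CYP2C19 uses a relative-weighted
  least-squares fit giving PM 1.6 / IM 22.1 / NM 70.4 / UM 5.9 (%) against
  targets 2.5 / 20.9 / 70.7 / 5.9.  A 2.2% CYP2D6 imputation-failure rate
  is applied as a quality flag.
* **Timelines**: each patient receives an index drug (probabilities
  proportional to the study's drug distribution, paroxetine 30.5% …) and a
  trajectory from the mixture (51.6 / 35.3 / 13.0% maintained / switched /
  discontinued, the study's realized shares).  Maintained patients run the
  index drug from a uniform start (1..10) through period 11; discontinued
  patients start and stop within periods 1–4; switchers end the index drug
  at a uniform period ≤ 9 and start a different drug, in 30% of cases
  after one AD-free gap period.  Group-specific switch/discontinue odds
  are tilted multiplicatively by configurable log odds ratios keyed
  `"ENZYME:GROUP"`, so the conditional 2×2 OR between a tilted group and
  the baseline equals exp(β) exactly — the basis of the parameter-recovery
  checks.  All periods are assessed by default (`assessed_prob` < 1
  introduces uniform missingness; the tests that assert exact round-trip
  label recovery assume the default).
* **Side effects and reasons** are independent Bernoulli/multinomial draws
  (default item probabilities 0.15 per pharmacological category, 0.10 for
  dizziness; reason mix 0.40 / 0.25 / 0.35 symptom-free / ineffective /
  side-effects, close to the study's tabulated reasons).

What the generator does *not* emulate: linkage between the two loci,
population structure, drug-specific trajectory differences, correlated or
drug-attributable side effects, informative drop-out, dose changes.
Passing recovery tests therefore demonstrate that the pipeline's
definitions and estimators are implemented correctly, not that the study's
substantive findings generalize.

## Validation studies and run sizes

`pgxtraj.validation.replicate_association` regenerates a full synthetic
cohort per replicate (fresh genotypes, timelines, phenotype translation,
trajectory classification, association fit) with per-replicate seeds
spawned from one master seed.  The suite runs 300 replicates at n = 4000
with ln 2 injected on CYP2D6 IM/PM switching and checks ≥ 93% CI coverage
of OR = 2, and 1500 null replicates checking the Wald rejection rate stays
within 0.05 ± 0.02; the acceptance script reports the same quantities at
300 replicates per arm.  These sizes give Monte-Carlo standard errors of
about 1.3 and 0.6 percentage points respectively; the null arm is larger
because a 0.009 standard error (a few hundred replicates) cannot reliably
resolve a ± 0.02 band.

## Known limitations

* Phenotype translation covers the default allele tables plus user CSV
  extensions; no copy-number awareness or activity-score schemes beyond
  the one above.
* The trajectory rules encode the published textual definitions; corner
  cases the source only depicts graphically follow the documented
  interpretations (switch = full replacement; switch-back still SWITCHED).
* Only crude associations are computed — no covariate adjustment, no
  multiple-testing correction, no time-to-event modelling.
* The generator's HWE constraint means the study's exact CYP2D6 PM/IM
  split cannot be reproduced (see above); prevalence-sensitive checks are
  therefore written against the HWE-implied values.
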
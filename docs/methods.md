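# Methods

This note records the modelling assumptions, parameter defaults and
numerical choices behind `equamu`, and what the synthetic validation does
and does not demonstrate about real practice data.

## Data model and consolidation

A practice export has one row per invoiced item (procedure,
pharmaceutical, or other billed service). The analysis unit is the
*consultation*: all items for one (practice, horse, calendar day) triple.
Records carry no within-day times, so within-day order is input order and
the consultation's combined text concatenates each member record's
anamnesis, diagnosis and description fields in that order. Horse
identifiers are scoped to their practice; no cross-practice identity is
attempted (routine exports offer none). Malformed rows — unparseable
dates, missing horse ids, pharmaceutical items without a product
reference — are counted in an ingest report, never silently dropped.

Inclusion filters follow standard surveillance practice: a configurable
calendar window (default 2018-01-01..2023-12-31) and a minimum practice
size (default 100 distinct equine patients; "registered patient" is
operationalised as a horse with at least one in-window record — the only
observable proxy in billing data). Age is (consultation date − birth
date)/365.25; values outside [0, 40] years are flagged implausible and
excluded from age analyses only.

## Treatment classification

Products are resolved against a catalog mapping each product to its
antibacterial substances, each substance to one of 13 classes. The four
WHO highest-priority critically important antimicrobial (HPCIA) classes
are 3rd/4th-generation cephalosporins, fluoroquinolones, macrolides and
polymyxins; the HPCIA flag is definitionally equal to membership in that
set. Trimethoprim is not treated as an independent class: sulfonamide +
trimethoprim products map entirely to the sulfonamides class, matching
the reporting convention for that combination. Clavulanic acid is carried
as a beta-lactam component, so amoxicillin/clavulanate counts as a
fixed-dose combination.

Two denominators coexist and are always labelled: *treated consultations*
(one per consultation with ≥ 1 antibiotic) and *applications/deliveries*
(one per distinct product × substance at a consultation; a product
invoiced twice on one day counts once). Combination categories partition
treated consultations: `single` (one product, one substance),
`fixed_dose` (one product, ≥ 2 substances), `empirical` (≥ 2 distinct
products; the sub-case where one of them is itself a fixed-dose
combination is folded into `empirical` for headline counts, since the two
cannot be distinguished in aggregate reporting).

The packaged catalog is a curated 26-product demonstration fixture
covering the substances relevant to equine practice (sulfonamide-TMP
pastes, aminopenicillins, penicillins, gentamicin, human ophthalmic
gentamicin/neomycin/ofloxacin/chloramphenicol, fluoroquinolones,
cephalosporins, tetracyclines, a macrolide, metronidazole, clindamycin,
fusidic acid, polymyxin B); real catalogs load from the same delimited
format.

## Indication classification

Free text is lower-cased, split on non-word characters (hyphens split,
umlauts and ß preserved), and matched token-wise: a catalog term (an
n-gram of tokens, each term mapped to exactly one of 20 diagnostic
categories) fires iff its token sequence occurs contiguously. Token-based
matching was chosen over raw substring matching so that, e.g., "husten"
does not fire inside "hustensaft". Multi-label assignment is intended: a
consultation is labelled with every category that has ≥ 1 matching term.

The shipped vocabulary (~150 German terms) is a demonstration fixture;
operational catalogs are orders of magnitude larger and load from the
same two-column format. The classifier's known failure mode is
reproduced, not patched: context-free keywords ("influenza" in a
vaccination note) still map to their organ system. That is precisely why
the package includes validation sampling — a seeded uniform sample of
assigned consultations plus Wilson-interval scoring of manually labelled
errors — rather than pretending dictionary matching is reliable.

## Episode construction

All windows are parameters; the defaults encode the two distinct
phrasings used in surveillance reporting:

- *initial treatment*: treated consultation with no treated consultation
  of the same horse on days d−30..d−1 inclusive (a prior treatment
  exactly 30 days earlier therefore makes it non-initial);
- *follow-up treatment*: treated consultation on days d+1..d+7 after an
  initial one (day-0 second products are combinations, not follow-ups);
- *repeated treatment*: a horse with two treated consultations whose gap
  is ≥ 30 and ≤ 365 days (note the deliberate asymmetry with the lookback
  window: "at least 30 days between" includes a 30-day gap);
- *switches*: restricted to consultations with exactly one antibiotic
  product (fixed-dose combinations count as one product); for each
  initial treatment the earliest single-product follow-up whose
  substance-class *signature* differs yields one event. A substance swap
  within a class (amoxicillin → ampicillin) is not an event — switch
  events are defined by a class change, which keeps the from/to fields
  meaningful and matches class-level reporting.
- *return times*: days to the horse's next consultation (any kind), kept
  within 1–21 days, stratified by whether the index consultation was
  treated, shares normalised within stratum.

Follow-up linkage never crosses horses or practices. The implementation
uses per-horse sorted-array window searches; its correctness is certified
in the test suite against a brute-force all-pairs oracle on random
timelines. When one initial treatment has several follow-up visits, each
visit is counted (visits, not episodes).

## Estimators

**Wilson interval.** Implemented from the closed form with
z = Φ⁻¹(0.975) = 1.959964 (printed 1-decimal percentages also reproduce
with z = 1.96). Bounds are clamped to [0, 1] and set exactly to 0 (k = 0)
or 1 (k = n) where the score bound is exact. Percentages for reports are
rounded half-up to one decimal. The exact coverage of the Wilson interval
oscillates with n·p because the binomial is discrete: summing binomial
probabilities gives, e.g., 91.1% at (n = 50, p = 0.01), 97.8% at
(n = 50, p = 0.07) and ~94.3–95.1% for the large-n cells; aggregated over
the 3 × 3 validation grid the exact coverage is 94.8%. The coverage
simulation therefore checks the aggregate against the nominal band and
each cell against its exact analytic value — a per-cell nominal band
would be unattainable for any correct implementation at small n·p.

**Practice-adjusted prevalence.** Common-effect (fixed-effect)
inverse-variance meta-analysis of per-practice proportions. Default
transform is the logit with within-practice variance 1/kᵢ + 1/(nᵢ−kᵢ),
the standard default for pooling proportions; boundary cells (kᵢ = 0 or
kᵢ = nᵢ — zero-use practices are real and common) receive a 0.5
continuity correction applied to both cells. A `raw`-scale variant
(variance p̂(1−p̂)/n, same continuity rule) is available; with the
correction in place no degenerate-variance case remains. No
random-effects model is offered: the estimand is the common-effect
average, and heterogeneity between practices is reported instead through
the per-practice table (forest-plot data with normalised weights).

**Yearly trend.** Per-calendar-year treated share with Wilson CIs;
optionally restricted to practices contributing at least one consultation
in every year of the range, so entry/exit of practices does not
masquerade as a trend.

**Age model.** Binomial GLM with logit link on a natural cubic spline
basis of age, df = 3: two interior knots at the terciles of the observed
age distribution, boundary knots at the observed range (knot placement is
stated explicitly because it is a genuine free choice). The basis is the
truncated-power construction of the natural spline space (continuous
second derivatives, linear beyond the boundary knots — both properties
are property-tested). Fitting is maximum likelihood via IRLS
(statsmodels GLM; relative convergence 1e-8, 25 iterations max); inputs
with a single outcome class, non-finite coefficients or solver failure
raise a `SeparationError` with the underlying diagnostics. Pointwise 95%
bands come from the delta method on the linear predictor, transformed to
the probability scale.

## Synthetic data generator

The generator emulates the statistical structure of a multi-practice
routine-records study; its defaults are the bundled study conditions:

| parameter | default | rationale |
|---|---|---|
| practices | 57 | multi-practice national sample |
| patients/practice | log-normal, median 430, σ = 1.2, clipped to [100, 6500] | matches a practice-size distribution with median ~430, range ~100–6500 and ~50k horses total |
| consultations/horse | 1 + Poisson(3.4) | ~4.4 visits per horse over six years |
| window | 2018–2023 | six calendar years |
| overall prevalence target | 7% of consultations | headline AMU rate in equine practice |
| practice prevalence | Beta(2.5, 27); zero-use with prob 10/57 | practice-specific rates spreading ~0–20% with a realistic share of practices never using antibiotics in horses |
| age at first visit | 8% uniform(0, 3) + 92% N(13.5, 8²) truncated to [0, 40] | median ~13 y with a young-stock component |
| missing birth dates | 37.5% | typical completeness of routine records |
| age effect | logit-quadratic U, minimum at 12.5 y, amplitude 0.76 at both range ends | treatment odds roughly double from mid-age to the range ends |
| indication structure | 32.4% of consultations carry indication text; category shares and per-category treated shares from the bundled profile (ophthalmology most treated) | drives both text generation and the indication effect on treatment |
| follow-up | P = 0.334 of a treated follow-up within 7 d; switch prob 0.088; offsets truncated-geometric (q = 0.34) | episode structure with most switches on days 1–2 |
| return times | geometric day offsets, q = 0.2734 treated / 0.1515 untreated (P(≤2 d) = 0.472 / 0.280), short-return prob 0.58 / 0.45, long gaps uniform 22–365 d | treated horses return earlier |
| text error rate | 0.23 | misleading-keyword injection emulating a ~23% dictionary-classifier error rate |

Treatment status is drawn per consultation from
logit(p) = intercept + practice effect + age effect + indication effect,
with the intercept calibrated by bisection so that the *mean assigned
probability* over the generated consultations equals the configured
target exactly. The calibration reuses one set of pre-drawn uniforms
(common random numbers) across candidate intercepts, so the final treated
flags remain an unbiased Bernoulli realisation of the calibrated
probabilities: the realised overall share is then within binomial noise
of the target by construction, not by accident. Zero-use practices are
forced to probability zero and the calibration compensates on the
remaining practices.

Visit timelines are generated as a chain: the gap to the next visit
depends on whether the current visit was treated (return-time dynamics),
and after a treated visit the next one is, with the follow-up
probability, scheduled within 1–7 days and treated again (continuing the
same product, or switching class with the switch probability). A
standalone `generate_followups` operation can instead append follow-up
consultations to any existing record set, which the tests use to pin the
switch machinery at probabilities 0 and 1.

Free texts are assembled from catalog keywords that are *generation-safe*
(no term of another category occurs inside them as a token subsequence),
joined by non-catalog filler; consultations without an indication get
non-clinical filler text. With the text error rate ε, a keyword from a
category outside the true label set is appended with probability ε, so
the measured misclassification rate equals ε in expectation — this is
what lets the validation-sampling machinery itself be validated.
Ground truth (per-practice prevalence as the mean assigned probability,
per-consultation labels, products, follow-up/switch flags, the age-effect
minimum) is returned alongside the records.

### What the synthetic validation does not show

The generator's texts are keyword assemblies, not clinical German prose:
passing the classifier-ceiling test shows the matching machinery is
correct, not that any particular vocabulary generalises to real notes
(the quantified ~23% error rate of dictionary matching on real text is
the honest benchmark). Treatment decisions are conditionally independent
given practice, age, indication and episode state — real prescribing has
richer correlation (clinician habits, seasonality, disease outbreaks).
Horse-level repeat-treatment clustering is weaker than in real data
(chronically ill horses are not explicitly modelled), so repeated
treatment shares come out lower than in the field. Product choice is a
static mixture per indication; no temporal trend in substance choice is
simulated, and quantities carry no dose information, so no mg/kg or
defined-daily-dose metrics are possible.

## Problem sizes used in validation

The bundled validation runs the full pipeline on a complete 57-practice
synthetic study (~10⁵–2·10⁵ consultations, seeded), certifies the episode
engine on 1,000 random timelines against a brute-force oracle, and uses
10,000 replicates per cell for the coverage grid; smaller configurations
(6–8 practices) back the unit tests. These sizes put Monte-Carlo error
well below the tolerances being checked while keeping the whole suite in
the tens of seconds.

## Known limitations

- Substance switches within one class are invisible by design; switch
  detection also ignores multi-product consultations entirely, matching
  the single-antibiotic restriction of the analysis it implements.
- The common-effect pooled estimate answers "what is the common rate if
  all practices shared one" — under real heterogeneity it is a weighted
  compromise and can sit noticeably away from the crude share; both are
  reported.
- The spline model estimates association of age with treatment, not
  causation; its minimum location inherits sampling noise of order ±1–2
  years at 10⁵ observations for effect sizes like the default.
- Day-resolution timestamps make same-day re-presentations
  indistinguishable from single consultations; they are consolidated.
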
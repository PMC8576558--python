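# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `opidup`, in the spirit of a statistical software methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Order model and activity semantics

A medication order carries exactly the fields a real-time pharmacy feed
exposes: drug name, route, formulation, dose and frequency text, PRN/PCA
flags, free-text PRN indication and administration instructions, start and
(optional) end timestamp, verification-location class, and an optional
linked-order-group id. Timestamps are timezone-naive ISO 8601 at minute
precision; a feed is assumed to come from one facility clock.

An order's activity window is **half-open**, `[start, end)`: a discontinued
order stops contributing to alerts at its end timestamp, and an order with
no end time is open-ended. Orders contribute to duplicate detection only if
they are opioids ordered PRN or as PCA.

Pain categories are the five template bands — mild 1–3, moderate 4–6,
severe 7–10, mild-and-moderate 1–6, moderate-and-severe 4–10 — plus PCA and
*unspecified* (no band). Two banded categories cover "the same pain level"
when their integer score ranges **intersect**, not when their labels are
equal: a 4–10 order duplicates both a 4–6 order and a 7–10 order. Combined
bands exist on real order templates, so overlap (rather than equality) is
the only definition that makes them participate in level-specific rules.

## Indication parsing

Parsing is rule-based and total. A valid numeric range (`1 ≤ a ≤ b ≤ 10`)
anywhere in the text takes precedence over word labels; a "score"/"scale"
prefix is preferred when several ranges appear, which keeps dose strengths
like "5-325 mg" from being misread as pain scores. An off-template range
maps to the *narrowest uniquely enclosing* band (2–5 → 1–6; 4–5 → 4–6) and
to unspecified when no band or no unique narrowest band encloses it; real
feeds drift from the templated vocabulary and this rule degrades gracefully
rather than guessing. Word labels are matched case-insensitively through an
ordered, YAML-editable rule table (combined labels before single labels).
Everything else — empty text, bare "pain", "breakthrough pain", "any pain",
unrecognised prose — is unspecified. PCA orders are categorised PCA
regardless of text.

## The alert bundle

Five rules are evaluated over a patient's co-active, non-censored opioid
PRN/PCA orders (censoring removes orders verified in operating rooms and
procedural areas, whose transient orders follow a different medical-record
workflow):

1–3. *Explicit* mild/moderate/severe rules: fire when ≥2 orders' bands
overlap that level's range; every such order is listed as triggering.

4. *Unclear indication* ("Opioids PRN for pain"): fires when at least one
co-active order is unspecified and at least two eligible orders exist; a
scale-free order duplicates any co-active PRN opioid, so all eligible
orders are listed. **Bundle version 1** — the rule set as first deployed —
does not count the "breakthrough pain"/"any pain" forms as triggers;
**version 2** (the package default) does. The version flag exists because
the distinction matters when replaying historical evaluations.

5. *PCA* rule: a PCA order co-active with ≥1 separately ordered intravenous
non-PCA PRN opioid of any pain level. Oral partners do not fire it.

Streaming evaluation runs the bundle at every order-start event (the
real-time proxy for order verification; re-evaluation at discontinuation
events is deliberately not performed, as silent resolution generates no
message). Throttling permits one alert per (patient, rule name) per
24-hour window, timed from the last *emitted* alert; a boundary hit at
exactly 24 h emits. The scope is per rule name because the five alerts are
configured independently; a stricter `per_patient` scope is available for
patient-review workflows. Alerts are emitted in a fixed rule order so logs
are reproducible.

The detector never reads `linked_group_id`: the live order feed carried no
linking information, and the package preserves that asymmetry — linking is
visible only to the chart-review-level triage.

## Appropriateness triage

A duplicate set is judged on three booleans. *Same route and formulation*
is evaluated pairwise — one interchangeable pair is enough to make the set
a hard duplicate (category 5, discontinue all but one) regardless of the
other attributes. Otherwise (clear, linked) maps to categories 1–4 with
interventions none / clarify instructions / link orders / clarify-and-link;
only category 1 is appropriate. *Clear administration instructions* is
operationalised as nonempty instruction text matching a configurable
conditional-guidance pattern list (seeded with "give if…"), since the
policy's own template texts are the only available evidence of what
"clear" means; clarity is required on **all** orders in the set, the
conservative reading. *Linked* requires one shared, present group id.

Discontinuation candidates for category-5 sets are ranked oldest start
first (ties by order id); reason codes for chart facts the feed cannot see
(no recent administration, documented adverse events, no associated order
set) are emitted only when the caller supplies them.

## Validation statistics

Evaluation is at the **patient level** — any alert in the window versus the
chart-review reference — matching how medication-profile review actually
consumes alerts. The five diagnostic metrics are derived from the 2×2
table, each with a Clopper–Pearson exact interval computed via beta
quantiles; one-sided lower bounds use `B(α; x, n−x+1)`, which for x = n
reduces to the closed form `α^(1/n)` (for a perfect 10/10 sample at
one-sided 97.5% this is 0.6915 — the package reports the computed value).
Exactness was chosen over asymptotic intervals because the evaluation
denominators of interest are small (tens of patients).

**Percent display** rounds half-up in two stages: to one decimal percent,
then to an integer percent (94.49 → 94.5 → 95). This matches the common
clinical-reporting practice of rounding an already-one-decimal display
value and is applied uniformly; raw proportions are always retained in
machine output.

Review-time effort is modelled as a saturated categorical regression:
minutes on action-category indicators without intercept, so fitted
coefficients are per-category means and intervals use the pooled residual
variance (classical OLS, not per-group Welch). The four mutually exclusive
action categories are no action, discontinuation, advanced modification,
and provider/nurse contact. The package fits the *structure*; it ships no
minute values, since per-patient timing data are not public. The
acceptance script exercises parameter recovery on simulated times with
generating means (5, 7, 14, 21) minutes and noise SD 3 — SD 3 makes the
category means distinguishable at realistic per-category sample sizes
while leaving visible sampling error; it uses 200 records per category for
stable estimates, and the test suite additionally checks CI coverage at
the small-sample size of 15 per category.

## Synthetic cohorts

The generator emulates a 5-day cross-sectional evaluation window. Defaults
are the package's fixed study conditions: 201 patients; a mean of 1.2
background PRN opioid orders per patient (Poisson); an order-level
indication mix of 1% mild, 51% moderate, 39% severe, 1% mild-and-moderate,
2% moderate-and-severe, 2% PCA, 4% unspecified; duplicate prevalence 0.17;
and a duplicate-type mix of 35% moderate / 26% severe / 21% both / 18%
unclear. Planted sets realise "both" as {moderate, severe, 4–10} triples so
one set duplicates two levels. Attribute triples for planted sets default
to 50% same-route-and-formulation, 40% clear instructions, 15% linked —
rough rates consistent with the intervention pattern seen when pharmacists
triage such alerts (discontinuation being the most common action, linking
and clarification each around a third).

`category_mix` governs the marginal distribution of *background* orders;
planted duplicate sets draw their level from `duplicate_type_mix`, so with
planting enabled the overall empirical mix is a mixture of the two (the
joint structure of order-level and patient-level mixes in a real cohort is
unknowable from published marginals; the goodness-of-fit contract is
therefore stated and tested on the background process).

Background orders are placed with a conflict-avoidance rule: a new order
that would be co-active with an order it forms any rule-satisfying pair
with is shifted past the conflict. Consequently, with all noise off, the
detector recovers the planted labels exactly — sensitivity and specificity
100% by construction. That is a property of internal consistency, not
evidence about real feeds: passing it shows the detector implements the
labelling rules, nothing more.

Realistic imperfection enters only through four explicit noise modes, each
a per-patient probability: `parser_evading` (a planted order's indication
becomes "breakthrough pain" — missed by bundle v1, caught by v2),
`procedural_verification` (one planted order is operating-room-verified and
censored), `chart_only` (the duplicate never enters the feed), and
`transient_duplicate` (a reference-negative patient alerts on a briefly
co-active pair discontinued before review). The first three depress
sensitivity; the last depresses specificity.

`make_step2_fixture()` is a deterministic, RNG-free instance of these
mechanisms: 201 patients, 34 chart-review duplicate patients (12 moderate,
9 severe, 7 both, 6 unclear), one censoring miss, one breakthrough-form
miss, 7 transient false positives, and 160 reference negatives, for 239
active orders overall. Evaluated with bundle v1 it yields TP=32, FP=7,
FN=2, TN=160.

What the generator does **not** model: medication-administration records,
pain-score trajectories, length-of-stay realism, dose equivalence, or
non-pain PRN indications.

## Numerical and interface conventions

* Route/formulation/location tokens are normalised to closed sets at
  ingest; unknown tokens map to `other`. Detection therefore never depends
  on free-text spelling of these fields.
* `is_opioid` is taken from the feed when present, else resolved by
  substring match against a configurable formulary (default: tramadol,
  codeine, hydrocodone, oxycodone, hydromorphone, morphine, fentanyl).
* Malformed feed rows are reported with line numbers and skipped by
  default (`strict=True` raises); duplicate order ids abort the read.
* The HL7-lite dialect is a minimal, documented stand-in shaped like an
  HL7 v2 pharmacy-order message, not a certified HL7 implementation; free
  text may not contain the `|` delimiter.
* All randomness flows through a single `numpy` Generator seeded from the
  config; identical configs produce byte-identical feeds.

## Known limitations

* "Clear instructions" is a pattern heuristic; sites with different
  instruction conventions must extend the pattern list.
* The detector evaluates at order starts only; a duplication created by
  *re-activating* an order without a new start event would be missed.
* Throttling drops within-window repeat alerts entirely rather than
  queueing them; event-level duplicate counting (as opposed to
  patient-level flagging) therefore needs the throttle disabled.
* Clopper–Pearson intervals are conservative (coverage ≥ nominal), which
  is the standard trade-off for exactness at small n.
* The synthetic noise modes are stylised single causes; real false
  positives and negatives can arise from messier mechanisms (order-message
  loss, mid-stream indication edits) that the generator does not model.
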
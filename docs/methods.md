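# Methods

## Problem setting

Retrospective clinical-research registries (the motivating case: breast and
sarcoma radiation-oncology treatment databases) are populated by technicians
abstracting narrative charts into structured records spread over ten or more
data-entry forms. Errors of *omission* — a field left empty although the true
value existed and was knowable — dominate over wrongly inserted values, and
they are not missing-at-random: an omitted relapse date reads as "never
relapsed" and silently biases outcome analyses. `registryqc` packages three
counter-measures that operate on such records:

1. **Cross-field "possible error" rules** that exploit the clinical logic
   connecting otherwise cognitively isolated fields.
2. **An integrated record summary** (key fields, timeline, flagged errors)
   designed to be reviewed at the end of an entry session.
3. **Statistics** quantifying omission prevalence, the within-record
   clustering of omissions, and whether summary review is associated with
   more corrections.

## Missingness model

Every nullable field is a `FieldValue` in exactly one of three states:
`present`, `unknown`, `not_applicable`. The distinction is load-bearing:
registries that overload a single NULL for "cancer never relapsed" and
"relapse date could not be established" make omissions invisible. In the
CSV schema an empty cell is *unknown* and the literal token `NA!` is
*not applicable*; both survive serialization round-trips. Rule R5 and the
probe-field statistics treat only *unknown* as suspect.

The relapse-date field and relapse events encode one clinical fact. The
loader synchronizes them (materializing the missing side and noting it in
the load report) so that downstream rules can reason over either.

## Rules

All rules emit *possible* errors — advisory, never interruptive, because
each pattern has a legitimate benign explanation (e.g. a patient may elect a
more radical surgery without recurrence).

| Rule | Pattern | Key parameters (default) |
|------|---------|--------------------------|
| R1 | later surgery outranks an earlier one on the radicality table, no relapse documented in `(d1, d2]` | `min_gap_days` (30), radicality table |
| R2 | remission documented ∧ died-from-disease ∧ relapse date not present | — |
| R3 | treatment start ≥ `quiescence_days` after the latest prior episode end, no relapse in between | `quiescence_days` (180) |
| R4 | radiation course duration < `min_completion_fraction` × planned (strict) | `min_completion_fraction` (0.8) |
| R5 | configured key field is *unknown* (`not_applicable` never fires) | `key_fields` (gender, dob, cancer_site, xrt_start) |

Parameter defaults are design choices, not empirical constants: no
thresholds are published for these patterns, so we chose clinically
plausible values (a month between surgeries before "escalation" is
meaningful; six months of quiescence before new treatment demands an
explanation; completing less than 80% of a planned radiation course is an
abrupt stop) and made every one configurable. The default radicality order
(biopsy < lumpectomy < simple < modified radical < radical mastectomy) fits
breast surgery and is overridable per site; procedures absent from the table
are incomparable and skipped rather than guessed.

A relapse suppresses R1/R3 only when it falls strictly after the earlier
reference event and at or before the flagged one — a relapse predating the
first surgery does not explain a later escalation.

Rules dispatch through a registry keyed by rule id, so site-specific rules
can be registered and enabled from the config file without touching the
engine. Disabling a rule removes exactly its firings (verified by a
set-difference test). `apply_rules` is a pure function; output order is
(rule id, implicated event date).

## Timeline

Entries are all dated events plus the diagnosis date; same-date ties use a
fixed clinically plausible priority (diagnosis < surgery < xrt start <
chemo start < relapse < remission < xrt end < chemo end < follow-up <
death). Any fixed total order would do — the point is that every permutation
of the stored events renders the identical timeline (property-tested
exhaustively on 5-event records and by random shuffles). Inter-entry spans
strictly exceeding the gap threshold (default 365 days) are rendered as
explicit gap lines, which is how the escalated-surgery pattern becomes
visually obvious.

## Statistics

* **Exact binomial CIs** (`clopper_pearson_ci`): Clopper–Pearson via beta
  quantiles (statsmodels `proportion_confint(method="beta")`), returned in
  percent; bounds are exactly 0/100 at x=0/x=n. Cross-checked in tests
  against an independent bisection on the binomial tail sums.
* **Fisher's exact test** (`fisher_exact_2x2`): two-sided by the
  probability-mass method (scipy), i.e. summing hypergeometric
  probabilities ≤ the observed one, not doubling a one-sided p.
  Cross-checked against exhaustive enumeration on all 2×2 tables with
  margins ≤ 12. A zero margin returns p = 1.0 with a warning.
* **Multiplicity** (`hochberg_adjust`): Simes–Hochberg step-up adjusted
  p-values (statsmodels), cross-checked against a direct evaluation of the
  step-up formula on random vectors including ties.
* **Record categories**: records are split by an index field (radiation
  start date by default) into complete / missing-not-found / missing-found,
  where "found" means a manual review recovered the value, i.e. the
  emptiness was an omission error. The review map must cover exactly the
  missing-index records; anything else is a hard error rather than a silent
  assumption.
* **Co-occurrence** (`cooccurrence_analysis`): per category × probe field,
  missing count, raw percent and exact CI; Fisher p per probe field
  comparing the two missing-index categories, with the Hochberg-adjusted
  family alongside. Raw values are kept at full precision; display rounding
  (half-up, 1 decimal by default) is applied only at formatting time,
  because published tables are inconsistent in their rounding conventions.
* **Effectiveness** (`effectiveness_analysis`): from access/edit traces, a
  record is *accessed* (≥ 1 summary access) or not, and *corrected* when an
  edit took the target field from a missing state to a present value; edits
  overwriting present values are tracked separately as revisions and no-op
  edits are ignored. The correction-vs-access contingency is tested with
  Fisher; corrections are *window-attributed* when the earliest qualifying
  edit falls within `window_minutes` (default 10, the observed latency
  bound) after the latest preceding access.
* **Utilization** (`utilization_summary`): access-count histogram
  (0/1/2/3+), overall and new-vs-update access rates, and per-user rates
  over the records each user touched (a user must appear in at least one
  trace for a record to be attributed to them — data entry itself leaves
  edit traces, so generated cohorts satisfy this by construction).

## Synthetic cohort generator

No registry data are deposited anywhere, so the generator defines the test
conditions. Defaults are fixed at the observed study scale: 1,356 records
with 200 new; three users with access probabilities 0.846 / 0.471 / 0.118
and a 1.6× access boost for new records; probe-field omission base rates
8.0% / 6.6% / 8.85% (gender / DOB / cancer site); a truly-unrecorded
radiation start in 10.0% of records and an erroneously omitted one in 5.2%;
relapse prevalence 25% with a 5% relapse-date omission rate.

Omission clustering uses the simplest mechanism that reproduces the
empirical co-occurrence: a latent two-point carelessness state (fraction
0.15) multiplying *all* of a record's omission probabilities by 2.3. The
multiplier is the largest clean-vs-error prevalence ratio observed across
the three probe fields (20.3/8.85 for cancer site); a single multiplier
cannot match all three observed ratios (≈1.9, 1.55, 2.3) simultaneously,
and we prefer one interpretable knob over three fitted ones. Because the
same latent state inflates both the index-field omission and the probe
fields, error-category records show enriched probe missingness (odds ratio
> 1, verified over 100 seeds).

The event scaffold is diagnosis → surgery → radiation course (with planned
duration) → optional chemotherapy → optional relapse → salvage surgery →
death/censoring, with inter-event gaps drawn from fixed plausible ranges.
It makes no attempt to match real breast/sarcoma treatment distributions
beyond what the rules and analyses require.

Rule scenarios (`scenario_counts`) rewrite sampled records to satisfy a
rule predicate exactly and are re-verified against the rule before emission;
the ground-truth log records every injection, every category assignment and
every access/correction outcome, so recall and attribution can be scored
without circular reference to the engine under test. Edit latencies after an
access are lognormal (median 5 min, σ = 0.8), which yields both
within-window and out-of-window attributions at the 10-minute default.

For power checks at the published effect sizes, `generate_table1_cohort`
samples probe-field missingness directly at the published per-category
prevalences and sizes (226 / 118, clean rates vs elevated rates) rather
than through the latent-state mechanism. At these effect sizes the
*smallest* probe-field Fisher p detects the clustering in ≳ 90% of seeds;
the gender effect alone (8.0% vs 15.2% at n = 226/118) has only ≈ 50%
power, which is why the power criterion is defined on the field family
rather than a single probe field.

## Numerical and determinism choices

* Dates are day-granularity `datetime.date`; trace timestamps are naive
  datetimes at minute-to-second precision. No timezones.
* All generator randomness flows through one `numpy.random.default_rng`
  seed; iteration order is fixed, so cohort, trace and log files are
  byte-identical across runs and platforms for a given seed.
* Rendered summaries contain no wall-clock timestamps; CLI provenance
  headers carry only seed, config hash and package version, keeping every
  output reproducible byte-for-byte.
* Display rounding is half-up (`decimal`), never banker's rounding, because
  prevalence tables are conventionally printed that way.
* Degenerate inputs: empty cohorts render placeholder sections; empty
  categories emit n = 0 rows with undefined-CI markers; a zero-margin 2×2
  table yields p = 1.0 with a warning.

## Problem sizes used in the test suite

Unit and property tests run at n = 150–1,000 records; the serialization
round-trip uses 1,000 generated records; rate-recovery uses one n = 10,000
cohort; the power and clustering checks use 100 seeds at the published
category sizes (2,250 records) and n = 400 respectively. The full suite
completes in well under a minute on a single CPU.

## Known limitations

* The supplementary list of production rules used by the original tool is
  not public; R1–R5 cover every pattern described in the main text, and the
  registry/dispatch design exists precisely so sites can add the rest.
* Hierarchical (multilevel, repeated-effects) logistic regressions of
  access/correction predictors are out of scope: they require the
  patient-level data, which were never deposited.
* The generator's behavioural model (independent per-record access and
  correction draws) ignores session-level correlation within users and
  learning effects over time; passing effectiveness tests show the
  analysis machinery is correct, not that real users behave this way.
* Any-of-probe-fields missingness rates depend on record-level co-occurrence
  structure that published marginals do not determine; they are reported for
  generated cohorts but cannot be validated against the published table.
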
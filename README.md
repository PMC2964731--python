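# registryqc

Data-quality toolkit for longitudinal clinical-research registries:
cross-field **"possible error" rules**, an integrated **record summary**
(key fields · timeline · flagged errors), and the **omission statistics**
needed to quantify how often data are omitted, how omissions cluster within
records, and whether reviewing a record summary is associated with more
corrections.

It is aimed at people who run retrospective treatment registries — the
breast/sarcoma radiation-oncology kind, where technicians abstract charts
into records with dozens of fields across many entry forms — and at
methodologists studying omitted-data errors. Omissions matter because they
are more common than wrongly inserted values and are not missing-at-random:
an omitted relapse date reads as "never relapsed".

## What it computes

* **Rules.** Five built-in cross-field checks, all advisory (a firing is a
  *possible* error, never a blocking alert): escalated surgery without a
  documented relapse in between (R1); documented remission + death from
  disease but no relapse date (R2); treatment resuming after a long quiet
  interval with no relapse recorded (R3); a radiation course stopped well
  short of its planned duration, suggesting unrecorded toxicity (R4); key
  fields left unknown (R5). Thresholds, key-field lists and the surgical
  radicality order are configurable (YAML/JSON), and new rules register into
  the same dispatch without engine changes.
* **Missingness with three values.** Every nullable field is `present`,
  `unknown` or `not_applicable` — de-overloading the registry NULL so that
  "cancer never relapsed" and "relapse date not established" stop being the
  same empty cell.
* **Statistics.** Record categorization by a missing index field and manual
  review (complete / missing-not-found / missing-found-on-review), per-field
  omission prevalence with exact Clopper–Pearson intervals
  (x/n at level α, bounds from beta quantiles), two-sided Fisher exact
  tests by the probability-mass method, Simes–Hochberg multiplicity
  adjustment, access/edit-trace effectiveness analysis with a configurable
  attribution window, and utilization summaries.
* **Synthetic cohorts.** A seeded generator produces registry-shaped
  records, user traces, and a ground-truth log of every injected omission,
  so the whole pipeline is testable without patient data.

## Worked example

```bash
registryqc simulate --seed 42 --n-records 200 --out sim
registryqc audit --cohort sim/cohort.csv --out audit
registryqc summarize --cohort sim/cohort.csv --record-id S00015 --out S00015.txt
```

The audit log reports `scanned 200 records, flagged 101 possible errors`,
and the summary for one flagged record prints:

```
== Key Fields ==
record_id       S00015
gender          F
dob             1974-02-14
cancer_site     breast
diagnosis_date  2005-07-16
tumor_grade     1
t_stage         T4
vital_status    alive
relapse_date    UNKNOWN

== Timeline ==
2005-07-16  diagnosis
2005-08-17  surgery: lumpectomy
2005-09-17  xrt start (planned 44 d)
2005-10-31  xrt end
──────────── gap: 556 days ────────────
2007-05-10  surgery: modified_radical_mastectomy
2008-01-23  follow up

== Possible Errors ==
[R1] modified_radical_mastectomy on 2007-05-10 escalates lumpectomy of
     2005-08-17 with no documented relapse in between; relapse date may be omitted
[R3] surgery on 2007-05-10 begins 556 days after the last treatment ended,
     with no relapse documented in between
```

Read it as: this patient had breast-conserving surgery and radiation, then
— after 556 quiet days — a modified radical mastectomy, with the relapse
date field still `UNKNOWN`. Salvage surgery without a recurrence on file is
exactly the kind of cross-form contradiction a data-entry technician cannot
see from any single screen; the gap line and the two rule firings make the
probable omission obvious.

`registryqc cooccurrence` and `registryqc effectiveness` produce the
statistical reports (prevalence table with exact CIs and Fisher p-values;
accessed-vs-not correction contingency with window attribution); see
`docs/methods.md` for the models and parameter choices.

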
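# Methods

## The phenotyping model

The package treats a patient's record as a set of dated encounters and
reduces it to five visit-level feature counts:

| feature | meaning | base-rule threshold |
| ------- | ------- | ------------------- |
| dx  | encounters with ≥ 1 asthma diagnosis code (ICD-9-CM `493.*`, ICD-10-CM `J45.*`) | ≥ 1 |
| bdr | encounters with ≥ 1 inhaled bronchodilator order | ≥ 2 |
| ics | encounters with ≥ 1 inhaled corticosteroid order | ≥ 1 |
| kw1 | encounters whose notes mention an asthma-specific keyword | ≥ 1 |
| kw2 | encounters whose notes mention a nonspecific respiratory keyword | ≥ 2 |

Each encounter contributes at most one event per category (visit
deduplication), so a rule threshold like `dx>=2` demands two *visits* with
asthma codes, not two codes. A single encounter may contribute to several
different categories at once — base-rule combinations explicitly describe
co-occurrence of diagnosis, medication and keyword evidence, which often
share visits.

Phenotype rules are monotone boolean combinations of threshold atoms over
these counts, with AND binding tighter than OR. The built-in COMPAC rule is
`(dx>=2 | dx>=1 & (bdr>=2 | ics>=1)) & kw1>=1`; it is logically identical
to the conjunction-first form `dx>=1 & (dx>=2 | ib>=2 | ics>=1) & kw1>=1`
in which it is also quoted (`ib` is an accepted alias for `bdr`), and the
test suite verifies that identity exhaustively.

### Age window

The pediatric window is ages [2, 18) years, the lower bound avoiding
confounding with viral-induced wheezing (bronchiolitis) in infancy. Events
at ages [1, 2) are retained only when the patient also has at least one
event of *any* category at [2, 18) — evidence in toddlerhood counts only
for children whose record continues into the unambiguous range. Ages are
exact day counts divided by 365.25; all bounds are half-open. The carryover
unlock is deliberately category-agnostic.

Age-subgroup analyses (bins [2, 6), [6, 13), [13, 18), labeled 2–5 / 6–12 /
13–18) key patients by the age at their first phenotype-related event.
The within-group mode re-applies the rule to counts rebuilt from events
inside the bin only; the carryover rule is not re-applied there — the
restriction is literal.

### Keyword matching

Note keywords are matched as case-insensitive, word-boundary-anchored
phrases (internal whitespace matches any run of whitespace). There is no
negation or context handling: "denies wheezing" counts as a mention. This
is intentional — the phenotype treats keyword features as weak, noisy
signals whose low stand-alone precision is handled at the rule level (kw1
is only ever used conjunctively in COMPAC), not by NLP machinery. Slash-
and parenthetical variants of published phrases are expanded one pattern
per variant (e.g. "reactive airway disease" and "RAD").

Medication classification is word-bounded substring matching of
generic/brand terms against free-text order strings; there is no RxNorm
normalization. Nasal fluticasone ("FLONASE") does not match the inhaled
corticosteroid lexicon, whose term is "fluticasone propionate". If a string
somehow matches both categories, ICS wins with a warning; the packaged
lexicons share no terms, so this arises only on degenerate input.

## Evaluation

Chart-review labels arrive per reviewer. A consensus label is the
reviewers' unanimous label, or an explicit `adjudicated` row; patients with
unresolved disagreement are excluded from evaluation and tallied. The
confirmation rate of a stratum is the percentage of reviewed patients in
it confirmed as asthma — an empirical within-stratum PPV — rounded half-up
to one decimal.

The bootstrap is stratified 20+20: per iteration, 20 labeled patients are
drawn with replacement from the phenotype-identified stratum and 20 from
the remaining labeled patients; sensitivity, PPV, specificity and F1 are
computed on that 40-patient sample; means and percentile (2.5/97.5) 95%
intervals summarize 10,000 iterations. Design choices where the procedure
is underdetermined:

- the "remaining pool" is the *reviewed* patients not identified by the
  rule, not the unreviewed cohort;
- F1 is the mean of per-iteration F1, not the harmonic mean of mean
  sensitivity and mean PPV (per-iteration computation is what makes
  published F1 means not recoverable from the printed sensitivity/PPV);
- iterations where a metric is 0/0 are dropped from that metric's mean and
  CI, with the dropped count recorded;
- the CI is the plain percentile bootstrap — no bias correction;
- metrics are displayed to 3 decimals and percentages to 1, rounded
  half-up.

A structural consequence of the 20+20 scheme, asserted in tests: the PPV
distribution depends only on the identified stratum's label composition.

Base-rule pattern strata come in two readings: **identified** (unlisted
features must be *absent*, i.e. below their base-rule threshold — one
bronchodilator visit still counts as absent because the bdr base rule is
≥ 2) and **covered** (unlisted features are ignored). Identified is a
subset of covered by construction.

## Review sampling

Chart-review selection proceeds: (1) a uniform 500-patient initial draw;
(2) for each candidate rule with fewer than 10 selected patients, a top-up
of `max(deficit, ceil(stratum × 500/cohort))` uniform draws from its
identified stratum; (3) pattern groups qualify when identified/covered
≥ 0.10, and qualifying groups are topped up to 18 reviewed members, rounds
repeating to a fixed point (guarded at 10 rounds). The 10% criterion is
read as an absolute ratio floor — the reading consistent with its stated
purpose of not missing relevant cases — rather than a difference between
two proportions, and top-ups draw from identified (absence-enforced)
strata by default.

## Synthetic cohorts and the oracle

The generator plants ground truth: per patient an asthma status
~ Bernoulli(prevalence), Poisson-many encounters (mean 6), encounter ages
uniform in days over [1, 18) years so the carryover path is exercised, and
per encounter five independent status-conditional Bernoulli emissions that
materialize as an asthma code, a bronchodilator or corticosteroid order
string, or a keyword phrase embedded among neutral filler sentences in a
note. Background noise — non-asthma codes, unrelated prescriptions,
keyword-free notes — is invisible to the extraction lexicons, and the
keyword sample phrases are chosen so that no kw1 phrase contains a kw2
phrase (or vice versa), keeping the emission categories independent in the
extracted counts, as the oracle assumes.

Default conditions: 2,000 patients, prevalence 0.30, case emission
probabilities (dx 0.30, bdr 0.10, ics 0.10, kw1 0.35, kw2 0.25) against
control probabilities (0.01, 0.01, 0.015, 0.04, 0.10). These produce the
qualitative confirmation-rate gradient seen in chart review — keyword-only
strata mostly non-asthma, repeat-diagnosis strata overwhelmingly asthma —
and are illustrative conditions, not values fitted to any dataset. The
demographic mix (52.6% male; NHW 0.485 / NHB 0.308 / Hispanic 0.099 /
Other 0.038 / Unknown 0.07) mirrors a large pediatric potential-asthma
population. Labels are written by two perfectly agreeing reviewers by
default; a configurable disagreement rate flips the second reviewer.

`expected_rule_performance` is the independent oracle. With a fixed
encounter count and ages entirely within [2, 18), P(rule | status) is exact:
category counts are independent Binomial(n, p) variables, enumerated on a
grid capped one past each rule threshold (the cap bin absorbing the upper
tail, with `=k` atoms forcing the cap past k). Otherwise it Monte-Carlo
simulates ≥ 10⁵ count vectors per status, reproducing the Poisson encounter
counts, day-quantized ages and carryover logic directly — without ever
building cohort tables or running feature extraction. Tests and the
acceptance script require the full pipeline (generate → extract → apply)
to agree with the oracle within three binomial standard errors at
n = 2,000.

What passing on synthetic data does *not* show: real notes are not bags of
independent keyword emissions (negation, family history, note-type
idiosyncrasies), real encounter ages cluster, medication strings vary
beyond the packaged templates, and chart reviewers are not oracle labelers.
Synthetic results validate the machinery, not the clinical operating
characteristics of any rule.

## Numerical and interface choices

- File dialect: CSV, UTF-8, header row, ISO-8601 dates; writers sort by
  primary key so output is byte-stable. Race/ethnicity arrives pre-mapped
  to the four analysis categories plus Unknown; mapping from raw source
  fields is the caller's job.
- The rule parser is a hand-written recursive-descent tokenizer/parser
  (five token kinds); it accepts the unicode `∣`/`≥` spellings on input
  and reports character positions in errors. The canonical printer emits
  ASCII and round-trips through the parser.
- Rule enumeration generates disjunctive normal forms (ORs of up to
  `max_terms` AND-clauses over an atom pool) and deduplicates by truth
  table over the pool's reachable count grid — per feature: 0, each
  threshold t, and t+1 — which is sufficient for logical equivalence. The
  published rule set is shipped as a named list rather than regenerated,
  since the original combination process included human-driven adjustments
  that are not an algorithm.
- The adapted external phenotypes: the CAPriCORN-style rule is
  `dx>=2 | dx>=1 & (bdr>=1 | ics>=1)` ("prescription" read as
  bronchodilator-or-corticosteroid, configurable); the PheKB-style rule is
  a mention rule — ≥ 3 distinct in-window encounters with an asthma code
  or a note mention of "wheezing"/"asthma" — with coded diagnoses counting
  as mentions by default (configurable, since the adaptation leaves this
  open).
- Subgroup bootstraps derive per-subgroup seeds deterministically from the
  master seed, so adding or removing a subgroup does not shift the others'
  draws.
- Problem sizes in tests and the acceptance script (400–2,000 patients,
  10⁵ oracle replicates, 10⁴ bootstrap iterations) keep every check
  sub-minute while leaving Monte-Carlo error well below the asserted
  tolerances.

## Known limitations

- No NLP beyond word-bounded phrase matching; no negation, section or
  note-type awareness (an optional `note_type` inclusion-regex filter is
  provided for extracts that carry a type column).
- No RxNorm/SNOMED normalization; medication matching is lexical.
- The keyword lexicons implement exactly the published phrase lists, which
  are explicitly examples ("e.g."); sites should extend the lexicon file.
- Chart-review adjudication cannot be reproduced: disagreements without an
  adjudicated row are excluded rather than resolved.
- The machine-learning and unavailable-source external phenotypes are out
  of scope; only the two rule-based adaptations are provided.
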
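# Methods

## Phenotyping model

The detector is a deterministic rule pipeline over clinical notes:

1. **Sectioning.** An ordered list of case-insensitive regexes locates the
   Assessment & Plan (A&P) header; the *last* occurrence of the first
   matching pattern anchors the section, since the A&P conventionally closes
   a note and earlier matches tend to be template echoes. The section ends
   at the next header from a broader section-header inventory, or at the end
   of the note. Notes with no recognizable header are scanned whole
   (`whole_note_fallback`) rather than dropped — a sensitivity-first choice,
   since dropping header-less notes would silently remove patients whose
   notes use non-standard formatting. Both pattern lists are plain-text
   config; the shipped defaults ("assessment and plan", "a&p",
   "impression:", …) are a reasonable clinical inventory but make no claim
   to completeness for any particular EHR.
2. **Sentence splitting.** Sentence-final punctuation plus list-item
   boundaries (newline before a bullet or numbering marker), with an
   abbreviation stop-list ("Dr.", "vs.", dosing shorthand). Sentences are
   the unit of negation scoping; offsets are preserved so every sentence and
   section slices exactly out of the original note text.
3. **Mention finding.** Word-boundary regex lexicon, matched per sentence,
   leftmost-longest and non-overlapping, so "nonalcoholic steatohepatitis"
   beats its embedded "steatohepatitis". The acronym entries `NASH`/`MASH`
   are case-sensitive to avoid the English words "gnash"/"mash"; the phrase
   entries are case-insensitive.
4. **Assertion.** NegEx-style: pre-triggers ("no evidence of", "rule out",
   "denies", …) and post-triggers ("is ruled out", "unlikely") negate a
   mention within a scope window of 6 content tokens (whitespace-delimited,
   punctuation-only tokens not counted) unless a terminator ("but",
   "however", ";") intervenes. Six tokens is the conventional NegEx window;
   it trades a small risk of over-negation in long enumerations against
   missing distant triggers. Hedged mentions ("possible NASH") count as
   affirmed: the model distinguishes presence/absence only, and in
   specialist A&P text a hedged diagnosis is usually being actively managed.
5. **Labels.** A note is positive iff ≥ 1 affirmed mention; a patient is a
   case iff ≥ 1 positive note, with the earliest positive note (ties broken
   by note id, which cannot change the date) anchoring the index.

## Cohort construction

- **Index date** = earliest positive note date + `offset_days` (default 90).
  The offset absorbs the lag between a diagnosis being made and its being
  recorded/recognized in notes.
- **Exclusions**, checked in a fixed priority order with exactly one reason
  recorded per excluded patient: death before index; diagnosis after a liver
  transplant (transplant before the index *note*); transplant before the
  index date; missing age or sex; age < 18 at index. The post-transplant
  rule is checked before the generic pre-index transplant rule because it is
  a strict subset of it — in the reverse order it could never fire, and
  patients diagnosed in a graft are a clinically distinct group worth
  counting separately.
- **Subcohorts.** Baseline cirrhosis = any matching ICD code dated ≤ index
  (boundary inclusive: a code entered the day the clock starts is baseline
  knowledge); likewise a decompensation flag from a second code list. Code
  lists are plain text with trailing-`*` prefix wildcards.
- **Covariates.** Whole-year age at index (floor; an age-at-first-note
  supplied instead of a birth date is carried unadjusted). BMI categories use
  18.5/25/30 cut-points, or 18.5/23/27.5 for patients flagged Asian. MELD
  3.0 uses the published coefficients and clamps (bilirubin/INR/creatinine
  floored at 1.0, creatinine capped at 3.0, sodium in [125, 137], albumin in
  [1.5, 3.5]); any missing input yields a missing score — imputation is
  deliberately out of scope.
- **Time to event.** One row per at-risk patient per outcome: mortality on
  the full cohort, incident cirrhosis (first post-index cirrhosis code) on
  the no-cirrhosis subcohort, transplant (first post-index CPT 47135) on the
  cirrhosis subcohort. Patients whose outcome is recorded on or before the
  index date are dropped from that outcome's risk set. Death always competes
  with the non-fatal outcomes; transplant additionally competes with
  incident cirrhosis.
- **Competing-event guard window.** When a competing event precedes the
  outcome of interest, the patient is censored at the competing event —
  unless the outcome is recorded within `guard_days` (default 90) after it,
  in which case the outcome still counts as an event. The guard reflects the
  same delayed-recording problem the index offset does: a transplant coded
  three weeks after a death record almost certainly happened before it.
  `guard_days=0` recovers strict censor-at-first-competing-event semantics;
  the choice between the two readings is exposed, not hard-coded.
- **Incidence** = 100 × events / person-years, person-years = Σ time_days /
  365.25. Applied to the package's own tables this identity is exact by
  construction, which the tests assert.

## Validation protocol

`sample_split` draws the review sample (default 300 notes → 150 dev / 150
test) uniformly without replacement, seeded. `adjudicate` resolves
dual-reviewer disagreements by a third review and refuses to proceed when
one is missing. `evaluate` computes the standard 2×2 metrics (positive =
MASH); undefined metrics (zero denominator) are reported as absent, never
as 0. Printed-percentage matching uses half-up rounding computed in exact
integer arithmetic.

`consistent_matrices(n, sens%, spec%, acc%)` exhaustively enumerates every
integer 2×2 matrix of size `n` whose three metrics round to the given
percents — the honest way to reason about published rounded metrics when
the underlying table is not available. Note that the three percents do not
in general determine F1: at n=150 with 89/84/86% the feasible F1 values
span 0.80–0.86, so a published F1 adds real information and should be
checked for *attainability* within the feasible set, not for uniqueness.

## Synthetic data

The generator's role is ground truth, not realism. Notes are built from a
small template family — an A&P containing an affirmed MASH term, a term
under a negation trigger, or no term; a configurable fraction of notes have
no headers at all — and the templates restrict themselves to constructions
the rule model covers (single-sentence negation, in-window triggers). On
such template-conforming notes the detector's agreement with the planted
labels is exact, and the tests require 100%. That establishes that the
pipeline implements its own rules faithfully; it says nothing about recall
on real clinical prose, which contains cross-sentence negation, hedging,
copy-forward text, and misspellings the rule model does not handle. A small
`ADVERSARIAL_TEMPLATES` set collects known failure constructions for
failure-mode tests and is excluded from any agreement guarantee.

Registry event times are exponential (memoryless) at configured hazards
measured from the index date — the simplest model that makes incidence-rate
recovery checkable, not a claim about MASH biology. Defaults are the study
conditions of a large tertiary-centre MASH cohort: death 0.044, incident
cirrhosis 0.045, transplant 0.031 events/person-year; 55.4% baseline
cirrhosis (61.4% of those decompensated); notes spanning 2012-01-01 to
2022-12-31 with follow-up through 2023-12-31; 15.8% Asian; 14.5% missing
BMI. Labs are drawn from unimodal distributions centred on typical
hepatology-clinic values and are sufficient to compute MELD 3.0. Quota mode
plants exact numbers of exclusion conditions (split evenly across death
before index / transplant before index / missing age-or-sex when given as a
total) and exact baseline-cirrhosis counts; cirrhosis carriers are drawn
from patients without a planted exclusion so that quota arithmetic composes
deterministically. All randomness flows from the single config seed.

## Numerical and testing choices

- Dates are `datetime.date` throughout; ISO-8601 in all file formats; no
  time zones. Offsets are 0-based half-open everywhere, and round-trip
  invariants (`text[start:end] == stored text`) are property-tested.
- Person-year conversion fixes 365.25 days/year.
- Rate-recovery testing: the rate estimator D/T applied to the generator's
  output was checked for bias (mean z ≈ 0 across 20 seeds). The shipped
  test pools three independent 5000-patient replicates and requires the
  pooled estimate within 3 SE of the generating hazard — a replicate design
  chosen so the verdict reflects the estimator rather than a single seed's
  sampling luck (any single-seed 3-SE check fails ~0.3% of seeds by
  construction).
- Problem sizes in the test suite (corpora of a few hundred to a thousand
  notes, registries of 2.8k–15k patients) were chosen to keep the full
  suite within a few minutes on one CPU while leaving Monte-Carlo standard
  errors small enough for the 3-SE checks to be meaningful.

## Known limitations

- The rule model has no concept of historical, hypothetical, family-history
  or uncertain assertions; all are affirmed unless a negation trigger fires.
- Cross-sentence negation scopes are not modelled.
- The shipped lexicon, header inventory, and ICD code lists are editable
  defaults, not validated site-specific artifacts.
- No hazard modelling, imputation, or comorbidity indices: the package
  stops at the time-to-event tables and crude incidence, which downstream
  survival packages (lifelines, R `survival`/`cmprsk`) consume directly.
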
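# Methods

## Detection model

The screen is a deterministic rule system over narrative notes; there is no
statistical model and no training step, which is what makes every verdict
auditable down to character offsets.

**Normalization.** Matching operates on casefolded text (Python
`str.casefold`: locale-independent, umlauts preserved, `ß → ss`) with
whitespace runs collapsed to single spaces. An offset map projects normalized
spans back to the raw note for display. Normalization is total and
idempotent.

**Matching.** Every inclusion and admission-context term is located as a
plain substring at every position, overlapping and nested occurrences
included. Substring (not word-boundary) semantics are deliberate: German
compounds (`Sturzereignis`, `Bodenbett`) would be invisible to a
word-boundary matcher, and compound collisions are precisely the hard part of
this screening problem. The flip side is handled by *exclusion compounds*:
an inclusion match whose span lies wholly inside an occurrence of a listed
compound is reported `suppressed` with the compound as reason, never silently
dropped. Matches are ordered by start position, longer term first; ordering
never affects suppression. Inflection is covered by explicit variant lists
rather than stemming, so a lexicon's behaviour is enumerable by reading its
config file. Validation flags (as warnings, not errors) exclusion compounds
that contain no inclusion term, since they can never suppress anything.

The default lexicon contains only the seed terms listed in
`fallscreen.lexicon.DEFAULT_CONFIG`; a production deployment is expected to
extend it from its own error analysis. `boden` is included as a standalone
term alongside `am Boden`: the floor-term is the classic source of both true
hits ("found on the floor") and the `Bodenbett` decoy, and without it the
default exclusion compound would have nothing to suppress.

**Stay aggregation.** The unit of classification is the hospital stay
(eligibility: age ≥ 18 years, length of stay ≥ 24 h). All note types and
author roles are scanned identically — falls are not always charted by both
professions, so nurse and physician notes are equally authoritative. The ANY
rule applies: one unsuppressed, non-POA match anywhere makes the stay
positive. Event counting (several falls in one stay) is out of scope. Stays
with zero notes classify `no_fall` with a warning rather than erroring,
because real extracts contain them. Notes timestamped up to 1 day outside
the stay window are tolerated (transcription lag); beyond that the corpus
loader refuses the record.

## Present-on-admission filter

A fall mention is classified pre-admission when (a) an admission-context term
co-occurs within the configured window, (b) the note type records
pre-admission history (admission anamnesis by default), or (c) the note was
written within `admission_period` (default 24 h) of admission and contains an
admission-context term. The co-occurrence window defaults to **same-note**,
the weakest assumption: nothing in the problem constrains how close the
context word must be to the fall term, and a too-narrow window would convert
pre-admission falls into false positives. `same-sentence` (boundary
characters `.!?` on normalized text, so abbreviation periods over-segment —
acceptable for a stricter opt-in mode) is available for tuning. Widening
`admission_period` is monotone: it can only move verdicts toward POA.

The filter intentionally under-suppresses. In this workflow a flagged stay
costs ~10 minutes of confirmation review, while a wrongly suppressed
in-hospital fall is silently lost; accepting a PPV around 50% for a
sensitivity near 100% is the design point, and precision tuning is a
lexicon/config exercise.

## Evaluation

Metrics are computed as exact `Fraction`s; the display form is the integer
percent with **half-up** rounding (90.8 → 91, 63.6 → 64, 99.5 → 100). A zero
denominator yields "not available" (`None`), never 0. Wilson 95% score
intervals (via statsmodels) are attachable with `ci=True` and off by default
so that printed percents equal plain fraction arithmetic.

No single fall-detection method is a true gold standard, so the reference is
a **pseudo gold standard**: logical OR across all supplied methods, followed
by explicit per-stay adjudication overrides (an auditable CSV standing in for
the human discussion of discordant cases, which are listed by
`pseudo_gold`). With a single method the OR degenerates to that method's
labels; adding methods never decreases the pre-override positive count.

Cohen's κ uses the standard two-rater form κ = (p_o − p_e)/(1 − p_e) with
exact rational arithmetic internally; the degenerate case p_e = 1 with
perfect agreement returns 1. Fall rates are 1000 · falls/patient-days,
displayed to 2 decimals. Review effort models a screen-then-confirm
workflow: full review costs `n_records × minutes_per_record`; the screen
reduces this to the flagged records only, so the percent reduction is
1 − n_flagged/n_records regardless of the per-record time.

The error-analysis report lists every false-positive and false-negative stay
with each matched term in ±60 characters of raw-note context, its
suppression state and POA assessment, and a diagnostic tag (candidate-POA /
term-list gap / over-broad exclusion / over-aggressive POA rule). This is
the feedback loop through which a deployment grows its lexicon.

## Synthetic corpora

`synthdata.generate_corpus` emulates a mixed internal-medicine/orthopaedics
inpatient sample. Defaults, chosen once as the package's study conditions:
300 stays; 5% planted in-hospital falls, 5% pre-admission falls, 20% decoy
probability among negatives; age ~ Normal(65.3, 18²) truncated to [18, 103];
length of stay lognormal with mean 11.5 d / SD 12.6 d for non-fall stays and
mean 22.6 d / SD 19.0 d for fall stays (falls and long stays are associated,
and the generator encodes that directly); 51% female; ten diagnosis
categories drawn uniformly. All draws flow from a single
`numpy.random.default_rng(seed)`, so corpora are byte-reproducible.

Notes are template-built: admission anamnesis, 3–10 progress notes with
filler ward vocabulary, discharge summary. In-hospital fall stays receive a
fall note written with default-lexicon terms on a day ≥ 2; POA stays receive
an admission anamnesis combining a fall term with emergency-context wording
("Sturz zu Hause, notfallmässig eingeliefert"); negative stays may receive a
`Bodenbett` decoy. Filler text contains no lexicon term, so planted truth is
exactly recoverable — the generator reproduces the *structure* of the
detection problem (compound decoys, pre-admission mentions, both author
roles), not the variability of real clinical German. Consequently, perfect
recovery on synthetic corpora demonstrates the correctness of the machinery,
**not** expected field performance: real notes contain unlisted variants,
typos, negations ("kein Sturz" — not modelled) and novel compounds. The
`adversarial=True` mode plants fall terms inside unlisted compounds
(`Sturzprophylaxe`, `Sturzrisikoassessment`) to demonstrate exactly this
suppression gap.

## Numerical and interface choices

- Offsets are 0-based half-open on normalized text; projection to raw text is
  exact except across multi-character folds (`ß`), where the raw span covers
  the originating character.
- Overlapping matches are all reported; containment inside an *inclusion*
  match does not suppress (only exclusion compounds do).
- CSV is comma-separated UTF-8 with a header row and ISO-8601 timestamps;
  notes are JSONL. Corpus loading collects per-line schema failures into a
  rejects report (line numbers, reasons) and raises only on structural
  corruption (unknown stay references, duplicate ids, out-of-window
  timestamps).
- Problem sizes in tests and the acceptance script (corpora of 25–400 stays,
  1000-string matcher oracle, 500 random κ tables) were chosen as desk-scale
  defaults that exercise every code path in seconds.

## Known limitations

- No negation or hedging detection; "kein Sturz" counts as a fall mention.
- No fuzzy matching; misspellings escape the screen.
- No temporal-expression resolution ("gestern gestürzt" in a day-10 note is
  treated as an in-hospital event).
- Fall sub-categories (assisted / unassisted / syncope-related) are detected
  but not distinguished.
- The POA filter's same-sentence mode over-segments on abbreviation periods.
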
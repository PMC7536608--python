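# fallscreen

Rule-based screening of German-language hospital notes for **in-hospital
falls**, with a present-on-admission filter and a diagnostic-accuracy
evaluation toolkit.

## The problem

Falls are among the most common adverse events in hospitals, but the usual
detection methods all have problems: voluntary incident reports underreport,
full manual chart review costs ~10 minutes per record, and single-day
patient-report surveys miss most events. Because fall events are reliably
*documented* in nurses' and physicians' narrative progress notes, a simple
keyword screen over the electronic health record can flag candidate stays in
seconds with near-perfect sensitivity, leaving only the flagged minority for
manual confirmation.

`fallscreen` is aimed at patient-safety researchers and clinical quality
teams who want such a screen that is fully auditable: every verdict carries
the matched terms, their positions, and the rule that kept or discarded them.

## The method

For each hospital stay with notes, the screen:

1. **normalizes** text (locale-independent casefold, `ß → ss`, whitespace
   collapse) and matches a configurable lexicon of fall terms (`am Boden`,
   `ausgerutscht`, `Sturz`/`Stürze`, `Synkope`/`synkopiert`, …) as
   **substrings** — German compounding (`Sturzereignis`) makes word-boundary
   matching unsafe;
2. **suppresses** any match lying inside a listed decoy compound such as
   `Bodenbett` (a floor-level bed — a fall-*prevention* device containing
   `Boden`);
3. applies a **present-on-admission (POA) filter**: a fall mention
   co-occurring with admission-context wording (`Notfall`, `Ambulanz`,
   `zu Hause`, `eingeliefert`), or documented in the admission anamnesis,
   or written within 24 h of admission alongside such wording, counts as a
   pre-admission fall;
4. aggregates per stay: any surviving match ⇒ `in_hospital_fall`; only
   POA-classified matches ⇒ `present_on_admission_only`; otherwise `no_fall`.

Evaluation against per-stay reference labels uses the standard 2×2 metrics
(Se = TP/(TP+FN), Sp = TN/(TN+FP), PPV, NPV, integer percents with half-up
rounding, optional Wilson 95% CIs), a **pseudo gold standard** (logical OR of
all available methods plus explicit adjudication overrides), Cohen's κ, fall
rates per 1000 patient-days, and a review-effort model
(reduction = 1 − n_flagged/n_records).

Because no patient data can ship with the package, `fallscreen.synthdata`
generates German note corpora with planted ground truth (fall notes, POA
admission texts, decoy compounds, realistic demographics) so the entire
pipeline is testable end to end.

## Worked example

```bash
$ fallscreen synth --n 300 --seed 7 --out-dir .
wrote 300 stays to ./ (notes.jsonl, stays.csv, truth.csv)

$ fallscreen detect --notes notes.jsonl --stays stays.csv --out verdicts.csv
300 stays screened (0 excluded): 17 flagged in-hospital, 9 present-on-admission only -> verdicts.csv

$ fallscreen evaluate --pred verdicts.csv --gold truth.csv --out metrics.csv
algorithm: tp=17 fp=0 tn=283 fn=0 sens=100% spec=100% ppv=100% npv=100%
metrics -> metrics.csv
```

Of 300 synthetic stays, the screen flagged all 17 planted in-hospital falls
(sensitivity 100%), routed all 9 planted pre-admission falls to the
`present_on_admission_only` verdict rather than flagging them, and raised no
false positives on decoy-bearing negatives — the planted truth is exactly
recoverable because the generator writes fall events with lexicon terms. On
real notes the interesting failure modes return (unlisted term variants,
novel compounds); the `fallscreen report` subcommand produces the
discordance report (matched snippets in context, suppression/POA states)
used to refine the lexicon iteratively, and `synth`'s adversarial mode
plants unlisted compounds to probe exactly those gaps.

The same evaluation machinery reproduces published-style comparisons of
detection methods: feeding any 2×2 confusion matrix to
`fallscreen.evaluation.accuracy_metrics` yields the exact fractions and the
integer percents, e.g. `ConfusionMatrix(tp=15, fp=17, tn=266, fn=0)` →
sensitivity 100%, specificity 94%, PPV 47%, NPV 100%.

## Layout

| module | contents |
|---|---|
| `fallscreen.lexicon` | lexicon config, normalization, substring matching with compound suppression |
| `fallscreen.detection` | stay/note data model, eligibility (≥18 y, ≥24 h), stay-level classification |
| `fallscreen.admission_filter` | present-on-admission rules |
| `fallscreen.evaluation` | 2×2 metrics, pseudo gold standard, κ, fall rates, review effort, error analysis |
| `fallscreen.synthdata` | synthetic German note corpora with planted truth |
| `fallscreen.corpus_io`, `fallscreen.cli` | JSONL/CSV readers & writers, `fallscreen` command |

See `docs/methods.md` for the modelling assumptions and design choices.
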
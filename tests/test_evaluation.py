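"""Diagnostic-accuracy statistics, pseudo gold composition, κ, rates, effort."""

import random
from fractions import Fraction

import pytest

from conftest import make_note, make_stay
from fallscreen.detection import run_corpus
from fallscreen.evaluation import (
    ConfusionMatrix,
    MethodLabels,
    accuracy_metrics,
    cohen_kappa,
    confusion,
    error_analysis,
    fall_rate,
    percent_half_up,
    pseudo_gold,
    review_effort,
)


class TestPseudoGold:
    METHODS = [
        MethodLabels("chart_review", {"a": 1, "b": 0, "c": 0}),
        MethodLabels("incident_report", {"a": 0, "b": 0, "c": 0}),
        MethodLabels("algorithm", {"a": 0, "b": 1, "c": 0}),
    ]

    def test_or_composition(self):
        gold, discordant = pseudo_gold(self.METHODS)
        assert gold == {"a": 1, "b": 1, "c": 0}
        assert discordant == ["a", "b"]

    def test_override_adjudicates_down(self):
        gold, _ = pseudo_gold(self.METHODS, overrides={"a": 0})
        assert gold["a"] == 0

    def test_adding_a_method_never_decreases_positives(self):
        gold2, _ = pseudo_gold(self.METHODS[:2])
        gold3, _ = pseudo_gold(self.METHODS)
        assert all(gold3[s] >= gold2[s] for s in gold2)

    def test_unknown_override_stay_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            pseudo_gold(self.METHODS, overrides={"zz": 1})

    def test_single_method_rejected(self):
        with pytest.raises(ValueError, match="two methods"):
            pseudo_gold(self.METHODS[:1])

    def test_mismatched_stay_sets_rejected(self):
        with pytest.raises(ValueError, match="same stay set"):
            pseudo_gold([self.METHODS[0],
                         MethodLabels("other", {"a": 1, "zz": 0, "c": 0})])


class TestConfusion:
    def test_identity_case(self):
        labels = {f"s{i}": int(i < 3) for i in range(10)}
        cm = confusion(labels, labels)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (3, 0, 7, 0)
        assert cm.total == 10

    def test_all_negative_prediction(self):
        gold = {"a": 1, "b": 1, "c": 0}
        cm = confusion({k: 0 for k in gold}, gold)
        assert (cm.tp, cm.fn) == (0, 2)

    def test_sequences_accepted(self):
        cm = confusion([1, 0, 1, 0], [1, 1, 0, 0])
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (1, 1, 1, 1)

    def test_misaligned_sets_rejected(self):
        with pytest.raises(ValueError):
            confusion({"a": 1}, {"b": 1})


# (method, tp, fp, tn, fn, sens%, spec%, ppv%, npv%); None = printed value
# inconsistent with its own counts under half-up rounding, not asserted.
TABLE_ROWS = [
    ("dev-set algorithm", 11, 10, 99, 0, 100, 91, 52, 100),
    ("dev-set manual GTT", 9, 0, 109, 2, 82, 100, 100, 98),
    ("dev-set incident reporting", 7, 0, 109, 4, 64, 100, 100, 96),
    ("test-set algorithm", 8, 9, 101, 2, 80, 92, 47, 98),
    ("test-set manual GTT", 9, 0, 110, 0, 100, 100, 100, 100),
    ("test-set incident reporting", 7, 0, 110, 3, 70, 100, 100, 97),
    ("validation algorithm", 15, 17, 266, 0, 100, 94, 47, 100),
    ("validation chart review", 14, 0, 283, 1, 93, 100, 100, None),
    ("validation patient-report survey", 5, 0, 283, 10, 33, 100, 100, 97),
]


class TestAccuracyMetrics:
    @pytest.mark.parametrize(
        "label,tp,fp,tn,fn,sens,spec,ppv,npv", TABLE_ROWS,
        ids=[r[0] for r in TABLE_ROWS])
    def test_published_style_rows(self, label, tp, fp, tn, fn, sens, spec,
                                  ppv, npv):
        pct = accuracy_metrics(ConfusionMatrix(tp, fp, tn, fn)).percents
        expected = {"sensitivity": sens, "specificity": spec,
                    "ppv": ppv, "npv": npv}
        for metric, want in expected.items():
            if want is not None:
                assert pct[metric] == want, metric

    def test_exact_fractions_kept(self):
        rep = accuracy_metrics(ConfusionMatrix(11, 10, 99, 0))
        assert rep.specificity == Fraction(99, 109)
        assert rep.ppv == Fraction(11, 21)

    def test_zero_denominator_is_not_available(self):
        rep = accuracy_metrics(ConfusionMatrix(0, 0, 5, 0))
        assert rep.sensitivity is None and rep.ppv is None
        assert rep.specificity == 1 and rep.percents["specificity"] == 100
        assert rep.percents["sensitivity"] is None

    def test_wilson_intervals_bracket_point_estimate(self):
        rep = accuracy_metrics(ConfusionMatrix(15, 17, 266, 0), ci=True)
        lo, hi = rep.intervals["ppv"]
        assert lo < float(rep.ppv) < hi
        assert 0.0 <= lo and hi <= 1.0

    def test_half_up_rounding(self):
        assert percent_half_up(Fraction(99, 109)) == 91   # 90.83
        assert percent_half_up(Fraction(7, 11)) == 64     # 63.64
        assert percent_half_up(Fraction(199, 200)) == 100  # 99.5 rounds up


class TestCombinedDevelopmentCounts:
    """Summing the two 120-stay subsets reproduces the whole-sample figures."""

    def test_trigger_tool_sensitivity_90(self):
        cm = ConfusionMatrix(tp=9 + 9, fp=0, tn=109 + 110, fn=2 + 0)
        assert accuracy_metrics(cm).percents["sensitivity"] == 90
        assert cm.tp == 18 and cm.tp + cm.fn == 20

    def test_incident_report_sensitivity_67(self):
        cm = ConfusionMatrix(tp=7 + 7, fp=0, tn=109 + 110, fn=4 + 3)
        assert accuracy_metrics(cm).percents["sensitivity"] == 67
        assert cm.tp == 14 and cm.tp + cm.fn == 21

    def test_algorithm_ppv_50_npv_99(self):
        cm = ConfusionMatrix(tp=11 + 8, fp=10 + 9, tn=99 + 101, fn=0 + 2)
        pct = accuracy_metrics(cm).percents
        assert pct["ppv"] == 50 and cm.tp + cm.fp == 38
        assert pct["npv"] == 99 and cm.tn + cm.fn == 202


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == 1.0

    def test_chance_level(self):
        assert cohen_kappa((1, 1, 0, 0), (1, 0, 1, 0)) == 0.0

    def test_hand_computed_example(self):
        a = (1, 1, 1, 0, 0, 0, 0, 0, 0, 0)
        b = (1, 1, 0, 0, 0, 0, 0, 0, 0, 0)
        # p_o = 9/10; p_e = .3*.2 + .7*.8 = .62; κ = .28/.38
        assert cohen_kappa(a, b) == pytest.approx(0.28 / 0.38)

    def test_degenerate_identical_single_category(self):
        assert cohen_kappa([1, 1, 1], [1, 1, 1]) == 1.0

    def test_symmetric_and_rename_invariant(self):
        rng = random.Random(11)
        for _ in range(50):
            n = rng.randint(2, 30)
            a = [rng.randint(0, 1) for _ in range(n)]
            b = [rng.randint(0, 1) for _ in range(n)]
            k = cohen_kappa(a, b)
            assert k == pytest.approx(cohen_kappa(b, a))
            swap = {0: "x", 1: "y"}
            assert k == pytest.approx(
                cohen_kappa([swap[v] for v in a], [swap[v] for v in b]))

    def test_agrees_with_independent_implementations(self):
        from sklearn.metrics import cohen_kappa_score

        rng = random.Random(99)
        for _ in range(200):
            n = rng.randint(2, 40)
            a = [rng.randint(0, 1) for _ in range(n)]
            b = [rng.randint(0, 1) for _ in range(n)]
            ours = cohen_kappa(a, b)
            # direct formula evaluation as primary oracle
            p_o = sum(x == y for x, y in zip(a, b)) / n
            p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in (0, 1))
            expected = 1.0 if p_e == 1 else (p_o - p_e) / (1 - p_e)
            assert ours == pytest.approx(expected)
            if p_e < 1:
                assert ours == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


class TestFallRate:
    @pytest.mark.parametrize("n,days,expected", [
        (15, 3606, 4.16),
        (0, 1000, 0.00),
        (1, 250, 4.00),
    ])
    def test_examples(self, n, days, expected):
        assert fall_rate(n, days).rate_2dp == expected

    def test_zero_days_rejected(self):
        with pytest.raises(ValueError):
            fall_rate(1, 0)


class TestReviewEffort:
    def test_validation_study_arithmetic(self):
        eff = review_effort(298, 10.8, 32)
        assert eff.full_minutes == pytest.approx(3218.4)
        assert eff.flagged_minutes == pytest.approx(345.6)
        assert eff.reduction_percent == 89

    def test_review_everything_saves_nothing(self):
        assert review_effort(50, 7.0, 50).reduction_percent == 0

    def test_nothing_flagged_saves_everything(self):
        eff = review_effort(100, 10, 0)
        assert eff.flagged_minutes == 0 and eff.reduction_percent == 100

    def test_reduction_independent_of_minutes(self):
        assert review_effort(200, 5, 20).reduction == \
            review_effort(200, 50, 20).reduction

    def test_flagged_exceeding_records_rejected(self):
        with pytest.raises(ValueError):
            review_effort(10, 5, 11)


class TestErrorAnalysis:
    def _setup(self, lexicon):
        stays = [
            make_stay(stay_id="FP", notes=[make_note(
                stay_id="FP", text="Pat. heute im Zimmer gestürzt", day=4)]),
            make_stay(stay_id="FN", notes=[make_note(
                stay_id="FN", text="Patient kollabiert aufgefunden", day=4)]),
            make_stay(stay_id="TN", notes=[make_note(
                stay_id="TN", text="Nacht ruhig verlaufen", day=2)]),
        ]
        results = run_corpus(stays, lexicon)
        return stays, results

    def test_discordant_stays_reported_with_snippets(self, lexicon):
        stays, results = self._setup(lexicon)
        gold = {"FP": 0, "FN": 1, "TN": 0}
        rep = error_analysis(results, gold, stays)
        kinds = {e.stay_id: e.kind for e in rep.entries}
        assert kinds == {"FP": "false_positive", "FN": "false_negative"}
        fp = next(e for e in rep.entries if e.stay_id == "FP")
        assert any("gestürzt" in s.text for s in fp.snippets)

    def test_fn_without_matches_tags_term_gap(self, lexicon):
        stays, results = self._setup(lexicon)
        rep = error_analysis(results, {"FP": 1, "FN": 1, "TN": 0}, stays)
        fn = rep.entries[0]
        assert fn.stay_id == "FN"
        assert "term-list gap" in fn.tag
        assert fn.snippets == ()

    def test_concordant_corpus_gives_empty_report(self, lexicon):
        stays, results = self._setup(lexicon)
        rep = error_analysis(results, {"FP": 1, "FN": 0, "TN": 0}, stays)
        assert rep.empty
        assert "No discordant" in rep.to_text()

    def test_poa_evidence_tagged_candidate_poa(self, lexicon):
        # positive verdict from a day-6 fall, but the stay also documents an
        # admission-context fall: the FP tag should point at POA
        stays = [make_stay(stay_id="X", notes=[
            make_note(stay_id="X", note_type="admission_anamnesis", day=0.05,
                      note_id="X-a",
                      text="Sturz zu Hause, notfallmässig eingeliefert"),
            make_note(stay_id="X", day=6, note_id="X-b",
                      text="erneut am Boden vorgefunden"),
        ])]
        results = run_corpus(stays, lexicon)
        rep = error_analysis(results, {"X": 0}, stays)
        assert rep.entries[0].kind == "false_positive"
        assert "candidate-POA" in rep.entries[0].tag
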
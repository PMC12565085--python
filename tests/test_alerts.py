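"""Fragment mining, LR scoring, rule selection, prediction and LR-AD."""

import math

import pytest
from rdkit import Chem

from tkqsar.alerts import (
    NO_MATCH,
    AlertPrediction,
    AlertRule,
    cap_infinite_lrs,
    enumerate_fragments,
    fragments_of_molecule,
    lr_ad_filter,
    mine_alerts,
    predict_by_alerts,
    score_alert_lr,
    select_alerts,
)
from tkqsar.chemreg import standardize_structure
from tkqsar.errors import InvalidCountsError


def rule(frag="CC", cls="high", tp=5, fp=1, nt=10, nn=10, lr=None,
         matched=frozenset()):
    lr = score_alert_lr(tp, fp, nt, nn) if lr is None else lr
    return AlertRule(frag, cls, tp, fp, nt, nn, lr,
                     lr if math.isfinite(lr) else math.nan, matched)


class TestEnumerateFragments:
    def test_ethanol_window_2_3_exact_enumeration(self):
        mol = Chem.MolFromSmiles("CCO")
        frags = fragments_of_molecule(mol, 2, 3)
        assert frags == {"CC", "CO", "CCO"}

    def test_empty_window(self):
        mol = Chem.MolFromSmiles("CCO")
        assert fragments_of_molecule(mol, 3, 2) == set()

    def test_duplicate_molecules_dedup(self):
        recs = [standardize_structure("CCO", "a"),
                standardize_structure("CCO.[Na+]", "b")]
        cands = enumerate_fragments(recs, 2, 3)
        assert set(cands) == {"CC", "CO", "CCO"}
        assert cands["CCO"] == {"a", "b"}


class TestScoreLr:
    def test_prevalence_normalized_ratio(self):
        assert score_alert_lr(8, 2, 10, 20) == pytest.approx(8.0)

    def test_equal_rates_neutral(self):
        assert score_alert_lr(5, 10, 10, 20) == pytest.approx(1.0)

    def test_zero_fp_infinite_then_capped_at_rule_set_max(self):
        assert score_alert_lr(5, 0, 10, 20) == math.inf
        rules = [rule(tp=5, fp=0), rule(frag="CO", tp=8, fp=2)]
        capped = cap_infinite_lrs(rules)
        finite_max = capped[1].lr
        assert capped[0].capped_lr == finite_max

    def test_invalid_counts(self):
        with pytest.raises(InvalidCountsError):
            score_alert_lr(11, 0, 10, 20)


class TestSelectAlerts:
    def test_kept_above_thresholds(self):
        r = rule(tp=8, fp=2, nt=10, nn=20)  # lr 8
        assert select_alerts([r], min_support=3, min_lr=2.0) == \
            cap_infinite_lrs([r])

    def test_low_support_dropped(self):
        r = rule(tp=1, fp=0)
        assert select_alerts([r], min_support=2, min_lr=0.0) == []

    def test_identical_coverage_pruned_to_higher_rank(self):
        matched = frozenset({"m1", "m2", "m3"})
        a = rule(frag="CC", tp=3, fp=0, matched=matched)
        b = rule(frag="CCO", tp=3, fp=0, matched=matched)
        kept = select_alerts([a, b], min_support=1, min_lr=0.0)
        assert len(kept) == 1 and kept[0].fragment == "CC"  # pattern asc tie

    def test_subset_coverage_pruned(self):
        big = rule(frag="CC", tp=6, fp=0, matched=frozenset("abcdef"))
        small = rule(frag="CN", tp=3, fp=0, matched=frozenset("abc"))
        kept = select_alerts([big, small], min_support=1, min_lr=0.0)
        assert [r.fragment for r in kept] == ["CC"]

    def test_different_class_not_pruned(self):
        hi = rule(frag="CC", cls="high", tp=6, fp=0, matched=frozenset("abc"))
        lo = rule(frag="CN", cls="low", tp=3, fp=0, matched=frozenset("abc"))
        kept = select_alerts([hi, lo], min_support=1, min_lr=0.0)
        assert len(kept) == 2


class TestPredict:
    def make_rules(self):
        return select_alerts([
            rule(frag="C(F)(F)F", cls="low", tp=9, fp=1, matched=frozenset("a")),
            rule(frag="CCO", cls="high", tp=5, fp=3, matched=frozenset("b")),
        ], min_support=1, min_lr=0.0)

    def test_first_matching_rule_wins(self):
        rules = self.make_rules()
        q = standardize_structure("OCCC(F)(F)F", "q")  # matches both patterns
        p = predict_by_alerts(q, rules)
        assert p.predicted_class == "low"
        assert p.lr_of_prediction == rules[0].capped_lr

    def test_no_match(self):
        p = predict_by_alerts(standardize_structure("c1ccccc1", "q"),
                              self.make_rules())
        assert p.predicted_class == NO_MATCH and p.lr_of_prediction == 0.0

    def test_lr_ad_filter_thresholds(self):
        preds = [
            AlertPrediction("a", "high", rule(), 1.5),
            AlertPrediction("b", "high", rule(), 2.5),
            AlertPrediction("c", NO_MATCH, None, 0.0),
        ]
        inside, outside = lr_ad_filter(preds, 1.90)
        assert [p.query_id for p in inside] == ["b"]
        inside0, _ = lr_ad_filter(preds, 0.0)
        assert {p.query_id for p in inside0} == {"a", "b"}
        none_in, _ = lr_ad_filter(preds, 99.0)
        assert none_in == []

    def test_coverage_monotone_in_threshold(self):
        preds = [AlertPrediction(f"q{i}", "high", rule(), float(i) / 4)
                 for i in range(12)]
        fracs = [len(lr_ad_filter(preds, t)[0]) / len(preds)
                 for t in [0.0, 0.5, 1.0, 1.5, 2.0, 3.0]]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestMining:
    def test_planted_fragment_recovered_with_count_ratio_lr(self, small_library):
        records, truth = small_library
        carriers = {rid for rid, t in truth.items() if t["fragment"]}
        labels = {r.record_id: ("high" if r.record_id in carriers else "low")
                  for r in records}
        rules = mine_alerts(records, labels, min_atoms=2, max_atoms=5,
                            min_support=3, min_lr=2.0)
        # brute-force count oracle via direct substructure matching
        patt = Chem.MolFromSmarts("C(F)(F)F")
        matched = frozenset(
            r.record_id for r in records
            if Chem.MolFromSmiles(r.smiles_std).HasSubstructMatch(patt))
        n_hi = len(carriers)
        n_lo = len(records) - n_hi
        tp = len(matched & carriers)
        fp = len(matched) - tp
        expected_lr = (tp / n_hi) / (fp / n_lo) if fp else math.inf
        hits = [r for r in rules
                if r.target_class == "high" and r.matched_ids == matched]
        assert hits, "no mined rule covers exactly the planted carriers"
        assert any(r.lr == expected_lr or (math.isinf(expected_lr)
                                           and math.isinf(r.lr))
                   for r in hits)

    def test_mining_order_independent_of_input_order(self, small_library):
        records, truth = small_library
        carriers = {rid for rid, t in truth.items() if t["fragment"]}
        labels = {r.record_id: ("high" if r.record_id in carriers else "low")
                  for r in records}
        a = mine_alerts(records, labels, 2, 4, 3, 2.0)
        b = mine_alerts(list(reversed(records)), labels, 2, 4, 3, 2.0)
        assert [(r.fragment, r.capped_lr) for r in a] == \
            [(r.fragment, r.capped_lr) for r in b]
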
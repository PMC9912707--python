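"""Confusion counting, the five metrics, stratification, review sampling."""

import numpy as np
import pytest

import symtalk as st
from symtalk.evaluation import EvaluationError, classify_turns
from symtalk.matching import DetectionResult, Match


def det(cid, ti, detected):
    r = DetectionResult(conversation_id=cid, turn_index=ti)
    if detected:
        r.matches.append(Match("pain", (0, 4), frozenset({"pain"})))
    return r


def gold(cid, ti, positive, focused=None):
    focused = positive if focused is None else focused
    return st.GoldLabel(cid, ti, 3.0 if positive else 0.0, positive, focused)


class TestConfusion:
    def test_all_detected_all_positive(self):
        n = 7
        c = st.confusion([det("c", i, True) for i in range(n)],
                         [gold("c", i, True) for i in range(n)])
        assert (c.tp, c.fp, c.tn, c.fn) == (n, 0, 0, 0)

    def test_hand_enumerated_fixture(self):
        plan = [  # (detected, positive)
            (True, True), (True, True), (True, False), (False, True),
            (False, False), (False, False), (True, False), (False, True),
            (False, True), (False, False),
        ]
        c = st.confusion(
            [det("c", i, d) for i, (d, _p) in enumerate(plan)],
            [gold("c", i, p) for i, (_d, p) in enumerate(plan)],
        )
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 2, 3, 3)
        assert c.total == 10

    def test_disjoint_turn_sets_error(self):
        with pytest.raises(EvaluationError, match="different turns"):
            st.confusion([det("c", 0, True)], [gold("c", 1, True)])

    def test_standard_selects_label_layer(self):
        detections = [det("c", 0, True)]
        g = [gold("c", 0, True, focused=False)]
        assert st.confusion(detections, g, "broad").tp == 1
        assert st.confusion(detections, g, "proctcae").fp == 1


class TestMetrics:
    def test_perfect_detector_has_undefined_specificity(self):
        m = st.metrics(st.ConfusionCounts(5, 0, 0, 0))
        assert m.sensitivity == m.precision == m.accuracy == m.f1 == 1.0
        assert m.specificity is None
        assert m.rounded()["specificity"] is None

    def test_zero_total_is_an_error(self):
        with pytest.raises(EvaluationError):
            st.metrics(st.ConfusionCounts(0, 0, 0, 0))

    def test_half_up_display_rounding(self):
        m = st.metrics(st.ConfusionCounts(1, 3, 0, 0))  # precision 0.25, sens 1.0
        assert m.rounded()["precision"] == 0.25
        m2 = st.metrics(st.ConfusionCounts(1, 7, 0, 0))  # precision 0.125 -> 0.13
        assert m2.rounded()["precision"] == 0.13

    def test_identities_over_random_counts(self):
        """accuracy == (TP+TN)/total and F1 == harmonic mean of P and R."""
        rng = np.random.default_rng(17)
        for _ in range(500):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 40, size=4))
            if tp + fp + tn + fn == 0:
                continue
            c = st.ConfusionCounts(tp, fp, tn, fn)
            m = st.metrics(c)
            assert m.accuracy == pytest.approx((tp + tn) / c.total)
            if m.precision not in (None, 0) and m.sensitivity not in (None, 0):
                harmonic = 2 / (1 / m.precision + 1 / m.sensitivity)
                assert m.f1 == pytest.approx(harmonic)


class TestStratified:
    def make_world(self, make_conv):
        convs = [
            make_conv(["a", "b"], cid="c1", pid="p1", metadata={"race": "White"}),
            make_conv(["c", "d", "e"], cid="c2", pid="p2",
                      metadata={"race": "Black/African American"}),
            make_conv(["f"], cid="c3", pid="p3", metadata={}),
        ]
        detections, labels = [], []
        rng = np.random.default_rng(2)
        for conv in convs:
            for t in conv.turns:
                d = bool(rng.random() < 0.5)
                p = bool(rng.random() < 0.5)
                detections.append(det(conv.conversation_id, t.turn_index, d))
                labels.append(gold(conv.conversation_id, t.turn_index, p))
        return convs, detections, labels

    def test_single_stratum_equals_overall(self, make_conv):
        convs = [make_conv(["a", "b"], cid="c1", metadata={"race": "Other"})]
        detections = [det("c1", 0, True), det("c1", 1, False)]
        labels = [gold("c1", 0, True), gold("c1", 1, False)]
        rep = st.stratified_report(detections, labels, convs, "broad", "race")
        assert set(rep.strata) == {"Other"}
        assert rep.strata["Other"][0] == rep.counts

    def test_strata_counts_sum_to_overall(self, make_conv):
        convs, detections, labels = self.make_world(make_conv)
        rep = st.stratified_report(detections, labels, convs, "broad", "race")
        total = sum((c for c, _m in rep.strata.values()),
                    st.ConfusionCounts(0, 0, 0, 0))
        assert total == rep.counts
        assert "Missing" in rep.strata

    def test_noisier_stratum_scores_lower_f1(self, lex):
        cfg = st.GeneratorConfig(
            n_conversations=40,
            turns_per_conversation=(40, 60),
            symptom_prevalence=0.2,
            colloquial_rate=0.0,
            seed=23,
            strata={"A": 0.5, "B": 0.5},
            # stratum A's decoys fire on the lexicon via a custom decoy list
            stratum_ambiguity={"A": 0.5, "B": 0.0},
        )
        corpus = st.generate(cfg, lex, decoys=("i am in pain he said on tv",))
        detections = st.detect_corpus(corpus.conversations, lex)
        rep = st.stratified_report(
            detections, corpus.broad_gold(), corpus.conversations, "broad", "race"
        )
        f1_a = rep.strata["A"][1].f1
        f1_b = rep.strata["B"][1].f1
        assert f1_a < f1_b


class TestReviewSampling:
    def make_world(self, make_conv, n_conv=12, turns=40, seed=4):
        rng = np.random.default_rng(seed)
        convs, detections, labels = [], [], []
        for i in range(n_conv):
            cid, pid = f"c{i}", f"p{i % 6}"
            dataset = "validation" if i % 2 == 0 else "test"
            convs.append(
                st.Conversation(cid, pid, [st.Turn(t, "patient", "x") for t in range(turns)],
                                dataset_label=dataset)
            )
            for t in range(turns):
                d = bool(rng.random() < 0.5)
                p = bool(rng.random() < 0.5)
                detections.append(det(cid, t, d))
                labels.append(gold(cid, t, p))
        return convs, detections, labels

    def test_sizes_classes_and_balance(self, make_conv):
        convs, detections, labels = self.make_world(make_conv)
        sample = st.sample_for_review(detections, labels, convs, 100, 50, seed=1)
        assert len(sample.turns) == 150
        classes = classify_turns(detections, labels)
        assert all(classes[k] == cls for k, cls in sample.turns)
        assert sample.per_class_sizes["TP"] == 50
        assert sample.per_class_sizes.get("FP", 0) + sample.per_class_sizes.get("FN", 0) == 100
        # even dataset proportions, as the pools allow
        assert abs(sample.per_dataset_sizes["validation"]
                   - sample.per_dataset_sizes["test"]) <= 2
        assert len(set(sample.turns)) == 150

    def test_deterministic_under_seed(self, make_conv):
        convs, detections, labels = self.make_world(make_conv)
        s1 = st.sample_for_review(detections, labels, convs, 60, 30, seed=7)
        s2 = st.sample_for_review(detections, labels, convs, 60, 30, seed=7)
        assert s1.turns == s2.turns

    def test_request_exceeding_pool_errors(self, make_conv):
        convs, detections, labels = self.make_world(make_conv, n_conv=2, turns=5)
        with pytest.raises(EvaluationError, match="available"):
            st.sample_for_review(detections, labels, convs, 1000, 0, seed=0)

    def test_per_patient_cap(self, make_conv):
        convs, detections, labels = self.make_world(make_conv)
        sample = st.sample_for_review(
            detections, labels, convs, 40, 20, seed=3, max_per_patient=15
        )
        per_patient: dict[str, int] = {}
        pid_of = {c.conversation_id: c.patient_id for c in convs}
        for (cid, _ti), _cls in sample.turns:
            per_patient[pid_of[cid]] = per_patient.get(pid_of[cid], 0) + 1
        assert max(per_patient.values()) <= 15

    def test_infeasible_cap_names_constraint(self, make_conv):
        convs, detections, labels = self.make_world(make_conv)
        with pytest.raises(EvaluationError, match="per-patient cap"):
            st.sample_for_review(detections, labels, convs, 200, 0, seed=0,
                                 max_per_patient=1)
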
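"""Turn-level matching semantics, exclusion suppression, KWIC, and the
naive-oracle equivalence property."""

import numpy as np
import pytest

import symtalk as st
from symtalk.matching import _CompiledLibrary
from symtalk.transcripts import normalize_and_tokenize, tokenize_phrase


def detect(text, lib):
    return st.detect_turn(
        normalize_and_tokenize(st.Turn(0, "patient", text)), lib
    )


class TestDetectTurn:
    def test_medication_term_detected_case_insensitively(self, tiny_lib):
        r = detect("Do you need any more Ativan?", tiny_lib)
        assert r.detected and r.matched_terms == ["ativan"]
        assert r.categories == frozenset({"mood/anxiety"})

    def test_clinician_system_question(self, lex):
        r = detect("How are your bowels", lex)
        assert r.detected and "GI" in r.categories

    def test_exam_context_exclusion_suppresses(self):
        lib = st.KeywordLibrary(
            entries=[st.make_entry("breaths", "respiratory")],
            exclusions=[st.ExclusionPattern("deep breaths", "exam")],
        )
        r = detect("Take a few deep breaths for me", lib)
        assert not r.detected
        assert [(m.term, phrase) for m, phrase in r.suppressed] == [("breaths", "deep breaths")]

    def test_exclusion_without_inner_keyword_is_inert(self, lex):
        assert not detect("Take a few deep breaths for me", lex).detected

    def test_exclusion_only_suppresses_inside_its_span(self):
        lib = st.KeywordLibrary(
            entries=[st.make_entry("breaths", "respiratory")],
            exclusions=[st.ExclusionPattern("deep breaths", "exam")],
        )
        r = detect("Deep breaths now; her breaths are shallow at night", lib)
        assert r.detected  # the second "breaths" is outside the exclusion span
        assert len(r.matches) == 1 and len(r.suppressed) == 1

    def test_negated_symptom_still_detected(self, lex):
        # detection is lexical: "don't have the appetite" names the symptom
        r = detect("I don’t have the appetite", lex)
        assert r.detected and r.matched_terms == ["appetite"]

    def test_empty_turn(self, tiny_lib):
        r = detect("", tiny_lib)
        assert not r.detected and r.matches == []

    def test_no_substring_matches(self):
        lib = st.KeywordLibrary(entries=[st.make_entry("red", "cutaneous")])
        assert not detect("That bothered me", lib).detected
        assert detect("My arm is red", lib).detected

    def test_multiword_phrase_matches_token_sequence(self, tiny_lib):
        r = detect("some days I get that fuzzy brain feeling", tiny_lib)
        assert r.matched_terms == ["fuzzy brain"]
        (m,) = r.matches
        assert m.span == (21, 32)

    def test_span_surface_equals_term(self, tiny_lib):
        text = "Fuzzy   brain?  no: Fuzzy brain."
        r = detect(text, tiny_lib)
        for m in r.matches:
            surface = tokenize_phrase(text[m.span[0] : m.span[1]])
            assert surface == tokenize_phrase(m.term)


class TestDetectCorpus:
    def test_one_result_per_turn(self, make_conv, tiny_lib):
        corpus = [make_conv(["a", "b", "c"], cid="c1"), make_conv(["d"], cid="c2", pid="p2")]
        results = st.detect_corpus(corpus, tiny_lib)
        assert [(r.conversation_id, r.turn_index) for r in results] == [
            ("c1", 0), ("c1", 1), ("c1", 2), ("c2", 0)
        ]

    def test_disjoint_vocabulary_detects_nothing(self, make_conv):
        lib = st.KeywordLibrary(entries=[st.make_entry("zzzz", "other")])
        corpus = [make_conv(["the weather is fine", "thanks for coming"])]
        assert not any(r.detected for r in st.detect_corpus(corpus, lib))

    def test_monotone_in_library_entries(self, make_conv, lex):
        """Adding entries never turns a detected turn undetected."""
        corpus = [make_conv(["my pain is bad", "nothing to report", "nausea again"])]
        small = st.KeywordLibrary(entries=[st.make_entry("pain", "pain")],
                                  exclusions=list(lex.exclusions))
        before = [r.detected for r in st.detect_corpus(corpus, small)]
        after = [r.detected for r in st.detect_corpus(corpus, lex)]
        assert all(not b or a for b, a in zip(before, after))

    def test_adding_exclusions_never_adds_detection(self, make_conv, lex):
        corpus = [make_conv(["take a deep breath for me", "my pain is bad"])]
        bare = st.KeywordLibrary(entries=list(lex.entries), version_label=lex.version_label)
        with_excl = lex
        before = [r.detected for r in st.detect_corpus(corpus, bare)]
        after = [r.detected for r in st.detect_corpus(corpus, with_excl)]
        assert all(not a or b for b, a in zip(before, after))


def oracle_detect(token_texts, lib):
    """Exhaustive window scan: every token window against every term/exclusion."""
    def occurrences(phrases):
        out = []
        for phrase in phrases:
            words = phrase.split()
            for i in range(len(token_texts) - len(words) + 1):
                if list(token_texts[i : i + len(words)]) == words:
                    out.append((i, i + len(words), phrase))
        return out

    cand = occurrences([e.term for e in lib.entries])
    excl = occurrences([x.phrase for x in lib.exclusions])
    surviving = [
        (s, e, t)
        for (s, e, t) in cand
        if not any(xs <= s and e <= xe for (xs, xe, _x) in excl)
    ]
    return sorted(surviving)


def random_case(rng, alphabet):
    n_terms = int(rng.integers(1, 6))
    terms = set()
    while len(terms) < n_terms:
        k = int(rng.integers(1, 3))
        terms.add(" ".join(rng.choice(alphabet, size=k)))
    n_excl = int(rng.integers(0, 3))
    exclusions = set()
    while len(exclusions) < n_excl:
        k = int(rng.integers(2, 4))
        exclusions.add(" ".join(rng.choice(alphabet, size=k)))
    lib = st.KeywordLibrary(
        entries=[st.make_entry(t, "other") for t in sorted(terms)],
        exclusions=[st.ExclusionPattern(p) for p in sorted(exclusions)],
    )
    tokens = list(rng.choice(alphabet, size=int(rng.integers(0, 15))))
    return lib, tokens


@pytest.mark.parametrize("seed", [7, 11])
def test_matcher_agrees_with_naive_oracle(seed):
    """detect_turn vs an exhaustive window scan on random (library, sequence) pairs."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(["ax", "bo", "cu", "di", "el"])
    for _ in range(300):
        lib, tokens = random_case(rng, alphabet)
        text = " ".join(tokens)
        r = detect(text, lib)
        expected = oracle_detect(tokens, lib)
        got_terms = sorted(m.term for m in r.matches)
        assert got_terms == sorted(t for (_s, _e, t) in expected)
        assert r.detected == bool(expected)


class TestKwic:
    def test_counts_and_contexts(self, make_conv):
        corpus = [
            make_conv(
                ["worry is natural", "I worry about the scan", "no worry here at all"],
                cid="c1",
            )
        ]
        lines = st.kwic(corpus, "worry", window=2)
        assert len(lines) == 3
        assert lines[0].left == "" and lines[0].keyword == "worry"
        assert lines[1].left == "i" and lines[1].right == "about the"

    def test_zero_window_keyword_only(self, make_conv):
        corpus = [make_conv(["the pain is back"])]
        (line,) = st.kwic(corpus, "pain", window=0)
        assert (line.left, line.keyword, line.right) == ("", "pain", "")

    def test_absent_term_empty(self, make_conv):
        assert st.kwic([make_conv(["hello there"])], "zzz", 3) == []

    def test_context_stops_at_turn_boundary(self, make_conv):
        corpus = [make_conv(["tail of previous", "pain", "head of next"])]
        (line,) = st.kwic(corpus, "pain", window=5)
        assert line.left == "" and line.right == ""

    def test_negative_window_rejected(self, make_conv):
        with pytest.raises(ValueError):
            st.kwic([make_conv(["x"])], "x", -1)


def test_compiled_library_reuse_is_equivalent(tiny_lib):
    tk = normalize_and_tokenize(st.Turn(0, "patient", "nausea and fuzzy brain"))
    a = st.detect_turn(tk, tiny_lib)
    b = st.detect_turn(tk, _CompiledLibrary(tiny_lib))
    assert a.matches == b.matches
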
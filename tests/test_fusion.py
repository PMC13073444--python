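"""Keyword lexicon, late fusion, and the regex override layer."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_segment
from msktriage.classify import predict_label
from msktriage.fusion import (DEFAULT_ALPHA_GRID, FusionConfig, KeywordLexicon,
                              RulePatternSet, apply_rules, compile_lexicon,
                              count_rule_changes, fuse, keyword_counts,
                              load_pattern_file, load_phrase_file, tune_alpha)
from msktriage.ingest import SegmentCorpus
from msktriage.labels import TriageLabel
from msktriage.text import simplify


def brute_force_count(text, phrases):
    """Exhaustive leftmost/longest-first non-overlapping match count."""
    ordered = sorted(phrases, key=len, reverse=True)
    i, hits = 0, 0
    while i < len(text):
        for ph in ordered:
            if text[i : i + len(ph)] == ph:
                hits += 1
                i += len(ph)
                break
        else:
            i += 1
    return hits


class TestCompileLexicon:
    def test_priority_red_over_yellow(self):
        lex = compile_lexicon([], ["hematom", "kist"], ["hematom"])
        assert "hematom" in lex.phrases[2]
        assert "hematom" not in lex.phrases[1]

    def test_empty_inputs_give_empty_lexicon(self):
        assert compile_lexicon([], [], []).is_empty()

    def test_phrases_are_normalized_and_simplified(self):
        lex = compile_lexicon([], [], ["MRG  Önerilir"])
        assert lex.phrases[2] == ("mrg onerilir",)

    def test_empty_phrase_rejected(self):
        with pytest.raises(ValueError):
            compile_lexicon(["  "], [], [])

    words = st.lists(st.sampled_from(["kist", "apse", "odem", "kitle", "mr"]),
                     max_size=5)

    @given(g=words, y=words, r=words)
    @settings(max_examples=200, derandomize=True)
    def test_disjoint_and_union_preserved(self, g, y, r):
        """Set-algebra oracle: output lists partition the input union."""
        lex = compile_lexicon(g, y, r)
        sets = [set(p) for p in lex.phrases]
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])
        assert sets[0] | sets[1] | sets[2] == set(g) | set(y) | set(r)
        # priority respected
        assert sets[2] == set(r)
        assert sets[1] == set(y) - set(r)


class TestKeywordCounts:
    def test_single_red_hit(self):
        lex = compile_lexicon([], [], ["hematom"])
        assert keyword_counts("hematom ile uyumlu", lex).tolist() == [0, 0, 1]

    def test_no_hits(self):
        lex = compile_lexicon(["kitle izlenmedi"], [], [])
        assert keyword_counts("tamamen farklı metin", lex).tolist() == [0, 0, 0]

    def test_diacritics_fold_before_matching(self):
        lex = compile_lexicon([], [], ["MRG önerilir"])
        assert keyword_counts("acil mrg ÖNERİLİR", lex)[2] == 1

    def test_longest_first_non_overlapping(self):
        lex = compile_lexicon([], ["kist", "kist kist"], [])
        text = "kist kist kisti"
        got = keyword_counts(text, lex)[1]
        assert got == brute_force_count(simplify(text), lex.phrases[1])
        assert got == 2  # "kist kist" then "kist"(i)

    @given(st.text(alphabet=st.sampled_from(list("kist apse ")), max_size=40))
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force_oracle(self, text):
        lex = compile_lexicon([], ["kist", "kist kist"], ["apse"])
        got = keyword_counts(text, lex)
        s = simplify(text)
        assert got[1] == brute_force_count(s, lex.phrases[1])
        assert got[2] == brute_force_count(s, lex.phrases[2])


class TestFuse:
    def test_alpha_zero_is_identity(self):
        z = np.array([0.5, -1.0, 2.0])
        assert np.array_equal(fuse(z, np.array([9, 9, 9.0]), 0.0), z)

    def test_elementwise_formula(self):
        out = fuse(np.zeros(3), np.array([1.0, 0, 2]), 1.0)
        assert out.tolist() == [1.0, 0.0, 2.0]

    def test_fusion_flips_prediction_toward_keywords(self):
        z = np.array([0.5, 1.0, 0.2])
        fused = fuse(z, np.array([0.0, 0, 1]), 2.0)
        assert np.allclose(fused, [0.5, 1.0, 2.2])
        assert predict_label(fused) is TriageLabel.RED

    @given(
        z=st.tuples(*[st.floats(-5, 5) for _ in range(3)]),
        k=st.tuples(*[st.integers(0, 3) for _ in range(3)]),
        a1=st.floats(0, 3), a2=st.floats(0, 3),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_alpha_for_dominant_keyword_class(self, z, k, a1, a2):
        """Raising alpha never lowers the score of the strictly largest K."""
        z, k = np.array(z), np.array(k, dtype=float)
        c = int(np.argmax(k))
        if (k == k[c]).sum() > 1:
            return  # no strictly dominant class
        lo, hi = min(a1, a2), max(a1, a2)
        assert fuse(z, k, hi)[c] >= fuse(z, k, lo)[c]

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            fuse(np.zeros(3), np.zeros(3), -0.1)


class _StubBackend:
    def __init__(self, logits):
        self._logits = np.asarray(logits, dtype=float)

    def predict_logits(self, texts):
        return self._logits


class TestTuneAlpha:
    def _validation(self, labels, texts):
        segs = [make_segment(i, t, l) for i, (t, l) in enumerate(zip(texts, labels))]
        return SegmentCorpus(segments=segs)

    def test_empty_lexicon_returns_zero(self):
        val = self._validation([0, 1, 2], ["a", "b", "c"])
        backend = _StubBackend(np.eye(3) * 2)
        assert tune_alpha(backend, compile_lexicon([], [], []), val) == 0.0

    def test_grid_of_zero_returns_zero(self):
        val = self._validation([0, 1, 2], ["a", "b", "c"])
        backend = _StubBackend(np.eye(3))
        lex = compile_lexicon([], [], ["hematom"])
        assert tune_alpha(backend, lex, val, grid=[0.0]) == 0.0

    def test_corrective_red_keyword_selects_positive_alpha(self):
        # backend under-calls RED on texts containing the keyword
        texts = ["hematom bulgusu", "hematom alanı", "normal", "kistik"]
        labels = [2, 2, 0, 1]
        logits = np.array([
            [0.0, 1.0, 0.5],  # wrongly YELLOW
            [0.0, 1.0, 0.5],  # wrongly YELLOW
            [2.0, 0.0, 0.0],
            [0.0, 2.0, 0.0],
        ])
        lex = compile_lexicon([], [], ["hematom"])
        alpha = tune_alpha(_StubBackend(logits), lex, self._validation(labels, texts))
        assert alpha > 0

    def test_empty_grid_rejected(self):
        val = self._validation([0, 1, 2], ["a", "b", "c"])
        with pytest.raises(ValueError):
            tune_alpha(_StubBackend(np.eye(3)), compile_lexicon([], [], []),
                       val, grid=[])


class TestApplyRules:
    pats = RulePatternSet.from_lists(
        negative=["kitle izlenmedi"], red_force=["hematom"]
    )

    def test_negative_shield_takes_precedence(self):
        final, changed = apply_rules(
            TriageLabel.YELLOW, "kitle izlenmedi ancak hematom?", self.pats
        )
        assert final is TriageLabel.GREEN and changed

    def test_red_force_escalates(self):
        final, changed = apply_rules(TriageLabel.GREEN, "yaygın hematom",
                                     self.pats)
        assert final is TriageLabel.RED and changed

    def test_no_match_keeps_base(self):
        final, changed = apply_rules(TriageLabel.YELLOW, "olağan bulgular",
                                     self.pats)
        assert final is TriageLabel.YELLOW and not changed

    @pytest.mark.parametrize("base", list(TriageLabel))
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("kitle izlenmedi", TriageLabel.GREEN),
            ("hematom var", TriageLabel.RED),
            ("KİTLE İZLENMEDİ ve hematom", TriageLabel.GREEN),
            ("başka bir şey", None),  # base passes through
        ],
    )
    def test_override_truth_table(self, base, text, expected):
        final, changed = apply_rules(base, text, self.pats)
        want = expected if expected is not None else base
        assert final is want
        assert changed == (want is not base)

    def test_idempotence(self):
        for text in ["kitle izlenmedi", "hematom", "nötr metin"]:
            once, _ = apply_rules(TriageLabel.YELLOW, text, self.pats)
            twice, changed = apply_rules(once, text, self.pats)
            assert twice is once

    def test_empty_patterns_never_change(self):
        empty = RulePatternSet.from_lists()
        for base in TriageLabel:
            final, changed = apply_rules(base, "hematom kitle izlenmedi", empty)
            assert final is base and not changed


class TestCountRuleChanges:
    def test_identical_sequences(self):
        preds = [TriageLabel.GREEN, TriageLabel.RED]
        assert count_rule_changes(preds, preds) == 0

    def test_single_difference(self):
        a = [TriageLabel.GREEN, TriageLabel.YELLOW, TriageLabel.RED]
        b = [TriageLabel.GREEN, TriageLabel.RED, TriageLabel.RED]
        assert count_rule_changes(a, b) == 1

    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)),
                    max_size=30))
    @settings(max_examples=200, derandomize=True)
    def test_matches_positional_comparison(self, pairs):
        a = [TriageLabel(x) for x, _ in pairs]
        b = [TriageLabel(y) for _, y in pairs]
        assert count_rule_changes(a, b) == sum(x != y for x, y in pairs)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_rule_changes([TriageLabel.GREEN], [])


def test_default_grid_spans_zero_to_three():
    assert DEFAULT_ALPHA_GRID[0] == 0.0
    assert DEFAULT_ALPHA_GRID[-1] == 3.0
    with pytest.raises(ValueError):
        FusionConfig(grid=(0.5, 1.0))  # must include 0


def test_inventory_files_round_trip(tmp_path):
    phrase_file = tmp_path / "lex.txt"
    phrase_file.write_text(
        "[GREEN]\nkitle izlenmedi\n[YELLOW]\nganglion\n[RED]\nhematom\n"
        "MRG önerilir\n",
        encoding="utf-8",
    )
    lex = load_phrase_file(phrase_file)
    assert lex.phrases == (("kitle izlenmedi",), ("ganglion",),
                           ("hematom", "mrg onerilir"))
    pattern_file = tmp_path / "pat.txt"
    pattern_file.write_text(
        "[NEGATIVE]\nlezyon saptanmadi\n[RED_FORCE]\napse\n", encoding="utf-8"
    )
    pats = load_pattern_file(pattern_file)
    assert apply_rules(TriageLabel.YELLOW, "apse şüphesi", pats)[0] is TriageLabel.RED
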
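"""Generator contracts: determinism, gold validity, noise bookkeeping,
standoff round-trip, and split arithmetic."""

import numpy as np
import pytest

from xlcui.documents import AnnotatedDocument, Mention, StandoffError, read_standoff, write_standoff
from xlcui.synthetic import (GenConfig, apply_translation_noise, build_lexicon,
                             generate_corpus, generate_terminology,
                             is_abbreviation, split_corpus)
from xlcui.terminology import lookup_exact, partition_terms_by_language_coverage


class TestTerminologyGeneration:
    def test_base_concept_count_per_group(self):
        cfg = GenConfig(concepts_per_group=5, ambiguous_pair_rate=0.0, seed=1)
        term = generate_terminology(cfg)
        assert len(term) == 20
        groups = [term.group_of(c) for c in term.cuis()]
        assert all(groups.count(g) == 5 for g in ("CHEM", "DEVI", "DISO", "PROC"))

    def test_ambiguity_duplicates_add_concepts(self):
        cfg = GenConfig(concepts_per_group=5, ambiguous_pair_rate=1.0, seed=1)
        term = generate_terminology(cfg)
        assert len(term) == 40  # every base concept gets a companion

    def test_zero_ambiguity_means_unique_surface_strings(self):
        cfg = GenConfig(ambiguous_pair_rate=0.0, seed=2)
        term = generate_terminology(cfg)
        for _, _, lang, surface in term.iter_terms():
            assert len(lookup_exact(surface, lang, term)) == 1

    def test_ambiguous_companion_shares_token_distinct_cui_same_group(self):
        cfg = GenConfig(ambiguous_pair_rate=1.0, seed=3)
        term = generate_terminology(cfg)
        cuis = term.cuis()
        # companions are emitted right after their base concept
        pairs = [(cuis[i], cuis[i + 1]) for i in range(0, len(cuis) - 1, 2)]
        for base, comp in pairs:
            assert term.group_of(base) == term.group_of(comp)
            base_words = {w for _, t, _ in term.concepts[base].terms
                          for w in t.split()}
            comp_words = {w for _, t, _ in term.concepts[comp].terms
                          for w in t.split()}
            assert base_words & comp_words

    def test_abbreviations_are_source_language_only(self):
        cfg = GenConfig(abbreviation_rate=1.0, seed=4)
        term = generate_terminology(cfg)
        abbrevs = [(c, t) for c, _, lang, t in term.iter_terms({"FRE"})
                   if is_abbreviation(t)]
        assert abbrevs
        for _, t in abbrevs:
            assert not any(t == t2 for _, _, lang, t2 in term.iter_terms({"ENG"}))
        # abbreviation-bearing concepts remain bilingual, so the ENG/FRE
        # partition keeps abbreviations on the shared (FRE-covered) side
        shared, sec = partition_terms_by_language_coverage(term, "FRE", "ENG")
        assert {t for _, _, t in shared} >= {t for _, t in abbrevs}

    def test_determinism_byte_identical(self):
        a = generate_terminology(GenConfig(seed=11))
        b = generate_terminology(GenConfig(seed=11))
        assert [(c, tuple(a.concepts[c].terms)) for c in a.cuis()] == \
            [(c, tuple(b.concepts[c].terms)) for c in b.cuis()]


class TestCorpusGeneration:
    def test_doc_count_and_determinism(self, small_world):
        cfg, term, docs, _ = small_world
        assert len(docs) == cfg.docs
        again = generate_corpus(term, cfg)
        assert [(d.doc_id, d.text, tuple(d.mentions)) for d in docs] == \
            [(d.doc_id, d.text, tuple(d.mentions)) for d in again]

    def test_default_docs_count_is_42(self):
        assert GenConfig().docs == 42

    def test_every_gold_mention_surface_is_a_source_term_of_its_cui(self, small_world):
        _, term, docs, _ = small_world
        for doc in docs:
            for m in doc.mentions:
                hits = lookup_exact(doc.surface(m), "FRE", term)
                assert m.cui in [c for c, _ in hits]

    def test_no_nesting_when_disabled(self):
        cfg = GenConfig(docs=6, nesting_rate=0.0, seed=6)
        docs = generate_corpus(generate_terminology(cfg), cfg)
        for doc in docs:
            ms = doc.sorted_mentions()
            for a in ms:
                for b in ms:
                    if a is not b:
                        assert a.end <= b.start or b.end <= a.start

    def test_forced_nesting_gives_nested_pair_every_sentence(self):
        cfg = GenConfig(docs=4, nesting_rate=1.0, mentions_per_sentence=1.0,
                        sentences_per_doc=3, seed=7)
        docs = generate_corpus(generate_terminology(cfg), cfg)
        for doc in docs:
            sentences = _sentence_spans(doc.text)
            for s_start, s_end in sentences:
                in_sent = [m for m in doc.mentions
                           if s_start <= m.start and m.end <= s_end]
                assert any(
                    a.start <= b.start and b.end <= a.end and
                    (a.end - a.start) > (b.end - b.start)
                    for a in in_sent for b in in_sent), doc.text[s_start:s_end]


def _sentence_spans(text):
    spans, start = [], 0
    for i, ch in enumerate(text):
        if ch == ".":
            spans.append((start, i + 1))
            start = i + 1
    return spans


class TestTranslationNoise:
    def test_noise_free_translation_uses_lexicon_exactly(self, small_world):
        cfg, term, docs, lex = small_world
        clean = GenConfig(docs=cfg.docs, seed=cfg.seed, p_literal=0.0,
                          p_abbrev_passthrough=0.0)
        for doc in docs[:6]:
            par = apply_translation_noise(doc, lex, clean)
            outer = [m for m in par.target_mentions
                     if not any(o is not m and o.start <= m.start and m.end <= o.end
                                for o in par.target_mentions)]
            for m in outer:
                emitted = par.target_text[m.start:m.end]
                assert emitted in lex.values()
            assert all(op == "faithful" for op, _, _ in par.noise_log)

    def test_full_literal_noise_emits_no_terminology_term(self):
        cfg = GenConfig(docs=8, seed=7, p_literal=1.0, p_abbrev_passthrough=0.0)
        term = generate_terminology(cfg)
        docs = generate_corpus(term, cfg)
        lex = build_lexicon(term)
        for doc in docs:
            par = apply_translation_noise(doc, lex, cfg)
            for op, _, emitted in par.noise_log:
                assert op == "literal"
                assert lookup_exact(emitted, "ENG", term) == []
                assert lookup_exact(emitted, "FRE", term) == []

    def test_abbreviation_passthrough_copies_source_string(self):
        cfg = GenConfig(docs=10, seed=8, abbreviation_rate=1.0,
                        p_literal=0.0, p_abbrev_passthrough=1.0)
        term = generate_terminology(cfg)
        docs = generate_corpus(term, cfg)
        lex = build_lexicon(term)
        seen = 0
        for doc in docs:
            par = apply_translation_noise(doc, lex, cfg)
            for op, (s, e), emitted in par.noise_log:
                if is_abbreviation(doc.text[s:e]):
                    assert op == "abbrev_passthrough"
                    assert emitted == doc.text[s:e]
                    seen += 1
        assert seen > 0

    def test_missing_lexicon_entry_error_names_the_term(self, small_world):
        cfg, term, docs, lex = small_world
        doc = docs[0]
        surface = doc.surface(doc.mentions[0])
        broken = {k: v for k, v in lex.items() if k != surface}
        with pytest.raises(KeyError, match=surface.split()[0]):
            apply_translation_noise(doc, broken, cfg)

    def test_noise_rates_converge_to_configuration(self):
        """Over ~2000 mentions the logged operation frequencies approach the
        configured probabilities within +-0.03."""
        cfg = GenConfig(docs=250, sentences_per_doc=5, mentions_per_sentence=2.0,
                        abbreviation_rate=1.0, p_literal=0.25,
                        p_abbrev_passthrough=0.5, seed=9)
        term = generate_terminology(cfg)
        docs = generate_corpus(term, cfg)
        lex = build_lexicon(term)
        ops, abbrev_total, abbrev_pass, total = [], 0, 0, 0
        for doc in docs:
            par = apply_translation_noise(doc, lex, cfg)
            for op, (s, e), _ in par.noise_log:
                total += 1
                ops.append(op)
                if is_abbreviation(doc.text[s:e]):
                    abbrev_total += 1
                    abbrev_pass += op == "abbrev_passthrough"
        assert total >= 2000
        lit_rate = ops.count("literal") / total
        assert abs(lit_rate - cfg.p_literal) < 0.03
        # passthrough competes with literal on abbreviations: expected share
        # among abbreviation mentions is p_abbrev_passthrough
        assert abs(abbrev_pass / abbrev_total - cfg.p_abbrev_passthrough) < 0.03

    def test_translation_is_deterministic(self, small_world):
        cfg, term, docs, lex = small_world
        a = apply_translation_noise(docs[0], lex, cfg)
        b = apply_translation_noise(docs[0], lex, cfg)
        assert a.target_text == b.target_text and a.noise_log == b.noise_log


class TestStandoff:
    def test_documented_example_lines(self, tmp_path):
        doc = AnnotatedDocument("d1", "echocardiography today",
                               [Mention(0, 16, "PROC", cui="C0013516")])
        write_standoff([doc], tmp_path)
        ann = (tmp_path / "d1.ann").read_text()
        assert "T1\tPROC 0 16\techocardiography" in ann
        assert "N1\tReference T1 UMLS:C0013516" in ann

    def test_empty_doc_round_trips_with_empty_ann(self, tmp_path):
        doc = AnnotatedDocument("d2", "no mentions here", [])
        write_standoff([doc], tmp_path)
        assert (tmp_path / "d2.ann").read_text() == ""
        [back] = read_standoff(tmp_path)
        assert back.text == doc.text and back.mentions == []

    def test_nested_mentions_survive_round_trip(self, tmp_path):
        doc = AnnotatedDocument("d3", "abcde fghij klmno pqrst uvwxy",
                               [Mention(0, 20, "DISO", cui="C0000001"),
                                Mention(6, 11, "CHEM", cui="C0000002")])
        write_standoff([doc], tmp_path)
        [back] = read_standoff(tmp_path)
        assert back.mentions == doc.sorted_mentions()

    def test_corpus_round_trip_is_identity(self, tmp_path, small_world):
        _, _, docs, _ = small_world
        write_standoff(docs, tmp_path)
        back = read_standoff(tmp_path)
        assert [(d.doc_id, d.text, tuple(d.sorted_mentions())) for d in docs] == \
            [(d.doc_id, d.text, tuple(d.sorted_mentions())) for d in back]

    def test_span_beyond_text_raises(self, tmp_path):
        (tmp_path / "bad.txt").write_text("short")
        (tmp_path / "bad.ann").write_text("T1\tPROC 0 99\tshort\n")
        with pytest.raises(StandoffError, match="exceeds"):
            read_standoff(tmp_path)

    def test_norm_line_referencing_unknown_span_raises(self, tmp_path):
        (tmp_path / "bad.txt").write_text("text here")
        (tmp_path / "bad.ann").write_text("N1\tReference T9 UMLS:C0000001\n")
        with pytest.raises(StandoffError, match="unknown"):
            read_standoff(tmp_path)


class TestSplit:
    @pytest.mark.parametrize("n,frac,expected", [
        (38, 0.8, (30, 8)),
        (42, 0.8, (34, 8)),
        (10, 0.5, (5, 5)),
    ])
    def test_split_sizes(self, n, frac, expected):
        docs = list(range(n))
        train, test = split_corpus(docs, frac, seed=3)
        assert (len(train), len(test)) == expected
        assert sorted(train + test) == docs
        assert not (set(train) & set(test))

    def test_split_is_seed_deterministic(self):
        docs = list(range(20))
        assert split_corpus(docs, 0.8, seed=4) == split_corpus(docs, 0.8, seed=4)
        assert split_corpus(docs, 0.8, seed=4) != split_corpus(docs, 0.8, seed=5)

    def test_tiny_or_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            split_corpus([1], 0.8, seed=0)
        with pytest.raises(ValueError):
            split_corpus([1, 2], 1.0, seed=0)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(p_literal=1.2), dict(nesting_rate=-0.1), dict(docs=0),
        dict(p_literal=0.7, p_abbrev_passthrough=0.7),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GenConfig(**kwargs)
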
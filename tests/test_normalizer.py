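"""Normalizer contracts: training phases, ranking, group filter, joint linker."""

import numpy as np
import pytest

from xlcui.normalizer import (ConceptIndex, HashEmbedder, IndexRow, NormConfig,
                              embed_term, exact_match_index,
                              joint_extract_and_link, load_index,
                              rank_candidates, save_index, select_cui,
                              train_normalizer)
from xlcui.synthetic import GenConfig, generate_terminology
from xlcui.terminology import Concept, Terminology, partition_terms_by_language_coverage


@pytest.fixture(scope="module")
def toy_terminology():
    """10 CUIs with well-separated surface strings, bilingual."""
    concepts = []
    words = ["balatone", "corimal", "dexavir", "eponium", "fexalol",
             "gabritex", "hilorin", "jupamab", "kelotran", "lisovex"]
    for i, w in enumerate(words):
        concepts.append(Concept(
            f"C{i + 1:07d}", "CHEM",
            [("FRE", w, True), ("FRE", f"{w} forte", False),
             ("ENG", w[::-1], True)]))
    return Terminology(concepts)


@pytest.fixture(scope="module")
def mixed_terminology():
    """Bilingual concepts plus ENG-only concepts for phase-2 coverage."""
    cfg = GenConfig(seed=13, concepts_per_group=4, ambiguous_pair_rate=0.0)
    base = generate_terminology(cfg)
    concepts = []
    for i, cui in enumerate(base.cuis()):
        c = base.concepts[cui]
        if i % 3 == 0:
            eng = [t for t in c.terms if t[0] == "ENG"]
            concepts.append(Concept(c.cui, c.group, eng))
        else:
            concepts.append(c)
    return Terminology(concepts)


@pytest.fixture(scope="module")
def phase1_index(toy_terminology):
    return train_normalizer(toy_terminology, NormConfig(seed=3, phase=1))


class TestPhase1:
    def test_self_retrieval_on_training_terms(self, toy_terminology, phase1_index):
        hits = 0
        for r in phase1_index.rows:
            hits += rank_candidates(r.term, phase1_index, 1)[0][0] == r.cui
        assert hits / len(phase1_index.rows) >= 0.95

    def test_empty_terminology_raises(self):
        with pytest.raises(ValueError):
            train_normalizer(Terminology([]), NormConfig(phase=1))

    def test_rows_are_unit_norm(self, phase1_index):
        assert np.allclose(np.linalg.norm(phase1_index.matrix, axis=1), 1.0,
                           atol=1e-6)


class TestPhase2:
    def test_requires_prior(self, mixed_terminology):
        with pytest.raises(ValueError, match="prior"):
            train_normalizer(mixed_terminology, NormConfig(phase=2))

    def test_freezes_encoder_and_shared_rows_adds_secondary_rows(self, mixed_terminology):
        cfg1 = NormConfig(seed=5, phase=1)
        idx1 = train_normalizer(mixed_terminology, cfg1)
        probe_before = idx1.embedder.embed("gabatolu proba").copy()
        idx2 = train_normalizer(mixed_terminology, NormConfig(seed=5, phase=2),
                                prior=idx1)
        _, sec = partition_terms_by_language_coverage(mixed_terminology, "FRE", "ENG")
        assert len(idx2) - len(idx1) == len(sec)
        assert {r.term for r in idx2.rows[len(idx1):]} == {t for _, _, t in sec}
        # encoder output bit-identical, phase-1 rows untouched
        assert np.array_equal(probe_before, idx2.embedder.embed("gabatolu proba"))
        assert np.array_equal(idx1.matrix, idx2.matrix[:len(idx1)])

    def test_phase2_without_secondary_terms_is_a_copy(self, toy_terminology, phase1_index):
        idx2 = train_normalizer(toy_terminology, NormConfig(seed=3, phase=2),
                                prior=phase1_index)
        assert len(idx2) == len(phase1_index)
        assert np.array_equal(idx2.matrix, phase1_index.matrix)


class TestEmbedding:
    def test_embeddings_are_unit_norm_and_deterministic(self, phase1_index):
        v1 = embed_term("balatone forte", phase1_index)
        v2 = embed_term("balatone forte", phase1_index)
        assert np.linalg.norm(v1) == pytest.approx(1.0, abs=1e-6)
        assert np.array_equal(v1, v2)

    def test_empty_string_raises(self, phase1_index):
        with pytest.raises(ValueError):
            embed_term("  ", phase1_index)

    def test_hash_embedder_separates_distinct_terms(self, toy_terminology):
        idx = exact_match_index(toy_terminology, {"FRE", "ENG"})
        M = idx.matrix
        cos = M @ M.T
        np.fill_diagonal(cos, 0.0)
        assert cos.max() < 0.5


class TestRanking:
    def test_exact_term_ranks_its_cui_first_with_cosine_one(self, toy_terminology):
        idx = exact_match_index(toy_terminology, {"FRE"})
        ranked = rank_candidates("balatone", idx, 3)
        assert ranked[0][0] == "C0000001"
        assert ranked[0][2] == pytest.approx(1.0, abs=1e-9)

    def test_k_larger_than_cui_count_returns_all(self, toy_terminology):
        idx = exact_match_index(toy_terminology, {"FRE"})
        assert len(rank_candidates("balatone", idx, 99)) == 10

    def test_cosine_ties_break_by_lexicographic_cui(self):
        emb = HashEmbedder(64)
        rows = [IndexRow("shared term", "C0000002", "DISO", "ENG"),
                IndexRow("shared term", "C0000001", "DISO", "ENG")]
        matrix = emb.embed_batch([r.term for r in rows])
        idx = ConceptIndex(emb, rows, matrix)
        ranked = rank_candidates("shared term", idx, 2)
        assert [c for c, _, _ in ranked] == ["C0000001", "C0000002"]

    def test_empty_index_raises(self):
        idx = ConceptIndex(HashEmbedder(16), [], np.zeros((0, 16)))
        with pytest.raises(ValueError):
            rank_candidates("x", idx, 1)

    def test_agrees_with_brute_force_cosine_scan(self, phase1_index):
        rng = np.random.default_rng(0)
        queries = [r.term for r in phase1_index.rows] + ["zorblat", "mixoped"]
        for q in queries:
            v = embed_term(q, phase1_index)
            best = {}
            for r, row in zip(phase1_index.rows, phase1_index.matrix):
                c = float(row @ v)
                if r.cui not in best or c > best[r.cui]:
                    best[r.cui] = c
            expected = sorted(best.items(), key=lambda it: (-it[1], it[0]))[:5]
            got = [(c, cos) for c, _, cos in rank_candidates(q, phase1_index, 5)]
            for (ec, ecos), (gc, gcos) in zip(expected, got):
                assert ec == gc and gcos == pytest.approx(ecos, abs=1e-12)


class TestGroupFilter:
    def test_first_in_group_within_k_wins(self):
        ranked = [("C1", "DISO", 0.9), ("C2", "PROC", 0.8)]
        sel = select_cui(ranked, "PROC", k=2)
        assert sel.cui == "C2" and not sel.fallback

    def test_k_window_limits_group_search(self):
        ranked = [("C1", "DISO", 0.9), ("C2", "PROC", 0.8)]
        sel = select_cui(ranked, "PROC", k=1)
        assert sel.cui == "C1" and sel.fallback

    def test_matching_top1_wins_regardless_of_k(self):
        ranked = [("C1", "PROC", 0.9), ("C2", "PROC", 0.8)]
        for k in (1, 2, 5):
            sel = select_cui(ranked, "PROC", k)
            assert sel.cui == "C1" and not sel.fallback

    def test_never_wrong_group_when_in_group_candidate_in_window(self):
        """Randomized check against a brute-force oracle."""
        rng = np.random.default_rng(12)
        groups = ["CHEM", "DEVI", "DISO", "PROC"]
        for _ in range(2000):
            n = int(rng.integers(1, 8))
            ranked = [(f"C{i:07d}", groups[rng.integers(4)],
                       float(rng.random())) for i in range(n)]
            ranked.sort(key=lambda t: -t[2])
            k = int(rng.integers(1, 7))
            target = groups[rng.integers(4)]
            sel = select_cui(ranked, target, k)
            oracle = next((c for c, g, _ in ranked[:k] if g == target), None)
            if oracle is not None:
                assert sel.cui == oracle and not sel.fallback
            else:
                assert sel.cui == ranked[0][0] and sel.fallback


class TestJointExtractor:
    def test_single_match_with_linked_cui(self, ambiguity_terminology):
        mentions = joint_extract_and_link("echocardiography now",
                                          ambiguity_terminology, "ENG")
        assert len(mentions) == 1
        m = mentions[0]
        assert (m.start, m.end, m.label, m.cui) == (0, 16, "PROC", "C0013516")

    def test_no_terminology_term_means_no_mentions(self, ambiguity_terminology):
        assert joint_extract_and_link("nothing to see here",
                                      ambiguity_terminology, "ENG") == []

    def test_longest_match_beats_single_token_misses(self, ambiguity_terminology):
        text = "had cardiac ultrasound done"
        mentions = joint_extract_and_link(text, ambiguity_terminology, "ENG")
        assert len(mentions) == 1
        m = mentions[0]
        assert text[m.start:m.end] == "cardiac ultrasound"
        assert m.cui == "C1655737"

    def test_multi_cui_string_links_smallest_cui(self):
        term = Terminology([
            Concept("C0000002", "DISO", [("ENG", "shared term", True)]),
            Concept("C0000001", "DISO", [("ENG", "shared term", True)]),
        ])
        [m] = joint_extract_and_link("a shared term b", term, "ENG")
        assert m.cui == "C0000001"

    def test_matches_do_not_overlap(self, small_world):
        _, term, docs, _ = small_world
        for doc in docs[:4]:
            ms = joint_extract_and_link(doc.text, term, "FRE")
            ms = sorted(ms)
            for a, b in zip(ms, ms[1:]):
                assert a.end <= b.start


class TestPersistence:
    def test_index_round_trip(self, tmp_path, phase1_index):
        path = tmp_path / "index.npz"
        save_index(phase1_index, path)
        loaded = load_index(path)
        assert [r.term for r in loaded.rows] == [r.term for r in phase1_index.rows]
        assert np.array_equal(loaded.matrix, phase1_index.matrix)
        q = "balatone"
        assert rank_candidates(q, loaded, 3) == rank_candidates(q, phase1_index, 3)
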
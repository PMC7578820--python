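import numpy as np
import pytest

from clinkg.linking import (
    Concept,
    Dictionary,
    KnowledgeBase,
    cosine_similarity,
    dedupe,
    default_dictionaries,
    dictionary_expand,
    hierarchical_match,
    knowledge_base_from_lexicons,
    link_key,
    link_mentions,
    similarity_rank,
)
from clinkg.synth import GeneratorConfig, generate_corpus
from clinkg.types import Mention


def _m(surface, sem_type, start=0, doc="d"):
    return Mention(doc, start, start + len(surface), surface, sem_type)


@pytest.fixture(scope="module")
def kb(schema):
    concepts = [
        Concept("C1", "disease", "胃癌", nonpreferred_terms=("胃恶性肿瘤",)),
        Concept("C2", "disease", "直肠腺癌"),
        Concept("C3", "surgery", "胃癌根治术", nonpreferred_terms=("根治性胃癌根治术",)),
        Concept("C4", "symptom", "恶心"),
        Concept("C5", "body structure", "直肠"),
        Concept("C6", "cancer", "结肠癌"),
    ]
    return KnowledgeBase(concepts=concepts, schema=schema)


@pytest.fixture(scope="module")
def dicts():
    d = {c: Dictionary(c) for c in ("disease", "surgery")}
    d["surgery"].entries["胃癌根治"] = "胃癌根治术"
    d["disease"].entries["胃Ca"] = "胃癌"
    return d


class TestDedupe:
    def test_unique_keys(self):
        ms = [_m("恶心", "symptom"), _m("恶心", "symptom", 5),
              _m("呕吐", "symptom", 10), _m("恶心", "sign", 15),
              _m("恶心", "symptom", 20)]
        keys, backrefs = dedupe(ms)
        assert len(keys) == 3
        assert sum(len(v) for v in backrefs.values()) == len(ms)

    def test_empty(self):
        keys, backrefs = dedupe([])
        assert keys == [] and backrefs == {}

    def test_fanout_restores_count(self, kb, dicts):
        docs = generate_corpus(GeneratorConfig(n_patients=5, seed=2))
        for d in docs:
            results = link_mentions(d.mentions, kb, dicts)
            assert len(results) == len(d.mentions)


class TestHierarchicalMatch:
    def test_preferred_term_exact(self, kb):
        r = hierarchical_match(("胃癌", "disease"), kb)
        assert (r.concept_id, r.method, r.score) == ("C1", "exact-concept", 1.0)

    def test_synonym_is_exact_property(self, kb):
        r = hierarchical_match(("胃恶性肿瘤", "disease"), kb)
        assert (r.concept_id, r.method) == ("C1", "exact-property")

    def test_class_scoping_blocks_other_class(self, kb):
        # 恶心 is a symptom concept; a disease-typed key must not match it
        assert hierarchical_match(("恶心", "disease"), kb) is None

    def test_subclass_concept_matches_parent_scope(self, kb):
        # C6 is "cancer", a subclass of disease
        r = hierarchical_match(("结肠癌", "disease"), kb)
        assert r.concept_id == "C6"

    def test_unknown_sem_type_rejected(self, kb):
        with pytest.raises(ValueError):
            hierarchical_match(("x", "tumor size"), kb)

    def test_scoping_equals_brute_force_filter(self, kb, schema, lexicons):
        big = knowledge_base_from_lexicons(lexicons, schema)
        rng = np.random.default_rng(0)
        surfaces = [(c.preferred_term, c.class_name) for c in big.concepts]
        sem_of = {"disease": "disease", "symptom": "symptom", "sign": "sign",
                  "surgery": "surgery", "medicine": "medicine", "test": "test",
                  "body structure": "body structure", "disease type": "disease type"}
        for _ in range(200):
            surface, cls = surfaces[int(rng.integers(len(surfaces)))]
            key = (surface, sem_of[cls])
            got = hierarchical_match(key, big)
            # brute force: unscoped scan filtered by class afterwards
            expected = [
                c for c in big.concepts
                if c.preferred_term == surface
                and big.schema.class_satisfies(c.class_name, cls)
            ]
            assert got is not None and got.concept_id == expected[0].concept_id


class TestDictionaryExpand:
    def test_expansion_example(self, dicts):
        assert dictionary_expand(("胃癌根治", "surgery"), dicts) == ["胃癌根治术"]

    def test_absent_surface_empty(self, dicts):
        assert dictionary_expand(("不存在", "surgery"), dicts) == []

    def test_never_returns_input(self, dicts):
        dicts2 = {"surgery": Dictionary("surgery", {"环": "环"})}
        assert dictionary_expand(("环", "surgery"), dicts2) == []

    def test_expanded_then_exact(self, kb, dicts):
        r = link_key(("胃癌根治", "surgery"), kb, dicts)
        assert (r.concept_id, r.method, r.score) == ("C3", "dictionary-expanded", 1.0)

    def test_six_default_categories(self):
        assert len(default_dictionaries()) == 6


class TestSimilarity:
    def test_identical_strings(self):
        assert cosine_similarity("胃癌根治术", "胃癌根治术") == pytest.approx(1.0)

    def test_disjoint_characters(self):
        assert cosine_similarity("abc", "xyz") == pytest.approx(0.0)

    def test_rank_identical_first(self, kb):
        ranked = similarity_rank(("胃癌根治术", "surgery"),
                                 kb.concepts_of_class("surgery"), threshold=0.2)
        assert ranked[0].concept_id == "C3"
        assert ranked[0].score == pytest.approx(1.0)

    def test_ranking_equals_brute_force(self, schema, lexicons):
        big = knowledge_base_from_lexicons(lexicons, schema)
        cands = big.concepts_of_class("disease")[:10]
        key = ("胃部腺癌", "disease")
        ranked = similarity_rank(key, cands, threshold=0.0)
        brute = sorted(
            (
                (
                    c.concept_id,
                    max(
                        cosine_similarity(key[0], t)
                        for t in (c.preferred_term, *c.nonpreferred_terms)
                    ),
                )
                for c in cands
            ),
            key=lambda x: (-x[1], x[0]),
        )
        assert [(r.concept_id, pytest.approx(r.score)) for r in ranked
                if r.concept_id is not None] == [
            (cid, pytest.approx(s)) for cid, s in brute if s >= 0.0
        ][: sum(r.concept_id is not None for r in ranked)]
        assert [r.score for r in ranked] == sorted(
            (r.score for r in ranked), reverse=True
        )

    def test_below_threshold_unlinked(self, kb):
        ranked = similarity_rank(("xyz", "surgery"),
                                 kb.concepts_of_class("surgery"), threshold=0.5)
        assert all(r.concept_id is None for r in ranked)

    def test_duplicated_synonyms_do_not_change_ranking(self, kb):
        key = ("胃癌根治手术", "surgery")
        base = similarity_rank(key, kb.concepts_of_class("surgery"), 0.0)
        dup = [
            Concept(c.concept_id, c.class_name, c.preferred_term,
                    nonpreferred_terms=c.nonpreferred_terms * 3)
            for c in kb.concepts_of_class("surgery")
        ]
        doubled = similarity_rank(key, dup, 0.0)
        assert [(r.concept_id, r.score) for r in base] == [
            (r.concept_id, r.score) for r in doubled
        ]


class TestPriority:
    def test_exact_match_wins_over_similarity(self, kb, dicts):
        # near-identical synonym exists elsewhere, but exact match must win
        r = link_key(("胃癌", "disease"), kb, dicts)
        assert r.method == "exact-concept"

    def test_similarity_only_when_no_exact(self, kb):
        r = link_key(("胃癌根治手术", "surgery"), kb, threshold=0.3)
        assert r.method == "similarity"
        assert r.concept_id == "C3"
        assert r.score < 1.0


class TestEndToEnd:
    def test_synthetic_corpus_links_perfectly(self, schema):
        cfg = GeneratorConfig(n_patients=40, seed=19, synonym_rate=0.5)
        rng = np.random.default_rng(cfg.seed)
        from clinkg.synth import build_lexicons

        lex = build_lexicons(cfg, rng)
        kb = knowledge_base_from_lexicons(lex, schema)
        dicts = default_dictionaries(lex)
        canon = {}
        for entries in lex.values():
            for e in entries:
                canon[e.canonical] = e.canonical
                for v in e.variants:
                    canon[v] = e.canonical
        pref_of = {c.concept_id: c.preferred_term for c in kb.concepts}
        for doc in generate_corpus(cfg):
            for m, r in zip(doc.mentions, link_mentions(doc.mentions, kb, dicts)):
                if r is None:
                    continue
                assert r.concept_id is not None, m.surface
                assert pref_of[r.concept_id] == canon[m.surface]
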
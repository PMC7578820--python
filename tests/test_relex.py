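import numpy as np
import pytest

from clinkg.relex import (
    REHyperparameters,
    auto_label_corpus,
    candidates_from_document,
    classify,
    generate_candidates,
    split_sentences,
    train_re,
    word_attention,
)
from clinkg.synth import GeneratorConfig, generate_corpus
from clinkg.types import Mention, span_type_to_class

FAST_HP = REHyperparameters(
    embedding_dim=16, word_hidden=16, sent_hidden=12,
    learning_rate=0.006, epochs=10, seed=0, patience=4,
)


def _m(doc, start, surface, sem_type):
    return Mention(doc, start, start + len(surface), surface, sem_type)


def _labeled_pairs(docs, schema):
    pairs = []
    for d in docs:
        gold = {}
        for r in d.relations:
            if isinstance(r.head, Mention) and r.label != "attribute_of":
                key = frozenset([(r.head.start, r.head.end),
                                 (r.tail.start, r.tail.end)])
                gold[key] = r.label
        for c in candidates_from_document(d, schema):
            key = frozenset([(c.head.start, c.head.end),
                             (c.tail.start, c.tail.end)])
            if key in gold:
                pairs.append((c, gold[key]))
    return pairs


class TestSplitSentences:
    def test_three_sentences(self):
        assert [s[2] for s in split_sentences("A。B！C")] == ["A。", "B！", "C"]

    def test_no_terminal_punctuation(self):
        assert [s[2] for s in split_sentences("ABC")] == ["ABC"]

    def test_reconstruction(self, small_corpus):
        for doc in small_corpus:
            pieces = split_sentences(doc.text)
            assert "".join(p[2] for p in pieces) == doc.text
            for start, end, text in pieces:
                assert doc.text[start:end] == text


class TestCandidates:
    def test_one_test_two_findings(self, schema):
        sent = (0, 20, "X" * 20)
        ms = [_m("d", 0, "胃镜", "test"), _m("d", 5, "恶心", "symptom"),
              _m("d", 10, "压痛", "sign")]
        cands = generate_candidates(sent, ms, schema)
        assert len(cands) == 2
        for c in cands:
            assert set(c.allowed) <= {"TeRS", "TeAS"}
            assert c.auto_label is None

    def test_single_type_no_candidates(self, schema):
        sent = (0, 10, "X" * 10)
        ms = [_m("d", 0, "恶心", "symptom"), _m("d", 4, "呕吐", "symptom")]
        assert generate_candidates(sent, ms, schema) == []

    def test_findings_body_structure_auto_loci(self, schema):
        sent = (0, 20, "X" * 20)
        ms = [_m("d", 0, "恶心", "symptom"), _m("d", 5, "压痛", "sign"),
              _m("d", 10, "胃体", "body structure")]
        cands = generate_candidates(sent, ms, schema)
        assert len(cands) == 2
        assert all(c.auto_label == "LOCI" for c in cands)

    def test_count_matches_pairwise_brute_force(self, schema, small_corpus):
        for doc in small_corpus[:10]:
            for sent in split_sentences(doc.text):
                in_sent = [m for m in doc.mentions
                           if m.start >= sent[0] and m.end <= sent[1]
                           and span_type_to_class(m.sem_type)]
                expected = 0
                for i, a in enumerate(in_sent):
                    for b in in_sent[i + 1:]:
                        if a.sem_type == b.sem_type:
                            continue
                        if schema.allowed_relations(
                            span_type_to_class(a.sem_type),
                            span_type_to_class(b.sem_type),
                        ):
                            expected += 1
                assert len(generate_candidates(sent, doc.mentions, schema)) == expected


class TestAutoLabel:
    def test_partition_conservation(self, schema, small_corpus):
        cands = [c for d in small_corpus
                 for c in candidates_from_document(d, schema)]
        labeled, ambiguous = auto_label_corpus(cands)
        assert len(labeled) + len(ambiguous) == len(cands)
        assert all(c.auto_label is not None for c in labeled)
        assert all(c.auto_label is None for c in ambiguous)

    def test_disease_test_always_ambiguous(self, schema):
        sent = (0, 20, "X" * 20)
        ms = [_m("d", 0, "胃镜", "test"), _m("d", 5, "胃癌", "disease")]
        cands = generate_candidates(sent, ms, schema)
        _labeled, ambiguous = auto_label_corpus(cands)
        assert len(ambiguous) == 1
        assert set(ambiguous[0].allowed) == {"TeCD", "TeRD"}


class TestWordAttention:
    def test_length_one(self):
        out, w = word_attention(np.array([[1.0, 2.0]]))
        assert w.tolist() == [1.0]
        assert out.tolist() == [1.0, 2.0]

    def test_identical_states_uniform(self):
        H = np.tile(np.array([1.0, -1.0, 2.0]), (4, 1))
        _out, w = word_attention(H, weights_vector=np.array([0.3, -0.2, 0.5]))
        assert np.allclose(w, 0.25)

    def test_weighted_sum_oracle(self):
        rng = np.random.default_rng(0)
        H = rng.normal(size=(6, 5))
        v = rng.normal(size=5)
        out, w = word_attention(H, v)
        assert w.min() >= 0 and w.sum() == pytest.approx(1.0)
        scores = H @ v
        e = np.exp(scores - scores.max())
        expected = (e / e.sum()) @ H
        assert np.allclose(out, expected, atol=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            word_attention(np.zeros((0, 3)))


@pytest.fixture(scope="module")
def trained_re(schema):
    docs = generate_corpus(GeneratorConfig(n_patients=120, seed=31))
    pairs = _labeled_pairs(docs, schema)
    split = int(len(pairs) * 0.85)
    model = train_re(pairs[:split], FAST_HP)
    return model, pairs[split:]


class TestTraining:
    def test_single_label_rejected(self, schema):
        docs = generate_corpus(
            GeneratorConfig(n_patients=10, seed=1, relation_mix={"LOCI": 1.0},
                            list_sentence_prob=0.0, property_sentence_prob=0.0)
        )
        pairs = _labeled_pairs(docs, schema)
        with pytest.raises(ValueError):
            train_re(pairs, FAST_HP)

    def test_seeded_determinism(self, schema):
        docs = generate_corpus(GeneratorConfig(n_patients=30, seed=8))
        pairs = _labeled_pairs(docs, schema)
        hp = REHyperparameters(**{**FAST_HP.__dict__, "epochs": 1})
        m1, m2 = train_re(pairs, hp), train_re(pairs, hp)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k]), k

    def test_held_out_accuracy(self, trained_re):
        model, held_out = trained_re
        correct = sum(int(classify(model, c).label == lab) for c, lab in held_out)
        assert correct / len(held_out) >= 0.8

    def test_shuffled_labels_near_chance(self, schema):
        docs = generate_corpus(GeneratorConfig(n_patients=60, seed=77))
        pairs = _labeled_pairs(docs, schema)
        rng = np.random.default_rng(0)
        labels = [lab for _c, lab in pairs]
        shuffled = list(rng.permutation(labels))
        noisy = [(c, lab) for (c, _), lab in zip(pairs, shuffled)]
        split = int(len(noisy) * 0.8)
        model = train_re(noisy[:split], FAST_HP)
        test = noisy[split:]
        # restrict to pairs where the shuffled label is even admissible
        scoreable = [(c, lab) for c, lab in test if lab in c.allowed]
        if scoreable:
            acc = sum(
                int(classify(model, c).label == lab) for c, lab in scoreable
            ) / len(scoreable)
            assert acc <= 0.75  # far from the separable-corpus ~1.0


class TestClassify:
    def test_unique_allowed_forces_label(self, schema, trained_re):
        model, held_out = trained_re
        for c, _lab in held_out:
            if len(c.allowed) == 1:
                inst = classify(model, c)
                assert inst.label == next(iter(c.allowed))
                assert inst.confidence == 1.0
                break
        else:
            pytest.skip("no unambiguous candidate in held-out sample")

    def test_confidence_in_unit_interval(self, trained_re):
        model, held_out = trained_re
        for c, _lab in held_out[:50]:
            inst = classify(model, c)
            assert 0.0 <= inst.confidence <= 1.0

    def test_predictions_always_schema_valid(self, schema, trained_re):
        model, held_out = trained_re
        for c, _lab in held_out:
            inst = classify(model, c)
            head_cls = span_type_to_class(inst.head.sem_type)
            tail_cls = span_type_to_class(inst.tail.sem_type)
            assert schema.validate_edge(head_cls, inst.label, tail_cls) == "valid"

    def test_empty_allowed_rejected(self, trained_re):
        model, _ = trained_re
        from clinkg.relex import RelationCandidate

        cand = RelationCandidate(
            doc_id="d", sentence_start=0, sentence_text="xy",
            head=_m("d", 0, "x", "symptom"), tail=_m("d", 1, "y", "symptom"),
            allowed={},
        )
        with pytest.raises(ValueError):
            classify(model, cand)
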
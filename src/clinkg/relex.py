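"""Type-pair-constrained relation extraction.

Pipeline: break documents into sentences, group each sentence's entity
mentions by span type, emit one candidate per cross-type mention pair whose
type pair admits at least one schema relation, auto-label candidates whose
type pair admits exactly one, and classify the ambiguous rest with a
character-level BiGRU using attention at the word level and — for entity
pairs observed in several sentences — at the sentence level.  Predicted
labels are renormalised over the schema-admissible set, so no emitted
relation can violate the schema.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .nn import (
    Adam,
    Attention,
    BiRecurrent,
    GRULayer,
    Linear,
    clip_gradients,
    softmax,
    softmax_cross_entropy,
)
from .schema import SchemaGraph
from .types import GoldDocument, Mention, RelationInstance, span_type_to_class

__all__ = [
    "split_sentences",
    "RelationCandidate",
    "generate_candidates",
    "candidates_from_document",
    "auto_label_corpus",
    "word_attention",
    "REHyperparameters",
    "REModel",
    "train_re",
    "classify",
]

_SENTENCE_BOUNDARY = set("。！？；;\n")

HEAD_OPEN, HEAD_CLOSE = "<h>", "</h>"
TAIL_OPEN, TAIL_CLOSE = "<t>", "</t>"
UNK = "<unk>"


def split_sentences(text: str) -> list[tuple[int, int, str]]:
    """(start, end, text) spans; delimiters stay attached, so concatenating
    the pieces reconstructs the input exactly."""
    out = []
    start = 0
    for i, ch in enumerate(text):
        if ch in _SENTENCE_BOUNDARY:
            out.append((start, i + 1, text[start : i + 1]))
            start = i + 1
    if start < len(text):
        out.append((start, len(text), text[start:]))
    return out


@dataclass
class RelationCandidate:
    """A candidate pair inside one sentence, in textual order."""

    doc_id: str
    sentence_start: int
    sentence_text: str
    head: Mention
    tail: Mention
    #: admissible labels -> canonical direction ("forward": head->tail)
    allowed: dict[str, str] = field(default_factory=dict)
    auto_label: str | None = None


def generate_candidates(
    sentence: tuple[int, int, str],
    mentions: Sequence[Mention],
    schema: SchemaGraph,
) -> list[RelationCandidate]:
    """Cross product of mention groups over admissible type pairs.

    Mentions are grouped by span type; same-type pairs yield nothing; a
    candidate carries ``auto_label`` when its type pair admits exactly one
    relation label.
    """
    start, end, text = sentence
    groups: dict[str, list[Mention]] = {}
    for m in mentions:
        if m.start < start or m.end > end:
            continue
        if span_type_to_class(m.sem_type) is None:
            continue  # property spans are attached structurally, not classified
        groups.setdefault(m.sem_type, []).append(m)
    types = sorted(groups)
    out: list[RelationCandidate] = []
    for i, t_a in enumerate(types):
        for t_b in types[i + 1 :]:
            cls_a = span_type_to_class(t_a)
            cls_b = span_type_to_class(t_b)
            if not schema.allowed_relations(cls_a, cls_b):
                continue
            for m_a in groups[t_a]:
                for m_b in groups[t_b]:
                    head, tail = (m_a, m_b) if m_a.start <= m_b.start else (m_b, m_a)
                    allowed = schema.allowed_relations(
                        span_type_to_class(head.sem_type),
                        span_type_to_class(tail.sem_type),
                    )
                    out.append(
                        RelationCandidate(
                            doc_id=head.doc_id,
                            sentence_start=start,
                            sentence_text=text,
                            head=head,
                            tail=tail,
                            allowed=allowed,
                            auto_label=(
                                next(iter(allowed)) if len(allowed) == 1 else None
                            ),
                        )
                    )
    return out


def candidates_from_document(
    doc: GoldDocument, schema: SchemaGraph
) -> list[RelationCandidate]:
    out = []
    for sent in split_sentences(doc.text):
        out.extend(generate_candidates(sent, doc.mentions, schema))
    return out


def auto_label_corpus(
    candidates: Sequence[RelationCandidate],
) -> tuple[list[RelationCandidate], list[RelationCandidate]]:
    """Partition into (auto-labeled, ambiguous); counts are conserved."""
    labeled = [c for c in candidates if len(c.allowed) == 1]
    ambiguous = [c for c in candidates if len(c.allowed) != 1]
    return labeled, ambiguous


def word_attention(
    hidden_states: np.ndarray, weights_vector: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Attention pooling: nonnegative weights summing to 1 over positions.

    With no (or a zero) scoring vector the weights are uniform.
    """
    H = np.asarray(hidden_states, dtype=float)
    if H.ndim != 2 or len(H) == 0:
        raise ValueError("hidden_states must be a nonempty (T, H) array")
    v = np.zeros(H.shape[1]) if weights_vector is None else np.asarray(weights_vector)
    weights = softmax(H @ v)
    return weights @ H, weights


@dataclass
class REHyperparameters:
    embedding_dim: int = 48
    word_hidden: int = 48
    sent_hidden: int = 32
    learning_rate: float = 0.002
    batch_size: int = 32
    epochs: int = 10
    seed: int = 0
    clip: float = 5.0
    patience: int = 3
    val_fraction: float = 0.1


def _bag_key(c: RelationCandidate) -> tuple:
    return (c.doc_id, c.head.surface, c.head.sem_type, c.tail.surface, c.tail.sem_type)


def _tokens(c: RelationCandidate) -> list[str]:
    """Sentence characters with positional markers around head and tail."""
    rel = c.sentence_start
    inserts = sorted(
        [
            (c.head.start - rel, HEAD_OPEN),
            (c.head.end - rel, HEAD_CLOSE),
            (c.tail.start - rel, TAIL_OPEN),
            (c.tail.end - rel, TAIL_CLOSE),
        ],
        key=lambda x: x[0],
    )
    out: list[str] = []
    pos = 0
    for at, marker in inserts:
        out.extend(c.sentence_text[pos:at])
        out.append(marker)
        pos = at
    out.extend(c.sentence_text[pos:])
    return out


class REModel:
    """BiGRU encoder with word- and sentence-level attention."""

    def __init__(self, vocab: dict[str, int], labels: list[str],
                 hp: REHyperparameters):
        self.vocab = vocab
        self.labels = labels
        self.hp = hp
        rng = np.random.default_rng(hp.seed)
        wh, sh = hp.word_hidden, hp.sent_hidden
        self._wf = GRULayer(rng, hp.embedding_dim, wh)
        self._wb = GRULayer(rng, hp.embedding_dim, wh)
        self.word_gru = BiRecurrent(self._wf, self._wb)
        self.word_attn = Attention(rng, 2 * wh)
        self._sf = GRULayer(rng, 2 * wh, sh)
        self._sb = GRULayer(rng, 2 * wh, sh)
        self.sent_gru = BiRecurrent(self._sf, self._sb)
        self.sent_attn = Attention(rng, 2 * sh)
        self.out = Linear(rng, 2 * sh, len(labels))
        self.params: dict[str, np.ndarray] = {
            "emb": rng.normal(0, 0.1, size=(len(vocab), hp.embedding_dim))
        }
        for name, layer in [
            ("wf", self._wf), ("wb", self._wb), ("sf", self._sf), ("sb", self._sb),
            ("wa", self.word_attn), ("sa", self.sent_attn), ("out", self.out),
        ]:
            for k, arr in layer.params.items():
                self.params[f"{name}_{k}"] = arr

    def _ids(self, tokens: list[str]) -> np.ndarray:
        unk = self.vocab[UNK]
        return np.array([self.vocab.get(t, unk) for t in tokens], dtype=int)

    def _forward(self, bag: list[list[str]]):
        caches = []
        vecs = np.zeros((len(bag), 2 * self.hp.word_hidden))
        for i, tokens in enumerate(bag):
            ids = self._ids(tokens)
            X = self.params["emb"][ids]
            H, rc = self.word_gru.forward(X)
            u, _w, ac = self.word_attn.forward(H)
            vecs[i] = u
            caches.append((ids, rc, ac))
        S, src = self.sent_gru.forward(vecs)
        z, _w, sac = self.sent_attn.forward(S)
        logits, lc = self.out.forward(z)
        return logits, (caches, vecs, src, sac, lc)

    def logits(self, bag: list[list[str]]) -> np.ndarray:
        return self._forward(bag)[0]

    def loss_and_grads(self, bag: list[list[str]], target: int):
        logits, cache = self._forward(bag)
        loss, _p, dlogits = softmax_cross_entropy(logits, target)
        caches, vecs, src, sac, lc = cache
        grads: dict[str, np.ndarray] = {}

        def put(prefix: str, g: dict) -> None:
            for k, v in g.items():
                key = f"{prefix}_{k}"
                grads[key] = grads.get(key, 0.0) + v

        dz, g_out = self.out.backward(dlogits, lc)
        put("out", g_out)
        dS, g_sa = self.sent_attn.backward(dz, sac)
        put("sa", g_sa)
        dvecs, g_sf, g_sb = self.sent_gru.backward(dS, src)
        put("sf", g_sf)
        put("sb", g_sb)
        d_emb = np.zeros_like(self.params["emb"])
        for i, (ids, rc, ac) in enumerate(caches):
            dH, g_wa = self.word_attn.backward(dvecs[i], ac)
            put("wa", g_wa)
            dX, g_wf, g_wb = self.word_gru.backward(dH, rc)
            put("wf", g_wf)
            put("wb", g_wb)
            np.add.at(d_emb, ids, dX)
        grads["emb"] = d_emb
        return loss, grads


def train_re(
    labeled: Sequence[tuple[RelationCandidate, str]],
    hp: REHyperparameters | None = None,
    verbose: bool = False,
) -> REModel:
    """Train the relation classifier on (candidate, gold label) pairs.

    Instances sharing an entity pair within a document form one bag scored
    jointly through the sentence-level stage.  Seeded; returns the
    checkpoint with the best held-out accuracy.
    """
    hp = hp or REHyperparameters()
    label_set = sorted({lab for _c, lab in labeled})
    if len(label_set) < 2:
        raise ValueError("need at least 2 distinct labels to train")
    bags: dict[tuple, tuple[list[list[str]], str]] = {}
    for cand, lab in labeled:
        key = (_bag_key(cand), lab)
        bags.setdefault(key, ([], lab))[0].append(_tokens(cand))
    data = list(bags.values())
    chars = sorted({t for toks, _ in data for sent in toks for t in sent})
    vocab = {UNK: 0, HEAD_OPEN: 1, HEAD_CLOSE: 2, TAIL_OPEN: 3, TAIL_CLOSE: 4}
    for ch in chars:
        vocab.setdefault(ch, len(vocab))
    model = REModel(vocab, label_set, hp)
    lab_idx = {l: i for i, l in enumerate(label_set)}

    rng = np.random.default_rng(hp.seed)
    order = rng.permutation(len(data))
    n_val = max(1, int(len(data) * hp.val_fraction))
    val_idx = order[:n_val]
    train_idx = order[n_val:]
    if len(train_idx) == 0:
        train_idx = order
    opt = Adam(lr=hp.learning_rate)
    best_acc = -1.0
    best_params = copy.deepcopy(model.params)
    stale = 0
    for epoch in range(hp.epochs):
        perm = rng.permutation(len(train_idx))
        total = 0.0
        for b0 in range(0, len(perm), hp.batch_size):
            batch = [train_idx[i] for i in perm[b0 : b0 + hp.batch_size]]
            acc_g: dict[str, np.ndarray] = {}
            for idx in batch:
                toks, lab = data[idx]
                loss, grads = model.loss_and_grads(toks, lab_idx[lab])
                total += loss
                for k, g in grads.items():
                    acc_g[k] = acc_g.get(k, 0.0) + g
            acc_g = {k: g / len(batch) for k, g in acc_g.items()}
            acc_g = clip_gradients(acc_g, hp.clip)
            opt.step(model.params, acc_g)
        correct = sum(
            int(np.argmax(model.logits(data[i][0])) == lab_idx[data[i][1]])
            for i in val_idx
        )
        acc = correct / len(val_idx)
        if verbose:
            print(f"epoch {epoch + 1}: loss={total:.2f} val_acc={acc:.4f}")
        if acc > best_acc:
            best_acc = acc
            best_params = copy.deepcopy(model.params)
            stale = 0
        else:
            stale += 1
            if stale >= hp.patience:
                break
    for k in model.params:
        model.params[k][...] = best_params[k]
    return model


def classify(model: REModel, candidate: RelationCandidate) -> RelationInstance:
    """Predict a schema-admissible label with confidence in [0, 1].

    Scores are renormalised over ``candidate.allowed``; the returned
    instance is oriented along the predicted label's canonical direction.
    """
    if not candidate.allowed:
        raise ValueError("candidate has an empty allowed set")
    allowed = sorted(candidate.allowed)
    if len(allowed) == 1:
        label, conf = allowed[0], 1.0
    else:
        logits = model.logits([_tokens(candidate)])
        idx = {l: i for i, l in enumerate(model.labels)}
        scores = np.array(
            [logits[idx[l]] if l in idx else -1e30 for l in allowed]
        )
        if np.all(scores <= -1e29):
            scores = np.zeros(len(allowed))
        probs = softmax(scores)
        k = int(np.argmax(probs))
        label, conf = allowed[k], float(probs[k])
    if candidate.allowed[label] == "forward":
        head, tail = candidate.head, candidate.tail
    else:
        head, tail = candidate.tail, candidate.head
    provenance = "rule" if len(candidate.allowed) == 1 else "classifier"
    return RelationInstance(
        doc_id=candidate.doc_id,
        label=label,
        head=head,
        tail=tail,
        provenance=provenance,
        confidence=conf,
    )
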
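"""Character-level BiLSTM-CRF named-entity recognition.

The tagger labels characters with BIO tags over the 12 span types (8 entity
types + 4 property types).  Four feature families feed the recurrent layer:
the character itself (embedded), the part-of-speech of the containing word,
the character's position in the sentence, and per-dictionary membership
flags.  The CRF layer scores whole label sequences; training minimises the
negative log-likelihood and decoding uses Viterbi.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np

from . import crf
from .bio import bio_to_spans, spans_to_bio
from .nn import Adam, BiRecurrent, LSTMLayer, clip_gradients, dropout_mask
from .relex import split_sentences
from .types import GoldDocument, Mention, SPAN_TYPES

__all__ = [
    "CharacterFeatures",
    "Hyperparameters",
    "Segmenter",
    "CharSegmenter",
    "RuleSegmenter",
    "featurize",
    "SequenceModel",
    "train",
    "tag_document",
]

UNK = "<unk>"


class Segmenter(Protocol):
    """Pluggable word segmenter + POS tagger."""

    def segment(self, text: str) -> list[tuple[str, str]]:
        """Return (word, pos) pairs covering ``text`` exactly."""
        ...


class CharSegmenter:
    """Trivial fallback: every character is its own word with POS 'x'."""

    def segment(self, text: str) -> list[tuple[str, str]]:
        return [(ch, "x") for ch in text]


class RuleSegmenter:
    """Greedy maximal forward match over a word list; non-matches are
    single characters with POS 'x', punctuation 'w'."""

    _PUNCT = set("，。；！？、,.;!?")

    def __init__(self, words: Mapping[str, str]):
        self.words = dict(words)
        self.max_len = max((len(w) for w in self.words), default=1)

    def segment(self, text: str) -> list[tuple[str, str]]:
        out = []
        i = 0
        while i < len(text):
            for length in range(min(self.max_len, len(text) - i), 1, -1):
                cand = text[i : i + length]
                if cand in self.words:
                    out.append((cand, self.words[cand]))
                    i += length
                    break
            else:
                ch = text[i]
                out.append((ch, "w" if ch in self._PUNCT else "x"))
                i += 1
        return out


@dataclass(frozen=True)
class CharacterFeatures:
    char: str
    pos_tag: str
    position: int
    dict_flags: tuple[bool, ...]


def featurize(
    sentence: str,
    dictionaries: Mapping[str, Sequence[str]] | None = None,
    segmenter: Segmenter | None = None,
) -> list[CharacterFeatures]:
    """One feature record per character; deterministic.

    The POS tag of a character is the tag of the word containing it; a
    dictionary flag is set when the character lies inside an occurrence of
    any term of that dictionary.
    """
    if not sentence:
        return []
    segmenter = segmenter or CharSegmenter()
    dictionaries = dictionaries or {}
    pos_per_char: list[str] = []
    for word, pos in segmenter.segment(sentence):
        pos_per_char.extend([pos] * len(word))
    if len(pos_per_char) != len(sentence):
        raise ValueError("segmenter output does not cover the sentence")

    categories = sorted(dictionaries)
    flags = [[False] * len(categories) for _ in sentence]
    for ci, cat in enumerate(categories):
        terms = set(dictionaries[cat])
        max_len = max((len(t) for t in terms), default=0)
        for i in range(len(sentence)):
            for length in range(1, min(max_len, len(sentence) - i) + 1):
                if sentence[i : i + length] in terms:
                    for k in range(i, i + length):
                        flags[k][ci] = True
    return [
        CharacterFeatures(ch, pos_per_char[i], i, tuple(flags[i]))
        for i, ch in enumerate(sentence)
    ]


@dataclass
class Hyperparameters:
    """Defaults follow the reference configuration: 100-dim character
    embeddings, batch size 50, learning rate 4e-4, dropout 0.5."""

    embedding_dim: int = 100
    batch_size: int = 50
    learning_rate: float = 0.0004
    dropout: float = 0.5
    epochs: int = 20
    seed: int = 0
    hidden_dim: int = 100
    pos_dim: int = 8
    clip: float = 5.0
    patience: int = 5


def _bio_labels() -> list[str]:
    labels = ["O"]
    for t in SPAN_TYPES:
        labels.append(f"B-{t}")
        labels.append(f"I-{t}")
    return labels


class SequenceModel:
    """BiLSTM-CRF with feature embeddings and start/stop-augmented CRF."""

    def __init__(
        self,
        vocab: dict[str, int],
        pos_vocab: dict[str, int],
        n_dicts: int,
        hp: Hyperparameters,
        dictionaries: Mapping[str, Sequence[str]] | None = None,
        segmenter: Segmenter | None = None,
    ):
        self.vocab = vocab
        self.pos_vocab = pos_vocab
        self.n_dicts = n_dicts
        self.hp = hp
        self.labels = _bio_labels()
        self.dictionaries = dict(dictionaries or {})
        self.segmenter = segmenter
        rng = np.random.default_rng(hp.seed)
        L = len(self.labels)
        D = hp.embedding_dim + hp.pos_dim + n_dicts + 1
        self._fwd = LSTMLayer(rng, D, hp.hidden_dim)
        self._bwd = LSTMLayer(rng, D, hp.hidden_dim)
        self.bilstm = BiRecurrent(self._fwd, self._bwd)
        self.params: dict[str, np.ndarray] = {
            "emb": rng.normal(0, 0.1, size=(len(vocab), hp.embedding_dim)),
            "pos_emb": rng.normal(0, 0.1, size=(len(pos_vocab), hp.pos_dim)),
            "proj_W": rng.normal(0, 0.1, size=(2 * hp.hidden_dim, L)),
            "proj_b": np.zeros(L),
            "trans": np.zeros((L, L)),
            "start": np.zeros(L),
            "stop": np.zeros(L),
        }
        for key, arr in self._fwd.params.items():
            self.params[f"lstm_f_{key}"] = arr
        for key, arr in self._bwd.params.items():
            self.params[f"lstm_b_{key}"] = arr

    # -- encoding ----------------------------------------------------------

    def _char_id(self, ch: str) -> int:
        return self.vocab.get(ch, self.vocab[UNK])

    def _pos_id(self, pos: str) -> int:
        return self.pos_vocab.get(pos, self.pos_vocab[UNK])

    def encode(self, feats: list[CharacterFeatures]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        char_ids = np.array([self._char_id(f.char) for f in feats], dtype=int)
        pos_ids = np.array([self._pos_id(f.pos_tag) for f in feats], dtype=int)
        T = len(feats)
        extra = np.zeros((T, self.n_dicts + 1))
        for i, f in enumerate(feats):
            flags = list(f.dict_flags)[: self.n_dicts]
            flags += [False] * (self.n_dicts - len(flags))
            extra[i, : self.n_dicts] = np.array(flags, dtype=float)
            extra[i, -1] = f.position / max(T - 1, 1)
        return char_ids, pos_ids, extra

    def _inputs(self, char_ids, pos_ids, extra) -> np.ndarray:
        return np.concatenate(
            [self.params["emb"][char_ids], self.params["pos_emb"][pos_ids], extra],
            axis=1,
        )

    def emissions(
        self, feats: list[CharacterFeatures], drop_mask: np.ndarray | None = None
    ) -> tuple[np.ndarray, tuple]:
        char_ids, pos_ids, extra = self.encode(feats)
        X = self._inputs(char_ids, pos_ids, extra)
        H_seq, rcache = self.bilstm.forward(X)
        if drop_mask is not None:
            H_seq = H_seq * drop_mask
        em = H_seq @ self.params["proj_W"] + self.params["proj_b"]
        em[0] += self.params["start"]
        em[-1] += self.params["stop"]
        cache = (char_ids, pos_ids, X, H_seq, rcache, drop_mask)
        return em, cache

    # -- training ----------------------------------------------------------

    def loss_and_grads(
        self, feats: list[CharacterFeatures], gold: np.ndarray,
        drop_mask: np.ndarray | None = None,
    ) -> tuple[float, dict[str, np.ndarray]]:
        em, cache = self.emissions(feats, drop_mask)
        char_ids, pos_ids, X, H_seq, rcache, mask = cache
        trans = self.params["trans"]
        unary, pairwise, log_z = crf.crf_marginals(em, trans)
        gold_score = crf.path_score(em, trans, gold)
        loss = log_z - gold_score

        d_em = unary
        T, L = em.shape
        d_em[np.arange(T), gold] -= 1.0
        d_trans = pairwise.sum(axis=0)
        if T > 1:
            np.add.at(d_trans, (gold[:-1], gold[1:]), -1.0)
        grads: dict[str, np.ndarray] = {
            "trans": d_trans,
            "start": d_em[0].copy(),
            "stop": d_em[-1].copy(),
        }
        # start/stop gradients equal the emission gradients at the ends,
        # already included in d_em since they were added into the emissions
        grads["proj_W"] = H_seq.T @ d_em
        grads["proj_b"] = d_em.sum(axis=0)
        dH = d_em @ self.params["proj_W"].T
        if mask is not None:
            dH = dH * mask
        dX, gf, gb = self.bilstm.backward(dH, rcache)
        for k, v in gf.items():
            grads[f"lstm_f_{k}"] = v
        for k, v in gb.items():
            grads[f"lstm_b_{k}"] = v
        E = self.hp.embedding_dim
        d_emb = np.zeros_like(self.params["emb"])
        np.add.at(d_emb, char_ids, dX[:, :E])
        grads["emb"] = d_emb
        d_pos = np.zeros_like(self.params["pos_emb"])
        np.add.at(d_pos, pos_ids, dX[:, E : E + self.hp.pos_dim])
        grads["pos_emb"] = d_pos
        return float(loss), grads

    # -- decoding ----------------------------------------------------------

    def decode(self, feats: list[CharacterFeatures]) -> list[str]:
        if not feats:
            return []
        em, _ = self.emissions(feats)
        ids, _score = crf.viterbi_decode(em, self.params["trans"])
        return [self.labels[i] for i in ids]

    def featurize(self, sentence: str) -> list[CharacterFeatures]:
        return featurize(sentence, self.dictionaries, self.segmenter)

    # -- persistence -------------------------------------------------------

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        np.savez(prefix.with_suffix(".npz"), **self.params)
        meta = {
            "vocab": self.vocab,
            "pos_vocab": self.pos_vocab,
            "n_dicts": self.n_dicts,
            "hp": asdict(self.hp),
            "labels": self.labels,
            "format_version": 1,
        }
        prefix.with_suffix(".json").write_text(
            json.dumps(meta, ensure_ascii=False), "utf-8"
        )

    @classmethod
    def load(
        cls,
        prefix: str | Path,
        dictionaries: Mapping[str, Sequence[str]] | None = None,
        segmenter: Segmenter | None = None,
    ) -> "SequenceModel":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text("utf-8"))
        model = cls(
            vocab=meta["vocab"],
            pos_vocab=meta["pos_vocab"],
            n_dicts=meta["n_dicts"],
            hp=Hyperparameters(**meta["hp"]),
            dictionaries=dictionaries,
            segmenter=segmenter,
        )
        data = np.load(prefix.with_suffix(".npz"))
        for k in model.params:
            model.params[k][...] = data[k]
        return model


def _doc_examples(
    doc: GoldDocument, model: SequenceModel
) -> list[tuple[list[CharacterFeatures], np.ndarray]]:
    labels = spans_to_bio(len(doc.text), doc.mentions)
    lab_idx = {l: i for i, l in enumerate(model.labels)}
    out = []
    for start, end, sent in split_sentences(doc.text):
        if not sent:
            continue
        feats = model.featurize(sent)
        gold = np.array([lab_idx[l] for l in labels[start:end]], dtype=int)
        out.append((feats, gold))
    return out


def train(
    train_docs: list[GoldDocument],
    val_docs: list[GoldDocument],
    hp: Hyperparameters | None = None,
    dictionaries: Mapping[str, Sequence[str]] | None = None,
    segmenter: Segmenter | None = None,
    verbose: bool = False,
) -> SequenceModel:
    """Train on BIO-converted documents; returns the best-validation model.

    Seeded and deterministic; the training objective is the negative CRF
    log-likelihood and model selection uses entity-level validation F1.
    """
    if not train_docs:
        raise ValueError("empty training set")
    hp = hp or Hyperparameters()
    chars = sorted({ch for doc in train_docs for ch in doc.text})
    vocab = {UNK: 0, **{ch: i + 1 for i, ch in enumerate(chars)}}
    seg = segmenter or CharSegmenter()
    pos_tags = sorted({p for doc in train_docs for _, p in seg.segment(doc.text)})
    pos_vocab = {UNK: 0, **{p: i + 1 for i, p in enumerate(pos_tags)}}
    model = SequenceModel(
        vocab, pos_vocab, len(dictionaries or {}), hp,
        dictionaries=dictionaries, segmenter=segmenter,
    )
    examples = [ex for doc in train_docs for ex in _doc_examples(doc, model)]
    rng = np.random.default_rng(hp.seed)
    opt = Adam(lr=hp.learning_rate)
    best_f1 = -1.0
    best_params = copy.deepcopy(model.params)
    stale = 0
    for epoch in range(hp.epochs):
        order = rng.permutation(len(examples))
        total_loss = 0.0
        for b0 in range(0, len(order), hp.batch_size):
            batch = order[b0 : b0 + hp.batch_size]
            acc: dict[str, np.ndarray] = {}
            for idx in batch:
                feats, gold = examples[idx]
                mask = (
                    dropout_mask(rng, (len(feats), 2 * hp.hidden_dim), hp.dropout)
                    if hp.dropout > 0
                    else None
                )
                loss, grads = model.loss_and_grads(feats, gold, mask)
                total_loss += loss
                for k, g in grads.items():
                    acc[k] = acc.get(k, 0.0) + g
            acc = {k: g / len(batch) for k, g in acc.items()}
            acc = clip_gradients(acc, hp.clip)
            opt.step(model.params, acc)
        f1 = _entity_f1(model, val_docs) if val_docs else -total_loss
        if verbose:
            print(f"epoch {epoch + 1}: loss={total_loss:.2f} val_f1={f1:.4f}")
        if f1 > best_f1:
            best_f1 = f1
            best_params = copy.deepcopy(model.params)
            stale = 0
        else:
            stale += 1
            if stale >= hp.patience:
                break
    for k in model.params:
        model.params[k][...] = best_params[k]
    return model


def _entity_f1(model: SequenceModel, docs: list[GoldDocument]) -> float:
    from .evaluation import ner_metrics

    gold = [m for d in docs for m in d.mentions]
    pred = [m for d in docs for m in tag_document(model, d.text, d.patient_id)]
    return ner_metrics(gold, pred).micro_f1


def tag_document(
    model: SequenceModel, text: str, doc_id: str = "doc"
) -> list[Mention]:
    """Decode per sentence; orphan I- tags are repaired to B-."""
    mentions: list[Mention] = []
    for start, _end, sent in split_sentences(text):
        if not sent:
            continue
        labels = model.decode(model.featurize(sent))
        mentions.extend(
            bio_to_spans(labels, sent, doc_id=doc_id, offset=start, repair=True)
        )
    return mentions
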
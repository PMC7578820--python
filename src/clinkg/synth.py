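"""Seeded generator of synthetic Chinese-clinical-style gold corpora.

Documents are built from per-relation sentence templates so that every
sentence mixes at most two entity types, negated finding/disease mentions
always follow a cue inside their clause, and each sentence's relation label
is recoverable from an unambiguous keyword token (which is what makes the
downstream extractors trainable on this data).  Realistic prose is an
explicit non-goal; the structural properties are the point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .bio import bio_to_spans, spans_to_bio
from .schema import SchemaGraph, build_default_schema
from .types import (
    ENTITY_SPAN_TYPES,
    GoldDocument,
    Mention,
    NEGATIVE,
    NOT_APPLICABLE,
    POSITIVE,
    PROPERTY_SPAN_TYPES,
    RelationInstance,
    span_type_to_class,
)

__all__ = [
    "Lexeme",
    "GeneratorConfig",
    "load_bundled_lexicon",
    "build_lexicons",
    "generate_corpus",
    "split_corpus",
    "corpus_to_bio",
    "save_corpus",
    "load_corpus",
]

#: textual relation labels the generator can realise in a sentence
TEXTUAL_LABELS = (
    "TeCD", "TeRD", "TeRS", "TeAS", "TrAD", "TrCD",
    "TrAS", "TrCS", "DCS", "SID", "CLAS", "LOCI",
)

#: (A-slot types, B-slot types, keyword, head_is_a)
_TEMPLATES: dict[str, tuple[tuple[str, ...], tuple[str, ...], str, bool]] = {
    "TeCD": (("test",), ("disease",), "排查", True),
    "TeRD": (("test",), ("disease",), "检出", True),
    "TeRS": (("test",), ("symptom", "sign"), "显示", True),
    "TeAS": (("test",), ("symptom", "sign"), "评估", True),
    "TrAD": (("surgery", "medicine"), ("disease",), "医治", True),
    "TrCD": (("surgery", "medicine"), ("disease",), "诱发", True),
    "TrAS": (("surgery", "medicine"), ("symptom", "sign"), "缓解", True),
    "TrCS": (("surgery", "medicine"), ("symptom", "sign"), "导致", True),
    "DCS": (("disease",), ("symptom", "sign"), "引发", True),
    "SID": (("symptom", "sign"), ("disease",), "提示", True),
    "CLAS": (("disease",), ("disease type",), "分型", True),
    "LOCI": (("body structure",), ("symptom", "sign"), "局部", False),
}

_PROPERTY_KEYWORDS = {
    "histological grade": "分级",
    "pathological stage": "分期",
    "naked eye type": "肉眼观",
    "tumor size": "体积",
}

_NEG_CUES = ("未见", "无明显", "不伴")
_STATEFUL = {"disease", "symptom", "sign"}

#: characters that must not appear in generated surface forms (negation
#: cues, enumeration filler, clause boundaries, template keywords)
_FORBIDDEN_CHARS = set(
    "无没有未见不伴明显等及和、，。；！？"
    "排查检出显示评估医治诱发缓解导致引发提示分型局部出现级期观积"
)


@dataclass(frozen=True)
class Lexeme:
    sem_type: str
    canonical: str
    english: str = ""
    variants: tuple[str, ...] = ()


def load_bundled_lexicon() -> dict[str, list[Lexeme]]:
    text = resources.files("clinkg.data").joinpath("lexicon.tsv").read_text("utf-8")
    out: dict[str, list[Lexeme]] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        sem_type, canonical = parts[0], parts[1]
        english = parts[2] if len(parts) > 2 else ""
        variants = tuple(parts[3].split("|")) if len(parts) > 3 and parts[3] else ()
        out.setdefault(sem_type, []).append(
            Lexeme(sem_type, canonical, english, variants)
        )
    return out


@dataclass
class GeneratorConfig:
    n_patients: int = 10
    vocab_sizes: dict[str, int] = field(default_factory=dict)
    negation_prob: float = 0.1
    relation_mix: dict[str, float] = field(default_factory=dict)
    sentences_per_doc: tuple[int, int] = (3, 6)
    synonym_rate: float = 0.2
    list_sentence_prob: float = 0.15
    property_sentence_prob: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.negation_prob <= 1.0):
            raise ValueError("negation_prob must lie in [0, 1]")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        lo, hi = self.sentences_per_doc
        if lo < 1 or hi < lo:
            raise ValueError("sentences_per_doc must be a non-empty range")
        for t, n in self.vocab_sizes.items():
            if n < 1:
                raise ValueError(f"vocab size for {t!r} must be >= 1")
        if self.relation_mix:
            unknown = set(self.relation_mix) - set(TEXTUAL_LABELS) - {"has_a"}
            if unknown:
                raise ValueError(f"unknown relation labels in mix: {sorted(unknown)}")
            if self.relation_mix.get("has_a", 0.0) > 0:
                raise ValueError(
                    "has_a is attached structurally per patient, not sampled"
                )
            total = sum(self.relation_mix.values())
            if total <= 0 or abs(total - 1.0) > 1e-6:
                raise ValueError("relation_mix must sum to 1")
        if not (0 <= self.list_sentence_prob + self.property_sentence_prob <= 1):
            raise ValueError("sentence-kind probabilities exceed 1")

    def mix_items(self) -> tuple[list[str], list[float]]:
        mix = self.relation_mix or {l: 1.0 / len(TEXTUAL_LABELS) for l in TEXTUAL_LABELS}
        labels = [l for l in mix if l != "has_a" and mix[l] > 0]
        probs = np.array([mix[l] for l in labels], dtype=float)
        return labels, list(probs / probs.sum())


def _char_pool(type_index: int) -> list[str]:
    """Disjoint pool of CJK characters for one span type."""
    base = 0x5000 + type_index * 0x100
    pool = []
    code = base
    while len(pool) < 48:
        ch = chr(code)
        if ch not in _FORBIDDEN_CHARS:
            pool.append(ch)
        code += 1
    return pool


def build_lexicons(
    config: GeneratorConfig, rng: np.random.Generator
) -> dict[str, list[Lexeme]]:
    """Bundled terms per type, extended with generated terms to vocab_sizes.

    Generated surface forms draw on per-type disjoint character pools, which
    keeps the type vocabularies separable for label-recovery experiments.
    """
    lexicons = {t: list(v) for t, v in load_bundled_lexicon().items()}
    all_types = ENTITY_SPAN_TYPES + PROPERTY_SPAN_TYPES
    for idx, sem_type in enumerate(all_types):
        entries = lexicons.setdefault(sem_type, [])
        want = config.vocab_sizes.get(sem_type, len(entries))
        if want < len(entries):
            del entries[want:]
        pool = _char_pool(idx)
        existing = {e.canonical for e in entries}
        while len(entries) < want:
            length = int(rng.integers(2, 5))
            name = "".join(rng.choice(pool, size=length))
            if name in existing:
                continue
            variants = (name + pool[0],) if rng.random() < 0.5 else ()
            entries.append(Lexeme(sem_type, name, "", variants))
            existing.add(name)
    return lexicons


class _SentenceBuilder:
    def __init__(self, doc_id: str, offset: int):
        self.doc_id = doc_id
        self.parts: list[str] = []
        self.pos = offset
        self.mentions: list[Mention] = []

    def text(self, s: str) -> None:
        self.parts.append(s)
        self.pos += len(s)

    def mention(self, surface: str, sem_type: str, state: str) -> Mention:
        m = Mention(
            doc_id=self.doc_id,
            start=self.pos,
            end=self.pos + len(surface),
            surface=surface,
            sem_type=sem_type,
            state=state,
        )
        self.mentions.append(m)
        self.text(surface)
        return m

    def build(self) -> str:
        return "".join(self.parts)


def _pick_surface(lexeme: Lexeme, rng: np.random.Generator, synonym_rate: float) -> str:
    if lexeme.variants and rng.random() < synonym_rate:
        return str(rng.choice(list(lexeme.variants)))
    return lexeme.canonical


def generate_corpus(config: GeneratorConfig) -> list[GoldDocument]:
    """Deterministic for a fixed seed (byte-identical output)."""
    rng = np.random.default_rng(config.seed)
    lexicons = build_lexicons(config, rng)
    labels, probs = config.mix_items()

    def draw(sem_types: tuple[str, ...]) -> Lexeme:
        sem_type = str(rng.choice(list(sem_types)))
        return lexicons[sem_type][int(rng.integers(len(lexicons[sem_type])))]

    docs: list[GoldDocument] = []
    for p in range(config.n_patients):
        doc_id = f"P{p + 1:04d}"
        lo, hi = config.sentences_per_doc
        n_sent = int(rng.integers(lo, hi + 1))
        text_parts: list[str] = []
        mentions: list[Mention] = []
        relations: list[RelationInstance] = []
        offset = 0
        for _ in range(n_sent):
            b = _SentenceBuilder(doc_id, offset)
            kind = rng.random()
            negate = rng.random() < config.negation_prob
            cue = str(rng.choice(list(_NEG_CUES)))

            def state_of(sem_type: str) -> str:
                if sem_type not in _STATEFUL:
                    return NOT_APPLICABLE
                return NEGATIVE if negate else POSITIVE

            if kind < config.list_sentence_prob:
                # finding enumeration, one shared state for the whole list
                pool = lexicons["symptom"] + lexicons["sign"]
                k = min(3, len(pool))
                chosen = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
                b.text(cue if negate else "出现")
                for j, lex in enumerate(chosen):
                    if j:
                        b.text("，")
                    b.mention(
                        _pick_surface(lex, rng, config.synonym_rate),
                        lex.sem_type,
                        state_of(lex.sem_type),
                    )
                b.text("等。" if negate else "。")
            elif kind < config.list_sentence_prob + config.property_sentence_prob:
                dtype = draw(("disease type",))
                ptype = str(rng.choice(list(PROPERTY_SPAN_TYPES)))
                value = lexicons[ptype][int(rng.integers(len(lexicons[ptype])))]
                head = b.mention(
                    _pick_surface(dtype, rng, config.synonym_rate),
                    "disease type",
                    NOT_APPLICABLE,
                )
                b.text(_PROPERTY_KEYWORDS[ptype] + "，")
                tail = b.mention(value.canonical, ptype, NOT_APPLICABLE)
                b.text("。")
                relations.append(
                    RelationInstance(doc_id, "attribute_of", head, tail,
                                     provenance="structural")
                )
            else:
                label = labels[int(rng.choice(len(labels), p=probs))]
                a_types, b_types, keyword, head_is_a = _TEMPLATES[label]
                lex_a, lex_b = draw(a_types), draw(b_types)
                if negate and lex_a.sem_type in _STATEFUL:
                    b.text(cue)
                m_a = b.mention(
                    _pick_surface(lex_a, rng, config.synonym_rate),
                    lex_a.sem_type,
                    state_of(lex_a.sem_type),
                )
                b.text(keyword + "，")
                if negate and lex_b.sem_type in _STATEFUL:
                    b.text(cue)
                m_b = b.mention(
                    _pick_surface(lex_b, rng, config.synonym_rate),
                    lex_b.sem_type,
                    state_of(lex_b.sem_type),
                )
                b.text("。")
                head, tail = (m_a, m_b) if head_is_a else (m_b, m_a)
                relations.append(
                    RelationInstance(doc_id, label, head, tail, provenance="gold")
                )
            text_parts.append(b.build())
            mentions.extend(b.mentions)
            offset = b.pos
        doc = GoldDocument(
            patient_id=doc_id,
            text="".join(text_parts),
            mentions=mentions,
            relations=relations,
        )
        doc.validate()
        docs.append(doc)
    return docs


def split_corpus(
    corpus: list[GoldDocument],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int | None = None,
) -> tuple[list[GoldDocument], list[GoldDocument], list[GoldDocument]]:
    """Disjoint, exhaustive partition with largest-remainder sizing."""
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ValueError("ratios must be three non-negative numbers")
    total = sum(ratios)
    if total <= 0 or abs(total - 1.0) > 1e-6:
        raise ValueError("ratios must sum to 1")
    n = len(corpus)
    exact = [n * r for r in ratios]
    sizes = [int(np.floor(x)) for x in exact]
    remainders = [x - s for x, s in zip(exact, sizes)]
    for _ in range(n - sum(sizes)):
        i = max(range(3), key=lambda j: (remainders[j], -j))
        sizes[i] += 1
        remainders[i] = -1.0
    order = list(range(n))
    if seed is not None:
        np.random.default_rng(seed).shuffle(order)
    docs = [corpus[i] for i in order]
    a, b = sizes[0], sizes[0] + sizes[1]
    return docs[:a], docs[a:b], docs[b:]


def corpus_to_bio(corpus: list[GoldDocument]) -> list[tuple[str, list[str], list[str]]]:
    """Per document: (doc_id, characters, BIO labels)."""
    out = []
    for doc in corpus:
        labels = spans_to_bio(len(doc.text), doc.mentions)
        out.append((doc.patient_id, list(doc.text), labels))
    return out


def bio_to_mentions(doc_id: str, text: str, labels: list[str]) -> list[Mention]:
    return bio_to_spans(labels, text, doc_id=doc_id)


# -- stable JSONL / standoff serialization ---------------------------------


def save_corpus(corpus: list[GoldDocument], docs_path: str | Path,
                ann_path: str | Path) -> None:
    """Documents as JSONL ({"patient_id", "text"}); annotations as JSONL
    standoff records ({"kind": "mention"|"relation", ...}); mention records
    carry doc_id/start/end/type/state, relation records carry
    doc_id/label/head/tail mention indices (or "patient")."""
    with open(docs_path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(json.dumps(
                {"patient_id": doc.patient_id, "text": doc.text},
                ensure_ascii=False) + "\n")
    with open(ann_path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            index = {id(m): i for i, m in enumerate(doc.mentions)}
            for m in doc.mentions:
                fh.write(json.dumps(
                    {"kind": "mention", "doc_id": m.doc_id, "start": m.start,
                     "end": m.end, "type": m.sem_type, "state": m.state},
                    ensure_ascii=False) + "\n")
            for r in doc.relations:
                head = "patient" if isinstance(r.head, str) else index[id(r.head)]
                fh.write(json.dumps(
                    {"kind": "relation", "doc_id": r.doc_id, "label": r.label,
                     "head": head, "tail": index[id(r.tail)],
                     "provenance": r.provenance},
                    ensure_ascii=False) + "\n")


def load_corpus(docs_path: str | Path, ann_path: str | Path) -> list[GoldDocument]:
    docs: dict[str, GoldDocument] = {}
    with open(docs_path, "r", encoding="utf-8") as fh:
        for line in fh:
            rec = json.loads(line)
            docs[rec["patient_id"]] = GoldDocument(
                patient_id=rec["patient_id"], text=rec["text"]
            )
    relations: list[dict] = []
    with open(ann_path, "r", encoding="utf-8") as fh:
        for line in fh:
            rec = json.loads(line)
            if rec["kind"] == "mention":
                doc = docs[rec["doc_id"]]
                doc.mentions.append(Mention(
                    doc_id=rec["doc_id"], start=rec["start"], end=rec["end"],
                    surface=doc.text[rec["start"]:rec["end"]],
                    sem_type=rec["type"], state=rec["state"]))
            else:
                relations.append(rec)
    for rec in relations:
        doc = docs[rec["doc_id"]]
        head = rec["doc_id"] if rec["head"] == "patient" else doc.mentions[rec["head"]]
        doc.relations.append(RelationInstance(
            doc_id=rec["doc_id"], label=rec["label"], head=head,
            tail=doc.mentions[rec["tail"]],
            provenance=rec.get("provenance", "gold")))
    out = list(docs.values())
    for doc in out:
        doc.validate()
    return out


def default_schema() -> SchemaGraph:
    return build_default_schema()
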
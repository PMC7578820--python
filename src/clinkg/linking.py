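"""Hierarchical, batch entity linking.

Order of attack for each unique (surface, span type) key of a document:
exact match on preferred terms of the key's class, then exact match on
nonpreferred terms / data-property values, then dictionary expansion of the
surface followed by the same two exact stages, and finally cosine-similarity
ranking over character-bigram count vectors.  Exact stages always win over
similarity; search never leaves the key's class (subclasses included).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .schema import SchemaGraph
from .types import Mention, span_type_to_class

__all__ = [
    "DICTIONARY_CATEGORIES",
    "Concept",
    "Dictionary",
    "KnowledgeBase",
    "LinkResult",
    "dedupe",
    "hierarchical_match",
    "dictionary_expand",
    "similarity_rank",
    "cosine_similarity",
    "link_mentions",
    "load_concepts_tsv",
    "load_dictionaries_tsv",
]

#: the six dictionary categories shipped by default
DICTIONARY_CATEGORIES = (
    "disease",
    "drug",
    "surgery",
    "test",
    "symptom/sign",
    "body structure",
)

EXACT_CONCEPT = "exact-concept"
EXACT_PROPERTY = "exact-property"
DICT_EXPANDED = "dictionary-expanded"
SIMILARITY = "similarity"


@dataclass(frozen=True)
class Concept:
    concept_id: str
    class_name: str
    preferred_term: str
    english_name: str = ""
    nonpreferred_terms: tuple[str, ...] = ()
    properties: tuple[str, ...] = ()


@dataclass
class Dictionary:
    category: str
    entries: dict[str, str] = field(default_factory=dict)  # surface -> canonical


@dataclass
class KnowledgeBase:
    concepts: list[Concept]
    schema: SchemaGraph

    def __post_init__(self) -> None:
        ids = [c.concept_id for c in self.concepts]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate concept ids")
        for c in self.concepts:
            if c.class_name not in self.schema.classes:
                raise ValueError(
                    f"concept {c.concept_id} has undeclared class {c.class_name!r}"
                )

    def concepts_of_class(self, class_name: str) -> list[Concept]:
        """Concepts whose class is ``class_name`` or a subclass of it."""
        return [
            c
            for c in self.concepts
            if self.schema.class_satisfies(c.class_name, class_name)
        ]


@dataclass
class LinkResult:
    mention_key: tuple[str, str]  # (surface, sem_type)
    concept_id: str | None
    method: str
    score: float

    def __post_init__(self) -> None:
        if self.method in (EXACT_CONCEPT, EXACT_PROPERTY, DICT_EXPANDED):
            if self.concept_id is not None and self.score != 1.0:
                raise ValueError("exact methods imply score 1.0")


def dedupe(
    mentions: Sequence[Mention],
) -> tuple[list[tuple[str, str]], dict[tuple[str, str], list[int]]]:
    """Unique (surface, sem_type) keys with back-references to mention
    indices, so each key is linked once and results fan back out."""
    keys: list[tuple[str, str]] = []
    backrefs: dict[tuple[str, str], list[int]] = {}
    for i, m in enumerate(mentions):
        key = (m.surface, m.sem_type)
        if key not in backrefs:
            keys.append(key)
            backrefs[key] = []
        backrefs[key].append(i)
    return keys, backrefs


def _key_class(key: tuple[str, str]) -> str:
    cls = span_type_to_class(key[1])
    if cls is None:
        raise ValueError(f"span type {key[1]!r} does not map to a schema class")
    return cls


def hierarchical_match(
    key: tuple[str, str], kb: KnowledgeBase
) -> LinkResult | None:
    """Class-scoped exact match: preferred terms first, then nonpreferred
    terms and data-property values; first hit wins."""
    surface = key[0]
    candidates = kb.concepts_of_class(_key_class(key))
    for c in candidates:
        if c.preferred_term == surface:
            return LinkResult(key, c.concept_id, EXACT_CONCEPT, 1.0)
    for c in candidates:
        if surface in c.nonpreferred_terms or surface in c.properties:
            return LinkResult(key, c.concept_id, EXACT_PROPERTY, 1.0)
    return None


def dictionary_expand(
    key: tuple[str, str], dictionaries: Mapping[str, Dictionary]
) -> list[str]:
    """Canonical forms reachable from the surface via dictionary entries;
    never returns the surface itself."""
    surface = key[0]
    out = []
    for d in dictionaries.values():
        canon = d.entries.get(surface)
        if canon and canon != surface and canon not in out:
            out.append(canon)
    return out


def _bigrams(s: str) -> Counter:
    padded = f"^{s}$"
    return Counter(padded[i : i + 2] for i in range(len(padded) - 1))


def cosine_similarity(a: str, b: str) -> float:
    """Cosine over character-bigram counts of boundary-padded strings."""
    va, vb = _bigrams(a), _bigrams(b)
    dot = sum(va[k] * vb[k] for k in va)
    na = math.sqrt(sum(v * v for v in va.values()))
    nb = math.sqrt(sum(v * v for v in vb.values()))
    if na == 0 or nb == 0:
        return 0.0
    return dot / (na * nb)


def similarity_rank(
    key: tuple[str, str],
    candidates: Sequence[Concept],
    threshold: float = 0.5,
) -> list[LinkResult]:
    """Descending cosine ranking (max over preferred + nonpreferred terms);
    ties broken by concept_id; below-threshold results are unlinked."""
    surface = key[0]
    scored = []
    for c in candidates:
        terms = (c.preferred_term, *c.nonpreferred_terms)
        best = max(cosine_similarity(surface, t) for t in terms)
        scored.append((c.concept_id, best))
    scored.sort(key=lambda x: (-x[1], x[0]))
    out = []
    for cid, s in scored:
        if s >= threshold:
            out.append(LinkResult(key, cid, SIMILARITY, min(s, 1.0)))
        else:
            out.append(LinkResult(key, None, SIMILARITY, s))
    return out


def link_key(
    key: tuple[str, str],
    kb: KnowledgeBase,
    dictionaries: Mapping[str, Dictionary] | None = None,
    threshold: float = 0.5,
) -> LinkResult:
    """Full hierarchy for one key: exact -> dictionary-expanded exact ->
    similarity -> unlinked."""
    hit = hierarchical_match(key, kb)
    if hit is not None:
        return hit
    if dictionaries:
        for variant in dictionary_expand(key, dictionaries):
            hit = hierarchical_match((variant, key[1]), kb)
            if hit is not None:
                return LinkResult(key, hit.concept_id, DICT_EXPANDED, 1.0)
    candidates = kb.concepts_of_class(_key_class(key))
    if candidates:
        ranked = similarity_rank(key, candidates, threshold)
        if ranked and ranked[0].concept_id is not None:
            return ranked[0]
    return LinkResult(key, None, SIMILARITY, 0.0)


def link_mentions(
    mentions: Sequence[Mention],
    kb: KnowledgeBase,
    dictionaries: Mapping[str, Dictionary] | None = None,
    threshold: float = 0.5,
) -> list[LinkResult | None]:
    """Dedupe, link each unique key once, fan results back out per mention.

    Property-span mentions (no schema class) get ``None``.
    """
    results: list[LinkResult | None] = [None] * len(mentions)
    linkable = [
        (i, m) for i, m in enumerate(mentions) if span_type_to_class(m.sem_type)
    ]
    keys, backrefs = dedupe([m for _i, m in linkable])
    per_key = {key: link_key(key, kb, dictionaries, threshold) for key in keys}
    for i, m in linkable:
        results[i] = per_key[(m.surface, m.sem_type)]
    return results


# -- TSV interchange -------------------------------------------------------


def load_concepts_tsv(path: str | Path, schema: SchemaGraph) -> KnowledgeBase:
    """Columns: concept_id, class, preferred, english, synonyms (| separated),
    properties (| separated)."""
    concepts = []
    for line in Path(path).read_text("utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = (line.split("\t") + [""] * 6)[:6]
        concepts.append(
            Concept(
                concept_id=parts[0],
                class_name=parts[1],
                preferred_term=parts[2],
                english_name=parts[3],
                nonpreferred_terms=tuple(t for t in parts[4].split("|") if t),
                properties=tuple(t for t in parts[5].split("|") if t),
            )
        )
    return KnowledgeBase(concepts=concepts, schema=schema)


def load_dictionaries_tsv(path: str | Path) -> dict[str, Dictionary]:
    """Columns: category, surface, canonical."""
    dicts: dict[str, Dictionary] = {}
    for line in Path(path).read_text("utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        category, surface, canonical = line.split("\t")[:3]
        dicts.setdefault(category, Dictionary(category)).entries[surface] = canonical
    return dicts


def default_dictionaries(
    lexicons: Mapping[str, Iterable] | None = None,
) -> dict[str, Dictionary]:
    """The six default dictionaries, optionally filled from generator
    lexicons (surface variants mapping to canonical forms)."""
    dicts = {cat: Dictionary(cat) for cat in DICTIONARY_CATEGORIES}
    mapping = {
        "disease": "disease",
        "disease type": "disease",
        "medicine": "drug",
        "surgery": "surgery",
        "test": "test",
        "symptom": "symptom/sign",
        "sign": "symptom/sign",
        "body structure": "body structure",
    }
    if lexicons:
        for sem_type, entries in lexicons.items():
            cat = mapping.get(sem_type)
            if cat is None:
                continue
            for lex in entries:
                for v in lex.variants:
                    dicts[cat].entries[v] = lex.canonical
    return dicts


def knowledge_base_from_lexicons(
    lexicons: Mapping[str, Iterable], schema: SchemaGraph
) -> KnowledgeBase:
    """Concept per canonical entity term (property types excluded)."""
    concepts = []
    i = 0
    for sem_type, entries in lexicons.items():
        cls = span_type_to_class(sem_type)
        if cls is None:
            continue
        for lex in entries:
            i += 1
            concepts.append(
                Concept(
                    concept_id=f"C{i:04d}",
                    class_name=cls,
                    preferred_term=lex.canonical,
                    english_name=lex.english,
                    nonpreferred_terms=tuple(lex.variants),
                )
            )
    return KnowledgeBase(concepts=concepts, schema=schema)
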
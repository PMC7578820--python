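"""Shared domain records: mentions, relation instances, gold documents."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "ENTITY_SPAN_TYPES",
    "PROPERTY_SPAN_TYPES",
    "SPAN_TYPES",
    "STATEFUL_CLASSES",
    "POSITIVE",
    "NEGATIVE",
    "NOT_APPLICABLE",
    "span_type_to_class",
    "Mention",
    "RelationInstance",
    "GoldDocument",
]

#: the 8 entity span types recognised by the tagger
ENTITY_SPAN_TYPES = (
    "body structure",
    "symptom",
    "sign",
    "surgery",
    "medicine",
    "disease",
    "disease type",
    "test",
)

#: the 4 property span types (attached later via attribute_of)
PROPERTY_SPAN_TYPES = (
    "histological grade",
    "pathological stage",
    "naked eye type",
    "tumor size",
)

SPAN_TYPES = ENTITY_SPAN_TYPES + PROPERTY_SPAN_TYPES

#: top-level classes whose mentions carry a positive/negative state
STATEFUL_CLASSES = ("disease", "clinical finding")

POSITIVE = "positive"
NEGATIVE = "negative"
NOT_APPLICABLE = "not-applicable"

_SPAN_TYPE_CLASS = {
    "body structure": "body structure",
    "symptom": "symptom",
    "sign": "sign",
    "surgery": "surgery",
    "medicine": "medicine",
    "disease": "disease",
    "disease type": "disease type",
    "test": "test",
}


def span_type_to_class(sem_type: str) -> str | None:
    """Schema class for a span type; None for the 4 property span types."""
    return _SPAN_TYPE_CLASS.get(sem_type)


@dataclass
class Mention:
    """A character-offset span in one document (0-based, half-open)."""

    doc_id: str
    start: int
    end: int
    surface: str
    sem_type: str
    state: str = NOT_APPLICABLE

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty or inverted span [{self.start}, {self.end})")

    def check_against(self, text: str) -> None:
        if self.end > len(text):
            raise ValueError(
                f"mention [{self.start}, {self.end}) outside text of length {len(text)}"
            )
        if text[self.start : self.end] != self.surface:
            raise ValueError(
                f"surface {self.surface!r} does not match text slice "
                f"{text[self.start:self.end]!r}"
            )

    def with_state(self, state: str) -> "Mention":
        return replace(self, state=state)


@dataclass
class RelationInstance:
    """A typed, directed edge between two mentions (or patient -> mention)."""

    doc_id: str
    label: str
    head: Mention | str  # a Mention, or a patient id for has_a
    tail: Mention
    provenance: str = "rule"  # rule | classifier | structural | gold
    confidence: float = 1.0


@dataclass
class GoldDocument:
    """One synthetic document with gold mentions, states, and relations."""

    patient_id: str
    text: str
    mentions: list[Mention] = field(default_factory=list)
    relations: list[RelationInstance] = field(default_factory=list)

    @property
    def doc_id(self) -> str:
        return self.patient_id

    def validate(self) -> None:
        prev_end = -1
        for m in sorted(self.mentions, key=lambda m: m.start):
            m.check_against(self.text)
            if m.start < prev_end:
                raise ValueError(
                    f"overlapping/nested mentions in {self.patient_id}: "
                    f"{m.surface!r} at {m.start}"
                )
            prev_end = m.end
        ids = {id(m) for m in self.mentions}
        for r in self.relations:
            for end in (r.head, r.tail):
                if isinstance(end, Mention) and id(end) not in ids:
                    raise ValueError(
                        f"relation endpoint not among document mentions: {end}"
                    )
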
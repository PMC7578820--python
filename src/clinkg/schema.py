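"""Knowledge-graph schema: classes, data properties, and typed relations.

The default schema declares 7 top-level clinical classes (patient, disease,
disease type, test, body structure, clinical finding, treatment), their
subconcept tree, per-class data properties, and 16 relation types (13
semantic + 3 structural), each with head/tail class constraints.  The schema
is shipped as a versioned YAML file so classes and relations can be added or
removed without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "SchemaError",
    "OntologyClass",
    "RelationType",
    "SchemaGraph",
    "build_default_schema",
    "load_schema",
    "dump_schema",
    "VALID",
    "WRONG_DIRECTION",
    "DISALLOWED",
    "ANY_CONCEPT",
]

#: wildcard endpoint used by the structural relations
ANY_CONCEPT = "*"

VALID = "valid"
WRONG_DIRECTION = "wrong-direction"
DISALLOWED = "disallowed"


class SchemaError(ValueError):
    """Raised for unknown classes/labels or inconsistent schema files."""


@dataclass(frozen=True)
class OntologyClass:
    name: str
    parent: str | None = None
    data_properties: tuple[str, ...] = ()
    source: str = ""


@dataclass(frozen=True)
class RelationType:
    label: str
    definition: str
    head_classes: tuple[str, ...]
    tail_classes: tuple[str, ...]
    coarse_category: str = ""
    structural: bool = False


@dataclass
class SchemaGraph:
    """Validated collection of ontology classes and relation types."""

    classes: dict[str, OntologyClass] = field(default_factory=dict)
    relations: dict[str, RelationType] = field(default_factory=dict)
    version: int = 1

    def __post_init__(self) -> None:
        self._check()

    # -- structure ---------------------------------------------------------

    def _check(self) -> None:
        for cls in self.classes.values():
            if cls.parent is not None and cls.parent not in self.classes:
                raise SchemaError(
                    f"class {cls.name!r} has undeclared parent {cls.parent!r}"
                )
        for name in self.classes:
            # acyclicity of the subclass tree
            seen: set[str] = set()
            cur: str | None = name
            while cur is not None:
                if cur in seen:
                    raise SchemaError(f"subclass cycle through {cur!r}")
                seen.add(cur)
                cur = self.classes[cur].parent
        for rel in self.relations.values():
            for endpoint in (*rel.head_classes, *rel.tail_classes):
                if endpoint != ANY_CONCEPT and endpoint not in self.classes:
                    raise SchemaError(
                        f"relation {rel.label!r} references unknown class {endpoint!r}"
                    )

    def top_level_classes(self) -> list[str]:
        return [c.name for c in self.classes.values() if c.parent is None]

    def subconcepts(self, name: str) -> list[str]:
        self._require_class(name)
        return [c.name for c in self.classes.values() if c.parent == name]

    def ancestry(self, name: str) -> list[str]:
        """Class name followed by its ancestors up to the root."""
        self._require_class(name)
        chain = [name]
        cur = self.classes[name].parent
        while cur is not None:
            chain.append(cur)
            cur = self.classes[cur].parent
        return chain

    def data_properties(self, name: str) -> tuple[str, ...]:
        self._require_class(name)
        return self.classes[name].data_properties

    def nonstructural_labels(self) -> list[str]:
        return [r.label for r in self.relations.values() if not r.structural]

    def structural_labels(self) -> list[str]:
        return [r.label for r in self.relations.values() if r.structural]

    def _require_class(self, name: str) -> None:
        if name not in self.classes:
            raise SchemaError(f"unknown class {name!r}")

    def _require_label(self, label: str) -> RelationType:
        try:
            return self.relations[label]
        except KeyError:
            raise SchemaError(f"unknown relation label {label!r}") from None

    # -- constraint queries ------------------------------------------------

    def class_satisfies(self, actual: str, declared: str) -> bool:
        """True when ``actual`` (or an ancestor of it) is ``declared``.

        A subconcept satisfies any constraint naming its ancestor, e.g.
        ``surgery`` satisfies a ``treatment`` endpoint.
        """
        if declared == ANY_CONCEPT:
            return True
        return declared in self.ancestry(actual)

    def _matches(self, classes: Iterable[str], actual: str) -> bool:
        return any(self.class_satisfies(actual, d) for d in classes)

    def allowed_relations(self, head_type: str, tail_type: str) -> dict[str, str]:
        """Non-structural labels admissible between two classes.

        Matches in either direction; the value annotates the canonical
        direction: ``"forward"`` when (head_type, tail_type) matches the
        declared (head, tail) pair, ``"reverse"`` when the flipped pair does.
        """
        self._require_class(head_type)
        self._require_class(tail_type)
        out: dict[str, str] = {}
        for rel in self.relations.values():
            if rel.structural:
                continue
            if self._matches(rel.head_classes, head_type) and self._matches(
                rel.tail_classes, tail_type
            ):
                out[rel.label] = "forward"
            elif self._matches(rel.head_classes, tail_type) and self._matches(
                rel.tail_classes, head_type
            ):
                out[rel.label] = "reverse"
        return out

    def validate_edge(self, head_class: str, label: str, tail_class: str) -> str:
        """Check one typed edge; returns valid / wrong-direction / disallowed."""
        rel = self._require_label(label)
        if not rel.structural:
            self._require_class(head_class)
            self._require_class(tail_class)
        if rel.structural:
            return VALID
        if self._matches(rel.head_classes, head_class) and self._matches(
            rel.tail_classes, tail_class
        ):
            return VALID
        if self._matches(rel.head_classes, tail_class) and self._matches(
            rel.tail_classes, head_class
        ):
            return WRONG_DIRECTION
        return DISALLOWED


# -- module-level conveniences (same contracts, schema passed explicitly) --


def allowed_relations(
    head_type: str, tail_type: str, schema: SchemaGraph
) -> dict[str, str]:
    return schema.allowed_relations(head_type, tail_type)


def validate_edge(
    head_class: str, label: str, tail_class: str, schema: SchemaGraph
) -> str:
    return schema.validate_edge(head_class, label, tail_class)


# -- serialization ---------------------------------------------------------


def _schema_from_mapping(doc: dict) -> SchemaGraph:
    classes: dict[str, OntologyClass] = {}
    for entry in doc.get("classes", []):
        cls = OntologyClass(
            name=entry["name"],
            parent=entry.get("parent"),
            data_properties=tuple(entry.get("data_properties") or ()),
            source=entry.get("source", ""),
        )
        if cls.name in classes:
            raise SchemaError(f"duplicate class {cls.name!r}")
        classes[cls.name] = cls
    relations: dict[str, RelationType] = {}
    for entry in doc.get("relations", []):
        rel = RelationType(
            label=entry["label"],
            definition=entry["definition"],
            head_classes=tuple(entry["head"]),
            tail_classes=tuple(entry["tail"]),
            coarse_category=entry.get("coarse_category", ""),
            structural=bool(entry.get("structural", False)),
        )
        if rel.label in relations:
            raise SchemaError(f"duplicate relation label {rel.label!r}")
        relations[rel.label] = rel
    return SchemaGraph(classes=classes, relations=relations, version=int(doc.get("version", 1)))


def _schema_to_mapping(schema: SchemaGraph) -> dict:
    return {
        "version": schema.version,
        "classes": [
            {
                "name": c.name,
                "parent": c.parent,
                "source": c.source,
                "data_properties": list(c.data_properties),
            }
            for c in schema.classes.values()
        ],
        "relations": [
            {
                "label": r.label,
                "definition": r.definition,
                "coarse_category": r.coarse_category,
                "head": list(r.head_classes),
                "tail": list(r.tail_classes),
                "structural": r.structural,
            }
            for r in schema.relations.values()
        ],
    }


def load_schema(path: str | Path) -> SchemaGraph:
    with open(path, "r", encoding="utf-8") as fh:
        return _schema_from_mapping(yaml.safe_load(fh))


def dump_schema(schema: SchemaGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            _schema_to_mapping(schema), fh, allow_unicode=True, sort_keys=False
        )


def build_default_schema(
    test_subconcepts: tuple[str, ...] | None = None,
) -> SchemaGraph:
    """Load the bundled default schema.

    ``test_subconcepts`` optionally renames the four subconcepts of ``test``
    (placeholders: laboratory test, imaging examination, endoscopic
    examination, pathological examination).
    """
    text = resources.files("clinkg.data").joinpath("schema.yaml").read_text("utf-8")
    schema = _schema_from_mapping(yaml.safe_load(text))
    if test_subconcepts is not None:
        defaults = tuple(schema.subconcepts("test"))
        if len(test_subconcepts) != len(defaults):
            raise SchemaError(
                f"expected {len(defaults)} test subconcept names, "
                f"got {len(test_subconcepts)}"
            )
        classes = dict(schema.classes)
        for old, new in zip(defaults, test_subconcepts):
            cls = classes.pop(old)
            classes[new] = OntologyClass(
                name=new,
                parent=cls.parent,
                data_properties=cls.data_properties,
                source=cls.source,
            )
        schema = SchemaGraph(classes=classes, relations=schema.relations,
                             version=schema.version)
    return schema
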
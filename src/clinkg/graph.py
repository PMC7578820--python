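"""Patient-centered property graph: construction, queries, statistics, export.

Node kinds and display levels: patient and class nodes sit at level 1
(patient nodes red and largest), concept nodes at level 2, entity and
property-value nodes at level 3 (entity nodes green and smallest).  Edge
colors default to a fixed palette (instance_of orange, TeRS pink, TrAD
green).  Exports: GraphML, a Cypher CREATE script, and a JSON dump that
round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import networkx as nx

from .linking import LinkResult, KnowledgeBase
from .schema import DISALLOWED, SchemaGraph, VALID
from .types import (
    GoldDocument,
    Mention,
    PROPERTY_SPAN_TYPES,
    RelationInstance,
    span_type_to_class,
)

__all__ = [
    "PropertyGraph",
    "build_graph",
    "patient_subgraph",
    "treatment_frequency",
    "count_summary",
    "export",
    "import_json",
    "NODE_STYLES",
    "EDGE_COLORS",
]

PATIENT, CLASS, CONCEPT, ENTITY, PROPERTY_VALUE = (
    "patient",
    "class",
    "concept",
    "entity",
    "property-value",
)

#: kind -> (level, color, relative size); patient largest/red, entity
#: smallest/green
NODE_STYLES: dict[str, tuple[int, str, int]] = {
    PATIENT: (1, "red", 60),
    CLASS: (1, "blue", 50),
    CONCEPT: (2, "yellow", 35),
    ENTITY: (3, "green", 20),
    PROPERTY_VALUE: (3, "gray", 20),
}

#: fixed edge palette; unlisted labels fall back to light gray
EDGE_COLORS: dict[str, str] = {
    "instance_of": "orange",
    "TeRS": "pink",
    "TrAD": "green",
    "is_a": "blue",
    "has_a": "red",
    "attribute_of": "purple",
}
_DEFAULT_EDGE_COLOR = "lightgray"


class GraphError(ValueError):
    pass


class PropertyGraph:
    """Thin wrapper over a ``networkx.MultiDiGraph`` with styled nodes."""

    def __init__(self, schema: SchemaGraph | None = None):
        self.g = nx.MultiDiGraph()
        self.schema = schema

    # -- construction ------------------------------------------------------

    def add_node(self, node_id: str, kind: str, label: str, **attrs) -> str:
        if kind not in NODE_STYLES:
            raise GraphError(f"unknown node kind {kind!r}")
        level, color, size = NODE_STYLES[kind]
        if node_id not in self.g:
            self.g.add_node(
                node_id, kind=kind, label=label, level=level, color=color,
                size=size, **attrs,
            )
        return node_id

    def add_patient(self, patient_id: str) -> str:
        return self.add_node(f"patient:{patient_id}", PATIENT, patient_id,
                             patient_id=patient_id)

    def add_class(self, class_name: str) -> str:
        return self.add_node(f"class:{class_name}", CLASS, class_name,
                             class_name=class_name)

    def add_concept(self, concept_id: str, label: str, class_name: str) -> str:
        return self.add_node(f"concept:{concept_id}", CONCEPT, label,
                             class_name=class_name, concept_id=concept_id)

    def add_entity(self, entity_id: str, label: str, class_name: str,
                   patient_id: str) -> str:
        return self.add_node(f"entity:{entity_id}", ENTITY, label,
                             class_name=class_name, patient_id=patient_id)

    def add_property_value(self, value_id: str, label: str, class_name: str) -> str:
        return self.add_node(f"value:{value_id}", PROPERTY_VALUE, label,
                             class_name=class_name)

    def add_edge(self, head_id: str, label: str, tail_id: str,
                 provenance: str = "structural", validate: bool = True) -> None:
        for n in (head_id, tail_id):
            if n not in self.g:
                raise GraphError(f"dangling edge endpoint {n!r}")
        if validate and self.schema is not None:
            if label not in self.schema.relations:
                raise GraphError(f"edge label {label!r} not in schema")
            head_cls = self.g.nodes[head_id].get("class_name")
            tail_cls = self.g.nodes[tail_id].get("class_name")
            if self.g.nodes[head_id]["kind"] == PATIENT:
                head_cls = "patient"
            if (
                not self.schema.relations[label].structural
                and head_cls in self.schema.classes
                and tail_cls in self.schema.classes
            ):
                verdict = self.schema.validate_edge(head_cls, label, tail_cls)
                if verdict != VALID:
                    raise GraphError(
                        f"edge ({head_id})-[{label}]->({tail_id}) is {verdict}"
                    )
        self.g.add_edge(
            head_id, tail_id, label=label,
            color=EDGE_COLORS.get(label, _DEFAULT_EDGE_COLOR),
            provenance=provenance,
        )

    # -- introspection -----------------------------------------------------

    def nodes_of_kind(self, kind: str) -> list[str]:
        return [n for n, d in self.g.nodes(data=True) if d["kind"] == kind]

    def edges(self) -> list[tuple[str, str, str]]:
        return [(u, v, d["label"]) for u, v, d in self.g.edges(data=True)]

    def __len__(self) -> int:
        return self.g.number_of_nodes()


def build_graph(
    documents: Sequence[tuple[GoldDocument, Sequence[LinkResult | None]]],
    schema: SchemaGraph,
    kb: KnowledgeBase | None = None,
) -> PropertyGraph:
    """Assemble the patient-centered graph from linked documents.

    Per document: one patient node; per linked entity mention a concept node
    (keyed by concept id) plus a per-patient entity node; ``has_a`` edges
    patient -> entity for disease/clinical finding/test/treatment entities;
    ``instance_of`` concept -> entity; ``is_a`` concept -> class and
    subclass -> parent class; ``attribute_of`` concept -> property value for
    property spans; every mention-level relation is lifted to entity nodes
    and validated against the schema.
    """
    pg = PropertyGraph(schema)
    concept_label: dict[str, tuple[str, str]] = {}
    if kb is not None:
        for c in kb.concepts:
            concept_label[c.concept_id] = (c.preferred_term, c.class_name)

    has_a_tails = ("disease", "clinical finding", "test", "treatment")

    for doc, links in documents:
        if len(links) != len(doc.mentions):
            raise GraphError(
                f"{doc.patient_id}: {len(links)} link results for "
                f"{len(doc.mentions)} mentions"
            )
        patient_node = pg.add_patient(doc.patient_id)
        entity_node_of: dict[int, str] = {}
        concept_of_mention: dict[int, str] = {}
        occurrence: dict[tuple[str, str], int] = {}
        for m, link in zip(doc.mentions, links):
            cls = span_type_to_class(m.sem_type)
            if cls is None:
                continue  # property values handled via attribute_of below
            if link is not None and link.concept_id is not None:
                cid = link.concept_id
                label, ccls = concept_label.get(cid, (m.surface, cls))
            else:
                cid = f"adhoc:{cls}:{m.surface}"
                label, ccls = m.surface, cls
            concept_node = pg.add_concept(cid, label, ccls)
            concept_of_mention[id(m)] = concept_node
            class_node = pg.add_class(ccls)
            pg.add_edge(concept_node, "is_a", class_node)
            top = schema.ancestry(ccls)[-1]
            if top != ccls:
                parent = pg.add_class(top)
                pg.add_edge(class_node, "is_a", parent)
            key = (doc.patient_id, cid)
            occurrence[key] = occurrence.get(key, 0) + 1
            entity_node = pg.add_entity(
                f"{doc.patient_id}:{cid}:{occurrence[key]}",
                label, ccls, doc.patient_id,
            )
            entity_node_of[id(m)] = entity_node
            pg.add_edge(concept_node, "instance_of", entity_node)
            if any(schema.class_satisfies(ccls, t) for t in has_a_tails):
                pg.add_edge(patient_node, "has_a", entity_node, provenance="structural")
        value_count = 0
        for rel in doc.relations:
            if isinstance(rel.head, str):
                continue  # patient-level relations are rebuilt structurally
            if rel.label == "attribute_of" or rel.tail.sem_type in PROPERTY_SPAN_TYPES:
                head_concept = concept_of_mention.get(id(rel.head))
                if head_concept is None:
                    continue
                value_count += 1
                vnode = pg.add_property_value(
                    f"{doc.patient_id}:{value_count}:{rel.tail.surface}",
                    rel.tail.surface,
                    f"{pg.g.nodes[head_concept]['class_name']} property",
                )
                pg.add_edge(head_concept, "attribute_of", vnode,
                            provenance="structural")
                continue
            head_node = entity_node_of.get(id(rel.head))
            tail_node = entity_node_of.get(id(rel.tail))
            if head_node is None or tail_node is None:
                raise GraphError(
                    f"{doc.patient_id}: relation {rel.label} endpoint has no "
                    "entity node"
                )
            pg.add_edge(head_node, rel.label, tail_node, provenance=rel.provenance)
    return pg


def patient_subgraph(pg: PropertyGraph, patient_id: str) -> PropertyGraph:
    """Nodes reachable from the patient via has_a plus one further hop."""
    root = f"patient:{patient_id}"
    if root not in pg.g:
        raise GraphError(f"unknown patient {patient_id!r}")
    keep = {root}
    for _u, v, d in pg.g.out_edges(root, data=True):
        if d["label"] != "has_a":
            continue
        keep.add(v)
        for _v2, w in pg.g.out_edges(v):
            keep.add(w)
    sub = PropertyGraph(pg.schema)
    sub.g = pg.g.subgraph(keep).copy()
    return sub


def _round_half_up_percent(count: int, total: int) -> int:
    return int((100.0 * count / total) + 0.5)


def treatment_frequency(
    pg: PropertyGraph, disease_name: str, n_patients: int
) -> list[tuple[str, int, int]]:
    """(treatment, distinct patient count, integer percent) rows for TrAD
    edges pointing at the named disease, sorted by descending count.

    Percent = round-half-up(100 * count / n_patients).
    """
    if n_patients <= 0:
        raise GraphError("n_patients must be positive")
    patients_per_treatment: dict[str, set[str]] = {}
    for u, v, d in pg.g.edges(data=True):
        if d["label"] != "TrAD":
            continue
        if pg.g.nodes[v].get("label") != disease_name:
            continue
        treatment = pg.g.nodes[u].get("label", u)
        patient = pg.g.nodes[u].get("patient_id") or pg.g.nodes[v].get("patient_id")
        patients_per_treatment.setdefault(treatment, set()).add(patient)
    rows = [
        (t, len(p), _round_half_up_percent(len(p), n_patients))
        for t, p in patients_per_treatment.items()
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows


def count_summary(pg: PropertyGraph) -> dict:
    """Per-class entity counts, per-label edge counts, and their totals.

    Entity nodes are grouped by their top-level class (when the graph knows
    its schema); property-value nodes by "<class> property".  Totals equal
    the sums of the per-category counts.
    """
    schema = getattr(pg, "schema", None)

    def roll_up(cls: str) -> str:
        if schema is not None and cls in schema.classes:
            return schema.ancestry(cls)[-1]
        return cls

    entities: dict[str, int] = {}
    for _n, d in pg.g.nodes(data=True):
        if d["kind"] == ENTITY:
            key = roll_up(d.get("class_name", "unknown"))
        elif d["kind"] == PROPERTY_VALUE:
            key = d.get("class_name", "property")
        else:
            continue
        entities[key] = entities.get(key, 0) + 1
    relations: dict[str, int] = {}
    for _u, _v, d in pg.g.edges(data=True):
        relations[d["label"]] = relations.get(d["label"], 0) + 1
    return {
        "entities": entities,
        "relations": relations,
        "total_entities": sum(entities.values()),
        "total_relations": sum(relations.values()),
    }


# -- export / import -------------------------------------------------------


def export(pg: PropertyGraph, fmt: str, path: str | Path) -> Path:
    """Write the graph as graphml, cypher, or json."""
    path = Path(path)
    if fmt == "graphml":
        g = nx.MultiDiGraph()
        for n, d in pg.g.nodes(data=True):
            g.add_node(n, **{k: _scalar(v) for k, v in d.items()})
        for u, v, k, d in pg.g.edges(data=True, keys=True):
            g.add_edge(u, v, key=k, **{k2: _scalar(v2) for k2, v2 in d.items()})
        nx.write_graphml(g, path, encoding="utf-8")
    elif fmt == "cypher":
        path.write_text(to_cypher(pg), "utf-8")
    elif fmt == "json":
        path.write_text(to_json(pg), "utf-8")
    else:
        raise GraphError(f"unknown export format {fmt!r}")
    return path


def _scalar(v):
    if isinstance(v, (str, int, float, bool)):
        return v
    return json.dumps(v, ensure_ascii=False)


def _cypher_escape(s: str) -> str:
    return str(s).replace("\\", "\\\\").replace("'", "\\'")


def to_cypher(pg: PropertyGraph) -> str:
    """CREATE-statement script; styling carried as properties."""
    lines = []
    var_of = {}
    for i, (n, d) in enumerate(pg.g.nodes(data=True)):
        var = f"n{i}"
        var_of[n] = var
        kind = d["kind"].replace("-", "_")
        props = ", ".join(
            f"{k}: '{_cypher_escape(v)}'"
            for k, v in [("id", n), *sorted(d.items())]
        )
        lines.append(f"CREATE ({var}:{kind} {{{props}}})")
    for u, v, d in pg.g.edges(data=True):
        props = ", ".join(
            f"{k}: '{_cypher_escape(val)}'"
            for k, val in sorted(d.items())
            if k != "label"
        )
        lines.append(
            f"CREATE ({var_of[u]})-[:{d['label']} {{{props}}}]->({var_of[v]})"
        )
    lines.append(";")
    return "\n".join(lines) + "\n"


def to_json(pg: PropertyGraph) -> str:
    doc = {
        "format_version": 1,
        "nodes": [{"id": n, **d} for n, d in sorted(pg.g.nodes(data=True))],
        "edges": [
            {"head": u, "tail": v, **d}
            for u, v, d in sorted(pg.g.edges(data=True), key=lambda e: (e[0], e[1], e[2]["label"]))
        ],
    }
    return json.dumps(doc, ensure_ascii=False, indent=1)


def import_json(path_or_text: str | Path) -> PropertyGraph:
    """Inverse of the JSON export (structure and attributes preserved)."""
    p = Path(path_or_text) if isinstance(path_or_text, Path) else None
    if p is None and isinstance(path_or_text, str):
        stripped = path_or_text.lstrip()
        if stripped.startswith("{"):
            text = path_or_text
        else:
            text = Path(path_or_text).read_text("utf-8")
    else:
        text = p.read_text("utf-8")
    doc = json.loads(text)
    pg = PropertyGraph()
    for n in doc["nodes"]:
        attrs = {k: v for k, v in n.items() if k != "id"}
        pg.g.add_node(n["id"], **attrs)
    for e in doc["edges"]:
        attrs = {k: v for k, v in e.items() if k not in ("head", "tail")}
        pg.g.add_edge(e["head"], e["tail"], **attrs)
    return pg
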
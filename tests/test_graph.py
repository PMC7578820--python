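import json
import xml.etree.ElementTree as ET

import pytest

from clinkg.graph import (
    GraphError,
    PropertyGraph,
    build_graph,
    count_summary,
    export,
    import_json,
    patient_subgraph,
    to_cypher,
    to_json,
    treatment_frequency,
)
from clinkg.linking import default_dictionaries, knowledge_base_from_lexicons, link_mentions
from clinkg.synth import GeneratorConfig, build_lexicons, generate_corpus
from clinkg.types import GoldDocument, Mention, RelationInstance

import numpy as np


def _doc_one_disease():
    text = "确诊胃癌。"
    m = Mention("P1", 2, 4, "胃癌", "disease")
    return GoldDocument(patient_id="P1", text=text, mentions=[m])


@pytest.fixture(scope="module")
def linked_corpus(schema):
    cfg = GeneratorConfig(n_patients=25, seed=33, synonym_rate=0.3)
    lex = build_lexicons(cfg, np.random.default_rng(cfg.seed))
    kb = knowledge_base_from_lexicons(lex, schema)
    dicts = default_dictionaries(lex)
    docs = generate_corpus(cfg)
    pairs = [(d, link_mentions(d.mentions, kb, dicts)) for d in docs]
    return pairs, kb


@pytest.fixture(scope="module")
def built(linked_corpus, schema):
    pairs, kb = linked_corpus
    return build_graph(pairs, schema, kb)


class TestBuild:
    def test_minimal_construction(self, schema):
        doc = _doc_one_disease()
        pg = build_graph([(doc, [None])], schema)
        kinds = {pg.g.nodes[n]["kind"] for n in pg.g.nodes}
        assert {"patient", "concept", "entity"} <= kinds
        labels = {d["label"] for _u, _v, d in pg.g.edges(data=True)}
        assert {"has_a", "instance_of"} <= labels

    def test_empty_input_empty_graph(self, schema):
        pg = build_graph([], schema)
        assert len(pg) == 0 and pg.edges() == []

    def test_attribute_of_property_value(self, schema):
        text = "胃原发性恶性肿瘤分期，pT1N0M0。"
        head = Mention("P1", 0, 8, "胃原发性恶性肿瘤", "disease")
        tail = Mention("P1", 11, 18, "pT1N0M0", "pathological stage")
        doc = GoldDocument(
            "P1", text, [head, tail],
            [RelationInstance("P1", "attribute_of", head, tail,
                              provenance="structural")],
        )
        pg = build_graph([(doc, [None, None])], schema)
        attr_edges = [(u, v) for u, v, d in pg.g.edges(data=True)
                      if d["label"] == "attribute_of"]
        assert len(attr_edges) == 1
        u, v = attr_edges[0]
        assert pg.g.nodes[u]["kind"] == "concept"
        assert pg.g.nodes[v]["kind"] == "property-value"
        assert pg.g.nodes[v]["label"] == "pT1N0M0"

    def test_every_edge_schema_listed(self, built, schema):
        for _u, _v, label in built.edges():
            assert label in schema.relations

    def test_entity_closure(self, built):
        # every entity node has an incoming has_a or instance_of edge
        for n in built.nodes_of_kind("entity"):
            incoming = {d["label"] for _u, _v, d in built.g.in_edges(n, data=True)}
            assert incoming & {"has_a", "instance_of"}

    def test_styling_contract(self, built):
        for n, d in built.g.nodes(data=True):
            if d["kind"] == "patient":
                assert d["color"] == "red" and d["level"] == 1
            if d["kind"] == "entity":
                assert d["color"] == "green" and d["level"] == 3
        sizes = {d["kind"]: d["size"] for _n, d in built.g.nodes(data=True)}
        assert sizes["patient"] == max(sizes.values())
        assert sizes["entity"] == min(sizes.values())

    def test_edge_palette(self, built):
        for _u, _v, d in built.g.edges(data=True):
            if d["label"] == "instance_of":
                assert d["color"] == "orange"
            if d["label"] == "TeRS":
                assert d["color"] == "pink"
            if d["label"] == "TrAD":
                assert d["color"] == "green"

    def test_invalid_edge_rejected(self, schema):
        pg = PropertyGraph(schema)
        a = pg.add_entity("e1", "甲", "treatment", "P1")
        b = pg.add_entity("e2", "乙", "body structure", "P1")
        with pytest.raises(GraphError):
            pg.add_edge(a, "LOCI", b)

    def test_dangling_endpoint_rejected(self, schema):
        pg = PropertyGraph(schema)
        a = pg.add_entity("e1", "甲", "disease", "P1")
        with pytest.raises(GraphError):
            pg.add_edge(a, "DCS", "entity:missing")


class TestPatientSubgraph:
    def test_patient_with_no_edges_singleton(self, schema):
        pg = PropertyGraph(schema)
        pg.add_patient("P9")
        sub = patient_subgraph(pg, "P9")
        assert len(sub) == 1

    def test_unknown_patient_rejected(self, built):
        with pytest.raises(GraphError):
            patient_subgraph(built, "NOPE")

    def test_subgraph_edges_subset(self, built):
        sub = patient_subgraph(built, "P0001")
        all_edges = built.edges()
        for e in sub.edges():
            assert e in all_edges

    def test_matches_brute_force_reachability(self, built):
        sub = patient_subgraph(built, "P0002")
        root = "patient:P0002"
        expected = {root}
        for _u, v, d in built.g.out_edges(root, data=True):
            if d["label"] == "has_a":
                expected.add(v)
                for _v2, w in built.g.out_edges(v):
                    expected.add(w)
        assert set(sub.g.nodes) == expected

    def test_contains_all_patient_entities(self, built):
        sub = patient_subgraph(built, "P0003")
        patient_entities = {
            n for n in built.nodes_of_kind("entity")
            if built.g.nodes[n]["patient_id"] == "P0003"
            and any(d["label"] == "has_a"
                    for _u, _v, d in built.g.in_edges(n, data=True))
        }
        assert patient_entities <= set(sub.g.nodes)


def _frequency_fixture(schema, spec_rows, disease="直肠腺癌"):
    """spec_rows: list of (treatment, class, patient_count)."""
    pg = PropertyGraph(schema)
    next_pid = 0
    for treatment, cls, count in spec_rows:
        for _ in range(count):
            pid = f"P{next_pid:05d}"
            next_pid += 1
            p = pg.add_patient(pid)
            d = pg.add_entity(f"{pid}:dis", disease, "disease", pid)
            t = pg.add_entity(f"{pid}:tr", treatment, cls, pid)
            pg.add_edge(p, "has_a", d)
            pg.add_edge(p, "has_a", t)
            pg.add_edge(t, "TrAD", d)
    return pg


class TestTreatmentFrequency:
    def test_printed_percentages(self, schema):
        pg = _frequency_fixture(schema, [
            ("Miles手术", "surgery", 365),
            ("奥沙利铂", "medicine", 110),
            ("XELOX方案", "medicine", 80),
        ])
        rows = {t: (c, p) for t, c, p in treatment_frequency(pg, "直肠腺癌", 731)}
        assert rows["Miles手术"] == (365, 50)
        assert rows["奥沙利铂"] == (110, 15)
        assert rows["XELOX方案"] == (80, 11)

    def test_zero_count_absent(self, schema):
        pg = _frequency_fixture(schema, [("Miles手术", "surgery", 3)])
        rows = treatment_frequency(pg, "直肠腺癌", 731)
        assert [r[0] for r in rows] == ["Miles手术"]
        assert rows[0][2] == 0  # 3/731 rounds to 0

    def test_absent_disease_empty(self, schema):
        pg = _frequency_fixture(schema, [("Miles手术", "surgery", 3)])
        assert treatment_frequency(pg, "不存在", 731) == []

    def test_sorted_descending(self, schema):
        pg = _frequency_fixture(schema, [
            ("a", "surgery", 5), ("b", "medicine", 9), ("c", "surgery", 7),
        ])
        assert [r[0] for r in treatment_frequency(pg, "直肠腺癌", 21)] == [
            "b", "c", "a",
        ]

    def test_internal_consistency(self, built, schema):
        for disease in ("直肠腺癌", "胃癌"):
            n = len(built.nodes_of_kind("patient"))
            for _t, count, pct in treatment_frequency(built, disease, n):
                assert pct == int(100.0 * count / n + 0.5)

    def test_nonpositive_n_rejected(self, built):
        with pytest.raises(GraphError):
            treatment_frequency(built, "直肠腺癌", 0)


class TestCountSummary:
    def test_empty_graph_zeros(self):
        s = count_summary(PropertyGraph())
        assert s["total_entities"] == 0 and s["total_relations"] == 0

    def test_totals_are_sums(self, built):
        s = count_summary(built)
        assert s["total_entities"] == sum(s["entities"].values())
        assert s["total_relations"] == sum(s["relations"].values())

    def test_entities_rolled_up_to_top_level(self, built, schema):
        s = count_summary(built)
        top = set(schema.top_level_classes())
        for key in s["entities"]:
            assert key in top or key.endswith(" property")


class TestExport:
    def test_graphml_is_valid_xml(self, built, tmp_path):
        path = export(built, "graphml", tmp_path / "g.graphml")
        root = ET.parse(path).getroot()
        assert root.tag.endswith("graphml")

    def test_cypher_script(self, built, schema):
        script = to_cypher(built)
        assert script.count("CREATE (") == (
            built.g.number_of_nodes() + built.g.number_of_edges()
        )
        for _u, _v, label in built.edges():
            assert f"-[:{label} " in script

    def test_empty_graph_exports(self, tmp_path):
        pg = PropertyGraph()
        for fmt in ("graphml", "cypher", "json"):
            export(pg, fmt, tmp_path / f"empty.{fmt}")
        assert json.loads((tmp_path / "empty.json").read_text("utf-8"))["nodes"] == []

    def test_json_round_trip_isomorphism(self, built, tmp_path):
        path = export(built, "json", tmp_path / "g.json")
        back = import_json(path)
        assert set(back.g.nodes) == set(built.g.nodes)
        assert sorted(back.edges()) == sorted(built.edges())
        for n in built.g.nodes:
            assert back.g.nodes[n] == built.g.nodes[n]

    def test_unknown_format_rejected(self, built, tmp_path):
        with pytest.raises(GraphError):
            export(built, "dot", tmp_path / "g.dot")
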
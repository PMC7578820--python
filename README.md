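# clinkg

Clinical-text knowledge-graph construction toolkit for Chinese-style
clinical documents: a schema-constrained pipeline running from raw text to
a patient-centered property graph, exercisable entirely on synthetic
corpora.

## Components

| Module | What it does |
| --- | --- |
| `clinkg.schema` | 7-class / 16-relation-type schema with domain/range constraints, subclass substitution, `allowed_relations`, `validate_edge`; shipped as versioned YAML (`clinkg/data/schema.yaml`) |
| `clinkg.synth` | Seeded generator of Chinese-clinical-style gold documents (mentions, negation states, relations), 8:1:1 corpus splitting, character-level BIO conversion, JSONL/standoff I/O |
| `clinkg.ner` | Character-level BiLSTM-CRF tagger over 12 span types (8 entity + 4 property) with character / POS / position / dictionary features; pure NumPy with manual backprop |
| `clinkg.assertion` | Rule-based positive/negative state tagging for disease and clinical-finding mentions (cues 无明显 / 没有 / 未见 / 不伴, clause-scoped with enumeration extension) |
| `clinkg.relex` | Sentence splitting, type-pair-constrained candidate generation with auto-labeling of unambiguous pairs, BiGRU + word/sentence dual-attention classifier with schema-masked decoding |
| `clinkg.linking` | Hierarchical batch entity linking: dedupe, class-scoped exact match (preferred then nonpreferred terms), dictionary expansion over 6 dictionaries, character-bigram cosine ranking |
| `clinkg.graph` | Patient-centered property graph (levels/colors styling), patient subgraphs, treatment-frequency statistics, per-class/per-label count summaries, GraphML / Cypher / JSON export |
| `clinkg.evaluation` | Entity-level exact-match P/R/F1, ICC(A,k) with 95% CI and verbal reliability bands, Likert means |
| `clinkg.crf`, `clinkg.nn` | Linear-chain CRF primitives (log-partition, marginals, Viterbi) and LSTM/GRU/attention layers with finite-difference-checked gradients |

The neural models are implemented directly in NumPy (no deep-learning
framework is required); gradients are verified against finite differences
in the test suite and the CRF against exhaustive enumeration.

## CLI

```bash
clinkg dump-schema --out schema.yaml
clinkg gen-corpus --n-patients 100 --seed 0 --out-docs docs.jsonl --out-ann ann.jsonl
clinkg train-ner --docs docs.jsonl --ann ann.jsonl --out ckpt
clinkg tag --model ckpt --docs docs.jsonl --out pred.jsonl
clinkg assert-state --docs docs.jsonl --ann pred.jsonl --out states.jsonl
clinkg link --kb concepts.tsv --dicts dicts.tsv --docs docs.jsonl --ann ann.jsonl --out links.jsonl
clinkg build-graph --docs docs.jsonl --ann ann.jsonl --out graph.json
clinkg stats --graph graph.json --disease 直肠腺癌 --n-patients 731
clinkg export --graph graph.json --format graphml --out graph.graphml
clinkg eval-ner --gold ann.jsonl --pred pred.jsonl
clinkg eval-icc --ratings ratings.csv
```

Corpus documents are JSONL (`{"patient_id", "text"}`); annotations are
JSONL standoff records (`{"kind": "mention", "doc_id", "start", "end",
"type", "state"}` and `{"kind": "relation", "doc_id", "label", "head",
"tail"}` with mention indices). Concept TSV columns: `concept_id, class,
preferred, english, synonyms(|), properties(|)`; dictionary TSV columns:
`category, surface, canonical`.

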
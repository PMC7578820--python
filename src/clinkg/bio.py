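"""Character-level BIO encoding of mention spans and its inverse."""

from __future__ import annotations

from .types import Mention, NOT_APPLICABLE

__all__ = ["spans_to_bio", "bio_to_spans"]


def spans_to_bio(text_len: int, mentions: list[Mention]) -> list[str]:
    """Per-character B-/I-/O labels; rejects overlapping spans."""
    labels = ["O"] * text_len
    for m in sorted(mentions, key=lambda m: m.start):
        if m.end > text_len:
            raise ValueError(f"span [{m.start}, {m.end}) outside text of length {text_len}")
        if any(labels[i] != "O" for i in range(m.start, m.end)):
            raise ValueError(f"overlapping gold spans at [{m.start}, {m.end})")
        labels[m.start] = f"B-{m.sem_type}"
        for i in range(m.start + 1, m.end):
            labels[i] = f"I-{m.sem_type}"
    return labels


def bio_to_spans(
    labels: list[str],
    text: str,
    doc_id: str = "doc",
    offset: int = 0,
    repair: bool = False,
) -> list[Mention]:
    """Decode BIO labels back to mentions.

    With ``repair=True`` an orphan I- tag (at sequence start, after O, or
    after a different span type) opens a new span as if it were B-; with
    ``repair=False`` such sequences are rejected.
    """
    if len(labels) != len(text):
        raise ValueError("label/text length mismatch")
    spans: list[Mention] = []
    start: int | None = None
    cur_type: str | None = None

    def close(end: int) -> None:
        nonlocal start, cur_type
        if start is not None:
            spans.append(
                Mention(
                    doc_id=doc_id,
                    start=offset + start,
                    end=offset + end,
                    surface=text[start:end],
                    sem_type=cur_type,
                    state=NOT_APPLICABLE,
                )
            )
        start, cur_type = None, None

    for i, lab in enumerate(labels):
        if lab == "O":
            close(i)
            continue
        if "-" not in lab:
            raise ValueError(f"malformed BIO label {lab!r}")
        prefix, sem_type = lab.split("-", 1)
        if prefix == "B":
            close(i)
            start, cur_type = i, sem_type
        elif prefix == "I":
            if start is not None and sem_type == cur_type:
                continue
            if not repair:
                raise ValueError(f"orphan {lab!r} at position {i}")
            close(i)
            start, cur_type = i, sem_type
        else:
            raise ValueError(f"malformed BIO label {lab!r}")
    close(len(labels))
    return spans
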
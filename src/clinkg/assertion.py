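"""Rule-based positive/negative state tagging for disease and finding spans.

A disease or clinical-finding mention is negative when a negation cue occurs
earlier in the same clause.  Cue scope additionally extends across commas
through an enumeration: a following clause that consists only of stateful
mentions plus closed-class filler (等, 及, 和, …) is still inside the scope,
so a single cue can negate a comma-separated list of findings.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

from .types import Mention, NEGATIVE, POSITIVE

__all__ = ["DEFAULT_CUES", "STRICT_CUES", "tag_states"]

#: default cue list; the bare 无 prefix is included so spans such as
#: 无阵发性加剧 are read as negated.
DEFAULT_CUES: tuple[str, ...] = ("无明显", "没有", "未见", "不伴", "无")

#: alternative cue list treating only the four full cue strings as cues
STRICT_CUES: tuple[str, ...] = ("无明显", "没有", "未见", "不伴")

#: clause boundaries
_CLAUSE_BOUNDARY = "，,；;。！？!?\n"

#: filler allowed inside a negated enumeration besides the mentions themselves
_ENUM_FILLER = re.compile(r"^[等及和、\s]*$")

#: span types that carry a state
_STATEFUL = {"disease", "symptom", "sign", "clinical finding"}


def _clauses(text: str) -> list[tuple[int, int]]:
    """(start, end) clause spans, boundaries excluded."""
    spans = []
    start = 0
    for i, ch in enumerate(text):
        if ch in _CLAUSE_BOUNDARY:
            spans.append((start, i))
            start = i + 1
    spans.append((start, len(text)))
    return [s for s in spans if s[1] > s[0]]


def _cue_positions(
    text: str, cues: Sequence[str], mentions: Sequence[Mention]
) -> list[tuple[int, int]]:
    """(start, end) of cue occurrences that do not overlap a mention."""
    taken = [(m.start, m.end) for m in mentions]
    out = []
    for cue in cues:
        for match in re.finditer(re.escape(cue), text):
            if any(match.start() < e and match.end() > s for s, e in taken):
                continue
            out.append((match.start(), match.end()))
    return sorted(set(out))


def tag_states(
    text: str,
    mentions: Iterable[Mention],
    cues: Sequence[str] = DEFAULT_CUES,
) -> list[Mention]:
    """Assign positive/negative states; idempotent, other types untouched.

    Mentions must lie within ``text`` and match its character slices.
    """
    mentions = sorted(mentions, key=lambda m: (m.start, m.end))
    for m in mentions:
        m.check_against(text)

    stateful = [m for m in mentions if m.sem_type in _STATEFUL]
    clause_spans = _clauses(text)
    cue_spans = _cue_positions(text, cues, mentions)

    def clause_index(pos: int) -> int:
        for i, (s, e) in enumerate(clause_spans):
            if s <= pos <= e:
                return i
        return len(clause_spans) - 1

    def enum_clause(idx: int) -> bool:
        """Clause is only stateful mentions plus filler."""
        s, e = clause_spans[idx]
        covered = list(text[s:e])
        for m in stateful:
            if m.start >= s and m.end <= e:
                for k in range(m.start - s, m.end - s):
                    covered[k] = ""
        return bool(_ENUM_FILLER.match("".join(covered)))

    negated_regions: list[tuple[int, int]] = []
    for cue_start, cue_end in cue_spans:
        ci = clause_index(cue_start)
        end = clause_spans[ci][1]
        j = ci + 1
        while j < len(clause_spans) and enum_clause(j):
            end = clause_spans[j][1]
            j += 1
        negated_regions.append((cue_end, end))

    out = []
    for m in mentions:
        if m.sem_type not in _STATEFUL:
            out.append(m)
            continue
        negative = any(s <= m.start and m.end <= e for s, e in negated_regions)
        out.append(m.with_state(NEGATIVE if negative else POSITIVE))
    return out
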
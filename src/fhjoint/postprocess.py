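"""Deterministic rules turning model output into final challenge records.

Covers side-of-family assignment for the three-type tagging scheme (the
five-type scheme reads the side off the entity tag), normalization of
family-member surfaces to the 15 canonical roles, keyword-based detection of
the Alive/Healthy living-status attributes, and the integer LS score, where
the total score is the alive score times the healthy score.

All functions are pure: same input, same output, no hidden state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .corpus import (
    Document,
    EntityMention,
    RelationInstance,
    ROLES,
    Sentence,
    is_family_member_type,
    normalize_observation_text,
)

# ---------------------------------------------------------------------------
# Configuration

#: Immediate family: side of family is NA by rule, before any other evidence.
FIRST_DEGREE = frozenset(
    {"Father", "Mother", "Parent", "Brother", "Sister", "Sibling",
     "Son", "Daughter", "Child"}
)


@dataclass(frozen=True)
class PostprocessConfig:
    """Keyword sets and proximity window for the rule cascade."""

    alive_keywords: frozenset = frozenset({"alive", "living"})
    healthy_keywords: frozenset = frozenset({"healthy", "well"})
    deceased_keywords: frozenset = frozenset(
        {"deceased", "dead", "died", "passed", "expired"})
    first_degree: frozenset = FIRST_DEGREE
    #: indicator token may appear this many tokens before the mention
    indicator_window: int = 3
    #: attribute pair for an LS mention containing no keyword at all
    no_keyword_default: tuple = ("Yes", "NA")


DEFAULT_CONFIG = PostprocessConfig()


# ---------------------------------------------------------------------------
# Section context


@dataclass(frozen=True)
class SectionContext:
    """Non-overlapping character ranges covering the document, each tagged
    with the active family-history section: maternal, paternal or none."""

    ranges: tuple[tuple[int, int, str], ...]

    def side_at(self, char_pos: int) -> str:
        for start, end, side in self.ranges:
            if start <= char_pos < end:
                return side
        return "none"


_HEADER_RE = re.compile(r"^\s*(maternal|paternal)\s+family\s+history\s*:",
                        re.IGNORECASE | re.MULTILINE)


def detect_sections(document_text: str) -> SectionContext:
    """Find ``maternal/paternal family history:`` headers; each opens a
    section running to the next header or end of document."""
    boundaries = [(m.start(), m.group(1).lower()) for m in
                  _HEADER_RE.finditer(document_text)]
    n = max(len(document_text), 1)
    if not boundaries:
        return SectionContext(((0, n, "none"),))
    ranges: list[tuple[int, int, str]] = []
    if boundaries[0][0] > 0:
        ranges.append((0, boundaries[0][0], "none"))
    for i, (start, side) in enumerate(boundaries):
        end = boundaries[i + 1][0] if i + 1 < len(boundaries) else n
        ranges.append((start, end, side))
    return SectionContext(tuple(ranges))


# ---------------------------------------------------------------------------
# Family-member role normalization

_ROLE_LEXICON: dict[str, str] = {}
for _role in ROLES:
    _ROLE_LEXICON[_role.lower()] = _role
    _ROLE_LEXICON[_role.lower() + "s"] = _role
_ROLE_LEXICON.update({
    "children": "Child", "grandma": "Grandmother", "grandpa": "Grandfather",
    "dad": "Father", "mom": "Mother", "mum": "Mother", "siblings": "Sibling",
    "grandmothers": "Grandmother", "grandfathers": "Grandfather",
})

# role of "X's Y": keyed by (role of X, role of Y)
_COMPOSITION: dict[tuple[str, str], str] = {
    ("Father", "Father"): "Grandfather",
    ("Father", "Mother"): "Grandmother",
    ("Mother", "Father"): "Grandfather",
    ("Mother", "Mother"): "Grandmother",
    ("Parent", "Father"): "Grandfather",
    ("Parent", "Mother"): "Grandmother",
    ("Father", "Parent"): "Grandparent",
    ("Mother", "Parent"): "Grandparent",
    ("Parent", "Parent"): "Grandparent",
    ("Father", "Brother"): "Uncle",
    ("Father", "Sister"): "Aunt",
    ("Mother", "Brother"): "Uncle",
    ("Mother", "Sister"): "Aunt",
    ("Aunt", "Child"): "Cousin",
    ("Uncle", "Child"): "Cousin",
    ("Aunt", "Son"): "Cousin",
    ("Aunt", "Daughter"): "Cousin",
    ("Uncle", "Son"): "Cousin",
    ("Uncle", "Daughter"): "Cousin",
}

#: returned when no role can be assigned at all
REJECT_ROLE = "REJECT"

_POSSESSIVE_RE = re.compile(r"['’]s$")


def normalize_family_member(surface: str) -> str:
    """Map a family-member surface to a canonical role.

    Case-insensitive lexicon lookup with singular/plural folding; possessive
    chains like ``father's father`` are composed left to right (grandfather).
    An unmappable chain falls back to the role of its head noun; a surface
    with no recognizable relative word returns :data:`REJECT_ROLE`.
    """
    words = [w for w in surface.lower().split() if w not in {"the", "a", "an"}]
    roles = []
    for word in words:
        bare = _POSSESSIVE_RE.sub("", word)
        if bare in _ROLE_LEXICON:
            roles.append(_ROLE_LEXICON[bare])
    if not roles:
        return REJECT_ROLE
    current = roles[0]
    for nxt in roles[1:]:
        composed = _COMPOSITION.get((current, nxt))
        current = composed if composed is not None else nxt
    return current


# ---------------------------------------------------------------------------
# Side of family (three-type scheme)


def side_of_family(fm: EntityMention, sentence: Sentence,
                   sections: SectionContext,
                   config: PostprocessConfig = DEFAULT_CONFIG) -> str:
    """Assign Maternal/Paternal/NA to a family-member mention.

    Rules fire strictly in order: (1) first-degree relative -> NA;
    (2) enclosing maternal/paternal section header -> that side;
    (3) indicator token ("maternal"/"paternal") within the preceding window
    in the same sentence -> that side; (4) otherwise NA.
    """
    role = fm.attrs.get("role") or normalize_family_member(fm.surface)
    if role in config.first_degree:
        return "NA"
    mention_char = sentence.tokens[fm.token_start].char_start
    section_side = sections.side_at(mention_char)
    if section_side == "maternal":
        return "Maternal"
    if section_side == "paternal":
        return "Paternal"
    lo = max(0, fm.token_start - config.indicator_window)
    for tok in sentence.tokens[lo:fm.token_start]:
        word = tok.text.lower()
        if word == "maternal":
            return "Maternal"
        if word == "paternal":
            return "Paternal"
    return "NA"


# ---------------------------------------------------------------------------
# Living status


def living_status_attrs(ls_surface: str,
                        config: PostprocessConfig = DEFAULT_CONFIG
                        ) -> tuple[str, str]:
    """Keyword scan of a living-status surface -> (alive, healthy).

    healthy is Yes iff a healthy keyword appears, else NA; alive is No iff a
    deceased keyword appears, else Yes iff an alive keyword appears, else the
    configured no-keyword default (a living-status mention with no death
    evidence defaults to alive).
    """
    words = set(re.findall(r"[a-z]+", ls_surface.lower()))
    healthy = "Yes" if words & config.healthy_keywords else "NA"
    if words & config.deceased_keywords:
        return "No", healthy
    if words & config.alive_keywords:
        return "Yes", healthy
    return config.no_keyword_default[0], healthy  # no-evidence default: alive


_ALIVE_SCORE = {"Yes": 2, "No": 0}
_HEALTHY_SCORE = {"Yes": 2, "NA": 1, "No": 0}


def ls_score(alive: str, healthy: str) -> int:
    """Total living-status score = alive score x healthy score.

    Alive No scores 0 regardless of healthy; alive Yes with healthy NA
    scores 2; alive Yes with healthy Yes scores 4 (alive 2 x healthy 2).
    """
    if alive not in _ALIVE_SCORE:
        raise ValueError(f"invalid alive value {alive!r}")
    if healthy not in _HEALTHY_SCORE:
        raise ValueError(f"invalid healthy value {healthy!r}")
    return _ALIVE_SCORE[alive] * _HEALTHY_SCORE[healthy]


# ---------------------------------------------------------------------------
# Record assembly


def fm_record_fields(fm: EntityMention, document: Document, scheme: str,
                     sections: SectionContext | None = None,
                     config: PostprocessConfig = DEFAULT_CONFIG
                     ) -> tuple[str, str]:
    """(role, side) for a family-member mention under either scheme."""
    role = normalize_family_member(fm.surface)
    if scheme == "five":
        side = fm.etype  # Maternal / Paternal / NA read off the tag
        if role in config.first_degree:
            side = "NA"
    else:
        if sections is None:
            sections = detect_sections(document.text)
        side = side_of_family(fm, document.sentences[fm.sentence_index],
                              sections, config)
    return role, side


def to_challenge_records(document: Document, entities: list[EntityMention],
                         relations: list[RelationInstance], scheme: str,
                         config: PostprocessConfig = DEFAULT_CONFIG
                         ) -> tuple[set[tuple], set[tuple]]:
    """Convert one document's entities and positive relations into the
    deduplicated subtask-1 and subtask-2 record tuples."""
    sections = detect_sections(document.text)
    subtask1: set[tuple] = set()
    subtask2: set[tuple] = set()
    fm_fields: dict[int, tuple[str, str]] = {}
    for ent in entities:
        if is_family_member_type(ent.etype, scheme):
            role, side = fm_record_fields(ent, document, scheme, sections, config)
            if role == REJECT_ROLE:
                continue
            fm_fields[id(ent)] = (role, side)
            subtask1.add((document.doc_id, "FamilyMember", role, side))
        elif ent.etype == "Observation":
            subtask1.add((document.doc_id, "Observation",
                          normalize_observation_text(ent.surface)))
    for rel in relations:
        if not rel.label or id(rel.fm) not in fm_fields:
            continue
        role, side = fm_fields[id(rel.fm)]
        if rel.target.etype == "Observation":
            subtask2.add((document.doc_id, role, side, "Observation",
                          normalize_observation_text(rel.target.surface)))
        elif rel.target.etype == "LivingStatus":
            alive, healthy = living_status_attrs(rel.target.surface, config)
            subtask2.add((document.doc_id, role, side, "LivingStatus",
                          ls_score(alive, healthy)))
    return subtask1, subtask2
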
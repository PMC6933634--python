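"""Domain types and text plumbing for family-history extraction.

Holds the tokenized-document model (documents, sentences, tokens with
character offsets and POS tags), entity/relation types for both tagging
schemes, the BIO label codec, and readers/writers for plain-text documents,
tab-separated standoff annotations, and challenge-style output records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

# ---------------------------------------------------------------------------
# Inventories

#: The 15 canonical family-member roles.
ROLES = (
    "Father", "Mother", "Sister", "Parent", "Brother",
    "Grandmother", "Grandfather", "Grandparent", "Daughter", "Son",
    "Child", "Cousin", "Sibling", "Aunt", "Uncle",
)

SIDES = ("Maternal", "Paternal", "NA")

#: Entity types of the three-type tagging scheme.
THREE_TYPES = ("FamilyMember", "Observation", "LivingStatus")
#: Entity types of the five-type scheme: family-member tags carry the side.
FIVE_TYPES = ("Maternal", "Paternal", "NA", "Observation", "LivingStatus")

SCHEMES = {"three": THREE_TYPES, "five": FIVE_TYPES}

#: Family-member entity types per scheme (the rest are attribute targets).
FM_TYPES = {"three": ("FamilyMember",), "five": ("Maternal", "Paternal", "NA")}


def is_family_member_type(etype: str, scheme: str) -> bool:
    return etype in FM_TYPES[scheme]


def entities_for_scheme(entities: Sequence["EntityMention"], scheme: str
                        ) -> list["EntityMention"]:
    """Re-type canonical (three-type) gold entities for a tagging scheme.

    Under the five-type scheme the family-member tag itself carries the side
    of family, taken from the mention's ``side`` attribute (NA if absent).
    """
    if scheme == "three":
        return list(entities)
    out = []
    for ent in entities:
        if ent.etype == "FamilyMember":
            out.append(replace(ent, etype=ent.attrs.get("side", "NA")))
        else:
            out.append(ent)
    return out


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class Token:
    """A word with its Penn-Treebank POS tag and document character span."""

    text: str
    pos: str
    char_start: int
    char_end: int

    def __post_init__(self) -> None:
        if not self.char_start < self.char_end:
            raise ValueError(
                f"token span must be non-empty: [{self.char_start}, {self.char_end})"
            )


@dataclass(frozen=True)
class Sentence:
    tokens: tuple[Token, ...]
    doc_id: str
    index: int

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("sentence must contain at least one token")
        object.__setattr__(self, "tokens", tuple(self.tokens))
        prev_end = -1
        for tok in self.tokens:
            if tok.char_start < prev_end:
                raise ValueError("tokens must be ordered and non-overlapping")
            prev_end = tok.char_end

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def char_start(self) -> int:
        return self.tokens[0].char_start

    @property
    def char_end(self) -> int:
        return self.tokens[-1].char_end


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str
    sentences: tuple[Sentence, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sentences", tuple(self.sentences))


@dataclass(frozen=True)
class EntityMention:
    """A typed token span within one sentence of one document.

    ``attrs`` carries normalized attributes where known: ``role`` and
    ``side`` for family members, ``alive``/``healthy``/``score`` for
    living-status mentions.
    """

    doc_id: str
    sentence_index: int
    token_start: int
    token_end: int
    etype: str
    surface: str
    attrs: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.token_start < self.token_end:
            raise ValueError("entity token span must be non-empty")

    @property
    def span(self) -> tuple[int, int]:
        return (self.token_start, self.token_end)


@dataclass(frozen=True)
class FamilyMemberRecord:
    mention: EntityMention
    role: str
    side: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown family-member role: {self.role!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side of family: {self.side!r}")


@dataclass(frozen=True)
class RelationInstance:
    """A (family member, observation-or-living-status) candidate pair."""

    fm: EntityMention
    target: EntityMention
    label: bool

    def __post_init__(self) -> None:
        if self.fm.doc_id != self.target.doc_id:
            raise ValueError("relation arguments must share a document")
        if self.fm.sentence_index != self.target.sentence_index:
            raise ValueError("relation arguments must share a sentence")


@dataclass(frozen=True)
class BioLabel:
    tag: str  # B, I or O
    etype: str = ""

    def __post_init__(self) -> None:
        if self.tag not in ("B", "I", "O"):
            raise ValueError(f"invalid BIO tag {self.tag!r}")
        if self.tag == "O" and self.etype:
            raise ValueError("O label carries no entity type")
        if self.tag != "O" and not self.etype:
            raise ValueError("B/I labels require an entity type")

    def __str__(self) -> str:
        return "O" if self.tag == "O" else f"{self.tag}-{self.etype}"

    @classmethod
    def parse(cls, text: str) -> "BioLabel":
        if text == "O":
            return cls("O")
        tag, _, etype = text.partition("-")
        return cls(tag, etype)


O_LABEL = BioLabel("O")


def scheme_labels(scheme: str) -> tuple[BioLabel, ...]:
    """All BIO labels of a scheme, O first then B/I per type."""
    labels = [O_LABEL]
    for etype in SCHEMES[scheme]:
        labels.append(BioLabel("B", etype))
        labels.append(BioLabel("I", etype))
    return tuple(labels)


# ---------------------------------------------------------------------------
# Tokenization and POS tagging

# Words keep internal hyphens and apostrophes so possessives ("father's") and
# compounds ("72-year-old") stay single tokens; everything else that is not
# whitespace becomes a one-character punctuation token.
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:[-'’][A-Za-z0-9]+)*|[^\sA-Za-z0-9]")

# Sentences end at newlines or at ./!/? followed by whitespace.
_SENT_BREAK_RE = re.compile(r"(?<=[.!?])\s+|\n+")

_POS_LEXICON = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "his": "PRP$", "her": "PRP$", "their": "PRP$", "my": "PRP$", "its": "PRP$",
    "he": "PRP", "she": "PRP", "they": "PRP", "it": "PRP", "who": "WP",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "has": "VBZ", "have": "VBP", "had": "VBD",
    "and": "CC", "or": "CC", "but": "CC",
    "of": "IN", "in": "IN", "at": "IN", "with": "IN", "for": "IN",
    "from": "IN", "on": "IN", "by": "IN", "to": "TO", "as": "IN",
    "not": "RB", "also": "RB", "still": "RB", "currently": "RB",
    "no": "DT", "both": "DT", "all": "DT",
    "reports": "VBZ", "reported": "VBD", "denies": "VBZ", "states": "VBZ",
    "diagnosed": "VBN", "died": "VBD", "passed": "VBD",
    "alive": "JJ", "healthy": "JJ", "well": "JJ", "deceased": "JJ",
    "dead": "JJ", "living": "JJ", "unknown": "JJ",
    "maternal": "JJ", "paternal": "JJ",
    ".": ".", ",": ",", ":": ":", ";": ":", "?": ".", "!": ".",
    "(": "-LRB-", ")": "-RRB-", '"': "``", "'": "''",
}

UNK_POS = "UNK"


def _pos_of(word: str) -> str:
    """Heuristic Penn-Treebank tag: lexicon, then shape/suffix rules."""
    lower = word.lower()
    if lower in _POS_LEXICON:
        return _POS_LEXICON[lower]
    if re.fullmatch(r"\d+(\.\d+)?", word):
        return "CD"
    if re.fullmatch(r"\d[\w-]*", word):
        return "JJ"  # "72-year-old"
    if "'" in word or "’" in word:
        return "NN"  # possessive-bearing nominal, e.g. "father's"
    if word[0].isupper():
        return "NNP"
    if lower.endswith("ly"):
        return "RB"
    if lower.endswith("ing"):
        return "VBG"
    if lower.endswith("ed"):
        return "VBD"
    if lower.endswith("s"):
        return "NNS"
    if not word[0].isalnum():
        return UNK_POS
    return "NN"


def tokenize(document_text: str, doc_id: str = "doc") -> list[Sentence]:
    """Sentence-split and word-tokenize raw text, preserving offsets.

    Offsets are 0-based half-open character positions into ``document_text``,
    so ``document_text[t.char_start:t.char_end] == t.text`` for every token.
    """
    sentences: list[Sentence] = []
    cursor = 0
    pieces: list[tuple[int, str]] = []
    for m in _SENT_BREAK_RE.finditer(document_text):
        pieces.append((cursor, document_text[cursor:m.start()]))
        cursor = m.end()
    pieces.append((cursor, document_text[cursor:]))

    index = 0
    for offset, piece in pieces:
        tokens = [
            Token(m.group(), _pos_of(m.group()), offset + m.start(), offset + m.end())
            for m in _TOKEN_RE.finditer(piece)
        ]
        if tokens:
            sentences.append(Sentence(tuple(tokens), doc_id, index))
            index += 1
    return sentences


def make_document(doc_id: str, text: str) -> Document:
    return Document(doc_id, text, tuple(tokenize(text, doc_id)))


# ---------------------------------------------------------------------------
# BIO encoding / decoding


def _check_entities(sentence: Sentence, entities: Sequence[EntityMention],
                    scheme: str) -> None:
    valid_types = SCHEMES[scheme]
    occupied = [False] * len(sentence)
    for ent in sorted(entities, key=lambda e: e.token_start):
        if ent.etype not in valid_types:
            raise ValueError(
                f"entity type {ent.etype!r} not in scheme {scheme!r}")
        if ent.token_end > len(sentence):
            raise ValueError(
                f"entity span {ent.span} exceeds sentence of {len(sentence)} tokens")
        for t in range(ent.token_start, ent.token_end):
            if occupied[t]:
                raise ValueError(
                    f"overlapping entities at token {t} of sentence "
                    f"{sentence.index} in {sentence.doc_id!r}")
            occupied[t] = True


def bio_encode(sentence: Sentence, entities: Sequence[EntityMention],
               scheme: str = "three") -> list[BioLabel]:
    """One BIO label per token; rejects overlapping or out-of-range spans."""
    _check_entities(sentence, entities, scheme)
    labels = [O_LABEL] * len(sentence)
    for ent in entities:
        labels[ent.token_start] = BioLabel("B", ent.etype)
        for t in range(ent.token_start + 1, ent.token_end):
            labels[t] = BioLabel("I", ent.etype)
    return labels


def bio_decode(labels: Sequence[BioLabel]) -> list[tuple[int, int, str]]:
    """Decode any label sequence into (start, end, etype) spans.

    Total on ill-formed input: an I following O or a different type opens a
    new entity, so no prediction is ever dropped.
    """
    spans: list[tuple[int, int, str]] = []
    start: int | None = None
    etype = ""
    for t, lab in enumerate(labels):
        if lab.tag == "B" or (lab.tag == "I" and (start is None or lab.etype != etype)):
            if start is not None:
                spans.append((start, t, etype))
            start, etype = t, lab.etype
        elif lab.tag == "O":
            if start is not None:
                spans.append((start, t, etype))
            start = None
    if start is not None:
        spans.append((start, len(labels), etype))
    return spans


def spans_to_mentions(sentence: Sentence,
                      spans: Iterable[tuple[int, int, str]]) -> list[EntityMention]:
    out = []
    for start, end, etype in spans:
        surface = " ".join(tok.text for tok in sentence.tokens[start:end])
        out.append(EntityMention(sentence.doc_id, sentence.index,
                                 start, end, etype, surface))
    return out


# ---------------------------------------------------------------------------
# Standoff annotation I/O
#
# One TSV file per document:
#   E<TAB>doc_id<TAB>etype<TAB>char_start<TAB>char_end<TAB>surface[<TAB>k=v;...]
#   R<TAB>doc_id<TAB>fm_ordinal<TAB>target_ordinal
# Ordinals index entity lines (0-based, in file order).


class StandoffError(ValueError):
    """Malformed standoff annotation, with file and line context."""


def _format_attrs(attrs: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in sorted(attrs.items()))


def _parse_attrs(text: str) -> dict:
    attrs: dict = {}
    for part in text.split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key] = int(value) if value.lstrip("-").isdigit() else value
    return attrs


def char_span_to_token_span(document: Document, char_start: int,
                            char_end: int) -> tuple[int, int, int]:
    """Map a document character span to (sentence_index, token_start, token_end)."""
    for sent in document.sentences:
        if sent.char_start <= char_start and char_end <= sent.char_end:
            starts = [t.char_start for t in sent.tokens]
            ends = [t.char_end for t in sent.tokens]
            if char_start not in starts or char_end not in ends:
                raise ValueError(
                    f"char span [{char_start}, {char_end}) is not token-aligned "
                    f"in {document.doc_id!r}")
            return sent.index, starts.index(char_start), ends.index(char_end) + 1
    raise ValueError(
        f"char span [{char_start}, {char_end}) crosses sentence boundaries "
        f"or lies outside {document.doc_id!r}")


def mention_char_span(document: Document, mention: EntityMention) -> tuple[int, int]:
    sent = document.sentences[mention.sentence_index]
    return (sent.tokens[mention.token_start].char_start,
            sent.tokens[mention.token_end - 1].char_end)


def write_standoff(path: str | Path, document: Document,
                   entities: Sequence[EntityMention],
                   relations: Sequence[RelationInstance]) -> None:
    entities = list(entities)
    index = {id(e): i for i, e in enumerate(entities)}
    lines = []
    for ent in entities:
        cs, ce = mention_char_span(document, ent)
        fields = ["E", document.doc_id, ent.etype, str(cs), str(ce), ent.surface]
        if ent.attrs:
            fields.append(_format_attrs(ent.attrs))
        lines.append("\t".join(fields))
    for rel in relations:
        if not rel.label:
            continue
        lines.append("\t".join(["R", document.doc_id,
                                str(index[id(rel.fm)]), str(index[id(rel.target)])]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""),
                          encoding="utf-8")


def read_standoff(path: str | Path, document: Document
                  ) -> tuple[list[EntityMention], list[RelationInstance]]:
    """Parse a standoff file against its document; errors name file and line."""
    path = Path(path)
    entities: list[EntityMention] = []
    relations: list[RelationInstance] = []
    pending: list[tuple[int, int, int]] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        kind = fields[0]
        try:
            if kind == "E":
                if len(fields) not in (6, 7):
                    raise ValueError(f"expected 6 or 7 fields, got {len(fields)}")
                _, doc_id, etype, cs, ce, surface = fields[:6]
                attrs = _parse_attrs(fields[6]) if len(fields) == 7 else {}
                si, ts, te = char_span_to_token_span(document, int(cs), int(ce))
                entities.append(EntityMention(doc_id, si, ts, te, etype,
                                              surface, attrs))
            elif kind == "R":
                if len(fields) != 4:
                    raise ValueError(f"expected 4 fields, got {len(fields)}")
                pending.append((lineno, int(fields[2]), int(fields[3])))
            else:
                raise ValueError(f"unknown record kind {kind!r}")
        except (ValueError, IndexError) as exc:
            raise StandoffError(f"{path.name}:{lineno}: {exc}") from exc
    for lineno, fm_i, tg_i in pending:
        try:
            relations.append(RelationInstance(entities[fm_i], entities[tg_i], True))
        except (IndexError, ValueError) as exc:
            raise StandoffError(f"{path.name}:{lineno}: {exc}") from exc
    return entities, relations


# ---------------------------------------------------------------------------
# Challenge-style output records
#
# subtask 1: ("doc_id", "FamilyMember", role, side) and
#            ("doc_id", "Observation", text)
# subtask 2: ("doc_id", role, side, "LivingStatus", score) and
#            ("doc_id", role, side, "Observation", text)


def normalize_observation_text(text: str) -> str:
    return " ".join(text.lower().split())


def write_challenge_output(path: str | Path, records: Iterable[tuple],
                           subtask: int) -> None:
    if subtask not in (1, 2):
        raise ValueError("subtask must be 1 or 2")
    unique = sorted({tuple(str(f) for f in rec) for rec in records})
    Path(path).write_text(
        "".join("\t".join(rec) + "\n" for rec in unique), encoding="utf-8")


def read_challenge_output(path: str | Path) -> list[tuple[str, ...]]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return [tuple(line.split("\t")) for line in lines if line.strip()]
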
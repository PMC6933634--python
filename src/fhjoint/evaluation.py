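"""Precision/recall/F1 scoring over deduplicated challenge record tuples.

Subtask 1 scores family-member records as exact (doc, role, side) tuples —
broken down by side — and observations as (doc, normalized text) tuples.
Subtask 2 scores family-member/observation and family-member/living-status
relations as exact tuples including the living-status score. Overall rows
are micro-averages of the included categories; living-status mention rows
are reported but excluded from the subtask-1 overall (their gold standard in
the challenge is indirect).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .corpus import normalize_observation_text


@dataclass(frozen=True)
class CategoryScore:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class EvalReport:
    categories: Mapping[str, CategoryScore]
    overall: CategoryScore

    def as_rows(self) -> list[tuple]:
        rows = [(name, s.tp, s.fp, s.fn, s.precision, s.recall, s.f1)
                for name, s in self.categories.items()]
        o = self.overall
        rows.append(("Overall", o.tp, o.fp, o.fn, o.precision, o.recall, o.f1))
        return rows

    def to_tsv(self) -> str:
        lines = ["category\tTP\tFP\tFN\tP\tR\tF1"]
        for name, tp, fp, fn, p, r, f1 in self.as_rows():
            lines.append(f"{name}\t{tp}\t{fp}\t{fn}\t{p:.4f}\t{r:.4f}\t{f1:.4f}")
        return "\n".join(lines) + "\n"


def prf1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from counts; zero denominators score 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def _score_sets(gold: set, pred: set) -> CategoryScore:
    tp = len(gold & pred)
    fp = len(pred - gold)
    fn = len(gold - pred)
    return CategoryScore(tp, fp, fn, *prf1(tp, fp, fn))


def _micro(scores: Iterable[CategoryScore]) -> CategoryScore:
    scores = list(scores)
    tp = sum(s.tp for s in scores)
    fp = sum(s.fp for s in scores)
    fn = sum(s.fn for s in scores)
    return CategoryScore(tp, fp, fn, *prf1(tp, fp, fn))


def _dedup(records: Iterable[tuple]) -> set[tuple]:
    return {tuple(str(f) for f in rec) for rec in records}


def score_subtask1(gold_records: Iterable[tuple],
                   pred_records: Iterable[tuple]) -> EvalReport:
    """Entity-level scoring on deduplicated record tuples.

    Family members match on exact (doc, role, side); observations on
    (doc, lowercased whitespace-collapsed text). Records tagged LivingStatus
    (optional ``(doc, "LivingStatus", text)`` tuples) get their own row but
    do not enter the overall micro-average.
    """
    gold = _dedup(gold_records)
    pred = _dedup(pred_records)

    def by_kind(records: set, kind: str, predicate=lambda rec: True) -> set:
        return {rec for rec in records if rec[1] == kind and predicate(rec)}

    categories: dict[str, CategoryScore] = {}
    for side in ("Maternal", "Paternal", "NA"):
        categories[f"FamilyMember ({side})"] = _score_sets(
            by_kind(gold, "FamilyMember", lambda r: r[3] == side),
            by_kind(pred, "FamilyMember", lambda r: r[3] == side))
    categories["Observation"] = _score_sets(
        {rec[:1] + rec[1:2] + (normalize_observation_text(rec[2]),)
         for rec in by_kind(gold, "Observation")},
        {rec[:1] + rec[1:2] + (normalize_observation_text(rec[2]),)
         for rec in by_kind(pred, "Observation")})
    included = list(categories.values())
    ls_gold = by_kind(gold, "LivingStatus")
    ls_pred = by_kind(pred, "LivingStatus")
    if ls_gold or ls_pred:
        categories["LivingStatus"] = _score_sets(ls_gold, ls_pred)
    return EvalReport(categories, _micro(included))


def score_subtask2(gold_records: Iterable[tuple],
                   pred_records: Iterable[tuple]) -> EvalReport:
    """Relation-level scoring: exact (doc, role, side, kind, value) tuples,
    micro-averaged across the two relation kinds for the overall row."""
    gold = _dedup(gold_records)
    pred = _dedup(pred_records)
    categories = {}
    for kind, name in (("Observation", "FM-Observation"),
                       ("LivingStatus", "FM-LS")):
        categories[name] = _score_sets(
            {rec for rec in gold if rec[3] == kind},
            {rec for rec in pred if rec[3] == kind})
    return EvalReport(categories, _micro(categories.values()))


# ---------------------------------------------------------------------------
# Mention / pair level scoring (model diagnostics, independent of the
# rule-based record conversion)


def mention_prf(gold_mentions: Iterable, pred_mentions: Iterable
                ) -> tuple[float, float, float]:
    """Exact span+type matching of entity mentions."""
    as_key = lambda m: (m.doc_id, m.sentence_index, m.token_start,
                        m.token_end, m.etype)
    gold = {as_key(m) for m in gold_mentions}
    pred = {as_key(m) for m in pred_mentions}
    tp = len(gold & pred)
    return prf1(tp, len(pred - gold), len(gold - pred))


def relation_prf(gold_relations: Iterable, pred_relations: Iterable
                 ) -> tuple[float, float, float]:
    """Exact matching of positive (fm span, target span) pairs."""
    as_key = lambda r: (r.fm.doc_id, r.fm.sentence_index, r.fm.span,
                        r.target.span)
    gold = {as_key(r) for r in gold_relations if r.label}
    pred = {as_key(r) for r in pred_relations if r.label}
    tp = len(gold & pred)
    return prf1(tp, len(pred - gold), len(gold - pred))
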
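"""Seeded generator of patient-provided-information style family-history notes.

Emulates the structure of family-history questionnaire narratives: sentences
mentioning one of the 15 canonical relatives, disease observations, living
status phrases, optional ``maternal/paternal family history:`` section
headers, and within-sentence gold relations. Generation is template-based
(slot filling) so gold spans, attributes and relations are exact by
construction, and fully deterministic given the seed.

Distractor sentences contain relative-of-relative constructions (``her
grandmother's sisters ...``) whose observations deliberately carry no
patient-level relation — the main error class of joint extractors on real
notes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .corpus import (
    Document,
    EntityMention,
    RelationInstance,
    make_document,
    read_standoff,
    write_standoff,
)

# ---------------------------------------------------------------------------
# Vocabularies

#: role -> surface form used in generated text
ROLE_SURFACES = {
    "Father": "father", "Mother": "mother", "Sister": "sister",
    "Parent": "parent", "Brother": "brother", "Grandmother": "grandmother",
    "Grandfather": "grandfather", "Grandparent": "grandparent",
    "Daughter": "daughter", "Son": "son", "Child": "child",
    "Cousin": "cousin", "Sibling": "sibling", "Aunt": "aunt", "Uncle": "uncle",
}

FIRST_DEGREE_ROLES = (
    "Father", "Mother", "Parent", "Brother", "Sister", "Sibling",
    "Son", "Daughter", "Child",
)
SIDED_ROLES = ("Grandmother", "Grandfather", "Grandparent", "Cousin",
               "Aunt", "Uncle")

DEFAULT_OBSERVATIONS = (
    "diabetes", "hypertension", "asthma", "breast cancer", "colon cancer",
    "lung cancer", "kidney cancer", "prostate cancer", "ovarian cancer",
    "skin cancer", "stomach cancer", "pancreatic cancer", "thyroid cancer",
    "heart disease", "coronary artery disease", "congestive heart failure",
    "high blood pressure", "high cholesterol", "atrial fibrillation",
    "stroke", "seizures", "epilepsy", "migraines", "depression", "anxiety",
    "bipolar disorder", "schizophrenia", "dementia", "memory loss",
    "arthritis", "rheumatoid arthritis", "osteoporosis", "gout", "obesity",
    "celiac disease", "crohn disease", "ulcerative colitis", "liver disease",
    "cirrhosis", "hepatitis", "kidney disease", "kidney stones", "anemia",
    "sickle cell anemia", "hemophilia", "leukemia",
    "chronic lymphocytic leukemia", "lymphoma", "melanoma", "glaucoma",
    "cataracts", "hearing loss", "thyroid problems", "emphysema",
    "chronic bronchitis", "tuberculosis", "polio", "cystic fibrosis",
    "muscular dystrophy", "multiple sclerosis",
)

#: living-status phrase bank partitioned by (alive, healthy) ground truth
DEFAULT_LS_PHRASES = {
    ("Yes", "Yes"): ("alive and healthy", "alive and well",
                     "living and well", "healthy and living"),
    ("Yes", "NA"): ("alive", "still alive", "still living", "currently alive"),
    ("No", "NA"): ("deceased", "dead", "passed away", "expired"),
}

#: LS phrases used as verbs ("her aunt passed away"), not predicates
_VERB_LS = frozenset({"passed away", "expired", "died"})

_FILLERS = (
    "She denies any other significant family history .",
    "No additional family history was reported .",
    "The patient completed the questionnaire today .",
    "Family history was reviewed in detail .",
)

_DISTRACTOR_HEADS = ("grandmother's", "grandfather's", "aunt's", "uncle's",
                     "cousin's")
_DISTRACTOR_PLURALS = ("sisters", "brothers", "cousins", "children")


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic note generator.

    Probabilities are per document (sections) or per sentence (everything
    else); the ratios are exposed because the real corpus' class balance is
    not published.
    """

    n_documents: int = 200
    min_sentences: int = 3
    max_sentences: int = 8
    observations: tuple = DEFAULT_OBSERVATIONS
    ls_phrases: dict = field(default_factory=lambda: dict(DEFAULT_LS_PHRASES))
    p_section: float = 0.3       # document contains section headers
    p_distractor: float = 0.1    # sentence is a relative-of-relative distractor
    p_two_fm: float = 0.3        # sentence mentions two relatives
    p_filler: float = 0.1        # sentence has no entities at all
    p_sided: float = 0.5         # non-first-degree relative gets an explicit side
    seed: int = 13

    def validate(self) -> None:
        if self.n_documents < 0:
            raise ValueError("n_documents must be nonnegative")
        if not (0 < self.min_sentences <= self.max_sentences):
            raise ValueError("sentence range must satisfy 0 < min <= max")
        if not self.observations:
            raise ValueError("observation vocabulary must be non-empty")
        if not self.ls_phrases or not all(self.ls_phrases.values()):
            raise ValueError("living-status phrase bank must be non-empty")
        for name in ("p_section", "p_distractor", "p_two_fm", "p_filler",
                     "p_sided"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["observations"] = list(self.observations)
        data["ls_phrases"] = {f"{a}|{h}": list(v)
                              for (a, h), v in self.ls_phrases.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if "observations" in data:
            data["observations"] = tuple(data["observations"])
        if "ls_phrases" in data:
            data["ls_phrases"] = {tuple(k.split("|")): tuple(v)
                                  for k, v in data["ls_phrases"].items()}
        return cls(**data)


@dataclass
class AnnotatedDocument:
    document: Document
    entities: list[EntityMention]
    relations: list[RelationInstance]

    @property
    def doc_id(self) -> str:
        return self.document.doc_id


Corpus = list[AnnotatedDocument]


# ---------------------------------------------------------------------------
# Sentence builders. Each returns (word list, entity specs, relation pairs)
# where an entity spec is (token_start, token_end, etype, attrs) and a
# relation pair indexes into the entity-spec list.


def _pick_side(rng: random.Random, role: str, section_side: str,
               p_sided: float) -> tuple[str, str | None]:
    """Ground-truth side and the indicator word to insert (or None)."""
    if role in FIRST_DEGREE_ROLES:
        return "NA", None
    if section_side in ("maternal", "paternal"):
        return section_side.capitalize(), None
    if rng.random() < p_sided:
        side = rng.choice(("Maternal", "Paternal"))
        return side, side.lower()
    return "NA", None


def _fm_words(rng: random.Random, role: str, indicator: str | None
              ) -> tuple[list[str], int, int]:
    """Words introducing a relative; returns (words, fm_start, fm_end)."""
    poss = rng.choice(("His", "Her", "her", "his"))
    words = [poss]
    if indicator:
        words.append(indicator)
    start = len(words)
    words.append(ROLE_SURFACES[role])
    return words, start, start + 1


def _obs_sentence(rng, cfg, section_side):
    role = rng.choice(tuple(ROLE_SURFACES))
    side, indicator = _pick_side(rng, role, section_side, cfg.p_sided)
    words, fs, fe = _fm_words(rng, role, indicator)
    verb = rng.choice((["has"], ["had"], ["was", "diagnosed", "with"],
                       ["suffers", "from"]))
    words += verb
    os_ = len(words)
    obs = rng.choice(cfg.observations).split()
    words += obs
    if rng.random() < 0.3:
        words += ["at", "age", str(rng.randrange(35, 90))]
    words.append(".")
    ents = [(fs, fe, "FamilyMember", {"role": role, "side": side}),
            (os_, os_ + len(obs), "Observation", {})]
    return words, ents, [(0, 1)]


def _ls_sentence(rng, cfg, section_side, with_obs: bool):
    role = rng.choice(tuple(ROLE_SURFACES))
    side, indicator = _pick_side(rng, role, section_side, cfg.p_sided)
    words, fs, fe = _fm_words(rng, role, indicator)
    keys = sorted(cfg.ls_phrases)
    alive, healthy = rng.choice(keys)
    phrase = rng.choice(cfg.ls_phrases[(alive, healthy)])
    if phrase in _VERB_LS and not with_obs:
        ls_start = len(words)
    else:
        words.append("is")
        ls_start = len(words)
        if phrase in _VERB_LS:  # verb phrases need the predicate form
            phrase = "deceased"
            alive, healthy = "No", "NA"
    ls_words = phrase.split()
    words += ls_words
    from .postprocess import ls_score

    ents = [(fs, fe, "FamilyMember", {"role": role, "side": side}),
            (ls_start, ls_start + len(ls_words), "LivingStatus",
             {"alive": alive, "healthy": healthy,
              "score": ls_score(alive, healthy)})]
    rels = [(0, 1)]
    if with_obs:
        words += ["and", "has"]
        os_ = len(words)
        obs = rng.choice(cfg.observations).split()
        words += obs
        ents.append((os_, os_ + len(obs), "Observation", {}))
        rels.append((0, 2))
    words.append(".")
    return words, ents, rels


def _two_fm_sentence(rng, cfg, section_side):
    words: list[str] = []
    ents = []
    rels = []
    for k in range(2):
        role = rng.choice(tuple(ROLE_SURFACES))
        side, indicator = _pick_side(rng, role, section_side, cfg.p_sided)
        part, fs, fe = _fm_words(rng, role, indicator)
        if k == 1:
            part[0] = part[0].lower()
            words.append("and")
        off = len(words)
        words += part
        words.append(rng.choice(("has", "had")))
        os_ = len(words)
        obs = rng.choice(cfg.observations).split()
        words += obs
        ents.append((off + fs, off + fe, "FamilyMember",
                     {"role": role, "side": side}))
        ents.append((os_, os_ + len(obs), "Observation", {}))
        rels.append((2 * k, 2 * k + 1))
    words.append(".")
    return words, ents, rels


def _distractor_sentence(rng, cfg):
    """Relative-of-relative: the observation has no patient-level relation."""
    words = [rng.choice(("Her", "His")), rng.choice(_DISTRACTOR_HEADS),
             rng.choice(_DISTRACTOR_PLURALS), "also",
             rng.choice(("had", "have"))]
    os_ = len(words)
    obs = rng.choice(cfg.observations).split()
    words += obs + ["."]
    return words, [(os_, os_ + len(obs), "Observation", {})], []


# ---------------------------------------------------------------------------
# Document assembly


def _content_sentence(rng, cfg, section_side):
    if rng.random() < cfg.p_distractor:
        return _distractor_sentence(rng, cfg)
    if rng.random() < cfg.p_filler:
        return rng.choice(_FILLERS).split(), [], []
    if rng.random() < cfg.p_two_fm:
        return _two_fm_sentence(rng, cfg, section_side)
    kind = rng.random()
    if kind < 0.45:
        return _obs_sentence(rng, cfg, section_side)
    if kind < 0.75:
        return _ls_sentence(rng, cfg, section_side, with_obs=False)
    return _ls_sentence(rng, cfg, section_side, with_obs=True)


def _generate_document(rng: random.Random, cfg: GeneratorConfig,
                       doc_id: str) -> AnnotatedDocument:
    n_sentences = rng.randint(cfg.min_sentences, cfg.max_sentences)
    plan: list[tuple[str, str]] = []  # (section side, kind)
    if rng.random() < cfg.p_section and n_sentences >= 3:
        n_intro = rng.randint(0, 1)
        sides = ["maternal", "paternal"]
        rng.shuffle(sides)
        n_first = max(1, (n_sentences - n_intro) // 2)
        plan += [("none", "content")] * n_intro
        plan.append((sides[0], "header"))
        plan += [(sides[0], "content")] * n_first
        plan.append((sides[1], "header"))
        plan += [(sides[1], "content")] * max(1, n_sentences - n_intro - n_first)
    else:
        plan = [("none", "content")] * n_sentences

    lines: list[str] = []
    sent_specs: list[tuple[list, list]] = []  # (entity specs, relation pairs)
    for section_side, kind in plan:
        if kind == "header":
            lines.append(f"{section_side.capitalize()} family history :")
            sent_specs.append(([], []))
        else:
            words, ents, rels = _content_sentence(rng, cfg, section_side)
            lines.append(" ".join(words))
            sent_specs.append((ents, rels))

    doc = make_document(doc_id, "\n".join(lines) + "\n")
    assert len(doc.sentences) == len(sent_specs), "template/tokenizer mismatch"

    entities: list[EntityMention] = []
    relations: list[RelationInstance] = []
    for sent, (ents, rels) in zip(doc.sentences, sent_specs):
        mentions = []
        for ts, te, etype, attrs in ents:
            surface = " ".join(t.text for t in sent.tokens[ts:te])
            mentions.append(EntityMention(doc_id, sent.index, ts, te, etype,
                                          surface, dict(attrs)))
        entities += mentions
        for fm_i, tg_i in rels:
            relations.append(RelationInstance(mentions[fm_i], mentions[tg_i],
                                              True))
    return AnnotatedDocument(doc, entities, relations)


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Generate a gold-annotated corpus; byte-identical for equal configs."""
    config.validate()
    rng = random.Random(config.seed)
    return [_generate_document(rng, config, f"doc_{i:04d}")
            for i in range(config.n_documents)]


def split_corpus(corpus: Corpus, train_fraction: float, seed: int
                 ) -> tuple[Corpus, Corpus]:
    """Deterministic document-level split into (train, heldout)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    order = list(range(len(corpus)))
    random.Random(seed).shuffle(order)
    k = int(round(len(corpus) * train_fraction))
    train_idx = sorted(order[:k])
    held_idx = sorted(order[k:])
    return [corpus[i] for i in train_idx], [corpus[i] for i in held_idx]


def gold_challenge_records(ad: AnnotatedDocument
                           ) -> tuple[set[tuple], set[tuple]]:
    """Ground-truth subtask-1 and subtask-2 record tuples of one document,
    read directly off the generator's gold attributes."""
    from .corpus import normalize_observation_text

    doc_id = ad.doc_id
    subtask1: set[tuple] = set()
    subtask2: set[tuple] = set()
    for ent in ad.entities:
        if ent.etype == "FamilyMember":
            subtask1.add((doc_id, "FamilyMember", ent.attrs["role"],
                          ent.attrs["side"]))
        elif ent.etype == "Observation":
            subtask1.add((doc_id, "Observation",
                          normalize_observation_text(ent.surface)))
    for rel in ad.relations:
        if not rel.label:
            continue
        role = rel.fm.attrs["role"]
        side = rel.fm.attrs["side"]
        if rel.target.etype == "Observation":
            subtask2.add((doc_id, role, side, "Observation",
                          normalize_observation_text(rel.target.surface)))
        else:
            subtask2.add((doc_id, role, side, "LivingStatus",
                          rel.target.attrs["score"]))
    return subtask1, subtask2


# ---------------------------------------------------------------------------
# Disk round trip (document text + standoff annotations per document)


def write_corpus(corpus: Corpus, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ad in corpus:
        (out / f"{ad.doc_id}.txt").write_text(ad.document.text,
                                              encoding="utf-8")
        write_standoff(out / f"{ad.doc_id}.ann", ad.document, ad.entities,
                       ad.relations)


def read_corpus(in_dir: str | Path) -> Corpus:
    corpus: Corpus = []
    for txt in sorted(Path(in_dir).glob("*.txt")):
        doc = make_document(txt.stem, txt.read_text(encoding="utf-8"))
        ann = txt.with_suffix(".ann")
        if ann.exists():
            entities, relations = read_standoff(ann, doc)
        else:
            entities, relations = [], []
        corpus.append(AnnotatedDocument(doc, entities, relations))
    return corpus
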
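"""Joint and pipeline training of the entity tagger and relation classifier.

The joint regime minimizes the combined loss L = alpha * L_e + (1 - alpha) *
L_r end to end through the shared encoder; the pipeline baseline trains the
tagger on L_e alone, freezes it, and then trains the relation head on L_r
alone. Both losses are cross-entropies, averaged over tokens (L_e) and over
candidate pairs (L_r) within a step so the alpha weighting acts on
comparably scaled terms. Optimization is plain SGD, one sentence per step,
with global gradient-norm clipping; sentence order is reshuffled each epoch
under the run seed, and every source of randomness (initialization, dropout,
shuffling) derives from that one seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .corpus import Sentence, entities_for_scheme
from .evaluation import mention_prf, relation_prf
from .model import FHModel, ModelHyperparams, Vocab, build_vocabs, \
    generate_candidates
from .synthetic import AnnotatedDocument, Corpus

#: relation-head tensors — the only ones updated in pipeline phase 2
RELATION_PARAMS = frozenset(
    {"ctx_f_W", "ctx_f_b", "ctx_b_W", "ctx_b_b", "W_r", "b_r"})


@dataclass
class TrainConfig:
    """Hyperparameters; defaults follow the published configuration
    (50/20/10-d word/POS/label embeddings, 100 hidden units, SGD at 0.005,
    dropout 0.5 on the tagger and 0.3 on the relation head, 20 epochs with a
    5-epoch continuation, alpha in {0.4, 0.5, 0.6})."""

    d_w: int = 50
    d_p: int = 20
    d_l: int = 10
    hidden: int = 100
    learning_rate: float = 0.005
    dropout_ner: float = 0.5
    dropout_rel: float = 0.3
    epochs: int = 20
    continue_epochs: int = 5
    alpha: float = 0.5
    scheme: str = "three"
    regime: str = "joint"
    clip_norm: float = 5.0
    seed: int = 13
    as_printed_sigma_candidate: bool = False

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if min(self.d_w, self.d_p, self.d_l, self.hidden) <= 0:
            raise ValueError("all dimensions must be positive")
        if self.epochs < 0 or self.continue_epochs < 0:
            raise ValueError("epoch counts must be nonnegative")
        if self.regime not in ("joint", "pipeline"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.scheme not in ("three", "five"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def hyperparams(self) -> ModelHyperparams:
        return ModelHyperparams(self.d_w, self.d_p, self.d_l, self.hidden,
                                self.scheme, self.as_printed_sigma_candidate)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        cfg = cls(**yaml.safe_load(Path(path).read_text(encoding="utf-8")))
        cfg.validate()
        return cfg


def joint_loss(L_e: float, L_r: float, alpha: float) -> float:
    """Combined loss alpha * L_e + (1 - alpha) * L_r, with alpha in (0, 1)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if L_e < 0.0 or L_r < 0.0:
        raise ValueError("cross-entropy losses are nonnegative")
    return alpha * L_e + (1.0 - alpha) * L_r


# ---------------------------------------------------------------------------
# Training items


@dataclass
class SentenceItem:
    sentence: Sentence
    gold_label_ids: list[int]
    candidates: list  # RelationInstance list with gold labels


def prepare_items(corpus: Corpus, model: FHModel) -> list[SentenceItem]:
    """Per-sentence gold label sequences and labelled candidate pairs."""
    scheme = model.hp.scheme
    items: list[SentenceItem] = []
    for ad in corpus:
        entities = entities_for_scheme(ad.entities, scheme)
        by_sent: dict[int, list] = {}
        for ent in entities:
            by_sent.setdefault(ent.sentence_index, []).append(ent)
        rel_by_sent: dict[int, list] = {}
        for rel in ad.relations:
            rel_by_sent.setdefault(rel.fm.sentence_index, []).append(rel)
        for sent in ad.document.sentences:
            ents = by_sent.get(sent.index, [])
            gold_ids = model.gold_label_ids(sent, ents)
            cands = generate_candidates(ents, scheme,
                                        rel_by_sent.get(sent.index, []))
            items.append(SentenceItem(sent, gold_ids, cands))
    return items


# ---------------------------------------------------------------------------
# Evaluation helpers


def predict_corpus(model: FHModel, corpus: Corpus) -> tuple[list, list]:
    """Predicted entities and positive relations over all documents."""
    entities, relations = [], []
    for ad in corpus:
        for sent in ad.document.sentences:
            ents, rels = model.predict_sentence(sent)
            entities += ents
            relations += rels
    return entities, relations


def evaluate_model(model: FHModel, corpus: Corpus) -> dict:
    """Mention-level entity P/R/F1 and pair-level relation P/R/F1."""
    gold_entities, gold_relations = [], []
    for ad in corpus:
        gold_entities += entities_for_scheme(ad.entities, model.hp.scheme)
        gold_relations += ad.relations
    pred_entities, pred_relations = predict_corpus(model, corpus)
    ep, er, ef = mention_prf(gold_entities, pred_entities)
    rp, rr, rf = relation_prf(gold_relations, pred_relations)
    return {"entity_p": ep, "entity_r": er, "entity_f1": ef,
            "relation_p": rp, "relation_r": rr, "relation_f1": rf}


# ---------------------------------------------------------------------------
# Training loops


def _run_epochs(model: FHModel, items: list[SentenceItem], config: TrainConfig,
                rng: np.random.Generator, n_epochs: int, phase: str,
                entity_weight: float | None, relation_weight: float | None,
                trainable: set[str] | None, heldout: Corpus | None,
                log: list[dict], early_stop: tuple[float, float] | None
                ) -> None:
    order = np.arange(len(items))
    for epoch in range(n_epochs):
        rng.shuffle(order)
        sum_e = sum_r = 0.0
        for idx in order:
            item = items[idx]
            L_e, L_r, grads = model.loss_and_grads(
                item.sentence, item.gold_label_ids, item.candidates,
                config.alpha, rng, config.dropout_ner, config.dropout_rel,
                entity_weight=entity_weight, relation_weight=relation_weight)
            model.sgd_update(grads, config.learning_rate, config.clip_norm,
                             trainable)
            sum_e += L_e
            sum_r += L_r
        entry = {"phase": phase, "epoch": len(log) + 1,
                 "L_e": sum_e / max(len(items), 1),
                 "L_r": sum_r / max(len(items), 1)}
        entry["L"] = joint_loss(entry["L_e"], entry["L_r"], config.alpha)
        if heldout is not None:
            entry.update(evaluate_model(model, heldout))
        log.append(entry)
        if early_stop is not None and heldout is not None:
            if entry["entity_f1"] >= early_stop[0] \
                    and entry["relation_f1"] >= early_stop[1]:
                break


def train(corpus: Corpus, config: TrainConfig, heldout: Corpus | None = None,
          early_stop: tuple[float, float] | None = None
          ) -> tuple[FHModel, list[dict]]:
    """Train a model from scratch; returns (model, per-epoch metrics log).

    ``early_stop`` optionally halts the (joint or tagger) loop once held-out
    entity and relation F1 both reach the given thresholds. Deterministic
    given the config seed.
    """
    config.validate()
    if not corpus:
        raise ValueError("training corpus is empty")
    words, pos = build_vocabs([s for ad in corpus
                               for s in ad.document.sentences])
    init_rng = np.random.default_rng(config.seed)
    model = FHModel(config.hyperparams(), words, pos, init_rng)
    items = prepare_items(corpus, model)
    rng = np.random.default_rng(config.seed + 1)
    log: list[dict] = []
    if config.regime == "joint":
        _run_epochs(model, items, config, rng, config.epochs, "joint",
                    None, None, None, heldout, log, early_stop)
    else:
        _run_epochs(model, items, config, rng, config.epochs, "tagger",
                    1.0, 0.0, None, heldout, log, None)
        _run_epochs(model, items, config, rng, config.epochs, "relation",
                    0.0, 1.0, set(RELATION_PARAMS), heldout, log, early_stop)
    return model, log


def continue_training(model: FHModel, corpus: Corpus, extra_epochs: int,
                      config: TrainConfig, heldout: Corpus | None = None
                      ) -> list[dict]:
    """Further SGD epochs on a loaded model (optimizer state is stateless
    SGD, so it is simply re-created). The vocabulary is left untouched;
    unseen words map to the unknown embedding."""
    config.validate()
    if extra_epochs < 0:
        raise ValueError("extra_epochs must be nonnegative")
    if model.hp != config.hyperparams():
        raise ValueError("checkpoint hyperparameters do not match the config")
    items = prepare_items(corpus, model)
    rng = np.random.default_rng(config.seed + 2)
    log: list[dict] = []
    if extra_epochs:
        _run_epochs(model, items, config, rng, extra_epochs, "continue",
                    None, None,
                    None if config.regime == "joint" else set(RELATION_PARAMS),
                    heldout, log, None)
    return log


# ---------------------------------------------------------------------------
# Comparison harnesses


def compare_regimes(corpus: Corpus, config: TrainConfig,
                    heldout: Corpus) -> dict[str, dict]:
    """Train joint and pipeline regimes from identical initialization (same
    seed, same init stream) and report final held-out metrics per regime."""
    results = {}
    for regime in ("joint", "pipeline"):
        cfg = dataclasses.replace(config, regime=regime)
        model, log = train(corpus, cfg, heldout)
        results[regime] = {"metrics": evaluate_model(model, heldout),
                           "log": log}
    return results


def alpha_grid(corpus: Corpus, config: TrainConfig, heldout: Corpus,
               alphas: tuple[float, ...] = (0.4, 0.5, 0.6)) -> list[dict]:
    """Held-out metrics for each combination coefficient in the grid."""
    rows = []
    for alpha in alphas:
        cfg = dataclasses.replace(config, alpha=alpha)
        model, _ = train(corpus, cfg, heldout=None)
        row = {"alpha": alpha}
        row.update(evaluate_model(model, heldout))
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# Metrics log serialization


_LOG_COLUMNS = ("phase", "epoch", "L_e", "L_r", "L", "entity_p", "entity_r",
                "entity_f1", "relation_p", "relation_r", "relation_f1")


def write_metrics_log(log: list[dict], path: str | Path) -> None:
    lines = ["\t".join(_LOG_COLUMNS)]
    for entry in log:
        cells = []
        for col in _LOG_COLUMNS:
            value = entry.get(col, "")
            cells.append(f"{value:.6f}" if isinstance(value, float) else
                         str(value))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
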
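"""Joint entity/relation neural architecture, implemented in NumPy.

The network has a shared input layer (word + POS embeddings) and a shared
sentence Bi-LSTM. On top of it sit two heads:

* a sequence tagger that predicts one BIO label per token through a softmax
  whose hidden layer consumes the Bi-LSTM state at time t together with the
  embedding of the *previous* label (label-embedding feedback, greedy
  left-to-right at inference, teacher-forced during training), and
* a relation classifier that represents an entity as the elementwise sum of
  its tokens' [h_t; l_t] vectors, encodes the tokens strictly between the two
  entities with a second Bi-LSTM (last forward and last backward states
  concatenated), and feeds [h_e1; h_context; h_e2] into a binary softmax.

Everything — forward passes, backpropagation, SGD — is self-contained here;
gradients are hand-derived and verified in the test suite against independent
plain-loop oracles and finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import (
    BioLabel,
    EntityMention,
    RelationInstance,
    Sentence,
    bio_decode,
    is_family_member_type,
    scheme_labels,
    spans_to_mentions,
)

UNK = "<unk>"


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - np.max(x))
    return e / e.sum()


# ---------------------------------------------------------------------------
# Vocabulary


class Vocab:
    """Item <-> index mapping with a reserved unknown symbol at index 0."""

    def __init__(self, items: Sequence[str], unk: str | None = UNK):
        self.unk = unk
        uniq = []
        seen = set()
        if unk is not None:
            uniq.append(unk)
            seen.add(unk)
        for it in items:
            if it not in seen:
                uniq.append(it)
                seen.add(it)
        self.items = uniq
        self.index = {it: i for i, it in enumerate(uniq)}

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item: str) -> int:
        if item in self.index:
            return self.index[item]
        if self.unk is None:
            raise KeyError(item)
        return self.index[self.unk]


# ---------------------------------------------------------------------------
# LSTM cell


class LstmParams:
    """Gate parameters of one LSTM direction, stored fused.

    ``W`` stacks the input, forget, candidate and output gate matrices
    (4H x (H + D)); ``b`` stacks the biases. The per-gate views W_i/W_f/
    W_c/W_o and b_i/b_f/b_c/b_o address the same memory.
    """

    def __init__(self, W: np.ndarray, b: np.ndarray):
        if W.shape[0] % 4 != 0 or b.shape != (W.shape[0],):
            raise ValueError("fused LSTM parameters must have 4H rows")
        self.W = W
        self.b = b

    @classmethod
    def init(cls, input_dim: int, hidden: int, rng: np.random.Generator,
             scale: float = 0.1) -> "LstmParams":
        W = rng.uniform(-scale, scale, (4 * hidden, hidden + input_dim))
        return cls(W, np.zeros(4 * hidden))

    @property
    def hidden(self) -> int:
        return self.W.shape[0] // 4

    @property
    def input_dim(self) -> int:
        return self.W.shape[1] - self.hidden

    def _gate(self, k: int):
        H = self.hidden
        return self.W[k * H:(k + 1) * H], self.b[k * H:(k + 1) * H]

    W_i = property(lambda self: self._gate(0)[0])
    b_i = property(lambda self: self._gate(0)[1])
    W_f = property(lambda self: self._gate(1)[0])
    b_f = property(lambda self: self._gate(1)[1])
    W_c = property(lambda self: self._gate(2)[0])
    b_c = property(lambda self: self._gate(2)[1])
    W_o = property(lambda self: self._gate(3)[0])
    b_o = property(lambda self: self._gate(3)[1])


def lstm_step(x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
              params: LstmParams, sigma_candidate: bool = False
              ) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM recurrence step -> (h_t, c_t).

    Gates are sigmoid; the candidate cell uses tanh by default, or sigmoid
    when ``sigma_candidate`` is set (bit-faithful to the printed recurrence,
    at the cost of the zero-parameters -> zero-state identity).
    """
    H = params.hidden
    if x_t.shape != (params.input_dim,) or h_prev.shape != (H,) \
            or c_prev.shape != (H,):
        raise ValueError(
            f"shape mismatch: x {x_t.shape}, h {h_prev.shape}, c {c_prev.shape} "
            f"for cell with input {params.input_dim}, hidden {H}")
    h_t, c_t, _ = _lstm_step_cached(x_t, h_prev, c_prev, params,
                                    sigma_candidate)
    return h_t, c_t


def _lstm_step_cached(x, h_prev, c_prev, p: LstmParams, sigma_candidate):
    H = p.hidden
    hx = np.concatenate([h_prev, x])
    z = p.W @ hx + p.b
    i = sigmoid(z[:H])
    f = sigmoid(z[H:2 * H])
    g = sigmoid(z[2 * H:3 * H]) if sigma_candidate else np.tanh(z[2 * H:3 * H])
    o = sigmoid(z[3 * H:])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c, (hx, c_prev, i, f, g, o, c)


def run_lstm(xs: np.ndarray, params: LstmParams, sigma_candidate: bool = False
             ) -> tuple[np.ndarray, list]:
    """Run an LSTM over a (n, D) input sequence -> ((n, H) states, cache)."""
    H = params.hidden
    h = np.zeros(H)
    c = np.zeros(H)
    hs = np.empty((len(xs), H))
    caches = []
    for t, x in enumerate(xs):
        h, c, cache = _lstm_step_cached(x, h, c, params, sigma_candidate)
        hs[t] = h
        caches.append(cache)
    return hs, caches


def lstm_backward(dhs: np.ndarray, caches: list, params: LstmParams,
                  sigma_candidate: bool = False
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backprop through time. ``dhs`` holds dLoss/dh_t contributions from
    outside the recurrence; returns (dxs, dW, db)."""
    H = params.hidden
    D = params.input_dim
    dW = np.zeros_like(params.W)
    db = np.zeros_like(params.b)
    dxs = np.empty((len(caches), D))
    dh_next = np.zeros(H)
    dc_next = np.zeros(H)
    for t in range(len(caches) - 1, -1, -1):
        hx, c_prev, i, f, g, o, c = caches[t]
        dh = dhs[t] + dh_next
        tc = np.tanh(c)
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dc_next = dc * f
        dz = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            dg * g * (1.0 - g) if sigma_candidate else dg * (1.0 - g * g),
            do * o * (1.0 - o),
        ])
        dW += np.outer(dz, hx)
        db += dz
        dhx = params.W.T @ dz
        dh_next = dhx[:H]
        dxs[t] = dhx[H:]
    return dxs, dW, db


# ---------------------------------------------------------------------------
# Sentence encoder (shared Bi-LSTM)


def encode_sentence(xs: np.ndarray, fwd: LstmParams, bwd: LstmParams,
                    sigma_candidate: bool = False
                    ) -> tuple[np.ndarray, tuple]:
    """Bi-LSTM over input representations (n, D) -> ((n, 2H) states, cache).

    Row t is [h_ft, h_bt]: the forward state at t concatenated with the
    backward state at t (the backward LSTM reads the sentence reversed).
    """
    if len(xs) == 0:
        raise ValueError("cannot encode an empty sentence")
    hf, cache_f = run_lstm(xs, fwd, sigma_candidate)
    hb_rev, cache_b = run_lstm(xs[::-1], bwd, sigma_candidate)
    hs = np.concatenate([hf, hb_rev[::-1]], axis=1)
    return hs, (cache_f, cache_b)


def encoder_backward(dhs: np.ndarray, cache: tuple, fwd: LstmParams,
                     bwd: LstmParams, sigma_candidate: bool = False):
    """Backward of :func:`encode_sentence`; returns (dxs, dWf, dbf, dWb, dbb)."""
    H = fwd.hidden
    cache_f, cache_b = cache
    dxs_f, dWf, dbf = lstm_backward(dhs[:, :H], cache_f, fwd, sigma_candidate)
    dxs_b, dWb, dbb = lstm_backward(dhs[::-1, H:], cache_b, bwd,
                                    sigma_candidate)
    return dxs_f + dxs_b[::-1], dWf, dbf, dWb, dbb


# ---------------------------------------------------------------------------
# Label decoder (softmax layer with label-embedding feedback)


class DecoderParams:
    """Label-embedding table (one row per BIO label plus START, the initial
    feedback symbol) and the two affine maps of the tagging head."""

    def __init__(self, label_table: np.ndarray, W_eh: np.ndarray,
                 b_eh: np.ndarray, W_ey: np.ndarray, b_ey: np.ndarray):
        self.label_table = label_table  # (n_labels + 1, d_l); last row START
        self.W_eh = W_eh
        self.b_eh = b_eh
        self.W_ey = W_ey
        self.b_ey = b_ey

    @property
    def n_labels(self) -> int:
        return self.label_table.shape[0] - 1

    @property
    def start_index(self) -> int:
        return self.label_table.shape[0] - 1


def decode_labels(hs: np.ndarray, params: DecoderParams,
                  gold_labels: Sequence[int] | None = None
                  ) -> tuple[list[int], np.ndarray, list]:
    """Predict one label per encoded token.

    At each position the hidden layer sees [h_t; l_{t-1}] where l_{t-1} is
    the embedding of the previous gold label when ``gold_labels`` is given
    (teacher forcing) or of the previous greedy prediction otherwise; l_0 is
    the START embedding. Returns (predicted ids, (n, n_labels) distributions,
    cache for backprop).
    """
    if len(hs) == 0:
        raise ValueError("cannot decode an empty encoding")
    preds: list[int] = []
    probs = np.empty((len(hs), params.n_labels))
    cache = []
    prev = params.start_index
    for t in range(len(hs)):
        u = np.concatenate([hs[t], params.label_table[prev]])
        e = np.tanh(params.W_eh @ u + params.b_eh)
        p = softmax(params.W_ey @ e + params.b_ey)
        pred = int(np.argmax(p))
        preds.append(pred)
        probs[t] = p
        cache.append((u, e, prev))
        prev = gold_labels[t] if gold_labels is not None else pred
    return preds, probs, cache


def decoder_backward(probs: np.ndarray, gold: Sequence[int], cache: list,
                     params: DecoderParams, scale: float):
    """Backward of the teacher-forced decoder under mean cross-entropy,
    pre-multiplied by ``scale``. Returns (dhs, grads dict)."""
    n_h = cache[0][0].shape[0] - params.label_table.shape[1]
    dhs = np.zeros((len(cache), n_h))
    g = {"label_table": np.zeros_like(params.label_table),
         "W_eh": np.zeros_like(params.W_eh),
         "b_eh": np.zeros_like(params.b_eh),
         "W_ey": np.zeros_like(params.W_ey),
         "b_ey": np.zeros_like(params.b_ey)}
    for t in range(len(cache)):
        u, e, prev = cache[t]
        ds = probs[t].copy()
        ds[gold[t]] -= 1.0
        ds *= scale
        g["W_ey"] += np.outer(ds, e)
        g["b_ey"] += ds
        de = params.W_ey.T @ ds
        da = de * (1.0 - e * e)
        g["W_eh"] += np.outer(da, u)
        g["b_eh"] += da
        du = params.W_eh.T @ da
        dhs[t] = du[:n_h]
        g["label_table"][prev] += du[n_h:]
    return dhs, g


def cross_entropy(probs: np.ndarray, gold: Sequence[int]) -> float:
    """Mean negative log-likelihood of the gold ids under (n, K) rows."""
    rows = probs[np.arange(len(gold)), list(gold)]
    return float(-np.log(np.clip(rows, 1e-12, None)).mean())


# ---------------------------------------------------------------------------
# Relation head


def entity_representation(span: tuple[int, int], hs: np.ndarray,
                          label_embs: np.ndarray) -> np.ndarray:
    """Elementwise sum of [h_t; l_t] over the entity's tokens."""
    start, end = span
    if not (0 <= start < end <= len(hs)):
        raise ValueError(f"entity span {span} out of range for {len(hs)} tokens")
    return np.concatenate([hs[start:end], label_embs[start:end]],
                          axis=1).sum(axis=0)


def context_representation(between: np.ndarray, ctx_f: LstmParams,
                           ctx_b: LstmParams, sigma_candidate: bool = False
                           ) -> tuple[np.ndarray, tuple | None]:
    """Encode the tokens strictly between two entities.

    A dedicated Bi-LSTM reads the between-token encoder states; the output is
    the last forward state concatenated with the last backward state. An
    empty context yields a zero vector of the same dimension.
    """
    H = ctx_f.hidden
    if len(between) == 0:
        return np.zeros(2 * H), None
    hf, cache_f = run_lstm(between, ctx_f, sigma_candidate)
    hb, cache_b = run_lstm(between[::-1], ctx_b, sigma_candidate)
    return np.concatenate([hf[-1], hb[-1]]), (cache_f, cache_b)


def classify_pair(h_r: np.ndarray, W_r: np.ndarray, b_r: np.ndarray
                  ) -> np.ndarray:
    """Binary softmax over {not-related, related} -> probability pair."""
    return softmax(W_r @ h_r + b_r)


def generate_candidates(entities: Sequence[EntityMention],
                        scheme: str = "three",
                        gold_relations: Sequence[RelationInstance] = ()
                        ) -> list[RelationInstance]:
    """All within-sentence (family member, observation-or-living-status)
    pairs, labelled true when present in ``gold_relations``."""
    gold = {(r.fm.sentence_index, r.fm.span, r.target.span)
            for r in gold_relations if r.label}
    out = []
    for fm in entities:
        if not is_family_member_type(fm.etype, scheme):
            continue
        for tg in entities:
            if tg.etype not in ("Observation", "LivingStatus"):
                continue
            if tg.sentence_index != fm.sentence_index:
                continue
            label = (fm.sentence_index, fm.span, tg.span) in gold
            out.append(RelationInstance(fm, tg, label))
    return out


# ---------------------------------------------------------------------------
# Full model


@dataclass(frozen=True)
class ModelHyperparams:
    """Architecture sizes. Defaults: 50-d word, 20-d POS and 10-d label
    embeddings over 100 LSTM hidden units per direction."""

    d_w: int = 50
    d_p: int = 20
    d_l: int = 10
    hidden: int = 100
    scheme: str = "three"
    as_printed_sigma_candidate: bool = False

    def validate(self) -> None:
        if min(self.d_w, self.d_p, self.d_l, self.hidden) <= 0:
            raise ValueError("all dimensions must be positive")
        if self.scheme not in ("three", "five"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


class FHModel:
    """Shared encoder + tagger + relation classifier with hand-rolled SGD."""

    def __init__(self, hp: ModelHyperparams, word_vocab: Vocab,
                 pos_vocab: Vocab, rng: np.random.Generator):
        hp.validate()
        self.hp = hp
        self.words = word_vocab
        self.pos = pos_vocab
        self.labels = [str(lab) for lab in scheme_labels(hp.scheme)]
        self.label_index = {lab: i for i, lab in enumerate(self.labels)}
        nl = len(self.labels)
        H, d_w, d_p, d_l = hp.hidden, hp.d_w, hp.d_p, hp.d_l
        d_in = d_w + d_p
        ent_dim = 2 * H + d_l
        u = lambda *shape: rng.uniform(-0.1, 0.1, shape)
        self.params: dict[str, np.ndarray] = {
            "E_word": u(len(word_vocab), d_w),
            "E_pos": u(len(pos_vocab), d_p),
            "label_table": u(nl + 1, d_l),
            "enc_f_W": u(4 * H, H + d_in), "enc_f_b": np.zeros(4 * H),
            "enc_b_W": u(4 * H, H + d_in), "enc_b_b": np.zeros(4 * H),
            "W_eh": u(H, 2 * H + d_l), "b_eh": np.zeros(H),
            "W_ey": u(nl, H), "b_ey": np.zeros(nl),
            "ctx_f_W": u(4 * H, H + 2 * H), "ctx_f_b": np.zeros(4 * H),
            "ctx_b_W": u(4 * H, H + 2 * H), "ctx_b_b": np.zeros(4 * H),
            "W_r": u(2, 2 * ent_dim + 2 * H), "b_r": np.zeros(2),
        }

    # -- parameter views ----------------------------------------------------

    def _lstm(self, name: str) -> LstmParams:
        return LstmParams(self.params[f"{name}_W"], self.params[f"{name}_b"])

    def _decoder(self) -> DecoderParams:
        p = self.params
        return DecoderParams(p["label_table"], p["W_eh"], p["b_eh"],
                             p["W_ey"], p["b_ey"])

    # -- forward pieces ------------------------------------------------------

    def input_representation(self, sentence: Sentence) -> tuple[np.ndarray,
                                                                list, list]:
        """(n, d_w + d_p) matrix of concatenated word and POS embeddings."""
        wi = [self.words[t.text.lower()] for t in sentence.tokens]
        pi = [self.pos[t.pos] for t in sentence.tokens]
        xs = np.concatenate([self.params["E_word"][wi],
                             self.params["E_pos"][pi]], axis=1)
        return xs, wi, pi

    def encode(self, sentence: Sentence) -> tuple[np.ndarray, tuple, list, list]:
        xs, wi, pi = self.input_representation(sentence)
        hs, cache = encode_sentence(xs, self._lstm("enc_f"),
                                    self._lstm("enc_b"),
                                    self.hp.as_printed_sigma_candidate)
        return hs, cache, wi, pi

    def _pair_forward(self, cand: RelationInstance, hs: np.ndarray,
                      label_ids: Sequence[int],
                      dropout_mask: np.ndarray | None = None):
        """Forward the relation head for one candidate; returns
        (probability pair, cache)."""
        sig = self.hp.as_printed_sigma_candidate
        lab_embs = self.params["label_table"][list(label_ids)]
        e1 = entity_representation(cand.fm.span, hs, lab_embs)
        e2 = entity_representation(cand.target.span, hs, lab_embs)
        left, right = sorted([cand.fm.span, cand.target.span])
        lo, hi = left[1], max(left[1], right[0])
        between = hs[lo:hi]
        hc, ctx_cache = context_representation(between, self._lstm("ctx_f"),
                                               self._lstm("ctx_b"), sig)
        h_r = np.concatenate([e1, hc, e2])
        h_r_d = h_r if dropout_mask is None else h_r * dropout_mask
        p = classify_pair(h_r_d, self.params["W_r"], self.params["b_r"])
        return p, (h_r_d, dropout_mask, ctx_cache, (lo, hi))

    def _pair_backward(self, cand: RelationInstance, p: np.ndarray,
                       gold: int, cache, label_ids: Sequence[int],
                       scale: float, dhs: np.ndarray, grads: dict) -> None:
        """Accumulate relation-head gradients for one candidate into
        ``grads`` and the shared encoder-state gradient ``dhs``."""
        sig = self.hp.as_printed_sigma_candidate
        H, d_l = self.hp.hidden, self.hp.d_l
        ent_dim = 2 * H + d_l
        h_r_d, mask, ctx_cache, (lo, hi) = cache
        ds = p.copy()
        ds[gold] -= 1.0
        ds *= scale
        grads["W_r"] += np.outer(ds, h_r_d)
        grads["b_r"] += ds
        dh_r = self.params["W_r"].T @ ds
        if mask is not None:
            dh_r = dh_r * mask
        de1 = dh_r[:ent_dim]
        dhc = dh_r[ent_dim:ent_dim + 2 * H]
        de2 = dh_r[ent_dim + 2 * H:]
        for span, de in ((cand.fm.span, de1), (cand.target.span, de2)):
            for t in range(span[0], span[1]):
                dhs[t] += de[:2 * H]
                grads["label_table"][label_ids[t]] += de[2 * H:]
        if ctx_cache is not None:
            cache_f, cache_b = ctx_cache
            n_b = hi - lo
            dh_f = np.zeros((n_b, H))
            dh_f[-1] = dhc[:H]
            dh_b = np.zeros((n_b, H))
            dh_b[-1] = dhc[H:]
            dx_f, dWf, dbf = lstm_backward(dh_f, cache_f, self._lstm("ctx_f"),
                                           sig)
            dx_b, dWb, dbb = lstm_backward(dh_b, cache_b, self._lstm("ctx_b"),
                                           sig)
            grads["ctx_f_W"] += dWf
            grads["ctx_f_b"] += dbf
            grads["ctx_b_W"] += dWb
            grads["ctx_b_b"] += dbb
            dhs[lo:hi] += dx_f + dx_b[::-1]

    # -- training step -------------------------------------------------------

    def loss_and_grads(self, sentence: Sentence, gold_label_ids: list[int],
                       candidates: list[RelationInstance], alpha: float,
                       rng: np.random.Generator | None,
                       dropout_ner: float = 0.5, dropout_rel: float = 0.3,
                       entity_weight: float | None = None,
                       relation_weight: float | None = None
                       ) -> tuple[float, float, dict]:
        """Forward + backward for one sentence.

        Teacher forcing throughout: the tagger feeds gold previous labels and
        the relation head reads gold spans and gold label embeddings, so the
        two heads share only the encoder (and the label table). L_e is the
        cross-entropy summed over the sentence's tokens and L_r the
        cross-entropy summed over its candidate pairs (the conventional
        reduction for sequence models under plain SGD). The loss is
        ``entity_weight * L_e + relation_weight * L_r``; by default the
        weights are the joint combination (alpha, 1 - alpha). Returns
        (L_e, L_r, grads).
        """
        sig = self.hp.as_printed_sigma_candidate
        if entity_weight is None:
            entity_weight = alpha
        if relation_weight is None:
            relation_weight = 1.0 - alpha
        hs, enc_cache, wi, pi = self.encode(sentence)
        n, two_h = hs.shape
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dhs = np.zeros_like(hs)

        # tagger path (dropout on the Bi-LSTM output)
        if rng is not None and dropout_ner > 0.0:
            mask_ner = (rng.random(hs.shape) >= dropout_ner) / (1.0 - dropout_ner)
        else:
            mask_ner = np.ones_like(hs)
        hs_ner = hs * mask_ner
        dec = self._decoder()
        L_e = 0.0
        if entity_weight > 0.0:
            _, probs, dec_cache = decode_labels(hs_ner, dec, gold_label_ids)
            L_e = cross_entropy(probs, gold_label_ids) * len(sentence)
            d_ner, dec_grads = decoder_backward(
                probs, gold_label_ids, dec_cache, dec, entity_weight)
            for k, v in dec_grads.items():
                grads[k] += v
            dhs += d_ner * mask_ner

        # relation path (dropout on h_r)
        L_r = 0.0
        if relation_weight > 0.0 and candidates:
            for cand in candidates:
                if rng is not None and dropout_rel > 0.0:
                    dim = self.params["W_r"].shape[1]
                    mask = (rng.random(dim) >= dropout_rel) / (1.0 - dropout_rel)
                else:
                    mask = None
                p, cache = self._pair_forward(cand, hs, gold_label_ids, mask)
                gold = int(cand.label)
                L_r += -np.log(max(p[gold], 1e-12))
                self._pair_backward(cand, p, gold, cache, gold_label_ids,
                                    relation_weight, dhs, grads)

        # shared encoder and embeddings
        dxs, dWf, dbf, dWb, dbb = encoder_backward(
            dhs, enc_cache, self._lstm("enc_f"), self._lstm("enc_b"), sig)
        grads["enc_f_W"] += dWf
        grads["enc_f_b"] += dbf
        grads["enc_b_W"] += dWb
        grads["enc_b_b"] += dbb
        d_w = self.hp.d_w
        for t in range(n):
            grads["E_word"][wi[t]] += dxs[t, :d_w]
            grads["E_pos"][pi[t]] += dxs[t, d_w:]
        return float(L_e), float(L_r), grads

    def sgd_update(self, grads: dict, lr: float, clip_norm: float = 5.0,
                   trainable: set[str] | None = None) -> None:
        """Clipped SGD step; ``trainable`` restricts the updated tensors."""
        keys = [k for k in self.params if trainable is None or k in trainable]
        total = np.sqrt(sum(float((grads[k] ** 2).sum()) for k in keys))
        factor = lr * (clip_norm / total if total > clip_norm else 1.0)
        for k in keys:
            self.params[k] -= factor * grads[k]

    # -- inference ------------------------------------------------------------

    def gold_label_ids(self, sentence: Sentence,
                       entities: Sequence[EntityMention]) -> list[int]:
        from .corpus import bio_encode

        return [self.label_index[str(lab)]
                for lab in bio_encode(sentence, entities, self.hp.scheme)]

    def predict_sentence(self, sentence: Sentence
                         ) -> tuple[list[EntityMention], list[RelationInstance]]:
        """Greedy tagging, BIO decoding, then relation classification over
        all candidate pairs using the predicted labels' embeddings."""
        hs, _, _, _ = self.encode(sentence)
        pred_ids, _, _ = decode_labels(hs, self._decoder())
        labels = [BioLabel.parse(self.labels[i]) for i in pred_ids]
        entities = spans_to_mentions(sentence, bio_decode(labels))
        relations = []
        for cand in generate_candidates(entities, self.hp.scheme):
            p, _ = self._pair_forward(cand, hs, pred_ids)
            if p[1] >= 0.5:
                relations.append(RelationInstance(cand.fm, cand.target, True))
        return entities, relations

    # -- persistence -----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: all tensors plus vocabularies, label
        inventory and hyperparameters; loading restores bit-identical
        predictions."""
        meta = {"hp": asdict(self.hp), "words": self.words.items,
                "pos": self.pos.items, "labels": self.labels}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "FHModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
        hp = ModelHyperparams(**meta["hp"])
        model = cls(hp, Vocab(meta["words"][1:]), Vocab(meta["pos"][1:]),
                    np.random.default_rng(0))
        assert model.labels == meta["labels"]
        for k in model.params:
            model.params[k] = arrays[k]
        return model


def build_vocabs(sentences: Sequence[Sentence]) -> tuple[Vocab, Vocab]:
    """Word (lowercased) and POS vocabularies from training sentences."""
    words = []
    tags = []
    for sent in sentences:
        for tok in sent.tokens:
            words.append(tok.text.lower())
            tags.append(tok.pos)
    return Vocab(words), Vocab(tags)


def load_pretrained_embeddings(path: str | Path, vocab: Vocab,
                               table: np.ndarray) -> int:
    """Overwrite embedding rows from a whitespace-separated text file
    (``word v1 v2 ...``); returns the number of rows initialized."""
    dim = table.shape[1]
    hits = 0
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        parts = line.rstrip().split(" ")
        if len(parts) != dim + 1:
            continue
        word = parts[0]
        if word in vocab.index:
            table[vocab.index[word]] = np.array(parts[1:], dtype=float)
            hits += 1
    return hits
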
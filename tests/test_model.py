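"""Neural-architecture tests against independent plain-loop oracles.

The oracles below recompute every forward quantity with explicit scalar
loops over the per-gate parameter views, sharing no code with the vectorized
implementation; backpropagation is checked against central finite
differences.
"""

import math

import numpy as np
import pytest

from fhjoint.corpus import EntityMention, make_document
from fhjoint.model import (
    DecoderParams,
    FHModel,
    LstmParams,
    ModelHyperparams,
    Vocab,
    classify_pair,
    context_representation,
    decode_labels,
    encode_sentence,
    entity_representation,
    generate_candidates,
    lstm_step,
    run_lstm,
)

RNG = np.random.default_rng(42)


def sig(x):
    return 1.0 / (1.0 + math.exp(-x))


# ---------------------------------------------------------------------------
# Scalar-loop oracles (independent of the vectorized code)


def oracle_lstm(xs, p: LstmParams, sigma_candidate=False):
    """Plain-Python recurrence using the named per-gate views."""
    H, D = p.hidden, p.input_dim
    h = [0.0] * H
    c = [0.0] * H
    out = []
    for x in xs:
        hx = list(h) + list(x)
        nh, nc = [0.0] * H, [0.0] * H
        for j in range(H):
            zi = sum(p.W_i[j][k] * hx[k] for k in range(H + D)) + p.b_i[j]
            zf = sum(p.W_f[j][k] * hx[k] for k in range(H + D)) + p.b_f[j]
            zc = sum(p.W_c[j][k] * hx[k] for k in range(H + D)) + p.b_c[j]
            zo = sum(p.W_o[j][k] * hx[k] for k in range(H + D)) + p.b_o[j]
            g = sig(zc) if sigma_candidate else math.tanh(zc)
            nc[j] = sig(zf) * c[j] + sig(zi) * g
            nh[j] = sig(zo) * math.tanh(nc[j])
        h, c = nh, nc
        out.append(list(h))
    return np.array(out)


def oracle_decoder(hs, dec: DecoderParams, gold):
    """Per-token label distributions via explicit matrix arithmetic."""
    probs = []
    prev = dec.start_index
    for t in range(len(hs)):
        u = np.concatenate([hs[t], dec.label_table[prev]])
        e = np.tanh(dec.W_eh @ u + dec.b_eh)
        s = dec.W_ey @ e + dec.b_ey
        exp = np.exp(s - s.max())
        probs.append(exp / exp.sum())
        prev = gold[t]
    return np.array(probs)


# ---------------------------------------------------------------------------
# LSTM cell


class TestLstmStep:
    def test_zero_parameters_give_zero_state(self):
        p = LstmParams(np.zeros((12, 5)), np.zeros(12))
        h, c = lstm_step(np.ones(2), np.zeros(3), np.zeros(3), p)
        assert np.allclose(h, 0.0) and np.allclose(c, 0.0)

    def test_printed_sigma_candidate_breaks_zero_identity(self):
        p = LstmParams(np.zeros((12, 5)), np.zeros(12))
        h, c = lstm_step(np.ones(2), np.zeros(3), np.zeros(3), p,
                         sigma_candidate=True)
        assert np.all(c > 0.0)  # sigma(0) = 0.5 candidate leaks in

    def test_saturated_gates_preserve_cell(self):
        H = 3
        W = np.zeros((4 * H, H + 2))
        b = np.zeros(4 * H)
        b[:H] = -50.0        # input gate shut
        b[H:2 * H] = 50.0    # forget gate open
        p = LstmParams(W, b)
        c_prev = np.array([0.3, -0.7, 1.1])
        _, c = lstm_step(np.ones(2), np.zeros(H), c_prev, p)
        assert np.allclose(c, c_prev, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        p = LstmParams(np.zeros((12, 5)), np.zeros(12))
        with pytest.raises(ValueError, match="shape"):
            lstm_step(np.ones(4), np.zeros(3), np.zeros(3), p)

    @pytest.mark.parametrize("sigma_candidate", [False, True])
    def test_matches_scalar_loop_oracle(self, sigma_candidate):
        H, D, n = 4, 3, 5
        p = LstmParams(RNG.uniform(-0.5, 0.5, (4 * H, H + D)),
                       RNG.uniform(-0.5, 0.5, 4 * H))
        xs = RNG.uniform(-1, 1, (n, D))
        hs, _ = run_lstm(xs, p, sigma_candidate)
        assert np.allclose(hs, oracle_lstm(xs, p, sigma_candidate), atol=1e-6)


# ---------------------------------------------------------------------------
# Sentence encoder


class TestEncoder:
    def test_empty_sentence_rejected(self):
        p = LstmParams(np.zeros((8, 5)), np.zeros(8))
        with pytest.raises(ValueError, match="empty"):
            encode_sentence(np.empty((0, 3)), p, p)

    def test_state_dimension_is_twice_hidden(self):
        H, D, n = 100, 7, 4
        f = LstmParams(RNG.uniform(-0.1, 0.1, (4 * H, H + D)), np.zeros(4 * H))
        b = LstmParams(RNG.uniform(-0.1, 0.1, (4 * H, H + D)), np.zeros(4 * H))
        hs, _ = encode_sentence(RNG.normal(size=(n, D)), f, b)
        assert hs.shape == (n, 2 * H)

    def test_length_one_sentence(self):
        H, D = 3, 2
        f = LstmParams(RNG.uniform(-0.3, 0.3, (4 * H, H + D)), np.zeros(4 * H))
        b = LstmParams(RNG.uniform(-0.3, 0.3, (4 * H, H + D)), np.zeros(4 * H))
        x = RNG.normal(size=(1, D))
        hs, _ = encode_sentence(x, f, b)
        hf, _ = run_lstm(x, f)
        hb, _ = run_lstm(x, b)
        assert np.allclose(hs[0], np.concatenate([hf[0], hb[0]]))

    def test_reversal_swaps_and_mirrors_halves_with_tied_params(self):
        H, D, n = 4, 3, 6
        p = LstmParams(RNG.uniform(-0.4, 0.4, (4 * H, H + D)),
                       RNG.uniform(-0.1, 0.1, 4 * H))
        xs = RNG.normal(size=(n, D))
        fwd, _ = encode_sentence(xs, p, p)
        rev, _ = encode_sentence(xs[::-1], p, p)
        for t in range(n):
            assert np.allclose(rev[t, :H], fwd[n - 1 - t, H:], atol=1e-10)
            assert np.allclose(rev[t, H:], fwd[n - 1 - t, :H], atol=1e-10)

    def test_palindromic_input_mirror_symmetry(self):
        H, D = 3, 2
        p = LstmParams(RNG.uniform(-0.4, 0.4, (4 * H, H + D)), np.zeros(4 * H))
        half = RNG.normal(size=(3, D))
        xs = np.concatenate([half, half[::-1]])
        hs, _ = encode_sentence(xs, p, p)
        n = len(xs)
        for t in range(n):
            assert np.allclose(hs[t, :H], hs[n - 1 - t, H:], atol=1e-10)


# ---------------------------------------------------------------------------
# Label decoder


def tiny_decoder(n_labels=3, d_l=2, n_h=4, d_e=5, zero_out=False):
    table = RNG.uniform(-0.5, 0.5, (n_labels + 1, d_l))
    W_eh = RNG.uniform(-0.5, 0.5, (d_e, n_h + d_l))
    W_ey = np.zeros((n_labels, d_e)) if zero_out else \
        RNG.uniform(-0.5, 0.5, (n_labels, d_e))
    return DecoderParams(table, W_eh, np.zeros(d_e), W_ey, np.zeros(n_labels))


class TestDecoder:
    def test_distributions_normalized_and_positive(self):
        dec = tiny_decoder()
        hs = RNG.normal(size=(6, 4))
        _, probs, _ = decode_labels(hs, dec)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert np.all(probs > 0.0)

    def test_zero_output_layer_gives_uniform(self):
        dec = tiny_decoder(zero_out=True)
        _, probs, _ = decode_labels(RNG.normal(size=(4, 4)), dec)
        assert np.allclose(probs, 1.0 / 3.0)

    def test_teacher_forced_matches_arithmetic_oracle(self):
        dec = tiny_decoder()
        hs = RNG.normal(size=(3, 4))
        gold = [2, 0, 1]
        _, probs, _ = decode_labels(hs, dec, gold)
        assert np.allclose(probs, oracle_decoder(hs, dec, gold), atol=1e-6)

    def test_greedy_feedback_uses_predicted_labels(self):
        dec = tiny_decoder()
        hs = RNG.normal(size=(3, 4))
        preds, probs, _ = decode_labels(hs, dec)
        assert np.allclose(probs, oracle_decoder(hs, dec, preds), atol=1e-6)

    def test_empty_encoding_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            decode_labels(np.empty((0, 4)), tiny_decoder())


# ---------------------------------------------------------------------------
# Relation head


class TestRelationHead:
    def test_single_token_entity_is_state_label_concat(self):
        hs = RNG.normal(size=(5, 4))
        labs = RNG.normal(size=(5, 2))
        v = entity_representation((2, 3), hs, labs)
        assert np.allclose(v, np.concatenate([hs[2], labs[2]]))

    def test_multi_token_entity_is_elementwise_sum(self):
        hs = RNG.normal(size=(5, 4))
        labs = RNG.normal(size=(5, 2))
        v = entity_representation((1, 3), hs, labs)
        expect = np.concatenate([hs[1], labs[1]]) + \
            np.concatenate([hs[2], labs[2]])
        assert np.allclose(v, expect)

    def test_out_of_range_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            entity_representation((3, 6), np.zeros((5, 4)), np.zeros((5, 2)))

    def test_empty_context_gives_zero_vector(self):
        H = 3
        p = LstmParams(RNG.uniform(-0.2, 0.2, (4 * H, H + 6)), np.zeros(4 * H))
        hc, cache = context_representation(np.empty((0, 6)), p, p)
        assert np.allclose(hc, 0.0) and hc.shape == (2 * H,) and cache is None

    def test_context_is_last_fwd_and_last_bwd_state(self):
        H, D = 3, 6
        f = LstmParams(RNG.uniform(-0.3, 0.3, (4 * H, H + D)), np.zeros(4 * H))
        b = LstmParams(RNG.uniform(-0.3, 0.3, (4 * H, H + D)), np.zeros(4 * H))
        between = RNG.normal(size=(4, D))
        hc, _ = context_representation(between, f, b)
        assert np.allclose(hc[:H], oracle_lstm(between, f)[-1], atol=1e-6)
        assert np.allclose(hc[H:], oracle_lstm(between[::-1], b)[-1], atol=1e-6)

    def test_context_dimension_constant_in_length(self):
        H, D = 3, 6
        f = LstmParams(RNG.uniform(-0.3, 0.3, (4 * H, H + D)), np.zeros(4 * H))
        dims = {context_representation(RNG.normal(size=(n, D)), f, f)[0].shape
                for n in (0, 1, 2, 5)}
        assert dims == {(2 * H,)}

    def test_zero_classifier_weights_give_half(self):
        p = classify_pair(RNG.normal(size=7), np.zeros((2, 7)), np.zeros(2))
        assert np.allclose(p, 0.5)

    def test_classifier_probabilities_sum_to_one(self):
        p = classify_pair(RNG.normal(size=7),
                          RNG.uniform(-1, 1, (2, 7)), RNG.uniform(-1, 1, 2))
        assert p.shape == (2,) and np.isclose(p.sum(), 1.0) and np.all(p > 0)

    def test_classifier_matches_arithmetic_oracle(self):
        h_r = RNG.normal(size=7)
        W = RNG.uniform(-1, 1, (2, 7))
        b = RNG.uniform(-1, 1, 2)
        s = [sum(W[k][j] * h_r[j] for j in range(7)) + b[k] for k in range(2)]
        z = [math.exp(v - max(s)) for v in s]
        assert np.allclose(classify_pair(h_r, W, b),
                           np.array(z) / sum(z), atol=1e-6)


# ---------------------------------------------------------------------------
# Candidate generation


def mention(start, end, etype, sent=0):
    return EntityMention("d", sent, start, end, etype, "x")


class TestCandidates:
    @pytest.mark.parametrize("entities,expected", [
        ([mention(0, 1, "FamilyMember"), mention(2, 3, "Observation"),
          mention(4, 5, "Observation")], 2),
        ([mention(0, 1, "FamilyMember"), mention(2, 3, "FamilyMember"),
          mention(4, 5, "LivingStatus")], 2),
        ([mention(0, 1, "Observation"), mention(2, 3, "Observation")], 0),
        ([mention(0, 1, "FamilyMember"), mention(2, 3, "FamilyMember")], 0),
    ])
    def test_pair_counts(self, entities, expected):
        assert len(generate_candidates(entities)) == expected

    def test_cross_sentence_pairs_excluded(self):
        ents = [mention(0, 1, "FamilyMember", sent=0),
                mention(0, 1, "Observation", sent=1)]
        assert generate_candidates(ents) == []

    def test_five_type_scheme_fm_types(self):
        ents = [mention(0, 1, "Maternal"), mention(2, 3, "Observation")]
        assert len(generate_candidates(ents, scheme="five")) == 1
        assert len(generate_candidates(ents, scheme="three")) == 0


# ---------------------------------------------------------------------------
# Full forward pass and gradients


def tiny_model(scheme="three", seed=3):
    hp = ModelHyperparams(d_w=4, d_p=3, d_l=2, hidden=5, scheme=scheme)
    words = Vocab(["her", "aunt", "has", "asthma", "and", "uncle", "is",
                   "alive", "."])
    pos = Vocab(["NN", "PRP$", "VBZ", "JJ", "."])
    return FHModel(hp, words, pos, np.random.default_rng(seed))


def test_full_tagger_forward_matches_plain_loop_oracle():
    """Embeddings -> shared Bi-LSTM -> label decoder, all re-derived with
    scalar loops over the per-gate views, to 1e-6."""
    model = tiny_model()
    doc = make_document("d", "Her aunt has asthma .\n")
    sent = doc.sentences[0]
    hs, _, wi, pi = model.encode(sent)

    xs = np.array([np.concatenate([model.params["E_word"][w],
                                   model.params["E_pos"][p]])
                   for w, p in zip(wi, pi)])
    hf = oracle_lstm(xs, model._lstm("enc_f"))
    hb = oracle_lstm(xs[::-1], model._lstm("enc_b"))[::-1]
    assert np.allclose(hs, np.concatenate([hf, hb], axis=1), atol=1e-6)

    gold = model.gold_label_ids(sent, [])
    _, probs, _ = decode_labels(hs, model._decoder(), gold)
    assert np.allclose(probs, oracle_decoder(hs, model._decoder(), gold),
                       atol=1e-6)


def test_tagger_output_length_and_label_inventory():
    model = tiny_model()
    doc = make_document("d", "Her aunt has asthma and her uncle is alive .\n")
    entities, _ = model.predict_sentence(doc.sentences[0])
    hs, _, _, _ = model.encode(doc.sentences[0])
    preds, _, _ = decode_labels(hs, model._decoder())
    assert len(preds) == len(doc.sentences[0])
    assert all(0 <= i < len(model.labels) for i in preds)
    for ent in entities:
        assert ent.etype in ("FamilyMember", "Observation", "LivingStatus")


def test_three_type_scheme_never_emits_side_tags():
    model = tiny_model("three")
    assert not any(l.endswith(("Maternal", "Paternal", "-NA"))
                   for l in model.labels)
    model5 = tiny_model("five")
    assert any(l == "B-Maternal" for l in model5.labels)


def test_backprop_matches_finite_differences():
    """Analytic gradients of alpha*L_e + (1-alpha)*L_r agree with central
    finite differences through the whole network (no dropout)."""
    model = tiny_model()
    doc = make_document("d", "Her aunt has asthma and her uncle is alive .\n")
    sent = doc.sentences[0]
    fm1 = mention(1, 2, "FamilyMember")
    obs = mention(3, 4, "Observation")
    fm2 = mention(6, 7, "FamilyMember")
    ls = mention(8, 9, "LivingStatus")
    gold = model.gold_label_ids(sent, [fm1, obs, fm2, ls])
    from fhjoint.corpus import RelationInstance
    cands = [RelationInstance(fm1, obs, True), RelationInstance(fm1, ls, False),
             RelationInstance(fm2, obs, False), RelationInstance(fm2, ls, True)]
    alpha = 0.4

    def loss():
        L_e, L_r, _ = model.loss_and_grads(sent, gold, cands, alpha, None)
        return alpha * L_e + (1 - alpha) * L_r

    _, _, grads = model.loss_and_grads(sent, gold, cands, alpha, None)
    rng = np.random.default_rng(0)
    eps = 1e-5
    for name in ("E_word", "E_pos", "label_table", "enc_f_W", "enc_b_b",
                 "W_eh", "W_ey", "ctx_f_W", "ctx_b_W", "W_r", "b_r"):
        arr = model.params[name]
        flat = arr.reshape(-1)
        for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            up = loss()
            flat[idx] = orig - eps
            down = loss()
            flat[idx] = orig
            numeric = (up - down) / (2 * eps)
            analytic = grads[name].reshape(-1)[idx]
            assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-7), name


def test_checkpoint_round_trip_bit_identical(tmp_path):
    model = tiny_model()
    doc = make_document("d", "Her aunt has asthma .\n")
    before = model.predict_sentence(doc.sentences[0])
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = FHModel.load(path)
    for k, v in model.params.items():
        assert np.array_equal(loaded.params[k], v)
    assert loaded.predict_sentence(doc.sentences[0]) == before
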
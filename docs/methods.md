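# Methods

This note documents the model, the rule system, the synthetic-data
generator, and the numerical and design choices behind `fhjoint`, in the
order a reader would meet them in the pipeline.

## Task and data model

A document is a plain-text note; tokenization is rule-based (whitespace +
punctuation, with possessive `'s` kept attached to its head so that
`father's father` forms a contiguous two-token span) and offsets are 0-based
half-open character positions, so `text[start:end]` always recovers a
token's surface. POS tags come from a small lexicon-and-suffix Penn-Treebank
tagger built into the corpus module; tags only feed a 20-d learned
embedding, so coarse accuracy suffices. Entities are non-overlapping,
non-nested token spans of three kinds — family member (FM), observation
(disease), living status (LS) — and relations are within-sentence
(FM, observation-or-LS) pairs. Two BIO tag schemes are supported: the
three-type scheme `{FamilyMember, Observation, LivingStatus}` and the
five-type scheme in which the FM tag itself carries the side of family
(`Maternal`, `Paternal`, `NA`). BIO decoding is total: an `I-` tag following
`O` or a different type opens a new entity, so no prediction is dropped.

## Network

* **Input layer.** `x_t = [word embedding (50-d); POS embedding (20-d)]`.
  Out-of-vocabulary words map to a dedicated unknown row. All embeddings are
  initialized uniformly in [−0.1, 0.1]; pretrained word vectors can be
  loaded from a whitespace-separated text file and overwrite matching rows.
* **Shared encoder.** One Bi-LSTM (100 hidden units per direction) over the
  sentence; `h_t` is the 200-d concatenation of the forward and backward
  states. The LSTM candidate cell uses tanh. The printed form of the
  recurrence we implement has a sigmoid there; since that variant breaks the
  zero-parameter → zero-state identity and the architecture is otherwise a
  standard LSTM, tanh is the default and a config switch
  (`as_printed_sigma_candidate`) restores the sigmoid variant exactly.
* **Tagger head.** At each position the decoder sees `[h_t; l_{t−1}]` where
  `l_{t−1}` is a 10-d label embedding — of the gold previous label during
  training (teacher forcing), of the previous greedy prediction at
  inference; position 0 uses a dedicated START embedding. A tanh hidden
  layer (100 units) feeds a softmax over the scheme's BIO labels. Decoding
  is greedy left-to-right; no beam search and no CRF.
* **Relation head.** Entities are represented as the elementwise sum of
  `[h_t; l_t]` over their tokens (so a one-token entity is exactly its own
  vector, and the representation is permutation-invariant within the span).
  The tokens strictly between the two entities are read by a *separate*
  Bi-LSTM (input: the encoder states; 100 units per direction); the last
  forward and last backward states are concatenated into `h_context`, and an
  empty context (adjacent entities) yields a zero vector of the same
  dimension. `h_r = [h_e1; h_context; h_e2]` goes through a binary softmax.
  Whether the context Bi-LSTM should share parameters with the sentence
  encoder is genuinely open; we use a separate one, which keeps the two
  heads' capacities independent.
* **Candidates.** All FM × observation and FM × LS pairs within one
  sentence; never FM × FM or observation × LS, and never across sentences.
  Cross-sentence relations are a declared limitation, not an error mode.

## Training

The combined loss is `L = α·L_e + (1−α)·L_r` with α ∈ (0, 1) (default 0.5;
the grid {0.4, 0.5, 0.6} is wired into the comparison harness). `L_e` is the
cross-entropy **summed** over a sentence's tokens and `L_r` the
cross-entropy summed over its candidate pairs. Sum reduction — the
conventional choice for sequence models under plain SGD — matters here:
with per-token/per-candidate means, the prescribed optimizer (SGD, learning
rate 0.005, one sentence per step) under-scales updates so much that the
tagger is still far from convergence after 20 epochs on the default corpus;
with sums it converges in well under 10.

During training both heads are teacher-forced: the tagger feeds gold
previous labels, and the relation head reads gold spans with gold label
embeddings. The two tasks therefore interact through the shared encoder,
the shared embeddings and the shared label table — a relation-only update
demonstrably moves the encoder (tested by parameter diff). At inference the
tagger's own greedy labels drive both BIO decoding and the relation head.

Regimes:

* **joint** — one loop minimizing `L` end to end;
* **pipeline** — the baseline: train the tagger on `L_e` alone for the
  configured epochs, freeze everything it touches (encoder, embeddings,
  label table, decoder), then train only the relation-head tensors on `L_r`.

Both regimes start from the same initialization when given the same seed,
so regime contrasts are seed-controlled. Engineering defaults not tied to
any published value: batch size 1 sentence, global gradient-norm clipping
at 5, per-epoch shuffling under the run seed, dropout applied to the
tagger's Bi-LSTM output (0.5) and to `h_r` before the relation softmax
(0.3), inverted-dropout scaling. `continue_training` runs extra epochs on a
loaded checkpoint (SGD carries no optimizer state to restore) and never
touches the vocabulary. Checkpoints are single `.npz` archives holding every
tensor plus the vocabularies, label inventory and hyperparameters; loading
restores bit-identical predictions.

## Rule-based post-processing

* **Side of family** (three-type scheme only; the five-type scheme reads the
  side off the tag). Rules fire strictly in order:
  1. first-degree relative → `NA` — the set is {Father, Mother, Parent,
     Brother, Sister, Sibling, Son, Daughter, Child} (standard genealogy;
     config-exposed);
  2. mention inside a `maternal family history:` / `paternal family
     history:` section → that side (a header line opens a section running to
     the next header or end of document);
  3. an indicator token `maternal`/`paternal` within the 3 tokens preceding
     the mention in the same sentence → that side (window covers
     "paternal grandmother"-style noun phrases without cross-clause
     leakage; config-exposed);
  4. otherwise `NA`.

  Rule 1 firing first means a first-degree relative stays `NA` even inside
  a sided section — the generator emits the same ground truth, so rules and
  generator are mutually consistent by construction.
* **Role normalization.** Case-insensitive lexicon over the 15 canonical
  roles with singular/plural folding, plus composition over possessive
  chains (`father's father` → Grandfather, `mother's sister` → Aunt,
  `aunt's daughter` → Cousin). A chain with no composition entry falls back
  to the head noun's role; a surface with no relative word at all returns a
  reject marker rather than raising.
* **Living status.** Keyword scan of the mention: healthy = Yes iff a
  healthy keyword ({healthy, well}) appears, else NA; alive = No iff a
  deceased keyword ({deceased, dead, died, passed, expired}) appears, else
  Yes. A mention with no keyword defaults to alive — a living-status mention
  with no death evidence is read as alive. All keyword sets are
  config-exposed. The score is the product of component scores (alive
  Yes = 2 / No = 0; healthy Yes = 2 / NA = 1): No/* → 0 and Yes/NA → 2 are
  fixed by the published rule table; Yes/Yes → 4 is our product-consistent
  extension (the table prints only the two rows).

## Evaluation

Both subtasks score exact, deduplicated record tuples per document:
subtask 1 on (doc, role, side) for family members — broken down by side —
and (doc, normalized text) for observations; subtask 2 on (doc, role, side,
observation text) and (doc, role, side, LS score). Text normalization is
lowercase + whitespace collapse, the strictest reasonable choice given that
the original scorer's tolerance is unspecified. Deduplication is at
document level: a relative mentioned twice is one record. Zero-denominator
precision/recall return 0. Overall rows are micro-averages; living-status
mention rows are excluded from the subtask-1 overall because the challenge
does not distribute a direct gold standard for them. The scorer satisfies
(and is tested for) gold-vs-gold perfection, FP/FN symmetry under
gold/prediction swap, and additivity of micro counts.

## Synthetic corpus

Generation is template slot-filling — not a language model — so gold spans,
attributes and relations are exact and free. A document is 3–8 sentences;
with probability 0.3 it is organized under `Maternal/Paternal family
history:` headers. Content sentences mention one or two of the 15 roles
with a disease observation (60-phrase vocabulary, 1–4 tokens) and/or a
living-status phrase drawn from a bank partitioned by (alive, healthy)
ground truth; the partition agrees with the keyword rules by construction.
Non-first-degree relatives outside sections take an explicit side with
probability 0.5, realized as an adjacent `maternal`/`paternal` indicator
token. Two-relative sentences (probability 0.3) supply the negative
relation candidates. Distractor sentences (probability 0.1) contain
relative-of-relative constructions (`her grandmother's sisters also had
kidney cancer`) whose observations carry no patient-level relation — the
main error class of joint extractors on real notes. Everything derives from
one integer seed; identical configs give byte-identical corpora.

The generator emulates questionnaire *structure*, not clinical reality: no
typos, no EHR template fragments, no pronoun coreference, no cross-sentence
relations, a closed disease vocabulary, and a class balance that is a guess
(the real corpus' balance is unpublished — the ratios are config knobs).
Consequently, passing the learnability test shows that the architecture,
gradients and decoding are correct and that the joint objective is
trainable at the published hyperparameters; it does not predict F1 on real
clinical text.

## Problem sizes and runtime

The default corpus is 200 documents (trains in a few minutes on one CPU);
the learnability check trains on a 90/10 split with early stopping at
held-out entity F1 0.95 / relation F1 0.90, reached in ~6–8 epochs. The
regime-contrast and α-grid harnesses in the test suite run on 24–30
document corpora for 2–3 epochs — enough to exercise both regimes and every
grid cell end to end; they assert completeness of the comparison, not a
direction of effect, which synthetic data need not reproduce.

## Known limitations

Within-sentence relations only; greedy decoding can lock in an early
tagging mistake (no CRF or beam); the rule cascade cannot recover a side of
family stated in a different sentence ("his mother's relatives… she …");
possessive-chain normalization handles two-link chains, falling back to the
head noun beyond that; and the relation classifier sees no characters or
subwords, so out-of-vocabulary disease names rely entirely on context.
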
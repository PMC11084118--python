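# Methods

## Problem and scope

`sudscope` implements a dark-web-to-social-media analysis pipeline for opioid
epidemiology: recognize drug mentions in text with a curated lexicon mapped to
eight super-categories (heroin, synthetic heroin, pharmaceutical fentanyl,
nonpharmaceutical fentanyl, fentanyl, oxycodone, kratom, opium); parse
cryptomarket listings into a property schema; derive sentiment, emotion and
topic features; and classify posts as SUDP/SUDA from the author's posting
history. The original study corpora (marketplace crawls, subreddit and Twitter
collections) are not publicly deposited, so the package ships a synthetic
generator that emulates their statistical structure and serves as the test
bed for every stage.

## Lexicon matching and masking

Matching is gazetteer NER: a case-insensitive, token-boundary-delimited
regex compiled from the lexicon. Overlapping candidates are resolved
longest-match-first, then leftmost, so multi-word terms ("china white",
"hillbilly heroin", "fentanyl transdermal system") beat their unigram
substrings. Mentions are masked as `[DRUG_<CATEGORY>]`; the token is
re-tokenizable, category-preserving, and matches no lexicon entry, making
masking idempotent. PII scrubbing replaces URLs and @-handles with `[URL]` /
`[USER]` before any feature extraction.

The packaged default lexicon holds 120 terms across the 8 categories —
generic, brand, slang, street, marketing, common and abbreviation types. It
is a compact curated stand-in for a full drug-abuse ontology, which is not
redistributable; surface forms are globally unique, and an ambiguous surface
listed under two categories resolves to its first row.

## Listings

Price strings accept the dialects `BTC x`, `x BTC`, `$x`, `USD x`, `x USD`.
Quantities parse number + unit with g/gr/gram(s) ×1, kg ×1000, mg ×0.001;
counted units (pint, tablets, pills, ml, oz) are recognized but yield null
grams, since no mass conversion is defined for them. The substance of a
listing is the first lexicon mention in the title (titles lead with the
product); dosage is read from the description. Per-field parse failures
become nulls with a warning so that a crawl batch never aborts. Market
summaries report distinct vendors/substances, per-category listing shares
over matched listings (summing to 100), and mean offered grams per category
(per month when timestamps are present).

## Affect features

Sentiment is a rule-based valence scorer in the style standard for
social-media text: human-annotated per-token valences in [-4, 4], a negation
flip (scalar -0.74) over a three-token window, ±0.293 per intensity booster,
sum pooled through s/√(s² + 15) and labeled with a ±0.05 neutral band. The
shipped valence lexicon is a small curated list (~130 tokens) written for
this package and skewed toward recovery/withdrawal vocabulary; it is a
synthetic stand-in for the full published dictionary, adequate because the
generator draws its sentiment-bearing words from the same vocabulary space.

Emotion uses distant supervision: a text qualifies when, after scrubbing, it
ends with exactly one hashtag whose stem names one of the seven emotions and
no other emotion hashtag appears; multi-emotion texts are excluded as
ambiguous. The label hashtag is removed, remaining hashtag markers are
stripped to their stems.

`AffectClassifier` (either task) is a trainable embedding bag: learned token
embeddings (width H), mean pooling, linear softmax, cross-entropy with Adam —
10 epochs, batch 32 by default. The pooled penultimate representation is the
fixed-width affect vector used downstream; we chose the pooled hidden
representation (rather than logits) because it preserves more than k
dimensions of affect information. Out-of-vocabulary tokens are dropped from
the pool.

## Sequence classifier

Per history step: content vector (hashed embedding-bag encoder, seeded
Gaussian table — a frozen random-projection bag of words), sentiment and
emotion vectors from the frozen affect models (treated as feature
extractors, not fine-tuned), and Δt = log1p(hours since the previous step),
standardized with training-set statistics. All three vector families share
one width H (mismatch raises). Histories are the same author's prior posts;
truncation keeps the K most recent (recency assumption, K = 10 default);
shorter histories are left-padded with masked zero steps excluded from
attention. The first retained step's Δt measures hours since the earliest
post of the full history.

Architecture: bidirectional LSTM (d units per direction) over the K steps;
additive attention pooling over valid steps; pooled context concatenated with
the target post's content vector; dense ReLU layer with inverted dropout 0.2
during training; 2-way softmax. Optimization is mean cross-entropy with Adam,
10 epochs, batch 64. All forward/backward passes are explicit numpy; the
analytic gradients are checked against central differences in the tests.

Ablations: *minus attention* mean-pools the recurrent outputs over valid
steps (pooling, not last-state, matches the concatenation-style removal of
the attention layer); *minus masking* feeds raw scrubbed text to all
encoders; *minus history* drops the recurrent branch entirely, so the model
is a feed-forward classifier on the target vector and exactly invariant to
the history argument. With K = 1 and attention off, the full model reduces
to a feed-forward network over the single step's features (verified by an
introspection test).

### Hyperparameters

| parameter | default | notes |
|---|---|---|
| H (feature width) | 32 (16 in compact tests) | 768 reproduces a contextual-encoder configuration; any width works |
| K (history window) | 10 | most-recent truncation |
| LSTM units / direction | 32 | |
| dropout | 0.2 | dense layer, training only |
| epochs / batch | 10 / 64 (SUD), 10 / 32 (affect) | |
| learning rate | 1e-3 | 1e-5 is the published setting for pretrained contextual encoders; it under-trains these small models in 10 epochs, so the desk default is 1e-3 (overridable). Small fixtures with few batches per epoch use more epochs instead (25 in the compact tests). |

## Evaluation

Stratified 75:5:20 train/dev/test splits use largest-remainder rounding per
stratum (ties resolved train-first), so proportions match to within one item;
strata below 3 items are rejected. Macro precision/recall/F1 average
unweighted over the union of observed classes, with classes absent from the
predictions contributing zero. The Wilcoxon signed-rank test discards zero
differences, mid-ranks ties, computes the exact tie-aware null distribution
by convolution for n ≤ 25 and a tie-corrected, continuity-corrected normal
approximation above; paired units are per-run metric values. Reported tables
use medians over repeated runs (desk default 5 runs).

## Synthetic generator

The generator defines the study conditions for every recovery test:

- **Posts.** Each of 400 authors (default) carries a latent SUDP/SUDA state
  (P = 0.5) and a drug category drawn from shares echoing the subreddit
  corpus composition (heroin 47%, kratom 27%, ...). History posts mix neutral
  filler with sentiment words drawn via P(negative | SUDP) = 0.8 vs
  P(negative | SUDA) = 0.3 and emotion words from a state-shifted mixture
  (sadness/fear dominant under SUDP; love elevated under SUDA) — the
  qualitative pattern observed in per-drug emotion tables. Drug terms appear
  at rate 0.9. The final post per author is the class-neutral labeled target,
  so under the default configuration the history, not the target text,
  carries the signal; a `target_leak` switch plants target-text signal for
  baseline checks. Timestamps are exponential gaps (mean 48 h) inside
  2015–2020.
- **Emotion tweets.** Keyword texts self-tagged with the matching hashtag,
  plus occasional handles/URLs to exercise scrubbing.
- **Listings.** Titles templated as `<qty> <unit> <drug term> <fillers>` with
  mass units only, Bitcoin prices in the supported dialects, categories drawn
  from shares echoing the marketplace composition (heroin 57.8%, novel
  synthetics 4.2%), so the parser recovers quantity, price and category
  exactly and shares match to binomial noise.

The generated text is templated bags of words, not natural language. Passing
recovery tests therefore demonstrates that the pipeline's mechanics —
masking, affect extraction, history encoding, attention, ablation ordering —
work end to end and that the planted dependence is identifiable; they say
nothing about performance on real social-media language, sarcasm, topic
drift, or annotation noise.

## Numerical choices and degenerate inputs

Smoothed idf = ln((1+N)/(1+df)) + 1 keeps single-group topic corpora finite;
tf = raw count / group token count; ties in topic rankings break
alphabetically for determinism. Stop words (scikit-learn's English list) and
bracketed mask tokens are excluded from topics so they reflect context
vocabulary rather than the query drugs. Empty texts encode to a zero vector
with a warning; empty histories produce an all-padded sequence whose
attention vector is zero. Softmax computations are max-shifted; attention
over fully padded rows is defined as zero. All randomness flows through
seeded numpy Generators; per-seed corpora are byte-identical across runs.

## Known limitations

- The content encoder is a frozen random-projection bag of words; it carries
  lexical, not contextual, information. A contextual encoder can be slotted
  behind the same `encode` interface.
- The valence and drug lexicons are compact curated stand-ins, not the full
  published resources.
- Non-mass dose units are not converted to grams.
- The Wilcoxon exact path is limited to n ≤ 25 pairs (by design; the normal
  approximation takes over above).
- Reported study-scale metrics from the original corpora are not reproducible
  here, since those corpora are unavailable; all quantitative claims in this
  package are about synthetic recovery.
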
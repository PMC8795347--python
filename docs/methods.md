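# Methods

## Problem and model

The package classifies social-media users as depressed or not from their
timeline — the ordered tweets $A = [t_1, \dots, t_L]$, each tweet a word
sequence $t_i = [w_{i1}, \dots, w_{iN}]$ — together with behavioural
statistics, and explains each prediction through the attention weights the
classifier itself used.

Two branches are fused:

**Text branch (hierarchical attention).** Words are mapped to frozen
pretrained embeddings $x_{ij}$. A bidirectional GRU produces contextual
states $h^w_{ij} = [\overrightarrow{h}_{ij} \oplus \overleftarrow{h}_{ij}]$;
a tanh attention layer scores them,

$$u_{ij} = \tanh(W_w h^w_{ij} + b_w), \qquad
\alpha_{ij} = \frac{\exp(u_{ij}^\top u_w)}{\sum_j \exp(u_{ij}^\top u_w)},$$

and pools them into a tweet vector $v_i = \sum_j \alpha_{ij} h^w_{ij}$.
The same construction, with its own parameters, runs over the sequence of
tweet vectors: a second BiGRU gives $h^t_i$, tweet attention gives
$\alpha_i$, and the user vector is $s = \sum_i \alpha_i h^t_i$.  (The
classification layer needs a single user vector; the per-position states
$h^t_i$ exist only inside the attention pooling.)

**Aspect branch.** Four feature blocks are concatenated into a
multi-aspect vector $m \in \mathbb{R}^M$ and passed through a one-layer
MLP, $p = \mathrm{ReLU}(W m + b)$.  The blocks:

| block | dim | contents |
|---|---|---|
| social | 30 | n-tweets, total character length, n-retweets, followers, friends, favourites, 24-hour posting histogram |
| emo | 8 | positive/neutral/negative emoji counts, summed valence/arousal/dominance, first-person singular/plural counts |
| topic | K=25 | LDA topic mixture of the user's pooled tokens |
| domain | 10 | counts of the nine depression-symptom groups + antidepressant mentions |

**Fusion.** $\hat{y} = \sigma(b_f + [p, s] W_f)$, trained with mean binary
cross-entropy (probabilities clipped at $10^{-7}$), Adam.  Variants gate
the branches: HAN (text only) and MM (aspects only) drop the other input
of the fusion layer; aspect masks drop feature blocks for ablations.

The network is implemented directly in NumPy with hand-derived backward
passes; the test suite checks every gradient against central finite
differences and the full forward pass against an independent scalar
re-implementation.

## Preprocessing and feature conventions

* Cleaning extracts emojis by codepoint range first, lowercases, splits on
  non-word characters (keeping apostrophes), then drops stopwords and any
  token containing a non-ASCII byte.  The stopword list is a bundled,
  editable file; first-person pronouns are intentionally not stopwords
  because their counts are a feature.
* User filters: at least 10 posts and at most 5000 followers (the upper
  bound removes celebrity/bot-like accounts); both are parameters.
* VAD scores are summed, not length-normalized; words outside the norm
  list contribute nothing.  Unknown emojis count as neutral.  Posting hour
  is the stored clock hour, no timezone correction.
* The LDA topic model is fitted on the pooled tweets (one document per
  tweet) of the *depressed training* users only, then applied to everyone;
  a user with no in-vocabulary tokens gets the uniform mixture.
* Symptom lexicons start from nine seed lists and are expanded with up to
  10 embedding nearest neighbours per seed at cosine ≥ 0.6; a word drawn
  into several groups goes to the group of its most similar seed (ties to
  the earlier group).  Matching is token-exact; multi-word antidepressant
  names match as token n-grams.
* Non-simplex feature columns are z-scored with statistics of the training
  split only; topic columns stay raw.  Constant columns get unit scale.

## Tunable parameters

Model defaults mirror the published configuration: 100-d embeddings,
hidden size 100 per GRU direction, MLP hidden 100, dropout 0.5 (applied to
each encoder output and the MLP hidden layer), at most 200 most-recent
tweets and 50 tokens per tweet, classification threshold 0.5.  Training
defaults: 10 epochs, batch 16, Adam lr 0.001, no early stopping.  The
attention projection width defaults to twice the hidden size.  An optional
max-pool of size 4 over tweet hidden states exists behind
`tweet_maxpool` (default off; its published location is unstated, and it
collapses per-tweet attention, so the explainer rejects it).

For the synthetic studies the geometry is scaled to the toy corpus: 50-d
embeddings, hidden 32 per direction, the 40 most recent tweets, 20 tokens
per tweet; training hyperparameters are kept at the published values.
These sizes are stated here once and used by both the test suite and
`scripts/acceptance.py`.

## The synthetic generator

`mdhan.synthetic` emulates the class-conditional contrasts the model is
built to exploit, as per-tweet event probabilities (depressed / control
defaults): symptom-word mention 0.30 / 0.02, negative emoji 0.25 / 0.05,
first-person singular 0.20 / 0.08, night-time (00:00–05:00) posting
fraction 0.40 / 0.10, antidepressant mention 0.02 / 0.002, plus a shifted
theme mixture for the filler text (`topic_shift` = 0.6).  Filler words
follow Zipf-like frequencies within five latent themes so LDA has
structure to find.  The toy embedding table places each symptom family's
seeds and three planted synonyms in a tight cluster (pairwise cosine
> 0.8), so lexicon expansion is genuinely exercised; timelines span one
synthetic year; timeline lengths are uniform on 10–200.  `SimConfig.null()`
removes every contrast for negative-control runs.

What the generator does *not* emulate: real language (tweets are bags of
pseudo-words), sarcasm/negation, retweet networks, covariate shift between
users, or label noise.  Passing tests therefore show that the pipeline
recovers planted statistical structure, not that it detects depression in
real text.

## Known limitations

Two study-scale checks are expected to fail under these conditions, and
the package reports them honestly rather than tuning around them:

* **Branch ordering.** On synthetic data the aspect-only variant is the
  strongest (≈ 0.99 macro-F1 vs ≈ 0.97 for the fused model): the night-hour
  and emoji channels reach only the aspect features, and aspect counts
  aggregate whole timelines.  The real-data finding that text dominates
  behavioural aggregates needs text that is richer than its summary
  statistics, which bag-of-pseudo-word filler is not.
* **Attention localization.** With strong, redundant signals the
  cross-entropy loss is minimized without selective attention: the
  bidirectional tweet encoder spreads evidence over all positions and the
  attention weights stay near their initialization, so the single planted
  symptom tweet of a probe user rarely tops the ranking (≈ 20% of correct
  cases).  Explanations remain *faithful* — the reported weights are
  bit-for-bit the weights of the prediction's forward pass — but
  faithful-and-diffuse.  This mirrors the known gap between attention and
  explanation; sparse-signal training data would create localization
  pressure, but sparsity is not part of the study conditions.

Other limitations: no GPU path (pure NumPy; minutes per 600-user training
run on one core); no early stopping or hyperparameter search; language
identification is accepted as an input flag, not performed; word-cloud
images are out of scope (the frequency tables behind them are provided).

## Numerical choices

Glorot-uniform initialization everywhere, zero biases; all randomness
(init, dropout, batch order, splits, simulation) flows from explicit
seeds.  Masked softmax rows with no real positions yield all-zero weights;
empty tweets contribute zero vectors and are excluded from explanation
reports.  Padding is provably inert (masked GRU steps carry state;
asserted to 1e-5 in tests).  Attention ranking ties break toward the
earlier tweet.  Stratified splits take `floor(n_class · 0.8)` training
users per class and depend only on user ids and the seed, not input
order.  Feature TSVs round-trip bit-exactly (`repr` floats).
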
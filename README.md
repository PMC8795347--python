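# mdhan

Explainable depression detection from social-media user timelines.

`mdhan` is for researchers in digital mental health / text mining who want
a self-contained, inspectable implementation of a hybrid
classifier that fuses

* a **hierarchical attention network** over a user's tweets — a
  bidirectional GRU plus attention pooling at the word level
  ($v_i = \sum_j \alpha_{ij} h^w_{ij}$) and again at the tweet level
  ($s = \sum_i \alpha_i h^t_i$) — with
* an **MLP over four behavioural aspect-feature groups**
  ($p = \mathrm{ReLU}(Wm + b)$): social information & interaction, emoji
  sentiment + valence/arousal/dominance, an LDA topic mixture (K = 25), and
  domain-specific counts (nine DSM-IV-style symptom groups, expanded via
  word-embedding similarity, plus antidepressant names),

classified through $\hat{y} = \sigma(b_f + [p, s]\,W_f)$ and trained with
binary cross-entropy.  The attention weights used in the forward pass are
exposed as the explanation of each prediction (HTML heat-map report with a
machine-readable JSON sidecar).

The network is pure NumPy with hand-derived, finite-difference-validated
gradients — no deep-learning framework required.  A synthetic-timeline
simulator with planted class-conditional signals (symptom-word rate,
negative-emoji rate, first-person usage, night posting, topic shift) makes
the entire pipeline runnable and testable without any external data.

## Worked example

```python
from mdhan.synthetic import SimConfig, generate
from mdhan.model import ModelConfig
from mdhan.train_eval import TrainSettings, run_pipeline, split

data = generate(SimConfig(n_users=200, tweets_per_user=(10, 60), seed=7))
train_users, test_users = split(data.users, seed=0)
cfg = ModelConfig(variant="MDHAN", seed=0, embed_dim=50, hidden_dim=32,
                  mlp_hidden=32, max_tweets=40, max_words=20)
model, metrics, history = run_pipeline(
    train_users, test_users, data.lexicons, data.embeddings, cfg,
    settings=TrainSettings(), seed=0)
print("loss history:", " ".join(f"{h:.3f}" for h in history))
print("confusion:", metrics.as_dict()["confusion"])
print(f"accuracy={metrics.accuracy:.3f} macro-F1={metrics.f1:.3f}")
```

prints

```
loss history: 0.663 0.509 0.361 0.218 0.143 0.085 0.068 0.060 0.051 0.046
confusion: {'tp': 19, 'fp': 1, 'fn': 0, 'tn': 21}
accuracy=0.976 macro-F1=0.976
```

The loss history shows the ten training epochs (Adam, batch 16, lr 0.001)
converging; the confusion matrix is over the held-out 20% (40 users): one
control user was misread as depressed, every depressed user was caught,
giving macro-F1 0.976 — the planted behavioural contrasts are recovered
almost perfectly.  `explain_user(model, user, embeddings)` then returns the
per-tweet and per-word attention weights behind any single prediction, and
`render_report` writes them as an HTML heat map.

The same pipeline is available from the shell:

```bash
mdhan simulate --out-dir data/ --n-users 200 --seed 7
mdhan featurize --timelines data/timelines.jsonl --lexicons data/lexicons \
      --embeddings data/embeddings.txt --out features.tsv --seed 7
mdhan train --timelines data/timelines.jsonl --embeddings data/embeddings.txt \
      --features features.tsv --out model.ckpt.npz --seed 7
mdhan eval --model model.ckpt.npz --timelines data/timelines.jsonl \
      --embeddings data/embeddings.txt --features features.tsv --report metrics.json
mdhan explain --model model.ckpt.npz --timelines data/timelines.jsonl \
      --embeddings data/embeddings.txt --features features.tsv --out report.html
```

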
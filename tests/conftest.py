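"""Shared fixtures.

The expensive fixtures (600-user planted-signal experiment, the trained
text-branch model used for explanation checks) are session-scoped so the
training cost is paid once for the whole suite.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from mdhan.model import ModelConfig
from mdhan.synthetic import SimConfig, generate
from mdhan.train_eval import TrainSettings, build_features, run_ablations, run_pipeline, split

#: Model geometry used throughout the experiments: embeddings and hidden
#: sizes matched to the synthetic corpus scale (50-d embeddings, 32 units
#: per GRU direction, 40 most recent tweets, 20 tokens per tweet).
EXPERIMENT_CONFIG = dict(
    embed_dim=50, hidden_dim=32, mlp_hidden=32, max_tweets=40, max_words=20,
    dropout=0.5,
)

TRAIN_SETTINGS = TrainSettings(epochs=10, batch_size=16, lr=0.001, k_topics=25)


@pytest.fixture(scope="session")
def sim_small():
    """A small cohort for fast functional tests (60 users, short timelines)."""
    return generate(SimConfig(n_users=60, tweets_per_user=(10, 25), seed=11))


@pytest.fixture(scope="session")
def planted_600():
    """The planted-signal study cohort: 600 users at default effect sizes."""
    return generate(SimConfig(n_users=600, seed=101))


@pytest.fixture(scope="session")
def ablation_results(planted_600):
    """Macro-F1 (and friends) for MDHAN / HAN / MM over three seeds.

    One stratified 80/20 split and one feature bundle per seed, shared by
    the three variants.
    """
    data = planted_600
    base = ModelConfig(variant="MDHAN", **EXPERIMENT_CONFIG)
    return run_ablations(
        data.users, data.lexicons, data.embeddings, base,
        settings=TRAIN_SETTINGS, seeds=(0, 1, 2), variants=("MDHAN", "HAN", "MM"),
    )


@pytest.fixture(scope="session")
def trained_han(planted_600):
    """A text-branch (HAN) model trained on the planted-signal cohort."""
    data = planted_600
    train_users, test_users = split(data.users, seed=0)
    cfg = ModelConfig(variant="HAN", seed=0, **EXPERIMENT_CONFIG)
    model, metrics, _ = run_pipeline(
        train_users, test_users, data.lexicons, data.embeddings, cfg,
        settings=TRAIN_SETTINGS, seed=0,
    )
    return model, metrics, data
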
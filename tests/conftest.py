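"""Shared fixtures: synthetic corpora and trained toy models.

The expensive desk-scale model (5,000 molecules, 20,000 steps) is trained
once per session and shared by every test that needs a converged model; a
much smaller model covers tests that only need *some* trained decoder.
"""

import numpy as np
import pytest

from moltrans import synthetic, training


@pytest.fixture(scope="session")
def small_corpus():
    """300 unique filter-passing molecules, fixed seed."""
    return synthetic.generate(synthetic.CorpusSpec(n_molecules=300, seed=1))


@pytest.fixture(scope="session")
def tiny_model(small_corpus):
    """A briefly trained small model: enough structure for decoding tests."""
    tc = training.TrainConfig(steps=1200, batch_size=32, eval_every=400,
                              holdout_frac=0.1)
    ckpt, log = training.train(
        small_corpus, "sml2can",
        {"encoder_layers": (96,), "decoder_layers": (96,), "latent_dim": 32},
        tc, seed=5)
    return ckpt, log


@pytest.fixture(scope="session")
def desk_corpus():
    """The desk-scale study corpus: 5,000 unique molecules."""
    return synthetic.generate(synthetic.CorpusSpec(n_molecules=5000, seed=11))


@pytest.fixture(scope="session")
def desk_model(desk_corpus):
    """D=64 translation model trained for 20,000 steps on the desk corpus.

    Architecture selected by held-out translation accuracy: bidirectional
    LSTM encoder (128 per direction), decoder 192, dropout 0.2 on the top
    decoder states, Adam 2e-3 halved every 5,000 steps.
    """
    tc = training.TrainConfig(steps=20000, batch_size=32, eval_every=200,
                              holdout_frac=0.05, lr=2e-3, lr_decay_every=5000,
                              dropout=0.2)
    ckpt, log = training.train(
        desk_corpus, "sml2can",
        {"encoder_layers": (128,), "decoder_layers": (192,), "latent_dim": 64,
         "bidirectional_encoder": True},
        tc, seed=7)
    return ckpt, log
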
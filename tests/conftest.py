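"""Shared fixtures.

The two trained-model fixtures run the scaled-down simulation studies
(single-motif and paired-motif) once per session; several tests inspect
different aspects of the same trained models.
"""

from __future__ import annotations

import numpy as np
import pytest

from aptvae.simdata import (
    generate_paired_motif_dataset,
    generate_single_motif_dataset,
)
from aptvae.vae import SequenceVAE

# scaled-down study conditions: 2,000 sequences, at most 300 epochs
N_TRAIN = 2000
MAX_EPOCHS = 300
SEED = 7


@pytest.fixture(scope="session")
def single_motif_data():
    data, motifs = generate_single_motif_dataset(n=N_TRAIN, seed=SEED,
                                                 return_motifs=True)
    return {
        "sequences": [d.sequence for d in data],
        "labels": np.array([d.label for d in data]),
        "motifs": motifs,
    }


def _fit(seqs, decoder, **kw):
    est = SequenceVAE(decoder=decoder, max_epochs=MAX_EPOCHS, patience=50,
                      batch_size=64, random_state=0, **kw)
    est.fit(seqs)
    return est


@pytest.fixture(scope="session")
def trained_phmm(single_motif_data):
    return _fit(single_motif_data["sequences"], "profile_hmm")


@pytest.fixture(scope="session")
def trained_multicat(single_motif_data):
    return _fit(single_motif_data["sequences"], "multicategorical")


@pytest.fixture(scope="session")
def trained_autoregressive(single_motif_data):
    return _fit(single_motif_data["sequences"], "autoregressive")


@pytest.fixture(scope="session")
def paired_motif_data():
    data, motifs = generate_paired_motif_dataset(n=N_TRAIN, seed=SEED,
                                                 return_motifs=True)
    return {
        "sequences": [d.sequence for d in data],
        "labels": np.array([d.label for d in data]),
        "motifs": motifs,
    }


@pytest.fixture(scope="session")
def trained_paired_phmm(paired_motif_data):
    # model length = the minimal both-motif core (5 + 2 + 5): one-motif
    # sequences must then be explained by skipping a match block.  The
    # free-bits floor keeps the latent informative enough at this reduced
    # pool size to separate the three populations (see docs/methods.md).
    return _fit(paired_motif_data["sequences"], "profile_hmm",
                model_length=12, free_bits=2.0)
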
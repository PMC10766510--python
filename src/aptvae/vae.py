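"""Scikit-learn style estimator tying the encoder, decoders and trainer.

``SequenceVAE`` is a transformer: ``fit`` trains the VAE on a list of
(unique, equal-length) sequences and ``transform`` maps sequences to the
posterior means in latent space.  The profile-HMM decoder additionally
supports decoding arbitrary latent points into concrete profile HMMs and
reconstituting their most probable sequences, including the truncation
mode where the decoder model length is shorter than the data length.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import phmm as _phmm
from .nets import CNNEncoder, ProfileHMMDecoder, make_decoder, tokenize
from .training import TrainingConfig, train

DECODER_KINDS = ("profile_hmm", "multicategorical", "autoregressive")


class SequenceVAE(BaseEstimator, TransformerMixin):
    """Variational autoencoder over nucleotide sequences.

    Parameters
    ----------
    decoder : one of "profile_hmm", "multicategorical", "autoregressive"
    model_length : int, optional
        Profile-HMM model length m.  Defaults to the training sequence
        length; a smaller value gives the truncated-decoder mode.
    latent_dim : int, default 2
        Dimension of the latent space (2 is the working default; any
        value in 1-12 is supported).
    max_epochs, patience, kl_anneal_epochs, transition_reg_rounds,
    batch_size, learning_rate, test_fraction :
        Training-schedule settings, see :class:`aptvae.training.TrainingConfig`.
    random_state : int, default 0
        Seed for initialization, the train/test split, reparameterization
        noise and batching.
    """

    def __init__(self, decoder: str = "profile_hmm", model_length: int | None = None,
                 latent_dim: int = 2, max_epochs: int = 2000, patience: int = 50,
                 kl_anneal_epochs: int = 50, transition_reg_rounds: int = 50,
                 batch_size: int = 64, learning_rate: float = 1e-3,
                 free_bits: float = 0.0, test_fraction: float = 0.1,
                 random_state: int = 0, verbose: int = 0):
        self.decoder = decoder
        self.model_length = model_length
        self.latent_dim = latent_dim
        self.max_epochs = max_epochs
        self.patience = patience
        self.kl_anneal_epochs = kl_anneal_epochs
        self.transition_reg_rounds = transition_reg_rounds
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.free_bits = free_bits
        self.test_fraction = test_fraction
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            max_epochs=self.max_epochs, patience=self.patience,
            kl_anneal_epochs=self.kl_anneal_epochs,
            transition_reg_rounds=self.transition_reg_rounds,
            test_fraction=self.test_fraction, batch_size=self.batch_size,
            learning_rate=self.learning_rate, free_bits=self.free_bits,
            seed=self.random_state)

    def _build(self, data_length: int) -> None:
        if self.decoder not in DECODER_KINDS:
            raise ValueError(f"decoder must be one of {DECODER_KINDS}")
        if not 1 <= self.latent_dim <= 12:
            raise ValueError("latent_dim must be in 1..12")
        rng = np.random.default_rng(self.random_state)
        self.data_length_ = data_length
        self.encoder_ = CNNEncoder(self.latent_dim, max_len=data_length, rng=rng)
        self.decoder_ = make_decoder(self.decoder, self.latent_dim,
                                     data_length, self.model_length, rng)

    def fit(self, X, y=None):
        """Train on a list of unique sequences of equal length."""
        X = [str(s) for s in X]
        if not X:
            raise ValueError("empty training set")
        self._build(len(X[0]))
        result = train(X, self.encoder_, self.decoder_, self._config(),
                       verbose=self.verbose)
        self.loss_record_ = result.record
        self.best_epoch_ = result.best_epoch
        self.stopped_epoch_ = result.stopped_epoch
        return self

    # ------------------------------------------------------------------
    def encode(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Posterior means and log-variances, each (n, latent_dim)."""
        check_is_fitted(self, "encoder_")
        return self.encoder_.encode([str(s) for s in X])

    def transform(self, X) -> np.ndarray:
        """Posterior means (no sampling); the standard embedding."""
        return self.encode(X)[0]

    def score(self, X, y=None) -> float:
        """Mean ELBO (nats per sequence, higher is better) at the posterior mean."""
        check_is_fitted(self, "encoder_")
        from ._autodiff import tensor
        from .nets import AutoregressiveDecoder, one_hot
        from .training import gaussian_kl

        tokens = tokenize([str(s) for s in X], self.data_length_)
        mu, logvar = self.encoder_(tokens)
        kl = gaussian_kl(mu.data, logvar.data)
        if isinstance(self.decoder_, AutoregressiveDecoder):
            ll = self.decoder_.log_likelihood(tensor(mu.data), tokens).data
        else:
            ll = self.decoder_.log_likelihood(tensor(mu.data), one_hot(tokens)).data
        return float(np.mean(ll - kl))

    # -- profile-HMM specific ------------------------------------------
    def decode_profile_hmm(self, z) -> list[_phmm.ProfileHMM]:
        """Decode latent points into profile HMMs (profile_hmm decoder only)."""
        check_is_fitted(self, "decoder_")
        if not isinstance(self.decoder_, ProfileHMMDecoder):
            raise ValueError("decode_profile_hmm requires the profile_hmm decoder")
        return self.decoder_.materialize(np.atleast_2d(np.asarray(z, float)))

    def reconstitute(self, z, max_candidates: int = 256,
                     seed: int | None = 0) -> list[_phmm.ReconstitutionResult]:
        """Most probable sequences at the given latent points."""
        return [_phmm.reconstitute(model, max_candidates=max_candidates, seed=seed)
                for model in self.decode_profile_hmm(z)]

    # -- persistence ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write parameters (.npz) plus a JSON sidecar describing the model."""
        check_is_fitted(self, "encoder_")
        path = Path(path)
        state = {f"encoder.{k}": v for k, v in self.encoder_.state().items()}
        state.update({f"decoder.{k}": v for k, v in self.decoder_.state().items()})
        np.savez(path.with_suffix(".npz"), **state)
        sidecar = {
            "decoder_kind": self.decoder,
            "model_length": getattr(self.decoder_, "m", None),
            "latent_dim": self.latent_dim,
            "data_length": self.data_length_,
            "alphabet": _phmm.ALPHABET,
            "random_state": self.random_state,
            "params": self.get_params(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SequenceVAE":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        est = cls(**sidecar["params"])
        est._build(sidecar["data_length"])
        with np.load(path.with_suffix(".npz")) as npz:
            enc = {k[len("encoder."):]: npz[k] for k in npz.files
                   if k.startswith("encoder.")}
            dec = {k[len("decoder."):]: npz[k] for k in npz.files
                   if k.startswith("decoder.")}
        est.encoder_.load_state(enc)
        est.decoder_.load_state(dec)
        est.loss_record_ = None
        est.best_epoch_ = None
        return est
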
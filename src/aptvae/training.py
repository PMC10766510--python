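"""ELBO objective, regularization schedules, and the training loop.

The loss minimized per batch is

    loss(e) = recon + kl_scale(e) * KL - reg(e)

where ``recon`` is a single-sample reparameterized estimate of
``-E_q[log p(x|z)]``, ``KL`` is the closed-form divergence of the diagonal
Gaussian posterior from the standard-normal prior, ``kl_scale(e) =
min(e/E, 1)`` is the annealing schedule, and ``reg`` (profile-HMM decoder
only) is the Dirichlet transition bonus

    L_M(p_i) = log( (2+w)(1+w)/2 * a_MM^w ),   w = 4 * (1 - e/R)  for e < R

summed over all match-source states and averaged over the batch.  ``L_M``
is the log-ratio of Dirichlet densities with concentration [1+w, 1, 1]
versus the flat [1, 1, 1]; it is added to the ELBO (hence subtracted from
the loss) and vanishes identically once the epoch counter reaches R.

Early stopping monitors the test negative ELBO (reconstruction + unscaled
KL, without the transition bonus, which is a training-time prior rather
than model evidence) and the best-scoring parameter snapshot is restored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor, tensor
from .nets import (
    AutoregressiveDecoder,
    CNNEncoder,
    Module,
    ProfileHMMDecoder,
    one_hot,
    tokenize,
)
from .phmm import NEG


@dataclass
class TrainingConfig:
    max_epochs: int = 2000
    patience: int = 50
    kl_anneal_epochs: int = 50       # E: epochs over which the KL weight ramps up
    transition_reg_rounds: int = 50  # R: epoch at which the transition bonus hits 0
    test_fraction: float = 0.1
    batch_size: int = 64
    learning_rate: float = 1e-3      # Adam, default parameters otherwise
    free_bits: float = 0.0           # nats per latent dim exempt from the KL
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")
        if self.kl_anneal_epochs < 1 or self.transition_reg_rounds < 1:
            raise ValueError("schedule lengths must be >= 1")


def kl_scale(e: int, E: int) -> float:
    """KL annealing weight: e/E during warm-up, then 1."""
    return min(e / E, 1.0)


def gaussian_kl(mu, logvar):
    """Per-example KL( N(mu, diag exp(logvar)) || N(0, I) ), shape (B,).

    Accepts either autodiff tensors (differentiable) or NumPy arrays.
    """
    if isinstance(mu, Tensor):
        var = logvar.exp()
        return 0.5 * (mu * mu + var - 1.0 - logvar).sum(axis=1)
    mu = np.atleast_2d(np.asarray(mu, dtype=np.float64))
    logvar = np.atleast_2d(np.asarray(logvar, dtype=np.float64))
    return 0.5 * (mu**2 + np.exp(logvar) - 1.0 - logvar).sum(axis=1)


def regularizer_weight(e: int, R: int) -> float:
    """Induction weight w_m = 4(1 - e/R) while e < R, afterwards 0."""
    return 4.0 * (1.0 - e / R) if e < R else 0.0


def transition_regularizer(p, e: int, R: int) -> float:
    """Closed-form Dirichlet log-odds bonus for one match-source
    distribution ``p = [a_MM, a_MI, a_MD]`` at epoch ``e``.

    Zero-probability ``a_MM`` hits the log floor instead of -inf.
    """
    p = np.asarray(p, dtype=np.float64)
    w = regularizer_weight(e, R)
    a = p[..., 0]
    log_a = np.where(a > 0.0, np.log(np.maximum(a, 1e-300)), NEG)
    val = math.log((2.0 + w) * (1.0 + w) / 2.0) + w * log_a
    return float(val) if np.ndim(val) == 0 else val


def _transition_bonus(ltM: Tensor, e: int, R: int) -> Tensor:
    """Batch-mean of L_M summed over match-source states (autodiff)."""
    w = regularizer_weight(e, R)
    log_a = ltM[:, :, 0]  # log a_{M_k, M_{k+1}}, k = 0..m
    n_states = log_a.shape[1]
    const = n_states * math.log((2.0 + w) * (1.0 + w) / 2.0)
    return (w * log_a).sum(axis=1).mean() + const


@dataclass
class LossParts:
    total: float
    recon: float
    kl: float
    reg: float
    scale: float


def elbo_loss(tokens: np.ndarray, onehot: np.ndarray, encoder: CNNEncoder,
              decoder: Module, epoch: int, config: TrainingConfig,
              rng: np.random.Generator) -> tuple[Tensor, LossParts]:
    """Single-sample negative-ELBO estimate for one batch.

    Returns the scalar loss tensor (for backprop) and its recorded parts;
    the recorded total equals recon + scale*KL + reg exactly.
    """
    mu, logvar = encoder(tokens)
    var = logvar.exp()
    kl_dims = (0.5 * (mu * mu + var - 1.0 - logvar)).mean(axis=0)  # (d,)
    if config.free_bits > 0.0:
        # free-bits floor: dimensions below the floor contribute a constant,
        # so the posterior can carry that much information unpenalized
        floored = np.maximum(kl_dims.data, config.free_bits)
        mask = (kl_dims.data > config.free_bits).astype(float)
        kl = (kl_dims * mask).sum() + float(
            (floored * (1.0 - mask)).sum())
    else:
        kl = kl_dims.sum()
    eps = rng.normal(size=mu.shape)
    z = mu + tensor(eps) * (0.5 * logvar).exp()
    if isinstance(decoder, AutoregressiveDecoder):
        recon = -decoder.log_likelihood(z, tokens).mean()
    else:
        recon = -decoder.log_likelihood(z, onehot).mean()
    scale = kl_scale(epoch, config.kl_anneal_epochs)
    loss = recon + scale * kl
    reg_val = 0.0
    if isinstance(decoder, ProfileHMMDecoder):
        _, ltM, _, _ = decoder.log_probs(z)
        bonus = _transition_bonus(ltM, epoch, config.transition_reg_rounds)
        loss = loss - bonus
        reg_val = -bonus.item()
    parts = LossParts(loss.item(), recon.item(), kl.item(), reg_val, scale)
    return loss, parts


@dataclass
class TrainResult:
    encoder: CNNEncoder
    decoder: Module
    record: pd.DataFrame
    best_epoch: int
    stopped_epoch: int
    config: TrainingConfig = field(repr=False, default=None)


def train(sequences: list[str], encoder: CNNEncoder, decoder: Module,
          config: TrainingConfig | None = None, verbose: int = 0) -> TrainResult:
    """Train a VAE on unique sequences with early stopping.

    Sequences are split 9:1 into train/test by a seeded permutation;
    training stops after ``max_epochs`` or once the test negative ELBO has
    not improved for ``patience`` epochs, and the parameters of the best
    test epoch are restored.
    """
    config = config or TrainingConfig()
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences to split train/test")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("all training sequences must have the same length")
    L = lengths.pop()

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(sequences))
    n_test = max(1, int(round(len(sequences) * config.test_fraction)))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    if len(train_idx) == 0:
        raise ValueError("train split is empty")
    seqs = np.array(sequences)
    tokens = tokenize(list(seqs), L)
    oh = one_hot(tokens)
    tr_tok, tr_oh = tokens[train_idx], oh[train_idx]
    te_tok, te_oh = tokens[test_idx], oh[test_idx]

    params = encoder.parameters() + decoder.parameters()
    opt = Adam(params, lr=config.learning_rate)

    rows = []
    best_loss, best_epoch, best_state = np.inf, -1, None
    epoch = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_idx))
        sums = np.zeros(4)  # total, recon, kl, reg weighted by batch size
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            loss, parts = elbo_loss(tr_tok[sel], tr_oh[sel], encoder, decoder,
                                    epoch, config, rng)
            opt.zero_grad()
            loss.backward()
            opt.step()
            sums += len(sel) * np.array(
                [parts.total, parts.recon, parts.kl, parts.reg])
        tr_total, tr_recon, tr_kl, tr_reg = sums / len(train_idx)

        # test negative ELBO (unscaled KL, no transition bonus)
        mu, logvar = encoder(te_tok)
        te_kl = gaussian_kl(mu, logvar).mean().item()
        eps = rng.normal(size=mu.shape)
        z = mu + tensor(eps) * (0.5 * logvar).exp()
        if isinstance(decoder, AutoregressiveDecoder):
            te_recon = (-decoder.log_likelihood(z, te_tok).mean()).item()
        else:
            te_recon = (-decoder.log_likelihood(z, te_oh).mean()).item()
        te_total = te_recon + te_kl

        rows.append({
            "epoch": epoch, "train_loss": tr_total, "train_recon": tr_recon,
            "train_kl": tr_kl, "train_reg": tr_reg,
            "kl_scale": kl_scale(epoch, config.kl_anneal_epochs),
            "test_loss": te_total, "test_recon": te_recon, "test_kl": te_kl,
        })
        if verbose and epoch % max(1, verbose) == 0:
            print(f"epoch {epoch}: train {tr_total:.3f} test {te_total:.3f}")
        if te_total < best_loss:
            best_loss, best_epoch = te_total, epoch
            best_state = (encoder.state(), decoder.state())
        elif epoch - best_epoch >= config.patience:
            break

    encoder.load_state(best_state[0])
    decoder.load_state(best_state[1])
    return TrainResult(encoder, decoder, pd.DataFrame(rows), best_epoch,
                       epoch, config)
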
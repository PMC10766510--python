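"""Encoder and decoder networks mapping between sequences and latent space.

The encoder is a 1-D convolutional network: each letter is embedded into a
32-channel vector, passed through seven convolutional blocks with additive
skip connections, max-pooled over positions (padding excluded), and mapped
by fully connected heads to the mean and log-variance of a diagonal
Gaussian posterior q(z|x).

Three decoder families realize p(x|z):

* ``ProfileHMMDecoder`` — a neural map from z to a full profile HMM
  (match emissions and all transition distributions, normalized by
  construction); the sequence likelihood is the forward algorithm run in
  log space on the autodiff tape, so the whole model trains end to end.
* ``MulticategoricalDecoder`` — an independent categorical distribution
  per sequence position.
* ``AutoregressiveDecoder`` — a GRU emitting one letter at a time
  conditioned on z and the prefix, with an explicit end token.

All parameters live in the package's own autodiff tensors; sizes not fixed
by the architecture description (hidden widths, kernel width 3) are module
defaults, documented in the methods note.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import (
    Adam,  # noqa: F401  (re-exported for the training loop)
    Tensor,
    concatenate,
    log_softmax,
    logsumexp,
    parameter,
    sigmoid,
    stack,
    tensor,
)
from .phmm import ALPHABET, LOG_QUARTER, NEG, ProfileHMM, seq_to_indices

PAD = 4          # padding token for the encoder
N_LETTERS = 4
START = 4        # start token for the autoregressive decoder
END = 4          # end-of-sequence class in autoregressive outputs


class LengthError(ValueError):
    """Sequence longer than the configured encoder maximum."""


def tokenize(seqs: list[str], max_len: int) -> np.ndarray:
    """Integer-encode sequences, right-padded with the PAD token."""
    out = np.full((len(seqs), max_len), PAD, dtype=np.int64)
    for i, s in enumerate(seqs):
        idx = seq_to_indices(s)
        if len(idx) > max_len:
            raise LengthError(f"sequence of length {len(idx)} exceeds max_len={max_len}")
        out[i, : len(idx)] = idx
    return out


def one_hot(tokens: np.ndarray, n: int = N_LETTERS) -> np.ndarray:
    oh = np.zeros(tokens.shape + (n,))
    valid = tokens < n
    oh[(*np.nonzero(valid), tokens[valid])] = 1.0
    return oh


class Module:
    """Lightweight parameter container with recursive discovery."""

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                out[key] = val
            elif isinstance(val, Module):
                out.update(val.named_parameters(f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{key}.{i}"] = item
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        if set(params) != set(state):
            raise ValueError("checkpoint parameter names do not match the model")
        for name, p in params.items():
            p.data = np.asarray(state[name], dtype=np.float64).reshape(p.shape)

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(n_in)
        self.W = parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


def _conv3(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Width-3 same-padding 1-D convolution, channel-last, as one tape op.

    ``x`` (B, L, C), ``W`` (3, C, C_out), ``b`` (C_out,).  Forward is an
    im2col GEMM; backward is the matching pair of GEMMs plus a scatter.
    """
    B, L, C = x.shape
    C_out = W.shape[2]
    xp = np.pad(x.data, ((0, 0), (1, 1), (0, 0)))
    col = np.lib.stride_tricks.sliding_window_view(xp, 3, axis=1)  # (B,L,C,3)
    col2 = np.ascontiguousarray(col.transpose(0, 1, 3, 2)).reshape(B * L, 3 * C)
    Wflat = W.data.reshape(3 * C, C_out)
    out = Tensor((col2 @ Wflat).reshape(B, L, C_out) + b.data, _prev=(x, W, b))

    def bw(g):
        gflat = g.reshape(B * L, C_out)
        if W.requires_grad:
            W._accumulate((col2.T @ gflat).reshape(3, C, C_out))
        if b.requires_grad:
            b._accumulate(gflat.sum(axis=0))
        if x.requires_grad:
            gcol = (gflat @ Wflat.T).reshape(B, L, 3, C)
            gx = np.zeros_like(xp)
            for k in range(3):
                gx[:, k : k + L] += gcol[:, :, k]
            x._accumulate(gx[:, 1 : L + 1])

    out._backward = bw
    return out


class ConvBlock(Module):
    """Width-3, same-padding 1-D convolution with residual addition."""

    def __init__(self, channels: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(3 * channels)
        self.W = parameter(rng.normal(0.0, scale, size=(3, channels, channels)))
        self.b = parameter(np.zeros(channels))

    def __call__(self, x: Tensor) -> Tensor:
        return x + _conv3(x, self.W, self.b).relu()


class CNNEncoder(Module):
    """Convolutional encoder producing the posterior mean and log-variance."""

    def __init__(self, latent_dim: int = 2, max_len: int = 20,
                 channels: int = 32, n_blocks: int = 7, hidden: int = 64,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.latent_dim = latent_dim
        self.max_len = max_len
        self.embed = parameter(rng.normal(0.0, 1.0, size=(N_LETTERS + 1, channels)))
        self.blocks = [ConvBlock(channels, rng) for _ in range(n_blocks)]
        self.fc = Linear(channels, hidden, rng)
        self.mu_head = Linear(hidden, latent_dim, rng)
        self.logvar_head = Linear(hidden, latent_dim, rng)
        # start near-deterministic: posteriors carry information from the
        # first epochs instead of collapsing onto the prior
        self.logvar_head.b.data[:] = -4.0

    def __call__(self, tokens: np.ndarray) -> tuple[Tensor, Tensor]:
        if tokens.shape[1] != self.max_len:
            raise LengthError(
                f"token matrix width {tokens.shape[1]} != max_len {self.max_len}")
        x = self.embed[tokens]              # (B, L, C)
        for block in self.blocks:
            x = block(x)
        mask = (tokens != PAD)[:, :, None]  # exclude padding from the pool
        x = x * tensor(mask) + tensor(np.where(mask, 0.0, -1e9))
        pooled = x.max(axis=1)              # (B, C)
        h = self.fc(pooled).relu()
        return self.mu_head(h), self.logvar_head(h)

    def encode(self, seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
        mu, logvar = self(tokenize(seqs, self.max_len))
        return mu.data.copy(), logvar.data.copy()


# ---------------------------------------------------------------------------
# decoders
# ---------------------------------------------------------------------------

class ProfileHMMDecoder(Module):
    """Neural map from z to a profile HMM of model length ``m``.

    Every output distribution is a softmax over per-edge scores, so the
    profile-HMM invariants (rows sum to one, disallowed edges have zero
    probability) hold for any z by construction.
    """

    kind = "profile_hmm"

    def __init__(self, latent_dim: int = 2, m: int = 20, hidden: int = 64,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.m = m
        self.latent_dim = latent_dim
        self.fc = Linear(latent_dim, hidden, rng)
        self.emis = Linear(hidden, m * 4, rng)
        self.t_match = Linear(hidden, (m + 1) * 3, rng)
        self.t_insert = Linear(hidden, (m + 1) * 2, rng)
        self.t_delete = Linear(hidden, m * 2, rng)
        # M_m -> D_{m+1} and D_m -> D_{m+1} do not exist
        mask_m = np.zeros((m + 1, 3))
        mask_m[m, 2] = -1e9
        self._mask_match = mask_m
        mask_d = np.zeros((m, 2))
        mask_d[m - 1, 1] = -1e9
        self._mask_delete = mask_d

    def log_probs(self, z: Tensor) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        B = z.shape[0]
        m = self.m
        h = self.fc(z).relu()
        le = log_softmax(self.emis(h).reshape(B, m, 4), axis=2)
        ltM = log_softmax(
            self.t_match(h).reshape(B, m + 1, 3) + tensor(self._mask_match), axis=2)
        ltI = log_softmax(self.t_insert(h).reshape(B, m + 1, 2), axis=2)
        ltD = log_softmax(
            self.t_delete(h).reshape(B, m, 2) + tensor(self._mask_delete), axis=2)
        return le, ltM, ltI, ltD

    def log_likelihood(self, z: Tensor, onehot: np.ndarray) -> Tensor:
        """Batched differentiable forward algorithm; returns (B,) log p(x|z).

        Uses the fused forward-backward op (analytic expected-count
        gradient); the cell-by-cell tape version below is retained as the
        cross-check oracle.
        """
        from ._forward_backward import phmm_log_likelihood

        le, ltM, ltI, ltD = self.log_probs(z)
        return phmm_log_likelihood(le, ltM, ltI, ltD, onehot)

    def materialize(self, z: np.ndarray) -> list[ProfileHMM]:
        """Decode latent points into concrete :class:`ProfileHMM` objects."""
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        le, ltM, ltI, ltD = self.log_probs(tensor(z))
        out = []
        for i in range(z.shape[0]):
            out.append(ProfileHMM(
                match_emissions=np.exp(le.data[i]),
                from_match=np.exp(ltM.data[i]),
                from_insert=np.exp(ltI.data[i]),
                from_delete=np.exp(ltD.data[i]),
            ))
        return out


def _phmm_forward(le: Tensor, ltM: Tensor, ltI: Tensor, ltD: Tensor,
                  onehot: np.ndarray) -> Tensor:
    """Forward recurrences on the autodiff tape, batched over sequences.

    Mirrors :func:`aptvae.phmm.forward_lattice`; the two are cross-checked
    in the test suite.
    """
    B, m, _ = le.shape
    L = onehot.shape[1]
    ltMM, ltMI, ltMD = ltM[:, :, 0], ltM[:, :, 1], ltM[:, :, 2]
    ltIM, ltII = ltI[:, :, 0], ltI[:, :, 1]
    ltDM, ltDD = ltD[:, :, 0], ltD[:, :, 1]
    neg1 = tensor(np.full((B, 1), NEG))

    fM = tensor(np.concatenate(
        [np.zeros((B, 1)), np.full((B, m), NEG)], axis=1))   # k = 0..m at l=0
    fI = tensor(np.full((B, m + 1), NEG))

    def delete_scan(fM_now: Tensor) -> Tensor:
        cols, prev = [], None
        for k in range(1, m + 1):
            t1 = ltMD[:, k - 1 : k] + fM_now[:, k - 1 : k]
            t2 = ltDD[:, k - 2 : k - 1] + prev if k >= 2 else neg1
            prev = logsumexp(stack([t1, t2], axis=0), axis=0)
            cols.append(prev)
        return concatenate(cols, axis=1)                      # (B, m), k = 1..m

    fD = delete_scan(fM)
    for l in range(1, L + 1):
        ex = (le * tensor(onehot[:, l - 1, :][:, None, :])).sum(axis=2)  # (B, m)
        into_m = stack([
            ltMM[:, :m] + fM[:, :m],
            ltIM[:, :m] + fI[:, :m],
            concatenate([neg1, ltDM[:, : m - 1] + fD[:, : m - 1]], axis=1),
        ], axis=0)
        newM = concatenate([neg1, ex + logsumexp(into_m, axis=0)], axis=1)
        newI = logsumexp(
            stack([ltMI + fM, ltII + fI], axis=0), axis=0) + LOG_QUARTER
        fM, fI = newM, newI
        fD = delete_scan(fM)

    final = stack([
        ltMM[:, m : m + 1] + fM[:, m : m + 1],
        ltIM[:, m : m + 1] + fI[:, m : m + 1],
        ltDM[:, m - 1 : m] + fD[:, m - 1 : m],
    ], axis=0)
    return logsumexp(final, axis=0).reshape(B)


class MulticategoricalDecoder(Module):
    """Independent categorical distribution per sequence position."""

    kind = "multicategorical"

    def __init__(self, latent_dim: int = 2, length: int = 20, hidden: int = 64,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.length = length
        self.latent_dim = latent_dim
        self.fc = Linear(latent_dim, hidden, rng)
        self.out = Linear(hidden, length * 4, rng)

    def position_log_probs(self, z: Tensor) -> Tensor:
        B = z.shape[0]
        h = self.fc(z).relu()
        return log_softmax(self.out(h).reshape(B, self.length, 4), axis=2)

    def position_probs(self, z: np.ndarray) -> np.ndarray:
        """L x 4 probability matrices for each latent point."""
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        return np.exp(self.position_log_probs(tensor(z)).data)

    def log_likelihood(self, z: Tensor, onehot: np.ndarray) -> Tensor:
        if onehot.shape[1] != self.length:
            raise LengthError("sequence length does not match decoder length")
        lp = self.position_log_probs(z)
        return (lp * tensor(onehot)).sum(axis=2).sum(axis=1)


class AutoregressiveDecoder(Module):
    """GRU decoder emitting letters (plus an end token) conditioned on z."""

    kind = "autoregressive"

    def __init__(self, latent_dim: int = 2, hidden: int = 32, embed_dim: int = 8,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.latent_dim = latent_dim
        self.hidden = hidden
        self.embed = parameter(rng.normal(0.0, 1.0, size=(N_LETTERS + 1, embed_dim)))
        n_in = embed_dim + latent_dim
        self.W_r = Linear(n_in + hidden, hidden, rng)
        self.W_u = Linear(n_in + hidden, hidden, rng)
        self.W_c = Linear(n_in + hidden, hidden, rng)
        self.h0 = Linear(latent_dim, hidden, rng)
        self.out = Linear(hidden, 5, rng)  # A, C, G, U, end

    def _step(self, tok: np.ndarray, z: Tensor, h: Tensor) -> tuple[Tensor, Tensor]:
        x = concatenate([self.embed[tok], z], axis=1)
        xh = concatenate([x, h], axis=1)
        r = sigmoid(self.W_r(xh))
        u = sigmoid(self.W_u(xh))
        c = self.W_c(concatenate([x, r * h], axis=1)).tanh()
        h_new = (1.0 - u) * h + u * c
        return log_softmax(self.out(h_new), axis=1), h_new

    def log_likelihood(self, z: Tensor, tokens: np.ndarray) -> Tensor:
        """Chain-rule log p(x|z) including the end token; tokens (B, L)."""
        B, L = tokens.shape
        h = self.h0(z).tanh()
        prev = np.full(B, START, dtype=np.int64)
        rows = np.arange(B)
        total = None
        for t in range(L + 1):
            lp, h = self._step(prev, z, h)
            target = tokens[:, t] if t < L else np.full(B, END, dtype=np.int64)
            step_lp = lp[rows, target]
            total = step_lp if total is None else total + step_lp
            prev = target
        return total

    def next_letter_distribution(self, z: np.ndarray, prefix: str) -> np.ndarray:
        """Distribution over {A, C, G, U, end} after the given prefix."""
        z_t = tensor(np.atleast_2d(np.asarray(z, dtype=np.float64)))
        h = self.h0(z_t).tanh()
        prev = np.array([START])
        lp = None
        for c in seq_to_indices(prefix):
            lp, h = self._step(prev, z_t, h)
            prev = np.array([c])
        lp, h = self._step(prev, z_t, h)
        return np.exp(lp.data[0])


def make_decoder(kind: str, latent_dim: int, data_length: int,
                 model_length: int | None, rng: np.random.Generator) -> Module:
    if kind == "profile_hmm":
        return ProfileHMMDecoder(latent_dim, model_length or data_length, rng=rng)
    if kind == "multicategorical":
        return MulticategoricalDecoder(latent_dim, data_length, rng=rng)
    if kind == "autoregressive":
        return AutoregressiveDecoder(latent_dim, rng=rng)
    raise ValueError(f"unknown decoder kind {kind!r}")
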
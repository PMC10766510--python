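"""Fused forward-backward pass for the profile-HMM likelihood.

The training loop needs ``log p(x|z)`` and its gradient with respect to
the decoder's log-emission and log-transition parameters for every
sequence in a batch.  Running the forward recurrence cell-by-cell on the
autodiff tape works but is slow; this module instead computes the forward
and backward lattices in vectorized NumPy and exposes a single tape op
whose analytic gradient is the matrix of posterior expected counts: for a
log-parameterized HMM,

    d log p(x) / d log a_e  = E[ number of uses of edge e | x ]
    d log p(x) / d log e_k(c) = E[ number of times M_k emits c | x ]

(the Baum-Welch E-step quantities).  The slow tape implementation is kept
in :mod:`aptvae.nets` and the two are cross-checked in the tests, along
with finite-difference gradient checks of this op.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor
from .phmm import LOG_QUARTER, NEG


def _lse3(a, b, c):
    return np.logaddexp(np.logaddexp(a, b), c)


def _lattices(ltMM, ltMI, ltMD, ltIM, ltII, ltDM, ltDD, EX):
    """Forward lattices FM/FI (L+1, B, m+1) and FD (L+1, B, m), plus logp."""
    Lp1, B, m = EX.shape
    L = Lp1 - 1
    FM = np.full((L + 1, B, m + 1), NEG)
    FI = np.full((L + 1, B, m + 1), NEG)
    FD = np.full((L + 1, B, m), NEG)
    FM[0, :, 0] = 0.0

    def delete_scan(l):
        FD[l, :, 0] = ltMD[:, 0] + FM[l, :, 0]
        for k in range(2, m + 1):
            FD[l, :, k - 1] = np.logaddexp(
                ltMD[:, k - 1] + FM[l, :, k - 1],
                ltDD[:, k - 2] + FD[l, :, k - 2])

    delete_scan(0)
    neg_col = np.full((B, 1), NEG)
    for l in range(1, L + 1):
        into_d = np.concatenate(
            [neg_col, ltDM[:, : m - 1] + FD[l - 1, :, : m - 1]], axis=1)
        FM[l, :, 1:] = EX[l] + _lse3(
            ltMM[:, :m] + FM[l - 1, :, :m],
            ltIM[:, :m] + FI[l - 1, :, :m],
            into_d)
        FI[l] = LOG_QUARTER + np.logaddexp(
            ltMI + FM[l - 1], ltII + FI[l - 1])
        delete_scan(l)

    logp = _lse3(ltMM[:, m] + FM[L, :, m],
                 ltIM[:, m] + FI[L, :, m],
                 ltDM[:, m - 1] + FD[L, :, m - 1])
    return FM, FI, FD, logp


def _backward_lattices(ltMM, ltMI, ltMD, ltIM, ltII, ltDM, ltDD, EX):
    """Backward lattices BM/BI (L+1, B, m+1) and BD (L+1, B, m)."""
    Lp1, B, m = EX.shape
    L = Lp1 - 1
    BM = np.full((L + 1, B, m + 1), NEG)
    BI = np.full((L + 1, B, m + 1), NEG)
    BD = np.full((L + 1, B, m), NEG)
    neg_col = np.full((B, 1), NEG)

    for l in range(L, -1, -1):
        at_end = l == L
        # delete states, descending k (BD[l, k] needs BD[l, k+1])
        BD[l, :, m - 1] = ltDM[:, m - 1] if at_end else NEG
        for k in range(m - 1, 0, -1):
            to_m = (ltDM[:, k - 1] + EX[l + 1][:, k] + BM[l + 1, :, k + 1]
                    if not at_end else np.full(B, NEG))
            BD[l, :, k - 1] = np.logaddexp(to_m, ltDD[:, k - 1] + BD[l, :, k])
        # match states
        to_m = np.full((B, m + 1), NEG)
        if not at_end:
            to_m[:, :m] = ltMM[:, :m] + EX[l + 1] + BM[l + 1, :, 1:]
        to_m[:, m] = ltMM[:, m] if at_end else NEG
        to_d = np.concatenate([ltMD[:, :m] + BD[l], neg_col], axis=1)
        to_i = (ltMI + LOG_QUARTER + BI[l + 1]) if not at_end \
            else np.full((B, m + 1), NEG)
        BM[l] = _lse3(to_m, to_i, to_d)
        # insert states
        to_m_i = np.full((B, m + 1), NEG)
        if not at_end:
            to_m_i[:, :m] = ltIM[:, :m] + EX[l + 1] + BM[l + 1, :, 1:]
        to_m_i[:, m] = ltIM[:, m] if at_end else NEG
        to_i_i = (ltII + LOG_QUARTER + BI[l + 1]) if not at_end \
            else np.full((B, m + 1), NEG)
        BI[l] = np.logaddexp(to_m_i, to_i_i)
    return BM, BI, BD


def phmm_log_likelihood(le: Tensor, ltM: Tensor, ltI: Tensor, ltD: Tensor,
                        onehot: np.ndarray) -> Tensor:
    """Batched log p(x|z) as a single autodiff op.

    ``le`` (B, m, 4), ``ltM`` (B, m+1, 3), ``ltI`` (B, m+1, 2) and ``ltD``
    (B, m, 2) hold log-probabilities; ``onehot`` (B, L, 4) the sequences.
    """
    B, m, _ = le.shape
    L = onehot.shape[1]
    ltMM, ltMI, ltMD = ltM.data[:, :, 0], ltM.data[:, :, 1], ltM.data[:, :, 2]
    ltIM, ltII = ltI.data[:, :, 0], ltI.data[:, :, 1]
    ltDM, ltDD = ltD.data[:, :, 0], ltD.data[:, :, 1]
    # EX[l] (B, m): log e_{M_k}(x_l); row 0 unused
    EX = np.full((L + 1, B, m), NEG)
    EX[1:] = np.einsum("bmc,lbc->lbm", le.data, np.moveaxis(onehot, 0, 1))
    FM, FI, FD, logp = _lattices(ltMM, ltMI, ltMD, ltIM, ltII, ltDM, ltDD, EX)
    out = Tensor(logp, _prev=(le, ltM, ltI, ltD))

    def bw(g):
        BM, BI, BD = _backward_lattices(
            ltMM, ltMI, ltMD, ltIM, ltII, ltDM, ltDD, EX)
        P = logp[None, :, None]
        with np.errstate(under="ignore"):
            # emission counts: gamma over match states, split by letter
            gamma = np.exp(FM[1:, :, 1:] + BM[1:, :, 1:] - P)     # (L, B, m)
            g_le = np.einsum("lbm,lbc->bmc", gamma, np.moveaxis(onehot, 0, 1))
            # transition counts
            cMM = np.zeros((B, m + 1))
            cMI = np.zeros((B, m + 1))
            cMD = np.zeros((B, m + 1))
            cIM = np.zeros((B, m + 1))
            cII = np.zeros((B, m + 1))
            cDM = np.zeros((B, m))
            cDD = np.zeros((B, m))
            emit_next = EX[1:] + BM[1:, :, 1:]                     # (L, B, m)
            cMM[:, :m] = np.exp(
                FM[:L, :, :m] + ltMM[None, :, :m] + emit_next - P).sum(axis=0)
            cMM[:, m] = np.exp(FM[L, :, m] + ltMM[:, m] - logp)
            cMI[:] = np.exp(FM[:L] + ltMI[None] + LOG_QUARTER
                            + BI[1:] - P).sum(axis=0)
            cMD[:, :m] = np.exp(
                FM[:, :, :m] + ltMD[None, :, :m] + BD - logp[None, :, None]
            ).sum(axis=0)
            cIM[:, :m] = np.exp(
                FI[:L, :, :m] + ltIM[None, :, :m] + emit_next - P).sum(axis=0)
            cIM[:, m] = np.exp(FI[L, :, m] + ltIM[:, m] - logp)
            cII[:] = np.exp(FI[:L] + ltII[None] + LOG_QUARTER
                            + BI[1:] - P).sum(axis=0)
            cDM[:, : m - 1] = np.exp(
                FD[:L, :, : m - 1] + ltDM[None, :, : m - 1]
                + emit_next[:, :, 1:] - P).sum(axis=0)
            cDM[:, m - 1] = np.exp(FD[L, :, m - 1] + ltDM[:, m - 1] - logp)
            cDD[:, : m - 1] = np.exp(
                FD[:, :, : m - 1] + ltDD[None, :, : m - 1] + BD[:, :, 1:]
                - logp[None, :, None]).sum(axis=0)
        gg = g[:, None]
        if le.requires_grad:
            le._accumulate(g[:, None, None] * g_le)
        if ltM.requires_grad:
            ltM._accumulate(np.stack(
                [gg * cMM, gg * cMI, gg * cMD], axis=2))
        if ltI.requires_grad:
            ltI._accumulate(np.stack([gg * cIM, gg * cII], axis=2))
        if ltD.requires_grad:
            ltD._accumulate(np.stack([gg * cDM, gg * cDD], axis=2))

    out._backward = bw
    return out
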
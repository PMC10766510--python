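"""Independent brute-force oracles for the profile-HMM dynamic programs.

These enumerate state paths explicitly and are deliberately written
against the model's probability matrices, not the package's lattices.
"""

from __future__ import annotations

import math

import numpy as np

from aptvae.phmm import ProfileHMM, seq_to_indices


def enumerate_logp(model: ProfileHMM, seq: str) -> float:
    """Exact log p(x) by recursive enumeration of every state path.

    Any path emitting exactly len(seq) letters is finite (insert
    self-loops emit), so this enumeration is exact, not truncated.
    """
    x = seq_to_indices(seq)
    L, m = len(x), model.m
    e = model.match_emissions
    tM, tI, tD = model.from_match, model.from_insert, model.from_delete
    total = 0.0

    def rec(state: str, k: int, pos: int, p: float) -> None:
        nonlocal total
        if p == 0.0:
            return
        if state == "M":
            if k + 1 == m + 1:
                if pos == L:
                    total += p * tM[k, 0]
            elif pos < L:
                rec("M", k + 1, pos + 1, p * tM[k, 0] * e[k, x[pos]])
            if pos < L:
                rec("I", k, pos + 1, p * tM[k, 1] * 0.25)
            if k + 1 <= m:
                rec("D", k + 1, pos, p * tM[k, 2])
        elif state == "I":
            if k + 1 == m + 1:
                if pos == L:
                    total += p * tI[k, 0]
            elif pos < L:
                rec("M", k + 1, pos + 1, p * tI[k, 0] * e[k, x[pos]])
            if pos < L:
                rec("I", k, pos + 1, p * tI[k, 1] * 0.25)
        else:  # delete
            if k + 1 == m + 1:
                if pos == L:
                    total += p * tD[k - 1, 0]
            elif pos < L:
                rec("M", k + 1, pos + 1, p * tD[k - 1, 0] * e[k, x[pos]])
            if k + 1 <= m:
                rec("D", k + 1, pos, p * tD[k - 1, 1])

    rec("M", 0, 0, 1.0)
    return math.log(total) if total > 0 else -math.inf


def best_path_logscore(model: ProfileHMM, max_insertions: int = 4) -> float:
    """Max over loop-free-plus-bounded-insertion paths of
    log(transitions * per-state best emissions)."""
    m = model.m
    e_best = model.match_emissions.max(axis=1)
    tM, tI, tD = model.from_match, model.from_insert, model.from_delete
    best = -math.inf

    def rec(state: str, k: int, ins: int, score: float) -> None:
        nonlocal best
        if state == "M":
            if k == m + 1:
                best = max(best, score)
                return
            rec("M", k + 1, ins,
                score + _log(tM[k, 0]) + (_log(e_best[k]) if k < m else 0.0))
            if ins < max_insertions:
                rec("I", k, ins + 1, score + _log(tM[k, 1]) + math.log(0.25))
            if k + 1 <= m:
                rec("D", k + 1, ins, score + _log(tM[k, 2]))
        elif state == "I":
            rec("M", k + 1, ins,
                score + _log(tI[k, 0]) + (_log(e_best[k]) if k < m else 0.0))
            if ins < max_insertions:
                rec("I", k, ins + 1, score + _log(tI[k, 1]) + math.log(0.25))
        else:
            rec("M", k + 1, ins,
                score + _log(tD[k - 1, 0]) + (_log(e_best[k]) if k < m else 0.0))
            if k + 1 <= m:
                rec("D", k + 1, ins, score + _log(tD[k - 1, 1]))

    def _log(p: float) -> float:
        return math.log(p) if p > 0 else -math.inf

    # note: rec("M", k+1, ...) with k == m transitions into the end state;
    # the emission guard (k < m) keeps the end state emission at log 1 = 0
    rec("M", 0, 0, 0.0)
    return best


def all_sequences(max_len: int):
    """Every A/C/G/U string of length 0..max_len, grouped by length."""
    from itertools import product

    for L in range(max_len + 1):
        yield L, ["".join(t) for t in product("ACGU", repeat=L)]
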
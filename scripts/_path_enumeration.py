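"""Brute-force path-enumeration oracle used by the acceptance script.

Independent of the package's forward lattice: sums path-times-emission
products by explicit recursion over the state topology.
"""

from __future__ import annotations

import math

from aptvae.phmm import ProfileHMM, seq_to_indices


def enumerate_logp(model: ProfileHMM, seq: str) -> float:
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
        else:
            if k + 1 == m + 1:
                if pos == L:
                    total += p * tD[k - 1, 0]
            elif pos < L:
                rec("M", k + 1, pos + 1, p * tD[k - 1, 0] * e[k, x[pos]])
            if k + 1 <= m:
                rec("D", k + 1, pos, p * tD[k - 1, 1])

    rec("M", 0, 0, 1.0)
    return math.log(total) if total > 0 else -math.inf
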
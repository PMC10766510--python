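"""Profile hidden Markov model as a standalone probabilistic object.

A profile HMM of model length ``m`` has match states ``M_1..M_m`` flanked by
a silent begin state ``M_0`` and end state ``M_{m+1}``, insert states
``I_0..I_m`` and delete states ``D_1..D_m``.  Match state ``M_k`` emits a
letter from its own categorical distribution; insert states emit uniformly
(probability 1/4 per letter); delete states are silent.  The allowed
transitions are

    M_k -> M_{k+1} | I_k | D_{k+1}
    I_k -> M_{k+1} | I_k
    D_k -> M_{k+1} | D_{k+1}

(no I->D or D->I edges), with the end-of-sequence emission at ``M_{m+1}``
fixed to probability 1.  The marginal probability of a sequence is the sum
over all state paths of the path-times-emission product, computed in
O(L*m) by the forward algorithm in log space.

This module is NumPy-only and is the reference semantics; the trainable,
batched version used inside the VAE decoder lives in :mod:`aptvae.nets`
and is cross-checked against this one in the tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGU"
LOG_QUARTER = math.log(0.25)
#: log-probability floor standing in for log(0); keeps arithmetic finite
NEG = -1e10
_ATOL = 1e-6


class AlphabetError(ValueError):
    """A sequence letter outside {A, C, G, U} (T is accepted as U)."""


def seq_to_indices(seq: str) -> np.ndarray:
    """Map a sequence string to integer indices in A/C/G/U order.

    DNA input is accepted: T (or t) is read as U.  Any other letter raises
    :class:`AlphabetError`.
    """
    out = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq.upper()):
        if c == "T":
            c = "U"
        j = ALPHABET.find(c)
        if j < 0:
            raise AlphabetError(f"invalid letter {c!r} at position {i}")
        out[i] = j
    return out


def _safe_log(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    with np.errstate(divide="ignore"):
        out = np.log(p)
    return np.where(p > 0.0, out, NEG)


@dataclass
class ProfileHMM:
    """Parameters of a profile HMM of model length ``m``.

    Attributes
    ----------
    match_emissions : (m, 4) array
        Row ``k`` is the emission distribution of match state ``M_{k+1}``
        over A/C/G/U.
    from_match : (m+1, 3) array
        Row ``k`` (k = 0..m) is the outgoing distribution of ``M_k`` over
        successors ``[M_{k+1}, I_k, D_{k+1}]``.  The last row's delete
        entry must be 0 (``D_{m+1}`` does not exist).
    from_insert : (m+1, 2) array
        Row ``k`` is the outgoing distribution of ``I_k`` over
        ``[M_{k+1}, I_k]``.
    from_delete : (m, 2) array
        Row ``k-1`` (k = 1..m) is the outgoing distribution of ``D_k`` over
        ``[M_{k+1}, D_{k+1}]``.  The last row's delete entry must be 0.
    """

    match_emissions: np.ndarray
    from_match: np.ndarray
    from_insert: np.ndarray
    from_delete: np.ndarray

    def __post_init__(self):
        self.match_emissions = np.asarray(self.match_emissions, dtype=np.float64)
        self.from_match = np.asarray(self.from_match, dtype=np.float64)
        self.from_insert = np.asarray(self.from_insert, dtype=np.float64)
        self.from_delete = np.asarray(self.from_delete, dtype=np.float64)
        self.validate()

    @property
    def m(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self) -> None:
        m = self.match_emissions.shape[0]
        if m < 1:
            raise ValueError("model length must be >= 1")
        shapes = {
            "match_emissions": (self.match_emissions, (m, 4)),
            "from_match": (self.from_match, (m + 1, 3)),
            "from_insert": (self.from_insert, (m + 1, 2)),
            "from_delete": (self.from_delete, (m, 2)),
        }
        for name, (arr, shape) in shapes.items():
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            if np.any(arr < -_ATOL):
                raise ValueError(f"{name} has negative entries")
            if not np.allclose(arr.sum(axis=-1), 1.0, atol=_ATOL):
                raise ValueError(f"{name} rows must sum to 1")
        if self.from_match[m, 2] > _ATOL:
            raise ValueError("M_m -> D_{m+1} must have probability 0")
        if self.from_delete[m - 1, 1] > _ATOL:
            raise ValueError("D_m -> D_{m+1} must have probability 0")

    # log-space views ----------------------------------------------------
    def _logs(self):
        le = _safe_log(self.match_emissions)
        ltM = _safe_log(self.from_match)
        ltI = _safe_log(self.from_insert)
        ltD = _safe_log(self.from_delete)
        return le, ltM, ltI, ltD

    # serialization ------------------------------------------------------
    def to_json(self) -> str:
        m = self.m
        trans: dict[str, float] = {}
        for k in range(m + 1):
            trans[f"M{k}->M{k + 1}"] = float(self.from_match[k, 0])
            trans[f"M{k}->I{k}"] = float(self.from_match[k, 1])
            if k < m:
                trans[f"M{k}->D{k + 1}"] = float(self.from_match[k, 2])
            trans[f"I{k}->M{k + 1}"] = float(self.from_insert[k, 0])
            trans[f"I{k}->I{k}"] = float(self.from_insert[k, 1])
        for k in range(1, m + 1):
            trans[f"D{k}->M{k + 1}"] = float(self.from_delete[k - 1, 0])
            if k < m:
                trans[f"D{k}->D{k + 1}"] = float(self.from_delete[k - 1, 1])
        return json.dumps(
            {
                "model_length": m,
                "alphabet": ALPHABET,
                "match_emissions": self.match_emissions.tolist(),
                "transitions": trans,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ProfileHMM":
        obj = json.loads(text)
        m = int(obj["model_length"])
        trans = obj["transitions"]
        from_match = np.zeros((m + 1, 3))
        from_insert = np.zeros((m + 1, 2))
        from_delete = np.zeros((m, 2))
        for k in range(m + 1):
            from_match[k, 0] = trans[f"M{k}->M{k + 1}"]
            from_match[k, 1] = trans[f"M{k}->I{k}"]
            from_match[k, 2] = trans.get(f"M{k}->D{k + 1}", 0.0)
            from_insert[k, 0] = trans[f"I{k}->M{k + 1}"]
            from_insert[k, 1] = trans[f"I{k}->I{k}"]
        for k in range(1, m + 1):
            from_delete[k - 1, 0] = trans[f"D{k}->M{k + 1}"]
            from_delete[k - 1, 1] = trans.get(f"D{k}->D{k + 1}", 0.0)
        return cls(np.asarray(obj["match_emissions"]), from_match,
                   from_insert, from_delete)

    def logo_table(self):
        """Position-probability table of the match emissions.

        Returns a :class:`pandas.DataFrame` with one row per match position
        (1-based) and columns A/C/G/U, writable as TSV for logo tools.
        """
        import pandas as pd

        return pd.DataFrame(
            self.match_emissions,
            index=pd.RangeIndex(1, self.m + 1, name="position"),
            columns=list(ALPHABET),
        )


def random_profile_hmm(m: int, rng: np.random.Generator,
                       concentration: float = 1.0) -> ProfileHMM:
    """Draw a valid random model (Dirichlet rows); used for tests and demos."""

    def dirichlet(shape):
        g = rng.gamma(concentration, size=shape)
        return g / g.sum(axis=-1, keepdims=True)

    from_match = dirichlet((m + 1, 3))
    from_match[m, 2] = 0.0
    from_match[m] /= from_match[m].sum()
    from_delete = dirichlet((m, 2))
    from_delete[m - 1] = [1.0, 0.0]
    return ProfileHMM(
        match_emissions=dirichlet((m, 4)),
        from_match=from_match,
        from_insert=dirichlet((m + 1, 2)),
        from_delete=from_delete,
    )


# ---------------------------------------------------------------------------
# forward algorithm
# ---------------------------------------------------------------------------

@dataclass
class ForwardLattice:
    """Log-probability lattices f^M, f^I, f^D, each (m+2) x (L+2).

    ``f[k, l]`` is the log-probability of emitting the first ``l`` letters
    and being in state ``k`` of the given kind; cells unreachable under the
    topology hold the ``NEG`` floor.
    """

    match: np.ndarray
    insert: np.ndarray
    delete: np.ndarray

    @property
    def log_probability(self) -> float:
        return float(self.match[-1, -1])


def forward_lattice(model: ProfileHMM, seq: str) -> ForwardLattice:
    """Fill the forward lattice for ``seq`` under ``model``."""
    model.validate()
    x = seq_to_indices(seq)
    L = len(x)
    m = model.m
    le, ltM, ltI, ltD = model._logs()

    fM = np.full((m + 2, L + 2), NEG)
    fI = np.full((m + 2, L + 2), NEG)
    fD = np.full((m + 2, L + 2), NEG)
    fM[0, 0] = 0.0

    def lse(*vals):
        arr = np.array(vals)
        hi = arr.max()
        if hi <= NEG:
            return NEG
        return hi + math.log(np.exp(arr - hi).sum())

    for k in range(1, m + 1):  # silent delete chain reachable at l = 0
        prev = ltD[k - 2, 1] + fD[k - 1, 0] if k >= 2 else NEG
        fD[k, 0] = lse(ltM[k - 1, 2] + fM[k - 1, 0], prev)

    for l in range(1, L + 1):
        c = x[l - 1]
        for k in range(1, m + 1):
            d_in = ltD[k - 2, 0] + fD[k - 1, l - 1] if k >= 2 else NEG
            fM[k, l] = le[k - 1, c] + lse(
                ltM[k - 1, 0] + fM[k - 1, l - 1],
                ltI[k - 1, 0] + fI[k - 1, l - 1],
                d_in,
            )
        for k in range(0, m + 1):
            fI[k, l] = LOG_QUARTER + lse(
                ltM[k, 1] + fM[k, l - 1], ltI[k, 1] + fI[k, l - 1]
            )
        for k in range(1, m + 1):
            prev = ltD[k - 2, 1] + fD[k - 1, l] if k >= 2 else NEG
            fD[k, l] = lse(ltM[k - 1, 2] + fM[k - 1, l], prev)

    # end state: emits the end-of-sequence token with probability 1
    fM[m + 1, L + 1] = lse(
        ltM[m, 0] + fM[m, L],
        ltI[m, 0] + fI[m, L],
        ltD[m - 1, 0] + fD[m, L],
    )
    return ForwardLattice(fM, fI, fD)


def log_forward(model: ProfileHMM, seq: str) -> float:
    """Log marginal probability log p(x): the sum over all state paths."""
    return forward_lattice(model, seq).log_probability


# ---------------------------------------------------------------------------
# most probable path / reconstitution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathStep:
    state: str  # "M", "I" or "D"
    index: int
    letter: str | None  # argmax letter for M, None for I/D


@dataclass
class StatePath:
    """A state path from M_0 to M_{m+1} with per-step emitted letters."""

    steps: list[PathStep] = field(default_factory=list)

    @property
    def insertion_visits(self) -> int:
        return sum(1 for s in self.steps if s.state == "I")

    def validate(self, m: int) -> None:
        allowed = {
            "M": lambda k: {("M", k + 1), ("I", k), ("D", k + 1)},
            "I": lambda k: {("M", k + 1), ("I", k)},
            "D": lambda k: {("M", k + 1), ("D", k + 1)},
        }
        first, last = self.steps[0], self.steps[-1]
        if (first.state, first.index) != ("M", 0):
            raise ValueError("path must start at M_0")
        if (last.state, last.index) != ("M", m + 1):
            raise ValueError("path must end at M_{m+1}")
        for a, b in zip(self.steps, self.steps[1:]):
            if (b.state, b.index) not in allowed[a.state](a.index):
                raise ValueError(f"illegal transition {a} -> {b}")


def most_probable_path(model: ProfileHMM) -> tuple[StatePath, float]:
    """Max-product path over states, scoring each emitting state by its
    best letter (insert states by 1/4).

    Insert self-loops are never taken: each loop multiplies the score by
    ``a_II * 1/4 < 1``.  Ties prefer Match > Delete > Insert.
    """
    model.validate()
    m = model.m
    le, ltM, ltI, ltD = model._logs()
    assert np.all(model.from_insert[:, 1] * 0.25 < 1.0)

    best_letter = le.max(axis=1)  # log of best emission per match state
    scoreM = np.full(m + 2, NEG)
    scoreI = np.full(m + 1, NEG)
    scoreD = np.full(m + 2, NEG)
    ptrM: list[str | None] = [None] * (m + 2)
    ptrD: list[str | None] = [None] * (m + 2)

    scoreM[0] = 0.0
    scoreI[0] = scoreM[0] + ltM[0, 1] + LOG_QUARTER
    for k in range(1, m + 2):
        # into M_k: prefer M > D > I on ties
        best, ptr = scoreM[k - 1] + ltM[k - 1, 0], "M"
        if 1 <= k - 1 <= m:
            cand = scoreD[k - 1] + ltD[k - 2, 0]
            if cand > best:
                best, ptr = cand, "D"
        cand = scoreI[k - 1] + ltI[k - 1, 0]
        if cand > best:
            best, ptr = cand, "I"
        emit = best_letter[k - 1] if k <= m else 0.0
        scoreM[k] = best + emit
        ptrM[k] = ptr
        if k <= m:
            scoreI[k] = scoreM[k] + ltM[k, 1] + LOG_QUARTER
            bestd, ptrd = scoreM[k - 1] + ltM[k - 1, 2], "M"
            if k >= 2:
                cand = scoreD[k - 1] + ltD[k - 2, 1]
                if cand > bestd:
                    bestd, ptrd = cand, "D"
            scoreD[k] = bestd
            ptrD[k] = ptrd

    # backtrack from M_{m+1}
    steps: list[PathStep] = []
    state, k = "M", m + 1
    while not (state == "M" and k == 0):
        if state == "M":
            letter = None if k == m + 1 else ALPHABET[int(np.argmax(le[k - 1]))]
            steps.append(PathStep("M", k, letter))
            prev = ptrM[k]
            if prev == "I":
                state, k = "I", k - 1
            elif prev == "D":
                state, k = "D", k - 1
            else:
                state, k = "M", k - 1
        elif state == "I":
            steps.append(PathStep("I", k, None))
            state = "M"  # I_k is entered from M_k (self-loops never optimal)
        else:  # delete
            steps.append(PathStep("D", k, None))
            if ptrD[k] == "D":
                state, k = "D", k - 1
            else:
                state, k = "M", k - 1
    steps.append(PathStep("M", 0, None))
    steps.reverse()
    path = StatePath(steps)
    path.validate(m)
    return path, float(scoreM[m + 1])


@dataclass
class ReconstitutionResult:
    sequence: str
    log_probability: float
    n_candidates_scored: int
    path: StatePath


def _insertion_assignments(q: int, max_candidates: int,
                           rng: np.random.Generator):
    """Distinct letter assignments for q insertion slots, at most
    ``max_candidates`` of them (enumerated when 4**q fits, otherwise
    sampled uniformly without duplication)."""
    total = 4**q
    if total <= max_candidates:
        for code in range(total):
            yield [(code // 4**j) % 4 for j in range(q)]
        return
    seen: set[int] = set()
    while len(seen) < max_candidates:
        draw = rng.integers(0, total, size=max_candidates)
        for code in draw:
            code = int(code)
            if code not in seen:
                seen.add(code)
                yield [(code // 4**j) % 4 for j in range(q)]
                if len(seen) == max_candidates:
                    return


def reconstitute(model: ProfileHMM, max_candidates: int = 256,
                 seed: int | np.random.Generator | None = 0) -> ReconstitutionResult:
    """Most probable sequence under the model.

    Takes the most probable state path; match states contribute their
    argmax letter.  If the path visits ``q`` insert states, up to
    ``max_candidates`` distinct letter assignments for the insertion slots
    are generated (all 4**q when that fits) and every full candidate is
    scored with :func:`log_forward`; the best one is returned.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    path, _ = most_probable_path(model)
    template: list[str | None] = []
    for step in path.steps:
        if step.state == "M" and step.letter is not None:
            template.append(step.letter)
        elif step.state == "I":
            template.append(None)
    slots = [i for i, c in enumerate(template) if c is None]
    q = len(slots)

    best_seq, best_lp, n_scored = None, -np.inf, 0
    for assign in _insertion_assignments(q, max_candidates, rng):
        letters = list(template)
        for pos, a in zip(slots, assign):
            letters[pos] = ALPHABET[a]
        cand = "".join(letters)  # type: ignore[arg-type]
        lp = log_forward(model, cand)
        n_scored += 1
        if lp > best_lp:
            best_seq, best_lp = cand, lp
    assert best_seq is not None
    return ReconstitutionResult(best_seq, best_lp, n_scored, path)
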
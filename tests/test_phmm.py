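"""Profile HMM: forward algorithm, Viterbi path, reconstitution."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aptvae import phmm
from aptvae.phmm import (
    AlphabetError,
    ProfileHMM,
    log_forward,
    most_probable_path,
    random_profile_hmm,
    reconstitute,
    seq_to_indices,
)

from ._oracles import all_sequences, best_path_logscore, enumerate_logp


def _one_match_model(letter="A"):
    """m=1 model that deterministically emits one letter."""
    e = np.zeros((1, 4))
    e[0, "ACGU".index(letter)] = 1.0
    return ProfileHMM(
        match_emissions=e,
        from_match=np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
        from_insert=np.array([[1.0, 0.0], [1.0, 0.0]]),
        from_delete=np.array([[1.0, 0.0]]),
    )


class TestLogForward:
    def test_single_deterministic_path_has_probability_one(self):
        assert log_forward(_one_match_model("A"), "A") == pytest.approx(0.0, abs=1e-12)

    def test_zero_probability_emission_hits_floor(self):
        assert log_forward(_one_match_model("A"), "C") < -1e9

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 4))
        model = random_profile_hmm(m, rng)
        L = int(rng.integers(0, 4))
        seq = "".join(rng.choice(list("ACGU"), size=L))
        ours = log_forward(model, seq)
        oracle = enumerate_logp(model, seq)
        if math.isinf(oracle):
            assert ours < -1e9
        else:
            assert ours == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_total_probability_normalized_and_monotone(self, seed):
        model = random_profile_hmm(2, np.random.default_rng(seed))
        total, prev = 0.0, 0.0
        for _, seqs in all_sequences(6):
            total += sum(math.exp(log_forward(model, s)) for s in seqs)
            assert prev <= total <= 1.0 + 1e-9
            prev = total
        assert total > 0.5  # most mass is on short sequences for small m

    def test_invalid_letter_raises(self):
        with pytest.raises(AlphabetError):
            log_forward(_one_match_model(), "AXA")

    def test_dna_thymine_read_as_uracil(self):
        model = random_profile_hmm(2, np.random.default_rng(0))
        assert log_forward(model, "AT") == pytest.approx(log_forward(model, "AU"))

    def test_non_normalized_model_rejected(self):
        model = _one_match_model()
        model.match_emissions = np.array([[0.5, 0.1, 0.1, 0.1]])
        with pytest.raises(ValueError):
            log_forward(model, "A")

    def test_lattice_entries_are_log_probabilities(self):
        model = random_profile_hmm(3, np.random.default_rng(5))
        lat = phmm.forward_lattice(model, "ACGU")
        for arr in (lat.match, lat.insert, lat.delete):
            assert (arr <= 1e-9).all()
        assert lat.match[0, 0] == 0.0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), L=st.integers(0, 6))
    def test_log_probability_never_positive(self, seed, L):
        rng = np.random.default_rng(seed)
        model = random_profile_hmm(int(rng.integers(1, 5)), rng)
        seq = "".join(rng.choice(list("ACGU"), size=L))
        assert log_forward(model, seq) <= 1e-9


class TestMostProbablePath:
    def test_dominant_match_transitions_give_pure_match_path(self):
        rng = np.random.default_rng(0)
        m = 4
        model = random_profile_hmm(m, rng)
        model.from_match[:, 0] = 0.9
        model.from_match[:, 1] = 0.05
        model.from_match[:-1, 2] = 0.05
        model.from_match[-1] = [0.95, 0.05, 0.0]
        path, _ = most_probable_path(model)
        assert [s.state for s in path.steps] == ["M"] * (m + 2)
        assert [s.index for s in path.steps] == list(range(m + 2))

    def test_high_delete_probability_routes_through_deletion(self):
        # begin state jumping to D_1 with 0.99: the motif-skip pattern
        rng = np.random.default_rng(1)
        model = random_profile_hmm(2, rng)
        model.from_match[0] = [0.005, 0.005, 0.99]
        model.from_delete[0] = [0.99, 0.01]
        path, _ = most_probable_path(model)
        assert ("D", 1) in [(s.state, s.index) for s in path.steps]

    @pytest.mark.parametrize("seed", range(10))
    def test_score_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        model = random_profile_hmm(3, rng)
        _, score = most_probable_path(model)
        assert score == pytest.approx(best_path_logscore(model, max_insertions=4),
                                      abs=1e-9)

    def test_deterministic_tie_breaking(self):
        model = random_profile_hmm(3, np.random.default_rng(2))
        p1, s1 = most_probable_path(model)
        p2, s2 = most_probable_path(model)
        assert p1.steps == p2.steps and s1 == s2

    def test_path_topology_validates(self):
        for seed in range(5):
            model = random_profile_hmm(3, np.random.default_rng(seed))
            path, _ = most_probable_path(model)
            path.validate(model.m)


def _insertion_heavy_model(m, n_insert_states, rng):
    """Model whose Viterbi path visits exactly ``n_insert_states`` inserts."""
    model = random_profile_hmm(m, rng)
    model.from_match[:, 0] = 0.949
    model.from_match[:, 1] = 0.05
    model.from_match[:-1, 2] = 0.001
    model.from_match[-1] = [0.95, 0.05, 0.0]
    model.from_match[-1] /= model.from_match[-1].sum()
    for k in range(n_insert_states):
        model.from_match[k] = [0.04, 0.959, 0.001]
    model.from_match[:-1] /= model.from_match[:-1].sum(axis=1, keepdims=True)
    model.from_insert[:, 0] = 0.99
    model.from_insert[:, 1] = 0.01
    model.from_delete[:-1] = [0.999, 0.001]  # deletion chains never optimal
    model.match_emissions[:] = 0.01
    model.match_emissions[np.arange(m), 0] = 0.97
    model.match_emissions /= model.match_emissions.sum(axis=1, keepdims=True)
    return model


class TestReconstitute:
    def test_no_insertions_single_candidate_of_match_argmaxes(self):
        rng = np.random.default_rng(3)
        model = random_profile_hmm(3, rng)
        model.from_match[:, 0] = 0.98
        model.from_match[:, 1] = 0.01
        model.from_match[:-1, 2] = 0.01
        model.from_match[-1] = [0.99, 0.01, 0.0]
        model.from_match[-1] /= model.from_match[-1].sum()
        res = reconstitute(model)
        assert res.n_candidates_scored == 1
        expected = "".join("ACGU"[i] for i in model.match_emissions.argmax(axis=1))
        assert res.sequence == expected

    @pytest.mark.parametrize("q,expected", [(1, 4), (2, 16), (3, 64),
                                            (4, 256), (5, 256), (6, 256)])
    def test_candidate_count_contract(self, q, expected):
        model = _insertion_heavy_model(8, q, np.random.default_rng(q))
        path, _ = most_probable_path(model)
        assert path.insertion_visits == q
        res = reconstitute(model, max_candidates=256, seed=0)
        assert res.n_candidates_scored == expected

    @pytest.mark.parametrize("q", [1, 2, 3])
    def test_returned_sequence_maximizes_forward_over_all_assignments(self, q):
        model = _insertion_heavy_model(6, q, np.random.default_rng(10 + q))
        res = reconstitute(model, seed=0)
        # exhaustive oracle: every assignment scored independently
        from itertools import product

        template = []
        for step in res.path.steps:
            if step.state == "M" and step.letter is not None:
                template.append(step.letter)
            elif step.state == "I":
                template.append(None)
        slots = [i for i, c in enumerate(template) if c is None]
        candidates = []
        for assign in product("ACGU", repeat=len(slots)):
            letters = list(template)
            for pos, a in zip(slots, assign):
                letters[pos] = a
            candidates.append("".join(letters))
        best = max(candidates, key=lambda s: log_forward(model, s))
        assert log_forward(model, res.sequence) == pytest.approx(
            log_forward(model, best), abs=1e-9)
        assert res.log_probability == pytest.approx(
            log_forward(model, res.sequence), abs=1e-12)

    def test_sampling_is_seeded_and_duplicate_free(self):
        model = _insertion_heavy_model(8, 6, np.random.default_rng(6))
        r1 = reconstitute(model, seed=5)
        r2 = reconstitute(model, seed=5)
        assert r1.sequence == r2.sequence
        assert r1.log_probability == r2.log_probability


class TestSerialization:
    def test_json_round_trip(self):
        model = random_profile_hmm(4, np.random.default_rng(11))
        clone = ProfileHMM.from_json(model.to_json())
        assert np.allclose(model.match_emissions, clone.match_emissions)
        assert np.allclose(model.from_match, clone.from_match)
        assert np.allclose(model.from_insert, clone.from_insert)
        assert np.allclose(model.from_delete, clone.from_delete)

    def test_logo_table_rows_are_distributions(self):
        model = random_profile_hmm(5, np.random.default_rng(12))
        df = model.logo_table()
        assert list(df.columns) == ["A", "C", "G", "U"]
        assert np.allclose(df.sum(axis=1), 1.0)


def test_seq_to_indices_rejects_ambiguity_codes():
    with pytest.raises(AlphabetError):
        seq_to_indices("ACGN")
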
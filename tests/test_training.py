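"""Objective terms, schedules and the training loop."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import dirichlet

from aptvae.nets import CNNEncoder, make_decoder, one_hot, tokenize
from aptvae.training import (
    TrainingConfig,
    elbo_loss,
    gaussian_kl,
    kl_scale,
    regularizer_weight,
    train,
    transition_regularizer,
)
from aptvae.vae import SequenceVAE


class TestKLScale:
    @pytest.mark.parametrize("e,E,expected", [(0, 50, 0.0), (50, 50, 1.0),
                                              (25, 50, 0.5), (120, 50, 1.0)])
    def test_schedule(self, e, E, expected):
        assert kl_scale(e, E) == expected

    def test_bounded_in_unit_interval(self):
        for e in range(0, 200, 7):
            assert 0.0 <= kl_scale(e, 50) <= 1.0


class TestGaussianKL:
    def test_zero_when_posterior_equals_prior(self):
        assert gaussian_kl(np.zeros((1, 3)), np.zeros((1, 3)))[0] == 0.0

    def test_closed_form_unit_mean(self):
        assert gaussian_kl(np.array([[1.0]]), np.array([[0.0]]))[0] == \
            pytest.approx(0.5)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        mu = np.array([[0.7, -1.2]])
        logvar = np.array([[0.3, -0.5]])
        sd = np.exp(0.5 * logvar)
        z = mu + sd * rng.normal(size=(1_000_000, 2))
        # E_q[log q(z) - log p(z)] per sample
        logq = (-0.5 * ((z - mu) / sd) ** 2 - 0.5 * logvar
                - 0.5 * math.log(2 * math.pi)).sum(axis=1)
        logp = (-0.5 * z**2 - 0.5 * math.log(2 * math.pi)).sum(axis=1)
        samples = logq - logp
        mc, se = samples.mean(), samples.std() / math.sqrt(len(samples))
        assert gaussian_kl(mu, logvar)[0] == pytest.approx(mc, abs=3 * se)


class TestTransitionRegularizer:
    def test_zero_at_round_R_for_any_distribution(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = rng.dirichlet([1, 1, 1])
            assert transition_regularizer(p, e=50, R=50) == pytest.approx(0.0)
            assert transition_regularizer(p, e=80, R=50) == pytest.approx(0.0)

    def test_matches_dirichlet_density_ratio(self):
        """The closed form is the log-ratio of Dir(p | [1+w,1,1]) to the
        flat Dir(p | [1,1,1]) density."""
        rng = np.random.default_rng(2)
        for e in [0, 10, 25, 40, 49]:
            w = regularizer_weight(e, 50)
            for _ in range(5):
                p = rng.dirichlet([2, 1, 1])
                expected = (dirichlet.logpdf(p, [1 + w, 1, 1])
                            - dirichlet.logpdf(p, [1, 1, 1]))
                assert transition_regularizer(p, e, 50) == pytest.approx(
                    expected, abs=1e-10)

    def test_full_weight_certain_match_is_log_fifteen(self):
        # w = 4: log((2+4)(1+4)/2 * 1^4) = log 15
        val = transition_regularizer(np.array([1.0, 0.0, 0.0]), e=0, R=50)
        assert val == pytest.approx(math.log(15.0), abs=1e-12)

    def test_monotone_increasing_in_match_probability(self):
        vals = [transition_regularizer(np.array([a, (1 - a) / 2, (1 - a) / 2]),
                                       e=10, R=50)
                for a in [0.1, 0.3, 0.5, 0.7, 0.9]]
        assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_zero_match_probability_hits_floor_without_crash(self):
        val = transition_regularizer(np.array([0.0, 0.5, 0.5]), e=0, R=50)
        assert np.isfinite(val) and val < -1e9


def _toy_setup(kind="profile_hmm", n=32, L=8, seed=0):
    rng = np.random.default_rng(seed)
    seqs = ["".join(rng.choice(list("ACGU"), size=L)) for _ in range(n)]
    enc = CNNEncoder(2, max_len=L, rng=rng)
    dec = make_decoder(kind, 2, L, None, rng)
    return seqs, enc, dec


class TestElboLoss:
    def test_kl_contributes_nothing_at_epoch_zero(self):
        seqs, enc, dec = _toy_setup()
        toks = tokenize(seqs, 8)
        cfg = TrainingConfig()
        _, parts = elbo_loss(toks, one_hot(toks), enc, dec, epoch=0,
                             config=cfg, rng=np.random.default_rng(1))
        assert parts.scale == 0.0
        assert parts.total == pytest.approx(parts.recon + parts.reg)

    def test_termwise_decomposition(self):
        for kind in ["profile_hmm", "multicategorical", "autoregressive"]:
            seqs, enc, dec = _toy_setup(kind)
            toks = tokenize(seqs, 8)
            cfg = TrainingConfig()
            _, parts = elbo_loss(toks, one_hot(toks), enc, dec, epoch=25,
                                 config=cfg, rng=np.random.default_rng(2))
            assert parts.scale == 0.5
            assert parts.total == pytest.approx(
                parts.recon + parts.scale * parts.kl + parts.reg, rel=1e-12)

    def test_perfect_reconstruction_limit(self):
        # deterministic encoder + one-hot multicategorical decoder
        seqs = ["ACGU"] * 8
        rng = np.random.default_rng(3)
        enc = CNNEncoder(2, max_len=4, rng=rng)
        enc.logvar_head.W.data[:] = 0.0
        enc.logvar_head.b.data[:] = -50.0  # variance ~ 0
        dec = make_decoder("multicategorical", 2, 4, None, rng)
        toks = tokenize(seqs, 4)
        dec.out.W.data[:] = 0.0
        b = np.full((4, 4), -1e3)
        b[np.arange(4), toks[0]] = 1e3
        dec.out.b.data[:] = b.reshape(-1)
        _, parts = elbo_loss(toks, one_hot(toks), enc, dec, epoch=0,
                             config=TrainingConfig(), rng=np.random.default_rng(4))
        assert parts.recon == pytest.approx(0.0, abs=1e-9)


class TestTrainLoop:
    def test_identical_seeds_give_identical_records(self):
        seqs, _, _ = _toy_setup(n=40)
        runs = []
        for _ in range(2):
            est = SequenceVAE(decoder="multicategorical", max_epochs=8,
                              patience=8, batch_size=16, random_state=11)
            est.fit(seqs)
            runs.append(est.loss_record_)
        assert runs[0].equals(runs[1])

    def test_returns_best_test_loss_snapshot(self):
        seqs, enc, dec = _toy_setup(n=40, seed=5)
        cfg = TrainingConfig(max_epochs=10, patience=10, batch_size=16, seed=1)
        result = train(seqs, enc, dec, cfg)
        record = result.record
        assert result.best_epoch == record["test_loss"].idxmin()
        assert result.best_epoch <= result.stopped_epoch

    def test_recorded_losses_decompose_exactly(self):
        seqs, enc, dec = _toy_setup(n=40, seed=6)
        cfg = TrainingConfig(max_epochs=6, patience=6, batch_size=40, seed=2)
        record = train(seqs, enc, dec, cfg).record
        lhs = record["train_loss"]
        rhs = (record["train_recon"] + record["kl_scale"] * record["train_kl"]
               + record["train_reg"])
        assert np.allclose(lhs, rhs, atol=1e-9)
        assert np.allclose(record["test_loss"],
                           record["test_recon"] + record["test_kl"], atol=1e-9)

    def test_schedules_vanish_after_their_rounds(self):
        seqs, enc, dec = _toy_setup(n=30, seed=7)
        cfg = TrainingConfig(max_epochs=8, patience=8, batch_size=30, seed=3,
                             kl_anneal_epochs=3, transition_reg_rounds=3)
        record = train(seqs, enc, dec, cfg).record
        late = record[record["epoch"] >= 3]
        assert (late["kl_scale"] == 1.0).all()
        assert np.allclose(late["train_reg"], 0.0, atol=1e-12)

    def test_empty_and_tiny_datasets_rejected(self):
        with pytest.raises(ValueError):
            SequenceVAE(decoder="multicategorical").fit([])
        _, enc, dec = _toy_setup()
        with pytest.raises(ValueError):
            train(["ACGU"], enc, dec, TrainingConfig())

    def test_unequal_lengths_rejected(self):
        _, enc, dec = _toy_setup()
        with pytest.raises(ValueError):
            train(["ACGU", "ACG"], enc, dec, TrainingConfig())

    def test_regularizer_raises_early_match_to_match_probability(self):
        """With the Dirichlet bonus active, decoded models early in training
        allocate more match-to-match probability than unregularized runs."""
        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list("ACGU"), size=8)) for _ in range(64)]
        diffs = []
        for seed in range(3):
            amm = {}
            for R in (50, 1):  # R=1 -> weight 0 from epoch 1 on (control)
                est = SequenceVAE(decoder="profile_hmm", max_epochs=6,
                                  patience=6, batch_size=32, random_state=seed,
                                  transition_reg_rounds=R)
                est.fit(seqs)
                z = est.transform(seqs[:16])
                models = est.decode_profile_hmm(z)
                amm[R] = np.mean([m.from_match[:, 0].mean() for m in models])
            diffs.append(amm[50] - amm[1])
        assert np.mean(diffs) > 0


class TestTrainingConfig:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(test_fraction=0.0)
        with pytest.raises(ValueError):
            TrainingConfig(patience=100, max_epochs=50)
        with pytest.raises(ValueError):
            TrainingConfig(kl_anneal_epochs=0)
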
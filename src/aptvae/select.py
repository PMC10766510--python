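"""Candidate generation from the latent space.

Three stages mirror the aptamer-discovery loop:

1. ``fit_gmm`` — a Gaussian mixture (10 components, best of 100 seeded
   EM restarts by total data log-likelihood) summarizes the latent
   embedding; its component means are the candidate coordinates.
2. ``centers_to_candidates`` — each center is decoded into a profile HMM
   and reconstituted into its most probable sequence.
3. ``BatchBayesianOptimizer`` — given measured relative binding
   activities at latent coordinates, fits a Gaussian-process regression
   and proposes a diverse batch of new coordinates by maximizing the
   GP upper confidence bound under local penalization (Gonzalez et al.
   style multiplicative "hammer" factors around already-chosen points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc
from sklearn.base import BaseEstimator
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from .phmm import ProfileHMM, ReconstitutionResult, reconstitute


# ---------------------------------------------------------------------------
# GMM center selection
# ---------------------------------------------------------------------------

@dataclass
class GMMResult:
    """Best-of-``restarts`` Gaussian mixture over the latent embedding."""

    means: np.ndarray                 # (k, d)
    covariances: np.ndarray
    weights: np.ndarray
    evidence: float                   # total data log-likelihood of the winner
    all_evidences: np.ndarray         # per-restart evidences
    model: GaussianMixture = field(repr=False, default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)


def fit_gmm(embeddings: np.ndarray, n_components: int = 10, restarts: int = 100,
            seed: int = 0, covariance_type: str = "full",
            tol: float = 1e-4) -> GMMResult:
    """Fit ``restarts`` seeded EM runs and keep the one with the best
    evidence (total log-likelihood of the data)."""
    X = np.asarray(embeddings, dtype=np.float64)
    if X.shape[0] < n_components:
        raise ValueError("fewer points than mixture components")
    best, evidences = None, []
    for r in range(restarts):
        gm = GaussianMixture(n_components=n_components,
                             covariance_type=covariance_type, tol=tol,
                             random_state=seed + r, init_params="random")
        gm.fit(X)
        ev = float(gm.score(X) * X.shape[0])
        evidences.append(ev)
        if best is None or ev > best[0]:
            best = (ev, gm)
    ev, gm = best
    return GMMResult(gm.means_.copy(), gm.covariances_.copy(), gm.weights_.copy(),
                     ev, np.array(evidences), gm)


@dataclass
class Candidate:
    component: int
    center: np.ndarray
    model: ProfileHMM
    sequence: str
    log_probability: float
    min_edit_distance: int | None = None


def centers_to_candidates(gmm: GMMResult, vae, max_candidates: int = 256,
                          seed: int = 0,
                          training_sequences: list[str] | None = None
                          ) -> list[Candidate]:
    """Decode each mixture center into (profile HMM, sequence, log-prob).

    With ``training_sequences`` given, each candidate also reports its
    minimum edit distance to the training set (0 means the candidate
    occurs verbatim; generated candidates routinely do not).
    """
    out = []
    for i, center in enumerate(gmm.means):
        model = vae.decode_profile_hmm(center[None, :])[0]
        rec: ReconstitutionResult = reconstitute(model, max_candidates, seed)
        dist = None
        if training_sequences is not None:
            dist = min_edit_distance(rec.sequence, training_sequences)
        out.append(Candidate(i, center.copy(), model, rec.sequence,
                             rec.log_probability, dist))
    return out


def min_edit_distance(seq: str, pool: list[str]) -> int:
    import edlib

    best = None
    for other in pool:
        d = edlib.align(seq, other, task="distance")["editDistance"]
        if best is None or d < best:
            best = d
            if best == 0:
                break
    return int(best)


def re_embed(sequences: list[str], vae) -> np.ndarray:
    """Posterior means of the given sequences (no sampling)."""
    return vae.transform(sequences)


# ---------------------------------------------------------------------------
# batch Bayesian optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityObservation:
    """A latent coordinate with its measured relative binding activity
    (percent of the positive control)."""

    coordinate: tuple[float, ...]
    activity: float


@dataclass
class BOProposal:
    points: np.ndarray            # (batch, d)
    acquisition: np.ndarray       # penalized acquisition value of each pick
    raw_acquisition: np.ndarray   # unpenalized value at the same points
    lipschitz: float


class BatchBayesianOptimizer(BaseEstimator):
    """GP-UCB proposals with local penalization for batch diversity.

    Parameters
    ----------
    batch_size : int, default 10
        Number of points proposed in parallel.
    beta : float, default 2.0
        UCB exploration weight: acquisition = mu + beta * sigma.
    bounds : (d, 2) array, optional
        Search box; defaults to the observed bounding box expanded by 10%.
    n_grid : int, default 4096
        Random candidate points used to maximize the acquisition.
    """

    def __init__(self, batch_size: int = 10, beta: float = 2.0, bounds=None,
                 n_grid: int = 4096, random_state: int = 0):
        self.batch_size = batch_size
        self.beta = beta
        self.bounds = bounds
        self.n_grid = n_grid
        self.random_state = random_state

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.shape[0] < 2:
            raise ValueError("need at least 2 activity observations")
        self.X_, self.y_ = X, y
        self._y_mean, self._y_std = y.mean(), y.std()
        if self._y_std == 0.0:
            self._y_std = 1.0  # degenerate activities: GP turns into prior
        ys = (y - self._y_mean) / self._y_std
        kernel = (ConstantKernel(1.0, (1e-3, 1e3))
                  * Matern(length_scale=1.0, length_scale_bounds=(1e-2, 1e2),
                           nu=2.5)
                  + WhiteKernel(1e-2, (1e-8, 1e1)))
        self.gp_ = GaussianProcessRegressor(kernel=kernel, normalize_y=False,
                                            random_state=self.random_state)
        self.gp_.fit(X, ys)
        if self.bounds is not None:
            self.bounds_ = np.asarray(self.bounds, dtype=np.float64)
        else:
            lo, hi = X.min(axis=0), X.max(axis=0)
            span = np.maximum(hi - lo, 1e-6)
            self.bounds_ = np.stack([lo - 0.1 * span, hi + 0.1 * span], axis=1)
        self.lipschitz_ = self._estimate_lipschitz()
        return self

    # -- internals ------------------------------------------------------
    def _posterior(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu, sd = self.gp_.predict(X, return_std=True)
        return mu, np.maximum(sd, 1e-9)

    def acquisition(self, X: np.ndarray) -> np.ndarray:
        """GP-UCB on the standardized activity scale."""
        mu, sd = self._posterior(np.atleast_2d(X))
        return mu + self.beta * sd

    def _estimate_lipschitz(self) -> float:
        rng = np.random.default_rng(self.random_state)
        pts = self._sample_box(rng, 512)
        eps = 1e-4
        grads = np.zeros(pts.shape)
        base, _ = self._posterior(pts)
        for j in range(pts.shape[1]):
            shifted = pts.copy()
            shifted[:, j] += eps
            grads[:, j] = (self._posterior(shifted)[0] - base) / eps
        return float(max(np.linalg.norm(grads, axis=1).max(), 1e-6))

    def _sample_box(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lo, hi = self.bounds_[:, 0], self.bounds_[:, 1]
        return lo + (hi - lo) * rng.random((n, lo.size))

    def penalizers(self, X: np.ndarray, chosen: np.ndarray) -> np.ndarray:
        """Product of hammer factors in [0, 1] around each chosen point."""
        if len(chosen) == 0:
            return np.ones(X.shape[0])
        mu_j, sd_j = self._posterior(np.atleast_2d(chosen))
        M = ((self.y_ - self._y_mean) / self._y_std).max()
        out = np.ones(X.shape[0])
        for xj, mj, sj in zip(np.atleast_2d(chosen), mu_j, sd_j):
            r = np.linalg.norm(X - xj, axis=1)
            zscore = (self.lipschitz_ * r - M + mj) / (np.sqrt(2.0) * sj)
            out *= 0.5 * erfc(-zscore)
        return out

    def propose(self) -> BOProposal:
        """Select ``batch_size`` points by sequentially maximizing the
        penalized acquisition over a seeded random candidate grid."""
        check_is_fitted(self, "gp_")
        rng = np.random.default_rng(self.random_state)
        grid = np.vstack([self._sample_box(rng, self.n_grid), self.X_])
        raw = self.acquisition(grid)
        raw_shifted = raw - raw.min()  # nonnegative so penalizers only shrink it
        chosen: list[np.ndarray] = []
        acq_vals, raw_vals = [], []
        used = np.zeros(len(grid), dtype=bool)  # a grid point is picked once
        for _ in range(self.batch_size):
            pen = raw_shifted * self.penalizers(grid, np.array(chosen))
            pen[used] = -np.inf
            idx = int(np.argmax(pen))
            used[idx] = True
            chosen.append(grid[idx].copy())
            acq_vals.append(float(pen[idx]))
            raw_vals.append(float(raw_shifted[idx]))
        return BOProposal(np.array(chosen), np.array(acq_vals),
                          np.array(raw_vals), self.lipschitz_)


def bo_propose(observations: list[ActivityObservation] | tuple[np.ndarray, np.ndarray],
               batch: int = 10, seed: int = 0, bounds=None) -> BOProposal:
    """Fit a GP to activity observations and propose a batch of points."""
    if isinstance(observations, tuple):
        X, y = observations
    else:
        X = np.array([o.coordinate for o in observations], dtype=np.float64)
        y = np.array([o.activity for o in observations], dtype=np.float64)
    bo = BatchBayesianOptimizer(batch_size=batch, random_state=seed, bounds=bounds)
    return bo.fit(X, y).propose()
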
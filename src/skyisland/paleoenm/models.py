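"""Presence-only suitability models.

Five algorithms with deliberately different inductive biases, all mapping
a climate vector to suitability in [0, 1]:

* ``bioclim`` — per-variable percentile envelope;
* ``domain`` — Gower similarity to the closest training point;
* ``enfa`` — marginality/specialization factor space, suitability from
  the upper tail of the Mahalanobis distance to the presence centroid;
* ``maxent_like`` — exponential model over linear + quadratic features
  fitted by penalized presence/background discrimination (logistic
  regression against a background sample);
* ``ocsvm`` — one-class support vector machine with a radial kernel,
  decision values rescaled to [0, 1] by the training range.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import OneClassSVM

__all__ = ["ALGORITHMS", "fit_model", "NicheModel"]

logger = logging.getLogger(__name__)

ALGORITHMS = ("bioclim", "domain", "enfa", "maxent_like", "ocsvm")


class NicheModel:
    """Base class: fitted presence-only model with ``predict`` in [0, 1]."""

    algorithm: str

    def predict(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class BioclimModel(NicheModel):
    """Percentile envelope: suit = min over variables of 2·min(F̂, 1-F̂).

    F̂ is the midpoint empirical CDF of the training presences, so the
    training median of every variable scores exactly 1.
    """

    algorithm = "bioclim"

    def __init__(self, train: np.ndarray):
        self._sorted = np.sort(train, axis=0)
        self._n = train.shape[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        suits = np.empty(X.shape)
        for v in range(X.shape[1]):
            col = self._sorted[:, v]
            le = np.searchsorted(col, X[:, v], side="right")
            lt = np.searchsorted(col, X[:, v], side="left")
            F = (le + lt) / (2.0 * self._n)
            suits[:, v] = 2.0 * np.minimum(F, 1.0 - F)
        return np.clip(suits.min(axis=1), 0.0, 1.0)


class DomainModel(NicheModel):
    """Gower similarity to the nearest training presence.

    suit(x) = max_t [1 - mean_v |x_v - t_v| / range_v]; variables with a
    degenerate (zero) training range are dropped with a warning.
    """

    algorithm = "domain"

    def __init__(self, train: np.ndarray):
        rng = train.max(axis=0) - train.min(axis=0)
        keep = rng > 0
        if not keep.all():
            logger.warning("domain: dropping %d zero-range variables", (~keep).sum())
        if not keep.any():
            raise ValueError("domain: all variables have degenerate ranges")
        self._train = train[:, keep]
        self._range = rng[keep]
        self._keep = keep

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)[:, self._keep]
        out = np.empty(X.shape[0])
        # chunked to bound the (n_points, n_train, n_vars) intermediate
        step = max(1, int(2e6 / max(1, self._train.size)))
        for lo in range(0, X.shape[0], step):
            block = X[lo:lo + step]
            gower = np.abs(block[:, None, :] - self._train[None, :, :]) / self._range
            sim = 1.0 - gower.mean(axis=2)
            out[lo:lo + step] = sim.max(axis=1)
        return np.clip(out, 0.0, 1.0)


class EnfaModel(NicheModel):
    """Ecological-niche factor analysis in the marginality/specialization
    factor space.

    Variables are standardized by the background; the marginality axis is
    (mean_presence - mean_background) / (1.96·sd_background); the
    specialization axes are the eigenvectors of the presence covariance
    residual to the marginality direction.  Suitability is the upper-tail
    percentile of the (diagonal) Mahalanobis distance of a point to the
    presence centroid among the training presences themselves.
    """

    algorithm = "enfa"

    def __init__(self, train: np.ndarray, background: np.ndarray, n_spec_axes: int = 4):
        mu_b = background.mean(axis=0)
        sd_b = background.std(axis=0)
        if np.any(sd_b == 0):
            raise ValueError("enfa: background has zero-variance variables")
        self._mu_b, self._sd_b = mu_b, sd_b
        Zp = (train - mu_b) / sd_b
        self.marginality = Zp.mean(axis=0) / 1.96
        norm = np.linalg.norm(self.marginality)
        u = self.marginality / norm if norm > 0 else np.eye(train.shape[1])[0]

        resid = Zp - np.outer(Zp @ u, u)
        cov = np.cov(resid, rowvar=False)
        cov = np.atleast_2d(cov)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        n_spec = min(n_spec_axes, train.shape[1] - 1)
        basis = [u] + [evecs[:, order[i]] for i in range(n_spec)]
        self._basis = np.column_stack(basis)          # (n_vars, n_factors)

        F = Zp @ self._basis
        self._centroid = F.mean(axis=0)
        sd = F.std(axis=0)
        self._factor_sd = np.where(sd > 0, sd, 1.0)
        self._train_dist = np.sort(self._mahal(F))

    def _mahal(self, F: np.ndarray) -> np.ndarray:
        z = (F - self._centroid) / self._factor_sd
        return np.sqrt((z**2).sum(axis=1))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        F = ((X - self._mu_b) / self._sd_b) @ self._basis
        d = self._mahal(F)
        n = self._train_dist.size
        below = np.searchsorted(self._train_dist, d, side="left")
        return (n - below) / n


class MaxentLikeModel(NicheModel):
    """Penalized presence/background exponential model.

    Linear + quadratic features (z-scored by the background) enter an
    L2-penalized logistic regression of presences against the background
    sample; suitability is the fitted probability, already in [0, 1].
    """

    algorithm = "maxent_like"

    def __init__(self, train: np.ndarray, background: np.ndarray, C: float = 1.0):
        self._mu = background.mean(axis=0)
        sd = background.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Xp = self._features(train)
        Xb = self._features(background)
        X = np.vstack([Xp, Xb])
        y = np.r_[np.ones(len(Xp)), np.zeros(len(Xb))]
        self._clf = LogisticRegression(C=C, max_iter=2000)
        self._clf.fit(X, y)

    def _features(self, X: np.ndarray) -> np.ndarray:
        Z = (np.atleast_2d(X) - self._mu) / self._sd
        return np.hstack([Z, Z**2])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._clf.predict_proba(self._features(X))[:, 1]


class OneClassSvmModel(NicheModel):
    """One-class SVM (radial kernel, ν = 0.1), decision values min/max
    rescaled to [0, 1] on the training presences and clipped elsewhere."""

    algorithm = "ocsvm"

    def __init__(self, train: np.ndarray, background: np.ndarray | None = None,
                 nu: float = 0.1):
        ref = background if background is not None else train
        self._mu = ref.mean(axis=0)
        sd = ref.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Z = (train - self._mu) / self._sd
        self._svm = OneClassSVM(nu=nu, kernel="rbf", gamma="scale")
        self._svm.fit(Z)
        dec = self._svm.decision_function(Z)
        self._lo, self._hi = float(dec.min()), float(dec.max())

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.atleast_2d(X) - self._mu) / self._sd
        dec = self._svm.decision_function(Z)
        if self._hi == self._lo:
            return np.ones(len(dec))
        return np.clip((dec - self._lo) / (self._hi - self._lo), 0.0, 1.0)


def fit_model(
    algorithm: str,
    train: np.ndarray,
    background: np.ndarray | None = None,
) -> NicheModel:
    """Fit one of the five presence-only algorithms.

    ``train`` holds the climate vectors of the training presences;
    ``background`` a sample of available climate (required by
    ``maxent_like``, ``enfa`` and for ``ocsvm`` standardization).
    """
    if train.shape[0] < 5:
        raise ValueError("need at least five training presences")
    if algorithm == "bioclim":
        return BioclimModel(train)
    if algorithm == "domain":
        return DomainModel(train)
    if algorithm == "enfa":
        if background is None:
            raise ValueError("enfa requires a background sample")
        return EnfaModel(train, background)
    if algorithm == "maxent_like":
        if background is None:
            raise ValueError("maxent_like requires a background sample")
        return MaxentLikeModel(train, background)
    if algorithm == "ocsvm":
        return OneClassSvmModel(train, background)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
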
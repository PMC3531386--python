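"""Full-covariance Gaussian mixture fitting by EM, with candidate
classification, genotype labeling, and uncertainty scores.

Each candidate SV is a 2-D feature vector x_i assumed drawn from a mixture
of G bivariate normals with weights tau_k, means mu_k, and unrestricted
covariances Sigma_k:

    L(theta) = sum_i log sum_k tau_k * phi(x_i; mu_k, Sigma_k)

The E-step computes responsibilities z_ik = tau_k phi_k(x_i) / sum_j tau_j
phi_j(x_i); the M-step re-estimates weighted moments.  G is fixed by the
biology: 3 for deletions (homozygous / heterozygous / normal region) and 2
for inversions (event / normal region).  A candidate's label is the argmax
component and its uncertainty is 1 minus the largest membership
probability.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

logger = logging.getLogger(__name__)

DEL_LABELS = ("HOM_DEL", "HET_DEL", "NORMAL")
INV_LABELS = ("INV", "NORMAL")


@dataclasses.dataclass
class MixtureModel:
    """G-component bivariate Gaussian mixture with full covariances."""

    tau: np.ndarray          # (G,)
    means: np.ndarray        # (G, 2)
    covs: np.ndarray         # (G, 2, 2)
    history: list[float] = dataclasses.field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    @property
    def G(self) -> int:
        return self.tau.shape[0]

    def to_dict(self) -> dict:
        """JSON-serializable parameter dump (reproducibility sidecar)."""
        return {
            "tau": self.tau.tolist(),
            "means": self.means.tolist(),
            "covs": self.covs.tolist(),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "log_likelihood": self.history[-1] if self.history else None,
        }


@dataclasses.dataclass(slots=True)
class Assignment:
    """Responsibilities, mapped label, and uncertainty of one candidate."""

    responsibilities: np.ndarray
    label: str
    uncertainty: float


def _ridge(X: np.ndarray, ridge: float | None) -> float:
    if ridge is not None:
        return float(ridge)
    mean_var = float(np.mean(np.var(X, axis=0)))
    return max(1e-6 * mean_var, 1e-12)


def _clamp_cov(cov: np.ndarray, eps: float) -> np.ndarray:
    """Constrained covariance estimate: eigenvalues floored at ``eps``.

    Clipping the eigenvalues of the weighted sample covariance is the exact
    M-step maximizer over the set {Sigma : lambda_min(Sigma) >= eps}, so EM
    stays monotone while collapsed/collinear components remain invertible.
    """
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    cov = (cov + cov.T) / 2.0
    vals, vecs = np.linalg.eigh(cov)
    if vals[0] >= eps:
        return cov
    vals = np.maximum(vals, eps)
    return (vecs * vals) @ vecs.T


def _log_density(X: np.ndarray, model: MixtureModel) -> np.ndarray:
    """Per-point, per-component log(tau_k * phi_k(x)); (n, G)."""
    n = X.shape[0]
    out = np.empty((n, model.G))
    for k in range(model.G):
        out[:, k] = np.log(model.tau[k]) + multivariate_normal.logpdf(
            X, mean=model.means[k], cov=model.covs[k], allow_singular=True)
    return out


def log_likelihood(X: np.ndarray, model: MixtureModel) -> float:
    """Observed-data log likelihood sum_i log sum_k tau_k phi_k(x_i)."""
    X = np.asarray(X, dtype=float)
    return float(logsumexp(_log_density(X, model), axis=1).sum())


def e_step(X: np.ndarray, model: MixtureModel) -> np.ndarray:
    """Responsibility matrix z (n, G); rows sum to 1.

    Computed in log space; if every component underflows at a point the row
    falls back to uniform (counted and logged)."""
    X = np.asarray(X, dtype=float)
    logd = _log_density(X, model)
    norm = logsumexp(logd, axis=1, keepdims=True)
    degenerate = ~np.isfinite(norm[:, 0])
    z = np.exp(logd - np.where(np.isfinite(norm), norm, 0.0))
    if degenerate.any():
        logger.warning("e_step: %d degenerate points set to uniform "
                       "responsibilities", int(degenerate.sum()))
        z[degenerate] = 1.0 / model.G
    return z


def m_step(
    X: np.ndarray,
    responsibilities: np.ndarray,
    ridge: float | None = None,
) -> MixtureModel:
    """Weighted-moment update; collapsed components are re-seeded from the
    point of highest uncertainty."""
    X = np.asarray(X, dtype=float)
    z = np.asarray(responsibilities, dtype=float)
    n, G = z.shape
    eps = _ridge(X, ridge)
    nk = z.sum(axis=0)
    tau = np.empty(G)
    means = np.empty((G, X.shape[1]))
    covs = np.empty((G, X.shape[1], X.shape[1]))
    global_cov = np.cov(X, rowvar=False, ddof=0) if n > 1 else np.eye(2)
    for k in range(G):
        if nk[k] < 1e-10:
            idx = int(np.argmax(1.0 - z.max(axis=1)))
            logger.warning("m_step: component %d collapsed; re-seeding from "
                           "point %d", k, idx)
            tau[k] = 1.0 / n
            means[k] = X[idx]
            covs[k] = _clamp_cov(np.atleast_2d(global_cov), eps)
            continue
        tau[k] = nk[k] / n
        means[k] = z[:, k] @ X / nk[k]
        diff = X - means[k]
        covs[k] = _clamp_cov((z[:, k, None] * diff).T @ diff / nk[k], eps)
    tau = tau / tau.sum()
    return MixtureModel(tau=tau, means=means, covs=covs)


def _quantile_init(X: np.ndarray, G: int, ridge: float | None) -> MixtureModel:
    """Deterministic initialization: points sorted by the second feature
    (the depth-like axis) are split into G equal groups whose moments seed
    the components."""
    n = X.shape[0]
    eps = _ridge(X, ridge)
    order = np.argsort(X[:, 1], kind="stable")
    groups = np.array_split(order, G)
    tau = np.array([len(g) / n for g in groups])
    means = np.vstack([X[g].mean(axis=0) for g in groups])
    covs = np.stack([
        _clamp_cov(
            np.cov(X[g], rowvar=False, ddof=0) if len(g) > 1
            else np.zeros((X.shape[1], X.shape[1])), eps)
        for g in groups
    ])
    return MixtureModel(tau=tau, means=means, covs=covs)


def _run_em(
    X: np.ndarray,
    model: MixtureModel,
    tol: float,
    max_iter: int,
    ridge: float | None,
) -> MixtureModel:
    ll_old = log_likelihood(X, model)
    history = [ll_old]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = e_step(X, model)
        model = m_step(X, z, ridge=ridge)
        ll = log_likelihood(X, model)
        if ll < ll_old - 1e-9 * max(1.0, abs(ll_old)):
            # EM is monotone up to the covariance ridge; anything beyond
            # that tolerance indicates a numerical problem
            logger.warning("EM log-likelihood decreased: %.6g -> %.6g",
                           ll_old, ll)
        history.append(ll)
        rel = (ll - ll_old) / max(abs(ll_old), 1e-300)
        ll_old = ll
        if rel < tol:
            converged = True
            break
    model.history = history
    model.n_iter = it
    model.converged = converged
    return model


def fit_em(
    X: np.ndarray,
    G: int,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    restarts: int = 0,
    ridge: float | None = None,
) -> MixtureModel:
    """Fit a G-component mixture by EM from the deterministic quantile
    initialization; convergence when the relative log-likelihood improvement
    drops below ``tol``.

    ``restarts`` adds seeded random restarts (means drawn from the data,
    pooled covariance) keeping the best final log-likelihood.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n points x 2 features)")
    if not np.isfinite(X).all():
        bad = int(np.argwhere(~np.isfinite(X).all(axis=1))[0][0])
        raise ValueError(f"non-finite feature vector at index {bad}")
    if X.shape[0] < G:
        raise ValueError(
            f"too few candidates: n={X.shape[0]} < G={G}")
    best = _run_em(X, _quantile_init(X, G, ridge), tol, max_iter, ridge)
    if restarts:
        rng = np.random.default_rng(seed)
        eps = _ridge(X, ridge)
        pooled = _clamp_cov(np.cov(X, rowvar=False, ddof=0), eps)
        for _ in range(restarts):
            idx = rng.choice(X.shape[0], size=G, replace=False)
            init = MixtureModel(
                tau=np.full(G, 1.0 / G),
                means=X[idx].astype(float).copy(),
                covs=np.stack([pooled.copy() for _ in range(G)]),
            )
            cand = _run_em(X, init, tol, max_iter, ridge)
            if cand.history[-1] > best.history[-1]:
                best = cand
    return best


def label_components(model: MixtureModel, sv_type: str) -> dict[int, str]:
    """Map component indices to biological labels from their mean features.

    Deletions (features: discordant count, concordant depth): the component
    with the lowest mean depth is the homozygous deletion (both haplotypes
    gone, depth ~0); of the rest, the one with the higher depth (ties: lower
    discordant count, then lower index) is the normal region; the remaining
    component, at roughly half depth, is the heterozygous deletion.
    Inversions (features f1, f2): higher mean f1 (ties: f2, then index) is
    the inversion component.
    """
    means = model.means
    if sv_type == "DEL":
        if model.G != 3:
            raise ValueError("deletion labeling requires G=3")
        if len({tuple(m) for m in map(tuple, means)}) < 3:
            logger.warning("identical component means; labels assigned by "
                           "component index")
        hom = int(np.lexsort((np.arange(3), means[:, 0], means[:, 1]))[0])
        rest = [k for k in range(3) if k != hom]
        # normal region: higher depth, tie-broken by lower discordant count
        a, b = rest
        if (means[a, 1], -means[a, 0], -a) >= (means[b, 1], -means[b, 0], -b):
            normal, het = a, b
        else:
            normal, het = b, a
        return {hom: "HOM_DEL", het: "HET_DEL", normal: "NORMAL"}
    if sv_type == "INV":
        if model.G != 2:
            raise ValueError("inversion labeling requires G=2")
        if np.array_equal(means[0], means[1]):
            logger.warning("identical component means; labels assigned by "
                           "component index")
        a, b = 0, 1
        if (means[a, 0], means[a, 1], -a) >= (means[b, 0], means[b, 1], -b):
            inv, normal = a, b
        else:
            inv, normal = b, a
        return {inv: "INV", normal: "NORMAL"}
    raise ValueError(f"unknown sv_type: {sv_type!r}")


def classify(
    X: np.ndarray,
    model: MixtureModel,
    label_map: dict[int, str],
) -> list[Assignment]:
    """Per-point responsibilities, argmax label, and uncertainty = 1 - max
    membership probability."""
    z = e_step(np.asarray(X, dtype=float), model)
    out = []
    for row in z:
        k = int(np.argmax(row))
        out.append(Assignment(
            responsibilities=row,
            label=label_map[k],
            uncertainty=float(1.0 - row[k]),
        ))
    return out


def bic(X: np.ndarray, model: MixtureModel) -> float:
    """Bayesian Information Criterion, 2*logL - p*log(n) (higher is
    better); reporting utility only — the caller always uses the
    unrestricted-covariance model."""
    X = np.asarray(X, dtype=float)
    n, dim = X.shape
    G = model.G
    p = (G - 1) + G * dim + G * dim * (dim + 1) // 2
    return 2.0 * log_likelihood(X, model) - p * np.log(n)
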
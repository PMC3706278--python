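"""Likelihood Score Statistic: penalized phylogenetic GLS at one SNP.

For a partition of the ``n`` haplotype tips into ``k`` clusters with design
matrix D and tree covariance V, trait values are modelled as

    Y ~ N(D mu, sigma^2 V)

with closed-form maximum-likelihood estimates

    mu_hat    = (D' V^-1 D)^-1 D' V^-1 Y
    sigma2hat = (Y - D mu_hat)' V^-1 (Y - D mu_hat) / n.

The score of the tree is the BIC-style penalized log-likelihood maximised
over cluster counts,

    LSS = max_k { 2 ln L(mu_hat, sigma2hat | Y, V_k) - k ln(n) },

penalizing the k cluster means (sigma^2 is left unpenalized).  ``n`` counts
haplotype tips, i.e. twice the number of diploid individuals; each
individual's trait value appears on both of its tips.  The independence
baseline replaces V by the identity (cluster means with iid errors), the
assumption made by QBlossoc-style scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .covariance import ClusterPartition, cluster_partition, clustered_covariance, k_available
from .local_tree import LocalTree

__all__ = [
    "DegenerateTraitError",
    "LssResult",
    "design_matrix",
    "gls_estimates",
    "log_likelihood",
    "lss",
    "independence_score",
    "score_profile",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class DegenerateTraitError(ValueError):
    """Raised for constant trait vectors (no variance to model)."""


@dataclass
class LssResult:
    """Penalized score of one local tree, maximised over cluster counts."""

    score: float
    best_k: int
    per_k_scores: np.ndarray
    mu_hat: np.ndarray
    sigma2_hat: float


def design_matrix(partition: ClusterPartition, n: int) -> np.ndarray:
    """n x k indicator matrix: D[i, j] = 1 iff tip i falls in cluster j+1."""
    if partition.assignment.shape[0] != n:
        raise ValueError("partition does not cover n tips")
    D = np.zeros((n, partition.k))
    D[np.arange(n), partition.assignment - 1] = 1.0
    return D


def gls_estimates(Y: np.ndarray, D: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, float]:
    """Closed-form GLS maximum-likelihood estimates (mu_hat, sigma2_hat)."""
    Y = np.asarray(Y, dtype=np.float64)
    n = Y.shape[0]
    c = cho_factor(V, lower=True)
    ViD = cho_solve(c, D)
    A = D.T @ ViD
    b = ViD.T @ Y
    try:
        mu_hat = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        raise ValueError("degenerate clustering: singular D' V^-1 D") from None
    r = Y - D @ mu_hat
    sigma2_hat = float(r @ cho_solve(c, r)) / n
    return mu_hat, sigma2_hat


def log_likelihood(
    Y: np.ndarray, D: np.ndarray, V: np.ndarray, mu_hat: np.ndarray, sigma2_hat: float
) -> float:
    """Multivariate-normal log-likelihood at (mu_hat, sigma2_hat).

    ln L = -(n/2) ln(2 pi) - (n/2) ln sigma2 - (1/2) ln det V
           - (1/2 sigma2) (Y - D mu)' V^-1 (Y - D mu);
    at the MLE the quadratic form equals n.
    """
    Y = np.asarray(Y, dtype=np.float64)
    n = Y.shape[0]
    c = cho_factor(V, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    r = Y - D @ mu_hat
    quad = float(r @ cho_solve(c, r))
    return -0.5 * n * _LOG_2PI - 0.5 * n * np.log(sigma2_hat) - 0.5 * logdet - 0.5 * quad / sigma2_hat


def score_profile(
    tree: LocalTree, Ymat: np.ndarray, kmax: int, identity: bool = False
) -> np.ndarray:
    """Penalized scores 2 lnL - k ln(n) for k = 1..min(kmax, k_avail).

    Vectorised over trait vectors: ``Ymat`` is ``n x m`` (columns are trait
    vectors sharing the tree, e.g. observed + permuted) and the result is
    ``n_k x m``.  With ``identity=True`` the tree covariance is replaced by
    the identity matrix (independence baseline).
    """
    Ymat = np.atleast_2d(np.asarray(Ymat, dtype=np.float64))
    if Ymat.ndim != 2:
        raise ValueError("Ymat must be n x m")
    n, m = Ymat.shape
    if n != tree.n_tips:
        raise ValueError("trait vectors must have one value per tip")
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    n_k = min(kmax, k_available(tree))
    scores = np.empty((n_k, m))
    log_n = np.log(n)
    for k in range(1, n_k + 1):
        part = cluster_partition(tree, k)
        D = design_matrix(part, n)
        if identity:
            ViY, ViD = Ymat, D
            logdet = 0.0
        else:
            V = clustered_covariance(tree, part)
            c = cho_factor(V, lower=True)
            logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
            ViY = cho_solve(c, Ymat)
            ViD = cho_solve(c, D)
        quad = np.einsum("ij,ij->j", Ymat, ViY)
        A = D.T @ ViD                      # k x k
        B = ViD.T @ Ymat                   # k x m  (= D' V^-1 Y)
        mu = np.linalg.solve(A, B)
        rss = quad - np.einsum("ij,ij->j", B, mu)  # (Y - D mu)' V^-1 (Y - D mu)
        sigma2 = rss / n
        if np.any(sigma2 <= 0):
            raise DegenerateTraitError("degenerate trait: zero residual variance")
        two_lnl = -n * _LOG_2PI - n * np.log(sigma2) - logdet - n
        scores[k - 1] = two_lnl - k * log_n
    return scores


def _lss_impl(Y: np.ndarray, tree: LocalTree, kmax: int, identity: bool) -> LssResult:
    Y = np.asarray(Y, dtype=np.float64)
    if np.ptp(Y) == 0:
        raise DegenerateTraitError("degenerate trait: constant values")
    per_k = score_profile(tree, Y[:, None], kmax, identity=identity)[:, 0]
    best_k = int(np.argmax(per_k)) + 1  # argmax returns the smallest k on ties
    part = cluster_partition(tree, best_k)
    D = design_matrix(part, len(Y))
    V = np.eye(len(Y)) if identity else clustered_covariance(tree, part)
    mu_hat, sigma2_hat = gls_estimates(Y, D, V)
    return LssResult(
        score=float(per_k[best_k - 1]),
        best_k=best_k,
        per_k_scores=per_k,
        mu_hat=mu_hat,
        sigma2_hat=sigma2_hat,
    )


def lss(Y: np.ndarray, tree: LocalTree, kmax: int = 15) -> LssResult:
    """Likelihood Score Statistic of a local tree for trait vector ``Y``."""
    return _lss_impl(Y, tree, kmax, identity=False)


def independence_score(Y: np.ndarray, tree: LocalTree, kmax: int = 15) -> LssResult:
    """Baseline score with V = I (independent, common-variance errors)."""
    return _lss_impl(Y, tree, kmax, identity=True)
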
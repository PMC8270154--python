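"""Penalized and marginal Gaussian log-likelihoods and information criteria.

Two objective functions drive the boosting algorithm:

* the *penalized* log-likelihood — the conditional Gaussian log-density of
  the responses given the random effects, minus the quadratic ridge penalty
  ``1/2 sum_i gamma_i' Q^{-1} gamma_i`` arising from the Laplace
  approximation of the random-effects integral (exact here, the model being
  Gaussian);
* the *marginal* log-likelihood — the random effects integrated out, so each
  cluster contributes a multivariate normal density with covariance
  ``V_i = Z_i Q Z_i' + sigma^2 I``.

AIC/BIC use ``-2 * loglik + penalty * df`` with model complexity
``df = #phi + #{nonzero beta}`` where ``#phi = 1 + q(q+1)/2`` counts the
variance-covariance parameters (sigma^2 plus the unique entries of Q).
The marginal likelihood is the default inside the criteria — it is free of
gamma, which keeps the component comparison in the selection step fair;
the conditional variant is available as a sensitivity switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .data_model import LMMData, NumericError

__all__ = [
    "ParamState",
    "ICValue",
    "penalized_loglik",
    "marginal_loglik",
    "conditional_loglik",
    "information_criterion",
]

logger = logging.getLogger("lbblmm")

# condition number beyond which Q is regularized before inversion
_Q_COND_LIMIT = 1e12
_Q_RIDGE = 1e-10


@dataclass
class ParamState:
    """Current iterate of the boosting algorithm.

    Attributes
    ----------
    beta0 : intercept.
    beta : (p,) fixed effects; unselected coordinates are exactly zero.
    gamma : (n*q,) stacked random effects, cluster-major
        (gamma_1', ..., gamma_n').
    sigma2 : model-error variance, > 0.
    Q : (q, q) random-effects covariance, symmetric positive semi-definite.
    """

    beta0: float
    beta: np.ndarray
    gamma: np.ndarray
    sigma2: float
    Q: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    def copy(self) -> "ParamState":
        return replace(
            self,
            beta=self.beta.copy(),
            gamma=self.gamma.copy(),
            Q=self.Q.copy(),
        )

    def eta(self, data: LMMData) -> np.ndarray:
        """Linear predictor beta0 + X beta + Z gamma (row-wise)."""
        g = self.gamma.reshape(data.n, data.q)
        out = self.beta0 + data.X @ self.beta
        out += np.einsum("ij,ij->i", data.Z, g[data.cluster_index])
        return out


@dataclass
class ICValue:
    """An information-criterion evaluation with its complexity count."""

    kind: str  # "AIC" | "BIC"
    value: float
    df: int


def q_inverse(Q: np.ndarray) -> np.ndarray:
    """Symmetric inverse of Q with a ridge fallback near singularity."""
    Q = np.atleast_2d(Q)
    try:
        cond = np.linalg.cond(Q)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > _Q_COND_LIMIT:
        eps = _Q_RIDGE * np.trace(Q) / Q.shape[0]
        if eps <= 0:
            eps = _Q_RIDGE
        logger.warning(
            "Q ill-conditioned (cond=%.3g); adding ridge %.3g", cond, eps
        )
        Q = Q + eps * np.eye(Q.shape[0])
    inv = np.linalg.inv(Q)
    return 0.5 * (inv + inv.T)


# ---------------------------------------------------------------------------
# cluster grouping and marginal-covariance factorizations
# ---------------------------------------------------------------------------


@dataclass
class _Group:
    """Clusters of identical size, gathered for batched linear algebra."""

    size: int
    clusters: np.ndarray  # (c,) cluster positions
    rows: np.ndarray  # (c, size) row indices into the stacked arrays


def cluster_groups(data: LMMData) -> list[_Group]:
    """Group clusters by size so per-cluster solves can be batched."""
    if "groups" not in data._cache:
        sizes = data.cluster_sizes
        starts = data.cluster_starts[:-1]
        groups = []
        for k in np.unique(sizes):
            sel = np.flatnonzero(sizes == k)
            rows = starts[sel][:, None] + np.arange(k)[None, :]
            groups.append(_Group(size=int(k), clusters=sel, rows=rows))
        data._cache["groups"] = groups
    return data._cache["groups"]


class MarginalFactor:
    """Cholesky factorizations of the cluster covariances V_i.

    ``V_i = Z_i Q Z_i' + sigma^2 I`` is factorized once per (sigma2, Q) and
    reused for log-determinants, quadratic forms and multi-RHS solves —
    (sigma2, Q) are constant across the p candidate evaluations of one
    boosting iteration.
    """

    def __init__(self, data: LMMData, sigma2: float, Q: np.ndarray) -> None:
        self.data = data
        self.sigma2 = float(sigma2)
        self.Q = np.atleast_2d(Q)
        self._blocks: list[tuple[_Group, np.ndarray]] = []
        logdet = 0.0
        for g in cluster_groups(data):
            Zk = data.Z[g.rows]  # (c, k, q)
            V = Zk @ self.Q @ Zk.transpose(0, 2, 1)
            V[:, np.arange(g.size), np.arange(g.size)] += self.sigma2
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError as exc:
                raise NumericError(
                    "cluster covariance V_i not positive definite "
                    f"(cluster size {g.size})"
                ) from exc
            logdet += 2.0 * float(
                np.sum(np.log(L[:, np.arange(g.size), np.arange(g.size)]))
            )
            self._blocks.append((g, L))
        self.logdet = logdet

    def solve(self, M: np.ndarray) -> np.ndarray:
        """Blockwise V^{-1} M for stacked (N,) or (N, r) arrays."""
        M = np.asarray(M, dtype=float)
        vec = M.ndim == 1
        if vec:
            M = M[:, None]
        out = np.empty_like(M)
        for g, L in self._blocks:
            rhs = M[g.rows]  # (c, k, r)
            w = np.linalg.solve(
                L.transpose(0, 2, 1), np.linalg.solve(L, rhs)
            )
            out[g.rows.reshape(-1)] = w.reshape(-1, M.shape[1])
        return out[:, 0] if vec else out

    def quad(self, resid: np.ndarray) -> float:
        """r' V^{-1} r for a stacked residual r."""
        return float(resid @ self.solve(resid))

    def loglik(self, resid: np.ndarray) -> float:
        """Gaussian log-density sum_i log N(r_i; 0, V_i)."""
        N = self.data.N
        return -0.5 * (N * np.log(2.0 * np.pi) + self.logdet + self.quad(resid))


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------


def penalized_loglik(state: ParamState, data: LMMData) -> float:
    """Conditional Gaussian log-likelihood minus the random-effects penalty.

    Returns ``sum_i log f(y_i | theta, phi) - 1/2 sum_i gamma_i' Q^{-1}
    gamma_i`` with f the N(eta_i, sigma^2 I) density.
    """
    resid = data.y - state.eta(data)
    N = data.N
    ll = -0.5 * (
        N * np.log(2.0 * np.pi * state.sigma2)
        + float(resid @ resid) / state.sigma2
    )
    g = state.gamma.reshape(data.n, data.q)
    Qinv = q_inverse(state.Q)
    penalty = 0.5 * float(np.einsum("ij,jk,ik->", g, Qinv, g))
    out = ll - penalty
    if not np.isfinite(out):
        per_cluster = np.add.reduceat(resid**2, data.cluster_starts[:-1])
        bad = int(np.flatnonzero(~np.isfinite(per_cluster))[0]) if np.any(
            ~np.isfinite(per_cluster)
        ) else -1
        raise NumericError(
            f"non-finite penalized log-likelihood (cluster {bad})"
        )
    return out


def conditional_loglik(state: ParamState, data: LMMData) -> float:
    """Conditional Gaussian log-likelihood sum_i log f(y_i | theta, phi)."""
    resid = data.y - state.eta(data)
    N = data.N
    return -0.5 * (
        N * np.log(2.0 * np.pi * state.sigma2)
        + float(resid @ resid) / state.sigma2
    )


def marginal_loglik(state: ParamState, data: LMMData) -> float:
    """Marginal Gaussian log-likelihood with the random effects integrated out.

    ``sum_i log N(y_i; beta0 1 + X_i beta, V_i)`` with
    ``V_i = Z_i Q Z_i' + sigma^2 I``; gamma does not enter.
    """
    factor = MarginalFactor(data, state.sigma2, state.Q)
    resid = data.y - state.beta0 - data.X @ state.beta
    return factor.loglik(resid)


def n_variance_parameters(q: int) -> int:
    """#phi = 1 (sigma^2) + q(q+1)/2 (unique entries of Q)."""
    return 1 + q * (q + 1) // 2


def model_df(state: ParamState, data: LMMData) -> int:
    """Model complexity df = #phi + #{i <= p : beta_i != 0}."""
    return n_variance_parameters(data.q) + int(np.count_nonzero(state.beta))


def information_criterion(
    state: ParamState,
    data: LMMData,
    kind: str = "BIC",
    likelihood: str = "marginal",
) -> ICValue:
    """AIC or BIC of the current state.

    ``-2 * loglik + 2 * df`` (AIC) or ``-2 * loglik + log(n) * df`` (BIC),
    with n the number of clusters. ``likelihood`` selects the marginal
    (default) or conditional Gaussian log-likelihood.
    """
    kind = kind.upper()
    if kind not in ("AIC", "BIC"):
        raise ValueError(f"unknown criterion {kind!r}")
    if likelihood == "marginal":
        ll = marginal_loglik(state, data)
    elif likelihood == "conditional":
        ll = conditional_loglik(state, data)
    else:
        raise ValueError(f"unknown likelihood {likelihood!r}")
    df = model_df(state, data)
    penalty = 2.0 * df if kind == "AIC" else np.log(data.n) * df
    return ICValue(kind=kind, value=-2.0 * ll + penalty, df=df)
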
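"""Component-wise likelihood-based boosting for linear mixed models.

Each iteration runs three steps:

1. **Fixed effects.** For every candidate covariate r, a Fisher-scoring
   update of the pair (intercept, beta_r) is computed from the score
   ``s_r = sigma^-2 Xr~'(y - eta)`` and Fisher matrix
   ``F_r = sigma^-2 Xr~' Xr~`` with ``Xr~ = [1, x_r]``; sigma^2 cancels in
   ``F_r^{-1} s_r``, so the update is the least-squares regression of the
   current residual on (1, x_r). The candidate whose (damped) update yields
   the smallest AIC/BIC is applied — only that coordinate moves, scaled by
   the step length nu, which produces sparse coefficient paths and implicit
   variable selection.
2. **Random effects.** A single weak Fisher step on the penalized
   log-likelihood, whose Fisher matrix is block-diagonal with blocks
   ``F_i = sigma^-2 Z_i' Z_i + Q^{-1}`` (one small q x q solve per cluster),
   followed by the orthogonal-projection correction so the cluster-level
   coefficients stay uncorrelated with the cluster-constant covariates.
3. **Variance components.** An approximate EM refresh
   ``Q_hat = 1/n sum_i (F_i^{-1} + gamma_i gamma_i')`` using the posterior
   curvatures, and ``sigma2_hat = Var(y - eta)``.

The run is stopped in retrospect at the iteration m* minimizing the chosen
information criterion along the path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corrections import CorrectionOperator, apply_correction, build_correction
from .data_model import DataError, LMMData, NumericError, classify_covariates
from .likelihood import (
    ICValue,
    MarginalFactor,
    ParamState,
    cluster_groups,
    information_criterion,
    n_variance_parameters,
    q_inverse,
)

__all__ = [
    "BoostConfig",
    "CandidateUpdate",
    "FitResult",
    "initialize",
    "candidate_update",
    "select_and_apply",
    "random_effects_step",
    "update_variance_components",
    "fit",
]

logger = logging.getLogger("lbblmm")

# relative determinant threshold below which a candidate's 2x2 normal
# equations are treated as collinear and the candidate is skipped
_COLLINEAR_RTOL = 1e-12

# spectral-norm clipping beyond this triggers a warning in the PSD projection
_PSD_CLIP_WARN = 1e-8


@dataclass
class BoostConfig:
    """Tuning knobs of the boosting run.

    Attributes
    ----------
    m_stop : maximum number of iterations (the path is always run to m_stop;
        the returned estimate is taken at the IC-optimal iteration).
    nu : step length in (0, 1] damping every fixed- and random-effects
        update; 0.1 is the established weak-learner choice.
    criterion : "AIC" or "BIC", used both for component selection and
        stopping.
    start_mode : "simple" (zero effects, moment starting values) or
        "premodel" (intercept-plus-random-effects mixed model fitted by an
        internal EM, providing beta0, gamma, sigma2, Q).
    seed : reserved for stochastic tie-breaking; the default algorithm is
        fully deterministic and never draws from it.
    ic_likelihood : "marginal" (default) or "conditional" likelihood inside
        the information criteria.
    center_intercept : include a ones column in the random intercept's
        correction space (see :mod:`lbblmm.corrections`).
    """

    m_stop: int = 1500
    nu: float = 0.1
    criterion: str = "BIC"
    start_mode: str = "simple"
    seed: int | None = None
    ic_likelihood: str = "marginal"
    center_intercept: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.nu <= 1:
            raise ValueError("nu must lie in (0, 1]")
        if self.m_stop < 1:
            raise ValueError("m_stop must be >= 1")
        self.criterion = self.criterion.upper()
        if self.criterion not in ("AIC", "BIC"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.start_mode not in ("simple", "premodel"):
            raise ValueError(f"unknown start_mode {self.start_mode!r}")


@dataclass
class CandidateUpdate:
    """One fixed-effect candidate: index, raw update and hypothetical IC."""

    r: int
    u: np.ndarray  # (u0, u_r)
    ic: ICValue


@dataclass
class FitResult:
    """Coefficient paths, IC path and the IC-optimal stopping point.

    Paths are indexed by iteration m = 1..M (M <= m_stop when the run was
    truncated by a numerical failure); the starting values are kept in
    ``initial_state``. ``m_star`` is the 1-based argmin of ``ic_path`` and
    the reported estimates (``state``, ``beta`` etc.) are the snapshot at
    m_star.
    """

    covariate_names: list[str]
    criterion: str
    initial_state: ParamState
    beta0_path: np.ndarray
    beta_path: np.ndarray
    sigma2_path: np.ndarray
    Q_path: np.ndarray
    gamma_path: np.ndarray
    ic_path: np.ndarray
    df_path: np.ndarray
    selected_path: np.ndarray
    truncated: bool = False

    @property
    def n_iterations(self) -> int:
        return len(self.ic_path)

    @property
    def m_star(self) -> int:
        """IC-optimal stopping iteration (1-based)."""
        return int(np.argmin(self.ic_path)) + 1

    def state_at(self, m: int) -> ParamState:
        """Snapshot of the parameters after iteration m (m=0: start)."""
        if m == 0:
            return self.initial_state.copy()
        i = m - 1
        return ParamState(
            beta0=float(self.beta0_path[i]),
            beta=self.beta_path[i].copy(),
            gamma=self.gamma_path[i].copy(),
            sigma2=float(self.sigma2_path[i]),
            Q=self.Q_path[i].copy(),
        )

    @property
    def state(self) -> ParamState:
        return self.state_at(self.m_star)

    @property
    def beta0(self) -> float:
        return float(self.beta0_path[self.m_star - 1])

    @property
    def beta(self) -> np.ndarray:
        return self.beta_path[self.m_star - 1]

    @property
    def sigma2(self) -> float:
        return float(self.sigma2_path[self.m_star - 1])

    @property
    def Q(self) -> np.ndarray:
        return self.Q_path[self.m_star - 1]

    @property
    def gamma(self) -> np.ndarray:
        return self.gamma_path[self.m_star - 1]

    @property
    def selected_covariates(self) -> list[str]:
        """Names of covariates with a nonzero coefficient at m_star."""
        return [
            name
            for name, b in zip(self.covariate_names, self.beta)
            if b != 0.0
        ]

    def path_frame(self) -> pd.DataFrame:
        """Coefficient path as a table (iteration 0 = starting values)."""
        q = self.Q_path.shape[1]
        iu = np.triu_indices(q)
        rows = []
        states = [self.initial_state] + [
            self.state_at(m) for m in range(1, self.n_iterations + 1)
        ]
        ics = np.concatenate([[np.nan], self.ic_path])
        sel = np.concatenate([[-1], self.selected_path])
        for m, st in enumerate(states):
            row = {"iteration": m, "beta0": st.beta0}
            for name, b in zip(self.covariate_names, st.beta):
                row[f"beta_{name}"] = b
            row["sigma2"] = st.sigma2
            for a, b in zip(*iu):
                row[f"Q_{a + 1}{b + 1}"] = st.Q[a, b]
            row[self.criterion] = ics[m]
            row["selected"] = (
                self.covariate_names[int(sel[m])] if sel[m] >= 0 else ""
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "lbbLMM fit",
            f"  iterations run : {self.n_iterations}"
            + (" (truncated)" if self.truncated else ""),
            f"  stopping (m*)  : {self.m_star} by {self.criterion} "
            f"= {self.ic_path[self.m_star - 1]:.3f}",
            f"  intercept      : {self.beta0:.6g}",
            f"  selected       : {', '.join(self.selected_covariates) or '-'}",
        ]
        for name in self.selected_covariates:
            i = self.covariate_names.index(name)
            lines.append(f"    beta[{name}] = {self.beta[i]:.6g}")
        lines.append(f"  sigma^2        : {self.sigma2:.6g}")
        lines.append("  Q              : " + np.array2string(self.Q, precision=4))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------


def _premodel_start(data: LMMData, max_iter: int = 500, tol: float = 1e-9
                    ) -> ParamState:
    """EM fit of the intercept-plus-random-effects model y = b0 + Z gamma + e."""
    y = data.y
    n, N, q = data.n, data.N, data.q
    beta0 = float(y.mean())
    sigma2 = float(y.var(ddof=1))
    Q = 0.1 * np.eye(q)
    gamma = np.zeros((n, q))
    groups = cluster_groups(data)
    for _ in range(max_iter):
        Qinv = q_inverse(Q)
        resid0 = y - beta0
        Qsum = np.zeros((q, q))
        trace_term = 0.0
        gamma_new = np.empty_like(gamma)
        for g in groups:
            Zk = data.Z[g.rows]
            rk = resid0[g.rows]
            F = np.einsum("ckq,ckr->cqr", Zk, Zk) / sigma2 + Qinv
            Finv = np.linalg.inv(F)
            rhs = np.einsum("ckq,ck->cq", Zk, rk) / sigma2
            gk = np.einsum("cqr,cr->cq", Finv, rhs)
            gamma_new[g.clusters] = gk
            Qsum += Finv.sum(axis=0) + np.einsum("cq,cr->qr", gk, gk)
            trace_term += float(np.einsum("ckq,cqr,ckr->", Zk, Finv, Zk))
        gamma = gamma_new
        Zg = np.einsum("ij,ij->i", data.Z, gamma[data.cluster_index])
        beta0_new = float((y - Zg).mean())
        resid = y - beta0_new - Zg
        sigma2_new = (float(resid @ resid) + trace_term) / N
        Q_new = Qsum / n
        delta = (
            abs(beta0_new - beta0)
            + abs(sigma2_new - sigma2)
            + float(np.abs(Q_new - Q).max())
        )
        beta0, sigma2, Q = beta0_new, max(sigma2_new, 1e-12), Q_new
        if delta < tol:
            break
    return ParamState(
        beta0=beta0,
        beta=np.zeros(data.p),
        gamma=gamma.reshape(-1),
        sigma2=sigma2,
        Q=Q,
    )


def initialize(data: LMMData, config: BoostConfig) -> ParamState:
    """Starting values: the selectable effects beta are always zero.

    simple mode uses moment starts (beta0 = mean(y), sigma2 = Var(y),
    gamma = 0, Q = 0.1 I); premodel mode extracts (beta0, gamma, sigma2, Q)
    from an intercept-plus-random-effects mixed model fitted internally.
    """
    var_y = float(data.y.var(ddof=1)) if data.N > 1 else 0.0
    if var_y <= 0:
        raise DataError("response has zero variance")
    if config.start_mode == "premodel":
        return _premodel_start(data)
    return ParamState(
        beta0=float(data.y.mean()),
        beta=np.zeros(data.p),
        gamma=np.zeros(data.n * data.q),
        sigma2=var_y,
        Q=0.1 * np.eye(data.q),
    )


# ---------------------------------------------------------------------------
# step 1: fixed effects
# ---------------------------------------------------------------------------


def _design_moments(data: LMMData) -> tuple[np.ndarray, np.ndarray]:
    """Cached column sums and squared-column sums of X."""
    if "moments" not in data._cache:
        data._cache["moments"] = (data.X.sum(axis=0), (data.X**2).sum(axis=0))
    return data._cache["moments"]


def _all_candidate_updates(
    state: ParamState, data: LMMData
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw Fisher updates (u0, u_r) for every candidate, vectorized.

    Returns (u0, ur, admissible); sigma^2 cancels in F_r^{-1} s_r so the
    update is the OLS fit of the current residual on (1, x_r).
    """
    sx, sxx = _design_moments(data)
    N = data.N
    resid = data.y - state.eta(data)
    s0 = float(resid.sum())
    s1 = data.X.T @ resid
    det = N * sxx - sx**2
    admissible = det > _COLLINEAR_RTOL * np.maximum(N * sxx, 1.0)
    ur = np.zeros(data.p)
    with np.errstate(divide="ignore", invalid="ignore"):
        ur[admissible] = (
            N * s1[admissible] - sx[admissible] * s0
        ) / det[admissible]
    u0 = (s0 - sx * ur) / N
    return u0, ur, admissible


def candidate_update(
    r: int,
    state: ParamState,
    data: LMMData,
    nu: float = 0.1,
    criterion: str = "BIC",
    ic_likelihood: str = "marginal",
) -> CandidateUpdate:
    """Fisher update of (intercept, beta_r) and the IC after applying nu*u."""
    if not 0 <= r < data.p:
        raise IndexError(f"candidate index {r} out of range")
    u0, ur, admissible = _all_candidate_updates(state, data)
    if not admissible[r]:
        raise NumericError(
            f"candidate {data.covariate_names[r]!r} collinear with the "
            "intercept"
        )
    trial = state.copy()
    trial.beta0 += nu * u0[r]
    trial.beta[r] += nu * ur[r]
    ic = information_criterion(trial, data, criterion, ic_likelihood)
    return CandidateUpdate(r=r, u=np.array([u0[r], ur[r]]), ic=ic)


def _candidate_ics(
    state: ParamState,
    data: LMMData,
    u0: np.ndarray,
    ur: np.ndarray,
    admissible: np.ndarray,
    config: BoostConfig,
) -> np.ndarray:
    """Information criteria of all hypothetical updates, vectorized.

    The per-candidate quadratic form is expanded around the current marginal
    residual so that one multi-RHS solve against the (iteration-constant)
    cluster covariances serves all p candidates.
    """
    nu = config.nu
    N, n = data.N, data.n
    a = nu * u0
    b = nu * ur
    nnz_base = int(np.count_nonzero(state.beta))
    enters = (state.beta == 0.0) & (b != 0.0)
    df = n_variance_parameters(data.q) + nnz_base + enters.astype(int)
    if config.ic_likelihood == "marginal":
        factor = MarginalFactor(data, state.sigma2, state.Q)
        rb = data.y - state.beta0 - data.X @ state.beta
        rhs = np.column_stack([rb, np.ones(N), data.X])
        W = factor.solve(rhs)
        wr, w1, WX = W[:, 0], W[:, 1], W[:, 2:]
        S_rr = float(rb @ wr)
        S_r1 = float(rb @ w1)
        S_11 = float(w1.sum())
        S_rx = rb @ WX
        S_1x = WX.sum(axis=0)
        S_xx = np.einsum("ij,ij->j", data.X, WX)
        quad = (
            S_rr
            - 2.0 * (a * S_r1 + b * S_rx)
            + a**2 * S_11
            + 2.0 * a * b * S_1x
            + b**2 * S_xx
        )
        m2ll = N * np.log(2.0 * np.pi) + factor.logdet + quad
    else:
        e = data.y - state.eta(data)
        sx, sxx = _design_moments(data)
        se = float(e.sum())
        sxe = data.X.T @ e
        ssq = (
            float(e @ e)
            - 2.0 * (a * se + b * sxe)
            + a**2 * N
            + 2.0 * a * b * sx
            + b**2 * sxx
        )
        m2ll = N * np.log(2.0 * np.pi * state.sigma2) + ssq / state.sigma2
    penalty = 2.0 * df if config.criterion == "AIC" else np.log(n) * df
    ic = m2ll + penalty
    ic[~admissible] = np.inf
    return ic


def select_and_apply(
    state: ParamState, data: LMMData, config: BoostConfig
) -> tuple[ParamState, int]:
    """Pick the IC-minimizing candidate and apply its damped update.

    Only the winning coordinate (plus the intercept) moves; ties are broken
    on the lowest index. Returns the new state and the selected index.
    """
    u0, ur, admissible = _all_candidate_updates(state, data)
    if not admissible.any():
        raise NumericError("all fixed-effect candidates are collinear")
    if not admissible.all():
        logger.warning(
            "skipping %d collinear candidate(s)", int((~admissible).sum())
        )
    ic = _candidate_ics(state, data, u0, ur, admissible, config)
    r = int(np.argmin(ic))
    new = state.copy()
    new.beta0 += config.nu * u0[r]
    new.beta[r] += config.nu * ur[r]
    return new, r


# ---------------------------------------------------------------------------
# step 2: random effects
# ---------------------------------------------------------------------------


def random_effects_step(
    state: ParamState,
    data: LMMData,
    op: CorrectionOperator,
    nu: float = 0.1,
) -> ParamState:
    """One weak, corrected Fisher step on the penalized log-likelihood.

    The raw step solves the block-diagonal system F_i delta_i = s_i per
    cluster (F_i = sigma^-2 Z_i'Z_i + Q^{-1}); the correction operator is
    applied to the stacked step before damping by nu.
    """
    n, q = data.n, data.q
    Qinv = q_inverse(state.Q)
    e = data.y - state.eta(data)
    g = state.gamma.reshape(n, q)
    delta = np.empty((n, q))
    for grp in cluster_groups(data):
        Zk = data.Z[grp.rows]
        ek = e[grp.rows]
        F = np.einsum("ckq,ckr->cqr", Zk, Zk) / state.sigma2 + Qinv
        s = np.einsum("ckq,ck->cq", Zk, ek) / state.sigma2 - g[
            grp.clusters
        ] @ Qinv
        try:
            delta[grp.clusters] = np.linalg.solve(F, s[..., None])[..., 0]
        except np.linalg.LinAlgError:
            for c, i in enumerate(grp.clusters):
                try:
                    delta[i] = np.linalg.solve(F[c], s[c])
                except np.linalg.LinAlgError as exc:
                    raise NumericError(
                        f"singular random-effects Fisher block for cluster "
                        f"{data.cluster_labels[i]!r}"
                    ) from exc
    corrected = apply_correction(op, delta.reshape(-1))
    new = state.copy()
    new.gamma = state.gamma + nu * corrected
    return new


# ---------------------------------------------------------------------------
# step 3: variance components
# ---------------------------------------------------------------------------


def _project_psd(Q: np.ndarray) -> np.ndarray:
    """Symmetrize and clip negative eigenvalues at zero."""
    Q = 0.5 * (Q + Q.T)
    w, V = np.linalg.eigh(Q)
    if w[0] < 0:
        if -w[0] > _PSD_CLIP_WARN:
            logger.warning(
                "clipping negative eigenvalue %.3g of Q to zero", w[0]
            )
        w = np.clip(w, 0.0, None)
        Q = (V * w) @ V.T
        Q = 0.5 * (Q + Q.T)
    return Q


def update_variance_components(state: ParamState, data: LMMData) -> ParamState:
    """Approximate-EM refresh of Q and the residual-variance update of sigma2.

    Q_hat = 1/n sum_i (F_i^{-1} + gamma_i gamma_i') with the posterior
    curvatures F_i at the current (sigma2, Q); sigma2_hat is the sample
    variance (ddof=1, mean subtracted) of the current residuals y - eta.
    """
    n, q = data.n, data.q
    Qinv = q_inverse(state.Q)
    g = state.gamma.reshape(n, q)
    Qsum = np.einsum("cq,cr->qr", g, g)
    for grp in cluster_groups(data):
        Zk = data.Z[grp.rows]
        F = np.einsum("ckq,ckr->cqr", Zk, Zk) / state.sigma2 + Qinv
        Qsum += np.linalg.inv(F).sum(axis=0)
    Q_new = _project_psd(Qsum / n)
    resid = data.y - state.eta(data)
    sigma2_new = float(resid.var(ddof=1))
    new = state.copy()
    new.Q = Q_new
    new.sigma2 = max(sigma2_new, 1e-12)
    return new


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------


def fit(data: LMMData, config: BoostConfig | None = None) -> FitResult:
    """Run the boosting loop and stop in retrospect at the IC optimum.

    Every iteration applies the selected fixed-effect update, the corrected
    random-effects step and the variance-component refresh, then records the
    information criterion of the new state. The algorithm is deterministic:
    rerunning with the same data and config reproduces the path bit for bit.
    """
    if config is None:
        config = BoostConfig()
    state = initialize(data, config)
    classification = classify_covariates(data)
    op = build_correction(
        data, classification, center_intercept=config.center_intercept
    )

    M = config.m_stop
    n, p, q = data.n, data.p, data.q
    beta0_path = np.empty(M)
    beta_path = np.empty((M, p))
    sigma2_path = np.empty(M)
    Q_path = np.empty((M, q, q))
    gamma_path = np.empty((M, n * q))
    ic_path = np.empty(M)
    df_path = np.empty(M, dtype=int)
    selected_path = np.empty(M, dtype=int)

    initial = state.copy()
    truncated = False
    m_done = 0
    for m in range(M):
        try:
            state, r = select_and_apply(state, data, config)
            state = random_effects_step(state, data, op, config.nu)
            state = update_variance_components(state, data)
            ic = information_criterion(
                state, data, config.criterion, config.ic_likelihood
            )
        except NumericError as exc:
            logger.warning(
                "numeric failure at iteration %d: %s; returning the partial "
                "path",
                m + 1,
                exc,
            )
            truncated = True
            break
        beta0_path[m] = state.beta0
        beta_path[m] = state.beta
        sigma2_path[m] = state.sigma2
        Q_path[m] = state.Q
        gamma_path[m] = state.gamma
        ic_path[m] = ic.value
        df_path[m] = ic.df
        selected_path[m] = r
        m_done = m + 1
        logger.debug(
            "iter %d: selected %s, %s = %.4f",
            m + 1,
            data.covariate_names[r],
            config.criterion,
            ic.value,
        )
    if m_done == 0:
        raise NumericError("boosting failed before completing one iteration")

    result = FitResult(
        covariate_names=list(data.covariate_names),
        criterion=config.criterion,
        initial_state=initial,
        beta0_path=beta0_path[:m_done],
        beta_path=beta_path[:m_done],
        sigma2_path=sigma2_path[:m_done],
        Q_path=Q_path[:m_done],
        gamma_path=gamma_path[:m_done],
        ic_path=ic_path[:m_done],
        df_path=df_path[:m_done],
        selected_path=selected_path[:m_done],
        truncated=truncated,
    )
    if not truncated and result.m_star == m_done:
        warnings.warn(
            f"{config.criterion} still decreasing at m_stop={M}; consider "
            "raising m_stop",
            UserWarning,
            stacklevel=2,
        )
    return result
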
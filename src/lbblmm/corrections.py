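"""Random-effects correction via orthogonal projection.

Likelihood-based boosting of mixed models can let random intercepts absorb
the signal of cluster-constant covariates (a female/male offset ending up in
the per-child intercepts instead of the gender coefficient). The remedy is a
correction operator C applied to every random-effects update: for each
random effect s, the cluster-level coefficient vector
``gamma_tilde_s = (gamma_s1, ..., gamma_sn)'`` is projected onto the
orthogonal complement of a correction space spanned by ``X_cs``:

* random intercept — a ones column plus all cluster-constant covariates
  (one representative row per cluster), so the intercepts stay uncorrelated
  with every observed cluster-level covariate;
* random slopes — just the ones column, i.e. each slope is centered.

With ``C_s = X_cs (X_cs' X_cs)^{-1} X_cs'`` the hat matrix of the correction
space, the per-effect projector is ``I_n - C_s``; stacking them effect-wise
and conjugating with the cluster-major/effect-major permutation P yields the
full operator ``C = P^{-1} (I_nq - diag(C_1, ..., C_q)) P``. Projectors are
precomputed once (the correction spaces do not change over iterations) and
applied as two skinny matrix products per effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import (
    ConfigurationError,
    CovariateClassification,
    LMMData,
)

__all__ = ["CorrectionOperator", "build_correction", "apply_correction"]

logger = logging.getLogger("lbblmm")


@dataclass
class CorrectionOperator:
    """Per-effect correction-space bases and the stacking layout.

    ``bases[s]`` is an orthonormal basis (n x rank_s) of the column space of
    ``correction_covariates[s]``; an empty basis means effect s is left
    uncorrected.
    """

    bases: list[np.ndarray]
    correction_covariates: list[np.ndarray]
    n: int
    q: int

    def projector(self, s: int) -> np.ndarray:
        """Dense (I_n - C_s) for effect s (diagnostics/tests)."""
        B = self.bases[s]
        return np.eye(self.n) - B @ B.T

    def permutation(self) -> np.ndarray:
        """Dense permutation P with P gamma = (gamma_tilde_1', ...)'."""
        n, q = self.n, self.q
        perm = np.empty(n * q, dtype=np.intp)
        for s in range(q):
            perm[s * n: (s + 1) * n] = np.arange(n) * q + s
        return np.eye(n * q)[perm]


def _orth_basis(M: np.ndarray, label: str) -> np.ndarray:
    """Orthonormal basis of col(M) via SVD, dropping rank-deficient directions."""
    if M.shape[1] == 0:
        return np.empty((M.shape[0], 0))
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    tol = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if rank < M.shape[1]:
        logger.warning(
            "correction covariates for %s are rank deficient "
            "(rank %d of %d columns); projecting onto the spanned subspace",
            label,
            rank,
            M.shape[1],
        )
    return U[:, :rank]


def build_correction(
    data: LMMData,
    classification: CovariateClassification,
    center_intercept: bool = True,
) -> CorrectionOperator:
    """Construct the correction operator for the given random-effects layout.

    Parameters
    ----------
    center_intercept : include a ones column in the intercept's correction
        space in addition to the cluster-constant covariates, so the random
        intercepts are also centered (keeps beta0 identifiable). On by
        default.
    """
    n, q = data.n, data.q
    if q < 1:
        raise ConfigurationError("model has no random effects to correct")
    ones = np.ones((n, 1))
    const_cols = classification.cluster_constant_matrix()
    bases: list[np.ndarray] = []
    covs: list[np.ndarray] = []
    for s, name in enumerate(data.random_effect_spec):
        if s == 0 and data.has_random_intercept:
            parts = ([ones] if center_intercept else []) + (
                [const_cols] if const_cols.shape[1] else []
            )
            Xc = np.hstack(parts) if parts else np.empty((n, 0))
        else:
            Xc = ones.copy()
        if Xc.shape[1] >= n:
            raise ConfigurationError(
                f"more correction covariates than clusters for effect "
                f"{name!r} ({Xc.shape[1]} >= {n})"
            )
        covs.append(Xc)
        bases.append(_orth_basis(Xc, name))
    return CorrectionOperator(bases=bases, correction_covariates=covs, n=n, q=q)


def apply_correction(op: CorrectionOperator, delta: np.ndarray) -> np.ndarray:
    """Apply C to a cluster-major stacked vector of length n*q.

    Equivalent to ``P^{-1} (I - diag(C_1,...,C_q)) P delta`` but computed
    effect-wise without materializing the n*q square matrix.
    """
    delta = np.asarray(delta, dtype=float)
    if delta.shape != (op.n * op.q,):
        raise ValueError(
            f"delta has shape {delta.shape}, expected ({op.n * op.q},)"
        )
    G = delta.reshape(op.n, op.q).copy()
    for s, B in enumerate(op.bases):
        if B.shape[1]:
            G[:, s] -= B @ (B.T @ G[:, s])
    return G.reshape(-1)
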
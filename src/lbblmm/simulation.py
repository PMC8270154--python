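"""Synthetic clustered-data generators and the recovery/selection study.

Two longitudinal designs with n = 50 clusters of n_i = 5 observations and
four informative fixed effects (beta0 = 1, beta = (2, 4, 3, 5, 0, ..., 0))
among p candidate covariates, all drawn standard normal. Covariates 1 and 2
are cluster-constant (one draw per cluster, repeated within); the rest vary
within clusters.

* ``intercepts`` — a random intercept gamma_0i ~ N(0, tau^2), model error
  eps ~ N(0, sigma^2) with sigma = 0.4 and tau in {0.4, 0.8, 1.6}.
* ``slopes`` — correlated random intercept plus slopes on the
  cluster-constant x2 and the cluster-varying x4:
  (gamma_0i, gamma_1i, gamma_2i) ~ N(0, Q) with tau^2 on the diagonal and
  off-diagonals tau* = rho * tau^2 so that cor(gamma_ki, gamma_li) = rho
  (default 0.6).

Designs and random components are regenerated fresh for every replication.
Recovery is summarized by squared errors (mse_beta over the full coefficient
vector including the intercept; mse_sigma and mse_tau on the standard-
deviation scale; mse_Q as squared Frobenius distance of the covariance
matrices) and selection by true/false positive and false discovery rates,
a covariate counting as selected iff its final coefficient is nonzero.
Medians (with IQR) summarize the skewed mse distributions; means summarize
the selection rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .boosting import BoostConfig, FitResult, fit
from .data_model import LMMData, build_design
from .likelihood import ParamState

__all__ = ["SimScenario", "SimMetrics", "StudyResult", "simulate", "evaluate",
           "run_study"]

logger = logging.getLogger("lbblmm")

_BETA_INFORMATIVE = (2.0, 4.0, 3.0, 5.0)
_BETA0 = 1.0


@dataclass
class SimScenario:
    """Parameters of one simulation cell.

    tau is the random-effect standard deviation; sigma the model-error
    standard deviation. ``slope_correlation`` only enters the slopes design.
    """

    design: str = "intercepts"
    n: int = 50
    n_i: int = 5
    p: int = 10
    tau: float = 0.4
    sigma: float = 0.4
    slope_correlation: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("intercepts", "slopes"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.p < 5:
            raise ValueError("p must be at least 5 (4 informative + noise)")

    @property
    def beta0_true(self) -> float:
        return _BETA0

    @property
    def beta_true(self) -> np.ndarray:
        """(p,) true fixed effects: (2, 4, 3, 5, 0, ..., 0)."""
        beta = np.zeros(self.p)
        beta[:4] = _BETA_INFORMATIVE
        return beta

    @property
    def Q_true(self) -> np.ndarray:
        """Generating random-effects covariance (1x1 or 3x3)."""
        t2 = self.tau**2
        if self.design == "intercepts":
            return np.array([[t2]])
        Q = np.full((3, 3), self.slope_correlation * t2)
        np.fill_diagonal(Q, t2)
        return Q

    @property
    def informative(self) -> np.ndarray:
        """Indices (0-based) of the informative covariates."""
        return np.arange(4)


@dataclass
class SimMetrics:
    """Recovery and selection summaries for one replication."""

    mse_beta: float
    mse_sigma: float
    tp: float
    fp: float
    fdr: float
    mse_tau: float | None = None
    mse_Q: float | None = None
    m_star: int | None = None

    def as_dict(self) -> dict:
        out = {
            "mse_beta": self.mse_beta,
            "mse_sigma": self.mse_sigma,
            "TP": self.tp,
            "FP": self.fp,
            "FDR": self.fdr,
        }
        if self.mse_tau is not None:
            out["mse_tau"] = self.mse_tau
        if self.mse_Q is not None:
            out["mse_Q"] = self.mse_Q
        if self.m_star is not None:
            out["m_star"] = self.m_star
        return out


def simulate(scenario: SimScenario) -> tuple[LMMData, ParamState]:
    """Draw one dataset from the scenario; returns the data and the truth.

    Covariates 1-2 are cluster-constant (identical within each cluster),
    covariates 3..p cluster-varying, all N(0, 1). The truth state carries
    the generating coefficients, random effects, sigma^2 and Q.
    """
    rng = np.random.default_rng(scenario.seed)
    n, n_i, p = scenario.n, scenario.n_i, scenario.p
    N = n * n_i
    X = np.empty((N, p))
    for r in range(p):
        if r < 2:
            X[:, r] = np.repeat(rng.standard_normal(n), n_i)
        else:
            X[:, r] = rng.standard_normal(N)
    beta = scenario.beta_true
    eps = rng.normal(0.0, scenario.sigma, size=N)
    cluster = np.repeat(np.arange(n), n_i)

    if scenario.design == "intercepts":
        gamma = rng.normal(0.0, scenario.tau, size=(n, 1))
        ranef = gamma[cluster, 0]
        slopes: list[str] = []
    else:
        gamma = rng.multivariate_normal(np.zeros(3), scenario.Q_true, size=n)
        ranef = (
            gamma[cluster, 0]
            + gamma[cluster, 1] * X[:, 1]
            + gamma[cluster, 2] * X[:, 3]
        )
        slopes = ["x2", "x4"]

    y = scenario.beta0_true + X @ beta + ranef + eps
    names = [f"x{r + 1}" for r in range(p)]
    table = pd.DataFrame(X, columns=names)
    table["y"] = y
    table["cluster"] = cluster
    data = build_design(
        table,
        response="y",
        cluster="cluster",
        fixed=names,
        random_slopes=slopes,
        random_intercept=True,
    )
    truth = ParamState(
        beta0=scenario.beta0_true,
        beta=beta,
        gamma=gamma.reshape(-1),
        sigma2=scenario.sigma**2,
        Q=scenario.Q_true,
    )
    return data, truth


def evaluate(
    result: FitResult, truth: ParamState, scenario: SimScenario
) -> SimMetrics:
    """Squared-error and selection metrics of a fit against the truth.

    mse_beta covers the full coefficient vector (intercept included);
    mse_sigma and mse_tau compare standard deviations; mse_Q is the squared
    Frobenius distance of the covariances. A covariate is selected iff its
    final coefficient is nonzero; FDR is defined as 0 when nothing is
    selected.
    """
    est = np.concatenate([[result.beta0], result.beta])
    tru = np.concatenate([[truth.beta0], truth.beta])
    mse_beta = float(np.sum((est - tru) ** 2))
    mse_sigma = float(
        (np.sqrt(truth.sigma2) - np.sqrt(result.sigma2)) ** 2
    )
    selected = result.beta != 0.0
    informative = np.zeros(scenario.p, dtype=bool)
    informative[scenario.informative] = True
    p_sel = int(np.sum(selected & informative))
    pbar_sel = int(np.sum(selected & ~informative))
    tp = p_sel / int(informative.sum())
    fp = pbar_sel / int((~informative).sum())
    fdr = pbar_sel / (pbar_sel + p_sel) if (pbar_sel + p_sel) else 0.0

    mse_tau = mse_Q = None
    if scenario.design == "intercepts":
        tau_hat = float(np.sqrt(result.Q[0, 0]))
        mse_tau = float((scenario.tau - tau_hat) ** 2)
    else:
        mse_Q = float(np.sum((truth.Q - result.Q) ** 2))
    return SimMetrics(
        mse_beta=mse_beta,
        mse_sigma=mse_sigma,
        tp=tp,
        fp=fp,
        fdr=fdr,
        mse_tau=mse_tau,
        mse_Q=mse_Q,
        m_star=result.m_star,
    )


@dataclass
class StudyResult:
    """Per-replication metrics and the median/mean summary of a study."""

    scenario: SimScenario
    per_replication: pd.DataFrame
    summary: pd.Series
    n_failed: int = 0


def replication_seed(scenario_seed: int, rep: int) -> int:
    """Deterministic per-replication seed (counter-based, subset-stable)."""
    ss = np.random.SeedSequence((int(scenario_seed), int(rep)))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_study(
    scenario: SimScenario,
    replications: int = 20,
    config: BoostConfig | None = None,
) -> StudyResult:
    """Fit the boosting algorithm on fresh draws and summarize the metrics.

    Every replication regenerates covariates and random components from a
    seed derived deterministically from the scenario seed, so any subset of
    replications is independently reproducible. mse columns are summarized
    by median and IQR, selection rates by their mean. Failed replications
    are logged, counted and excluded.
    """
    if replications < 1:
        raise ValueError("need at least one replication")
    if config is None:
        config = BoostConfig()
    rows = []
    n_failed = 0
    for rep in range(replications):
        sc = replace(scenario, seed=replication_seed(scenario.seed, rep))
        try:
            data, truth = simulate(sc)
            result = fit(data, config)
            metrics = evaluate(result, truth, sc)
        except Exception:  # noqa: BLE001 - a bad draw must not kill the study
            logger.exception("replication %d failed; excluded", rep)
            n_failed += 1
            continue
        row = {"replication": rep, "seed": sc.seed}
        row.update(metrics.as_dict())
        rows.append(row)
    per_rep = pd.DataFrame(rows)
    if per_rep.empty:
        raise RuntimeError("all replications failed")

    summary: dict[str, float] = {}
    for col in per_rep.columns:
        if col.startswith("mse_"):
            qs = per_rep[col].quantile([0.25, 0.5, 0.75])
            summary[f"median_{col}"] = float(qs[0.5])
            summary[f"iqr_{col}"] = float(qs[0.75] - qs[0.25])
    for col in ("TP", "FP", "FDR"):
        summary[f"mean_{col}"] = float(per_rep[col].mean())
    summary["median_m_star"] = float(per_rep["m_star"].median())
    summary["replications"] = float(len(per_rep))
    return StudyResult(
        scenario=scenario,
        per_replication=per_rep,
        summary=pd.Series(summary),
        n_failed=n_failed,
    )
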
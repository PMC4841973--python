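"""Intrinsic-estimator fitting of Poisson APC models with exposure offset.

The model for cell (i, j) with cohort k = a - i + j is

    log E[D_ij] = log P_ij + mu + alpha_i + beta_j + gamma_k,

with D Poisson.  The stacked coefficient vector is identified only up to
movement along the design kernel B0; the intrinsic estimator fixes this
by estimating within the orthogonal complement of B0.  Concretely we
form an orthonormal basis U of that (m-1)-dimensional complement, fit
the full-rank Poisson GLM with design X @ U and offset log P by
iteratively reweighted least squares, and map the estimate and its
covariance back through U.  The dropped last category of each
sum-to-zero block is reconstructed as the negative block sum, with
variance 1' Sigma_block 1.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import null_space

from .apc_table import APCTable
from .design import DesignSpec, build_design

__all__ = ["APCFit", "IEFit", "fit_ie", "predict", "summary_table", "ConvergenceError"]

#: IRLS stopping rule: change in deviance below this, or 100 iterations
IRLS_TOL = 1e-10
IRLS_MAXITER = 100

BLOCKS = ("age", "period", "cohort")


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the deviance trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class APCFit:
    """A fitted, identified APC model.

    ``alpha``, ``beta`` and ``gamma`` are the full sum-to-zero effect
    blocks (a, p and a+p-1 entries, each including the reconstructed
    dropped category).  ``theta`` is the stacked coefficient vector on the
    truncated (m-length) scale; ``covariance`` its m x m covariance.
    ``se`` / ``ci95`` map block name -> per-category values, with 95%
    Wald intervals ``estimate +/- 1.96 se`` on the log-rate scale.
    """

    design: DesignSpec
    method: str
    theta: np.ndarray
    covariance: np.ndarray
    mu: float
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    se: dict[str, np.ndarray]
    ci95: dict[str, np.ndarray]
    deviance: float
    fitted: np.ndarray
    converged: bool
    n_iter: int
    age_labels: list[str]
    period_labels: list[str]
    cohort_labels: list[str]
    flags: list[str] = field(default_factory=list)

    def effects(self, block: str) -> np.ndarray:
        return {"age": self.alpha, "period": self.beta, "cohort": self.gamma}[block]

    def stacked_effects(self) -> np.ndarray:
        """Intercept followed by all full effect blocks (1+a+p+(a+p-1))."""
        return np.concatenate([[self.mu], self.alpha, self.beta, self.gamma])


#: spec alias for the intrinsic-estimator fit
IEFit = APCFit


def _reconstruct_block(est: np.ndarray, cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Append the dropped category (-sum) and its standard error."""
    full = np.append(est, -est.sum())
    ones = np.ones(est.size)
    var_last = float(ones @ cov @ ones)
    se = np.append(np.sqrt(np.clip(np.diag(cov), 0, None)),
                   np.sqrt(max(var_last, 0.0)))
    return full, se


def _fit_in_subspace(
    table: APCTable, design: DesignSpec, basis: np.ndarray, method: str
) -> APCFit:
    """Fit the Poisson GLM with design X @ basis and map back to theta.

    ``basis`` is an m x (m-1) matrix whose columns span a complement of
    the kernel, so X @ basis has full column rank and the GLM is
    identified.  Shared by the intrinsic estimator (orthogonal complement
    of B0) and CGLIM (hyperplane of an equality constraint).
    """
    y = table.deaths.ravel()
    offset = np.log(table.exposures).ravel()
    exog = design.X @ basis

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # perfect fits emit benign precision warnings
        model = sm.GLM(y, exog, family=sm.families.Poisson(), offset=offset)
        res = model.fit(maxiter=IRLS_MAXITER, tol=IRLS_TOL, scale=1.0)
    trace = [float(d) for d in res.fit_history.get("deviance", [])]
    converged = bool(res.converged)
    if not converged and len(trace) >= 2:
        # statsmodels tests absolute deviance change; our criterion is
        # relative, so re-check the trace on that scale
        converged = abs(trace[-1] - trace[-2]) <= IRLS_TOL * max(1.0, abs(trace[-1]))
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {IRLS_MAXITER} iterations "
            f"(deviance trace tail {trace[-3:]})",
            trace,
        )

    theta = basis @ res.params
    cov = basis @ np.asarray(res.cov_params()) @ basis.T

    a, p = design.a, design.p
    blocks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for block in BLOCKS:
        sl = design.block_slice(block)
        blocks[block] = _reconstruct_block(theta[sl], cov[sl, sl])

    se = {"intercept": np.array([np.sqrt(max(cov[0, 0], 0.0))])}
    ci95: dict[str, np.ndarray] = {}
    est_by_block = {"intercept": np.array([theta[0]])}
    for block in BLOCKS:
        est_by_block[block], se[block] = blocks[block]
    for block, est in est_by_block.items():
        ci95[block] = np.column_stack([est - 1.96 * se[block], est + 1.96 * se[block]])

    eta = design.X @ theta + offset
    fitted = np.exp(eta).reshape(a, p)

    flags = []
    koc = table.cohort_of_cell()
    for block, sums in (
        ("age", table.deaths.sum(axis=1)),
        ("period", table.deaths.sum(axis=0)),
        ("cohort", np.array([table.deaths[koc == c].sum()
                             for c in range(1, table.n_cohorts + 1)])),
    ):
        zero = np.flatnonzero(sums == 0)
        if zero.size:
            flags.append(f"all-zero counts in {block} categories {list(zero + 1)}")

    return APCFit(
        design=design,
        method=method,
        theta=theta,
        covariance=cov,
        mu=float(theta[0]),
        alpha=est_by_block["age"],
        beta=est_by_block["period"],
        gamma=est_by_block["cohort"],
        se=se,
        ci95=ci95,
        deviance=float(res.deviance),
        fitted=fitted,
        converged=converged,
        n_iter=len(trace),
        age_labels=table.age_labels,
        period_labels=table.period_labels,
        cohort_labels=table.cohort_labels,
        flags=flags,
    )


def fit_ie(table: APCTable) -> APCFit:
    """Fit the intrinsic-estimator APC model to a count table.

    Estimation is restricted to the orthogonal complement of the design
    kernel B0, the identification that depends only on the numbers of age
    and period categories.  Returns an :class:`APCFit` whose stacked
    coefficient vector satisfies ``theta . B0 = 0``.
    """
    design = build_design(table.n_ages, table.n_periods)
    U = null_space(design.B0[None, :])  # orthonormal, m x (m-1)
    return _fit_in_subspace(table, design, U, method="ie")


def predict(fit: APCFit, table: APCTable) -> tuple[np.ndarray, np.ndarray]:
    """Expected counts and rates for a table under a fitted model.

    ``E[i, j] = P[i, j] * exp(mu + alpha_i + beta_j + gamma_k)``; rates
    are per 100,000 person-years.  The table must share the fit's grid
    dimensions.
    """
    a, p = fit.design.a, fit.design.p
    if table.deaths.shape != (a, p):
        raise ValueError(
            f"table grid {table.deaths.shape} does not match fit grid {(a, p)}"
        )
    k = table.cohort_of_cell() - 1
    eta = fit.mu + fit.alpha[:, None] + fit.beta[None, :] + fit.gamma[k]
    expected = table.exposures * np.exp(eta)
    rates = 100_000.0 * np.exp(eta)
    return expected, rates


def summary_table(fit: APCFit) -> pd.DataFrame:
    """Long-format effect table: one row per reported coefficient.

    Rows ordered intercept, age, period, cohort; columns ``block,
    category, estimate, se, ci_low, ci_high``.  Row count is
    ``1 + a + p + (a + p - 1)``.
    """
    labels = {
        "intercept": ["mu"],
        "age": fit.age_labels,
        "period": fit.period_labels,
        "cohort": fit.cohort_labels,
    }
    est = {
        "intercept": np.array([fit.mu]),
        "age": fit.alpha,
        "period": fit.beta,
        "cohort": fit.gamma,
    }
    rows = []
    for block in ("intercept",) + BLOCKS:
        for c, label in enumerate(labels[block]):
            rows.append({
                "block": block,
                "category": label,
                "estimate": est[block][c],
                "se": fit.se[block][c],
                "ci_low": fit.ci95[block][c, 0],
                "ci_high": fit.ci95[block][c, 1],
            })
    return pd.DataFrame(rows)
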
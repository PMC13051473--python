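"""Gamma GLM with log link, and marginal standardization of mean costs.

Annualized healthcare costs are right-skewed and strictly positive, with
variance growing with the mean; the standard model is a generalized linear
model with gamma variance function and log link,

    E[Y | x] = exp(x'beta),      Var[Y | x] = phi * E[Y | x]^2.

With the log link the IRLS working weights are identically 1, so each
iteration is an ordinary least-squares solve of the working response
z = eta + (y - mu)/mu against the fixed design — the normal-equations
Cholesky factor is computed once per design and reused across iterations,
which keeps bootstrap refits cheap.

Group means by exposure status come from marginal standardization
("recycled predictions"): predict every participant's cost with the
exposure forced to 1, then to 0, and average each set of predictions.
The incremental cost is the difference of the two averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import ConfigurationError, FitError, ValidationError

__all__ = [
    "Term",
    "ModelSpec",
    "Design",
    "GlmFit",
    "MarginalMeans",
    "build_design",
    "irls_gamma_log",
    "fit",
    "marginal_means",
    "apply_zero_rule",
]


@dataclass(frozen=True)
class Term:
    """One model term: a column entered linear, or categorical with a
    reference level (dummy coding)."""

    column: str
    kind: str = "linear"  # "linear" | "categorical"
    reference: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "categorical"):
            raise ConfigurationError(f"unknown term kind {self.kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    exposure: str
    covariates: tuple[Term, ...] = ()

    def __post_init__(self) -> None:
        if any(t.column == self.exposure for t in self.covariates):
            raise ConfigurationError("exposure must not be duplicated among covariates")

    def with_covariates(self, extra: Sequence[Term]) -> "ModelSpec":
        return ModelSpec(self.outcome, self.exposure, self.covariates + tuple(extra))


@dataclass
class Design:
    """Materialized design matrix with named columns.

    Column 0 is the intercept, column 1 the binary exposure indicator;
    covariate columns follow in spec order.
    """

    X: np.ndarray
    columns: list[str]
    exposure_index: int = 1

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]


def _dummy_columns(values: pd.Series, term: Term) -> tuple[np.ndarray, list[str]]:
    levels = sorted(map(str, pd.unique(values.astype(str))))
    reference = term.reference if term.reference is not None else levels[0]
    if str(reference) not in levels:
        raise ConfigurationError(
            f"reference level {reference!r} absent from column {term.column!r}"
        )
    keep = [lv for lv in levels if lv != str(reference)]
    vals = values.astype(str).to_numpy()
    cols = np.column_stack([(vals == lv).astype(float) for lv in keep]) if keep else np.empty((len(vals), 0))
    names = [f"{term.column}[{lv}]" for lv in keep]
    return cols, names


def build_design(spec: ModelSpec, data: pd.DataFrame) -> Design:
    """Build the model matrix: intercept, exposure, then covariate columns."""
    exposure = data[spec.exposure].to_numpy(dtype=float)
    uniq = np.unique(exposure)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValidationError(f"exposure column {spec.exposure!r} must be binary 0/1")
    blocks = [np.ones((len(data), 1)), exposure[:, None]]
    names = ["intercept", spec.exposure]
    for term in spec.covariates:
        if term.column not in data.columns:
            raise ConfigurationError(f"covariate column {term.column!r} not in data")
        if term.kind == "linear":
            col = data[term.column].to_numpy(dtype=float)[:, None]
            blocks.append(col)
            names.append(term.column)
        else:
            cols, cnames = _dummy_columns(data[term.column], term)
            if cols.shape[1] == 0:
                raise ConfigurationError(
                    f"categorical term {term.column!r} resolves to no design columns"
                )
            blocks.append(cols)
            names.extend(cnames)
    X = np.hstack(blocks)
    return Design(X=X, columns=names)


@dataclass
class GlmFit:
    coefficients: np.ndarray
    columns: list[str]
    dispersion: float
    converged: bool
    n_iterations: int
    n_obs: int
    deviance: float
    cov: Optional[np.ndarray] = None
    n_zero_adjusted: int = 0

    @property
    def term_map(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.columns)}

    def se(self) -> np.ndarray:
        if self.cov is None:
            raise FitError("no covariance available")
        return np.sqrt(np.diag(self.cov))


def _gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum((y - mu) / mu - np.log(y / mu)))


def _check_rank(X: np.ndarray, columns: list[str]) -> None:
    # QR with pivoting names the aliased columns when the design is deficient
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        aliased = [columns[j] for j in piv[rank:]]
        raise FitError(f"design matrix is rank deficient; aliased columns: {aliased}")


def irls_gamma_log(
    X: np.ndarray,
    y: np.ndarray,
    beta0: Optional[np.ndarray] = None,
    tol_coef: float = 1e-8,
    tol_dev: float = 1e-10,
    max_iter: int = 100,
    xtx_factor=None,
) -> tuple[np.ndarray, float, int, bool]:
    """Solve the gamma/log score equations by IRLS.

    Returns ``(beta, deviance, n_iterations, converged)``. ``xtx_factor`` may
    carry a precomputed Cholesky factor of X'X (the working weights are unit
    under the log link, so the factor is iteration-invariant).
    """
    if np.any(y <= 0):
        raise ValidationError(
            "gamma outcome must be strictly positive; apply a zero-cost rule first"
        )
    if xtx_factor is None:
        xtx = X.T @ X
        try:
            xtx_factor = linalg.cho_factor(xtx, lower=True)
        except linalg.LinAlgError:
            _check_rank(X, [f"x{j}" for j in range(X.shape[1])])
            raise
    if beta0 is None:
        # initialize from the log outcome, clipped below at log(0.1)
        z0 = np.log(np.clip(y, 0.1, None))
        beta = linalg.cho_solve(xtx_factor, X.T @ z0)
    else:
        beta = np.asarray(beta0, dtype=float).copy()
    eta = X @ beta
    mu = np.exp(eta)
    dev = _gamma_deviance(y, mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = eta + (y - mu) / mu
        beta_new = linalg.cho_solve(xtx_factor, X.T @ z)
        step = beta_new - beta
        # step-halving on deviance increase
        for _ in range(30):
            eta_new = X @ (beta + step)
            dev_new = _gamma_deviance(y, np.exp(eta_new))
            if np.isfinite(dev_new) and dev_new <= dev * (1 + 1e-12) + 1e-12:
                break
            step *= 0.5
        beta_next = beta + step
        eta = X @ beta_next
        mu = np.exp(eta)
        dev_new = _gamma_deviance(y, mu)
        delta = np.max(np.abs(beta_next - beta))
        rel_dev = abs(dev - dev_new) / (abs(dev) + 1e-300)
        beta = beta_next
        dev = dev_new
        if delta < tol_coef or rel_dev < tol_dev:
            converged = True
            break
    return beta, dev, it, converged


def apply_zero_rule(
    y: np.ndarray, rule: str = "replace_one", delta: float = 1.0
) -> tuple[np.ndarray, np.ndarray, int]:
    """Handle zero costs before a gamma fit.

    rule "replace_one": zeros become $1; "shift": add ``delta`` to every
    outcome; "exclude": drop zero rows; "error": refuse. Returns
    ``(y_adjusted, keep_mask, n_adjusted)``.
    """
    y = np.asarray(y, dtype=float)
    keep = np.ones(len(y), dtype=bool)
    zeros = y <= 0
    n_zero = int(zeros.sum())
    if n_zero == 0:
        return y, keep, 0
    if rule == "replace_one":
        y = np.where(zeros, 1.0, y)
    elif rule == "shift":
        y = y + delta
    elif rule == "exclude":
        keep = ~zeros
    elif rule == "error":
        raise ValidationError(f"{n_zero} zero-cost outcomes with zero-handling disabled")
    else:
        raise ConfigurationError(f"unknown zero-cost rule {rule!r}")
    return y, keep, n_zero


def fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    zero_rule: str = "replace_one",
    tol_coef: float = 1e-8,
    tol_dev: float = 1e-10,
    max_iter: int = 100,
    with_cov: bool = True,
) -> GlmFit:
    """Fit the gamma/log GLM described by ``spec`` on the cohort rows."""
    design = build_design(spec, data)
    y_raw = data[spec.outcome].to_numpy(dtype=float)
    y, keep, n_zero = apply_zero_rule(y_raw, zero_rule)
    X = design.X[keep]
    y = y[keep]
    if X.shape[0] <= X.shape[1]:
        raise FitError("more design columns than observations")
    _check_rank(X, design.columns)
    xtx = X.T @ X
    factor = linalg.cho_factor(xtx, lower=True)
    beta, dev, n_iter, converged = irls_gamma_log(
        X, y, tol_coef=tol_coef, tol_dev=tol_dev, max_iter=max_iter, xtx_factor=factor
    )
    if not converged:
        raise FitError(
            f"IRLS did not converge in {max_iter} iterations (deviance {dev:.6g})"
        )
    mu = np.exp(X @ beta)
    n, p = X.shape
    pearson = float(np.sum(((y - mu) / mu) ** 2))
    dispersion = pearson / (n - p)
    cov = dispersion * linalg.cho_solve(factor, np.eye(p)) if with_cov else None
    return GlmFit(
        coefficients=beta,
        columns=design.columns,
        dispersion=dispersion,
        converged=converged,
        n_iterations=n_iter,
        n_obs=n,
        deviance=dev,
        cov=cov,
        n_zero_adjusted=n_zero,
    )


@dataclass(frozen=True)
class MarginalMeans:
    """Marginally standardized mean costs by exposure status."""

    mean_exposed: float
    mean_unexposed: float

    @property
    def incremental(self) -> float:
        return self.mean_exposed - self.mean_unexposed


def marginal_means_from_design(
    beta: np.ndarray, design: Design
) -> MarginalMeans:
    """Recycled predictions on a prebuilt design (fast path for bootstraps)."""
    eta = design.X @ beta
    b = beta[design.exposure_index]
    x_e = design.X[:, design.exposure_index]
    mean_exposed = float(np.mean(np.exp(eta + b * (1.0 - x_e))))
    mean_unexposed = float(np.mean(np.exp(eta - b * x_e)))
    return MarginalMeans(mean_exposed=mean_exposed, mean_unexposed=mean_unexposed)


def marginal_means(fit_result: GlmFit, spec: ModelSpec, data: pd.DataFrame) -> MarginalMeans:
    """Predict every participant's cost under exposure = 1 and = 0 and
    average: covariate-adjusted group means and their difference."""
    if not fit_result.converged:
        raise FitError("marginal means require a converged fit")
    design = build_design(spec, data)
    if design.columns != fit_result.columns:
        raise ConfigurationError("data/spec do not match the fitted design")
    return marginal_means_from_design(fit_result.coefficients, design)
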
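"""Ridge-regression BLUP (rrBLUP).

The single-marker model is y = beta0 + X beta + e with marker effects
beta_i ~ iid N(0, sigma^2_beta) and residuals e ~ N(0, sigma^2_e I).  Under
this mixed-model reading, the ridge estimator with shrinkage

    lambda = sigma^2_e / sigma^2_beta

is the best linear unbiased predictor (BLUP) of the marker effects.  The
variance components are estimated by restricted maximum likelihood (REML)
through a single eigendecomposition of the centered X X^T, profiling the
restricted likelihood over the ratio lambda — the spectral strategy of
mixed.solve-style solvers, so each candidate lambda costs O(n) after the
decomposition.

The intercept is unpenalized: y and the columns of X are centered for the
solve and the intercept recovered as ybar - xbar' beta.  For m > n the dual
identity beta = X_c' (X_c X_c' + lambda I)^{-1} y_c keeps the cost at
min(n, m)^3 and never materializes X'X.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from traitpred.core import TraitVector, TraitPredError
from traitpred.io_formats import EncodedMatrix

LAMBDA_MIN = 1e-6
LAMBDA_MAX = 1e6
_LOG_TOL = 1e-8
_GRID_POINTS = 61


class ModelError(TraitPredError):
    """Raised for unusable design matrices or mismatched features."""


@dataclass
class VarianceComponents:
    """REML estimates of the marker-effect and residual variances."""

    sigma2_beta: float
    sigma2_e: float
    reml_loglik: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.reml_loglik):
            raise ValueError("REML log-likelihood must be finite at the optimum")


@dataclass
class FittedRidgeModel:
    """Fitted rrBLUP/ridge model: intercept, shrunk coefficients, lambda."""

    intercept: float
    coefficients: np.ndarray
    feature_ids: list[str]
    lam: float
    sigma2_beta: float | None = None
    sigma2_e: float | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        self.feature_ids = list(self.feature_ids)
        if self.coefficients.size != len(self.feature_ids):
            raise ValueError("one coefficient per feature id required")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")

    def to_tsv(self, path: str) -> None:
        """Serialize as a header block plus (feature id, coefficient) rows."""
        with open(path, "w") as fh:
            fh.write(f"#intercept\t{self.intercept:.17g}\n")
            fh.write(f"#lambda\t{self.lam:.17g}\n")
            if self.sigma2_beta is not None:
                fh.write(f"#sigma2_beta\t{self.sigma2_beta:.17g}\n")
            if self.sigma2_e is not None:
                fh.write(f"#sigma2_e\t{self.sigma2_e:.17g}\n")
            fh.write("feature_id\tcoefficient\n")
            for fid, b in zip(self.feature_ids, self.coefficients):
                fh.write(f"{fid}\t{b:.17g}\n")


def _check_xy(X: EncodedMatrix, y: TraitVector) -> tuple[np.ndarray, np.ndarray]:
    if X.sample_ids != y.sample_ids:
        raise ModelError("design matrix and trait vector are not aligned")
    if not np.all(np.isfinite(X.values)):
        raise ModelError("design matrix contains non-finite values")
    return X.values, y.values


def _center(Xv: np.ndarray, yv: np.ndarray):
    xbar = Xv.mean(axis=0) if Xv.size else np.zeros(Xv.shape[1])
    ybar = float(yv.mean())
    return Xv - xbar, yv - ybar, xbar, ybar


def _ridge_beta(Xc: np.ndarray, yc: np.ndarray, lam: float) -> np.ndarray:
    """Penalized coefficients on centered data, primal or dual by shape."""
    n, m = Xc.shape
    if m == 0:
        return np.zeros(0)
    if m <= n:
        A = Xc.T @ Xc + lam * np.eye(m)
        return np.linalg.solve(A, Xc.T @ yc)
    K = Xc @ Xc.T + lam * np.eye(n)
    return Xc.T @ np.linalg.solve(K, yc)


def solve_fixed_lambda(
    X: EncodedMatrix, y: TraitVector, lam: float
) -> FittedRidgeModel:
    """Ridge regression at a user-supplied shrinkage lambda.

    Minimizes sum (y - beta0 - X beta)^2 + lam * ||beta||^2 with an
    unpenalized intercept.
    """
    if lam <= 0:
        raise ModelError("lambda must be positive")
    Xv, yv = _check_xy(X, y)
    Xc, yc, xbar, ybar = _center(Xv, yv)
    beta = _ridge_beta(Xc, yc, lam)
    intercept = ybar - float(xbar @ beta) if beta.size else ybar
    return FittedRidgeModel(intercept, beta, X.feature_ids, lam)


def _reml_profile(d: np.ndarray, r2: np.ndarray, n: int):
    """Restricted log-likelihood profiled over sigma^2_beta, as f(lambda).

    d are the eigenvalues of the centered kernel X_c X_c^T, r2 the squared
    projections of y_c on the eigenvectors.  One degree of freedom (the
    intercept direction, eigenvalue 0, projection 0) is removed from the
    log-determinant.
    """
    df = n - 1

    def neg_loglik(log_lam: float) -> float:
        lam = np.exp(log_lam)
        denom = d + lam
        s2b = float(np.sum(r2 / denom)) / df
        if s2b <= 0:
            return np.inf
        logdet = float(np.sum(np.log(denom))) - np.log(lam)
        return 0.5 * (df * np.log(s2b) + logdet + df)

    return neg_loglik


def reml_fit(
    X: EncodedMatrix, y: TraitVector
) -> tuple[VarianceComponents, FittedRidgeModel]:
    """Estimate lambda = sigma^2_e / sigma^2_beta by REML and return the BLUP.

    The ratio is profiled on a log grid over [1e-6, 1e6] and refined by
    bounded minimization to 1e-8 in log-lambda; hitting a bound emits a
    warning (the data carry no information to separate the variances there).
    """
    Xv, yv = _check_xy(X, y)
    n = Xv.shape[0]
    if n < 3:
        raise ModelError(f"REML needs at least 3 samples, got {n}")
    if Xv.shape[1] == 0 or np.allclose(Xv, Xv[0:1, :]):
        raise ModelError("all features constant; lambda is unidentifiable")
    Xc, yc, xbar, ybar = _center(Xv, yv)

    K = Xc @ Xc.T
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    r = U.T @ yc
    r2 = r**2

    neg_loglik = _reml_profile(d, r2, n)
    lo, hi = np.log(LAMBDA_MIN), np.log(LAMBDA_MAX)
    grid = np.linspace(lo, hi, _GRID_POINTS)
    vals = np.array([neg_loglik(g) for g in grid])
    k = int(np.argmin(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, _GRID_POINTS - 1)]
    if a == b:
        log_lam = grid[k]
    else:
        res = minimize_scalar(
            neg_loglik, bounds=(a, b), method="bounded",
            options={"xatol": _LOG_TOL},
        )
        log_lam = float(res.x)
        if neg_loglik(grid[k]) < res.fun:
            log_lam = grid[k]
    lam = float(np.exp(log_lam))
    if lam <= LAMBDA_MIN * (1 + 1e-3) or lam >= LAMBDA_MAX * (1 - 1e-3):
        warnings.warn(
            f"REML lambda estimate hit the search bound ({lam:.3g}); "
            "variance components are weakly identified"
        )

    df = n - 1
    denom = d + lam
    sigma2_beta = float(np.sum(r2 / denom)) / df
    sigma2_e = lam * sigma2_beta
    loglik = -neg_loglik(log_lam)

    alpha = U @ (r / denom)
    beta = Xc.T @ alpha
    intercept = ybar - float(xbar @ beta)
    model = FittedRidgeModel(
        intercept, beta, X.feature_ids, lam,
        sigma2_beta=sigma2_beta, sigma2_e=sigma2_e,
    )
    return VarianceComponents(sigma2_beta, sigma2_e, loglik), model


def predict(model: FittedRidgeModel, X_new: EncodedMatrix) -> TraitVector:
    """Predict trait values: yhat = beta0 + X_new beta.

    Features of ``X_new`` must match the model's features; columns are
    reordered by id if needed.
    """
    if X_new.feature_ids != model.feature_ids:
        missing = sorted(set(model.feature_ids) - set(X_new.feature_ids))
        extra = sorted(set(X_new.feature_ids) - set(model.feature_ids))
        if missing or extra:
            raise ModelError(
                f"feature mismatch: missing {missing[:5]}, extra {extra[:5]}"
            )
        order = [X_new.feature_ids.index(f) for f in model.feature_ids]
        values = X_new.values[:, order]
    else:
        values = X_new.values
    yhat = model.intercept + (values @ model.coefficients if values.size else 0.0)
    yhat = np.broadcast_to(np.atleast_1d(yhat), (X_new.n_samples,)).astype(float)
    return TraitVector(X_new.sample_ids, yhat)
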
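"""Firth-penalized logistic regression.

Maximum-likelihood logistic estimates diverge under (quasi-)complete
separation, a common failure mode when a sparse binary outcome is
regressed on age in a small cohort.  Firth's correction maximizes the
penalized log-likelihood

    l*(beta) = l(beta) + 1/2 * log |I(beta)|

(the Jeffreys-prior penalty), whose score equations

    sum_i [y_i - p_i + h_i (1/2 - p_i)] x_ij = 0

(h_i the hat-matrix diagonal) always have a finite root when both
outcome classes are present.  The solver is Newton-Raphson on the
modified score with step-halving on the penalized likelihood.

The model/results split follows statsmodels: ``FirthLogit(y, X).fit()``
returns a :class:`FirthLogitResults` with ``params``, ``bse``,
``pvalues``, ``conf_int()`` and ``summary()``.  Confidence intervals are
Wald intervals on the penalized fit.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

_P_CLIP = 1e-12


class ConvergenceError(RuntimeError):
    """Newton iterations failed to reach the score tolerance."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-eta))
    return np.clip(p, _P_CLIP, 1.0 - _P_CLIP)


class FirthLogit:
    """Penalized-likelihood logistic model for a binary outcome.

    Parameters
    ----------
    endog : (n,) 0/1 outcome array.
    exog : (n, k) design matrix including the constant column.
    exog_names : optional column names for reporting.
    """

    def __init__(self, endog, exog, exog_names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        if len(self.endog) != self.exog.shape[0]:
            raise ValueError("endog/exog length mismatch")
        if not set(np.unique(self.endog)) <= {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if len(np.unique(self.endog)) < 2:
            raise ValueError("outcome has a single class")
        k = self.exog.shape[1]
        self.exog_names = (
            list(exog_names) if exog_names is not None else [f"x{j}" for j in range(k)]
        )

    def _info(self, p: np.ndarray) -> np.ndarray:
        w = p * (1.0 - p)
        return (self.exog * w[:, None]).T @ self.exog

    def penalized_loglike(self, params: np.ndarray) -> float:
        p = _sigmoid(self.exog @ params)
        ll = float(np.sum(self.endog * np.log(p) + (1 - self.endog) * np.log(1 - p)))
        sign, logdet = np.linalg.slogdet(self._info(p))
        if sign <= 0:
            return -np.inf
        return ll + 0.5 * logdet

    def _modified_score(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = self.exog
        p = _sigmoid(X @ params)
        w = p * (1.0 - p)
        info = (X * w[:, None]).T @ X
        info_inv = np.linalg.inv(info)
        # hat diagonal of W^(1/2) X I^-1 X' W^(1/2)
        h = w * np.einsum("ij,jk,ik->i", X, info_inv, X)
        score = X.T @ (self.endog - p + h * (0.5 - p))
        return score, info

    def fit(self, maxiter: int = 50, tol: float = 1e-8) -> "FirthLogitResults":
        k = self.exog.shape[1]
        params = np.zeros(k)
        pll = self.penalized_loglike(params)
        trace = [pll]
        converged = False
        n_iter = 0
        for n_iter in range(1, maxiter + 1):
            score, info = self._modified_score(params)
            if np.linalg.norm(score) < tol:
                converged = True
                break
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError as err:
                raise ConvergenceError(f"singular information matrix: {err}", trace)
            # step-halving keeps the penalized likelihood non-decreasing
            for _ in range(25):
                candidate = params + step
                new_pll = self.penalized_loglike(candidate)
                if new_pll >= pll - 1e-12:
                    break
                step = step / 2.0
            params, pll = candidate, new_pll
            trace.append(pll)
        else:
            score, info = self._modified_score(params)
            converged = np.linalg.norm(score) < tol
        if not converged:
            raise ConvergenceError(
                f"Firth Newton iterations did not converge in {maxiter} steps "
                f"(final |score| = {np.linalg.norm(score):.3g})",
                trace,
            )
        p = _sigmoid(self.exog @ params)
        cov = np.linalg.inv(self._info(p))
        return FirthLogitResults(self, params, cov, pll, n_iter)


class FirthLogitResults:
    """Fitted Firth logistic model: estimates, Wald inference, summary."""

    def __init__(self, model: FirthLogit, params, cov_params, pll, n_iter):
        self.model = model
        self.params = np.asarray(params)
        self._cov = np.asarray(cov_params)
        self.penalized_llf = float(pll)
        self.n_iter = int(n_iter)
        self.nobs = len(model.endog)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self._cov))

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.tvalues))

    def cov_params(self) -> np.ndarray:
        return self._cov

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack(
            [self.params - z * self.bse, self.params + z * self.bse]
        )

    def odds_ratios(self, alpha: float = 0.05) -> np.ndarray:
        """exp(beta) with Wald CI, rows (OR, low, high)."""
        ci = self.conf_int(alpha)
        return np.column_stack([np.exp(self.params), np.exp(ci)])

    def summary(self) -> str:
        lines = [
            "Firth Penalized Logistic Regression",
            f"  n obs: {self.nobs}   iterations: {self.n_iter}   "
            f"penalized loglik: {self.penalized_llf:.4f}",
            f"  {'term':<20}{'coef':>10}{'std err':>10}{'z':>8}"
            f"{'P>|z|':>10}{'[0.025':>10}{'0.975]':>10}",
        ]
        ci = self.conf_int()
        for j, name in enumerate(self.model.exog_names):
            lines.append(
                f"  {name:<20}{self.params[j]:>10.4f}{self.bse[j]:>10.4f}"
                f"{self.tvalues[j]:>8.2f}{self.pvalues[j]:>10.3g}"
                f"{ci[j, 0]:>10.4f}{ci[j, 1]:>10.4f}"
            )
        return "\n".join(lines)


def detect_separation(endog, exog, bound: float = 15.0, maxiter: int = 100) -> bool:
    """Detect (quasi-)complete separation by monitoring ML divergence.

    Runs plain Newton-Raphson on a standardized design and reports True
    when the coefficient norm escapes ``bound`` or the log-likelihood
    plateaus while the norm keeps growing — the signature of a monotone
    likelihood.
    """
    y = np.asarray(endog, dtype=float).ravel()
    X = np.asarray(exog, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    # standardize non-constant columns so the norm bound is scale-free
    Xs = X.copy()
    for j in range(Xs.shape[1]):
        sd = Xs[:, j].std()
        if sd > 0 and not np.allclose(Xs[:, j], Xs[0, j]):
            Xs[:, j] = (Xs[:, j] - Xs[:, j].mean()) / sd
    beta = np.zeros(Xs.shape[1])
    prev_ll = -np.inf
    prev_norm = 0.0
    for _ in range(maxiter):
        p = _sigmoid(Xs @ beta)
        w = p * (1 - p)
        info = (Xs * w[:, None]).T @ Xs + 1e-10 * np.eye(Xs.shape[1])
        score = Xs.T @ (y - p)
        try:
            beta = beta + np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return True
        norm = float(np.linalg.norm(beta))
        ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        if norm > bound:
            return True
        if abs(ll - prev_ll) < 1e-9 and norm > prev_norm + 1e-8:
            return True
        if abs(ll - prev_ll) < 1e-12 and np.linalg.norm(score) < 1e-6:
            return False
        prev_ll, prev_norm = ll, norm
    return False
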
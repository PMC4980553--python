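"""Random-intercept logistic regression by maximum likelihood.

Model: y_ij | u_i ~ Bernoulli(expit(x_ij' b + u_i)), u_i ~ N(0, s^2),
with the per-group integral evaluated by Gauss-Hermite quadrature. The
variance is parameterised as gamma = log(s) and profiled jointly with the
fixed effects; Wald intervals come from the observed information at the
optimum. This is the standard frequentist fit for clustered binary
agreement data (repeated prompt-occasions within participants).

Setting ``sigma=0`` in :meth:`RandomInterceptLogit.fit` collapses the model
to ordinary logistic regression (useful as a degenerate-limit check).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.tools import numdiff

_GAMMA_MIN, _GAMMA_MAX = -10.0, 5.0

#: |log-odds| beyond which the fit is treated as separated (flagged, NA).
_SEPARATION_BOUND = 10.0


@dataclass
class MixedLogitResults:
    """Estimates from a random-intercept logit fit.

    ``params`` holds the fixed effects, ``sigma`` the random-intercept SD.
    ``bse``/``conf_int`` are Wald quantities from the observed information;
    ``converged`` is False when the optimiser failed or the information
    matrix was singular, in which case the uncertainty fields are NaN.
    """

    params: np.ndarray
    sigma: float
    bse: np.ndarray
    llf: float
    converged: bool
    exog_names: list

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def pvalues(self) -> np.ndarray:
        from scipy.stats import norm

        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.params / self.bse
        return 2 * norm.sf(np.abs(z))

    def odds_ratio(self, name_or_idx=1, alpha: float = 0.05) -> dict:
        """OR = exp(beta) for one coefficient, with Wald CI and p-value.

        A flagged (non-converged or separated) fit yields NaN estimates.
        """
        idx = (
            self.exog_names.index(name_or_idx)
            if isinstance(name_or_idx, str)
            else int(name_or_idx)
        )
        if not self.converged:
            return {"or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "p": np.nan, "converged": False}
        lo, hi = self.conf_int(alpha)[idx]
        return {
            "or": float(np.exp(self.params[idx])),
            "ci_low": float(np.exp(lo)),
            "ci_high": float(np.exp(hi)),
            "p": float(self.pvalues()[idx]),
            "converged": self.converged,
        }


class RandomInterceptLogit:
    """Mixed logistic regression with a participant-level random intercept.

    Parameters
    ----------
    endog : array of 0/1 outcomes
    exog : design matrix (include the constant column yourself, or use
        :meth:`from_frame`)
    groups : group labels, one per row
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        codes, _ = pd.factorize(np.asarray(groups))
        self.group_codes = codes
        self.n_groups = codes.max() + 1 if len(codes) else 0
        if not set(np.unique(self.endog)) <= {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if len(self.endog) != len(self.exog) or len(self.endog) != len(codes):
            raise ValueError("endog, exog and groups must have equal length")
        self.exog_names = (
            list(exog_names) if exog_names is not None else [f"x{i}" for i in range(self.exog.shape[1])]
        )

    @classmethod
    def from_frame(cls, data: pd.DataFrame, outcome: str, predictors: list[str], group: str):
        """Build from a tidy occasion table, prepending a constant."""
        X = np.column_stack([np.ones(len(data))] + [data[p].to_numpy(float) for p in predictors])
        return cls(
            data[outcome].to_numpy(float), X, data[group].to_numpy(), ["const"] + list(predictors)
        )

    def _loglike(self, theta: np.ndarray, nodes: np.ndarray, weights: np.ndarray) -> float:
        beta, gamma = theta[:-1], theta[-1]
        sigma = np.exp(gamma)
        eta = self.exog @ beta
        u = np.sqrt(2.0) * sigma * nodes  # (K,)
        z = eta[:, None] + u[None, :]  # (n, K)
        ll_obs = self.endog[:, None] * z - np.logaddexp(0.0, z)
        grp_ll = np.zeros((self.n_groups, len(nodes)))
        np.add.at(grp_ll, self.group_codes, ll_obs)
        log_w = np.log(weights) - 0.5 * np.log(np.pi)
        return float(special.logsumexp(grp_ll + log_w[None, :], axis=1).sum())

    def _loglike_fixed(self, beta: np.ndarray) -> float:
        eta = self.exog @ beta
        return float(np.sum(self.endog * eta - np.logaddexp(0.0, eta)))

    def fit(
        self,
        n_points: int = 25,
        sigma: float | None = None,
        maxiter: int = 500,
        gtol: float = 1e-6,
    ) -> MixedLogitResults:
        """Maximise the marginal likelihood.

        ``sigma=None`` (default) estimates the random-intercept SD;
        ``sigma=0`` fixes it at zero (plain logit); any positive value
        fixes it there. Non-convergence or a singular information matrix is
        flagged, never raised.
        """
        k = self.exog.shape[1]
        nodes, weights = np.polynomial.hermite.hermgauss(n_points)

        # start from the pooled logit solution
        beta0 = np.zeros(k)
        try:
            res0 = optimize.minimize(
                lambda b: -self._loglike_fixed(b), beta0, method="BFGS",
                options={"maxiter": 200},
            )
            beta0 = res0.x
        except Exception:
            pass

        if sigma is not None and sigma == 0:
            nll = lambda b: -self._loglike_fixed(b)
            res = optimize.minimize(nll, beta0, method="BFGS", options={"maxiter": maxiter, "gtol": gtol})
            params, llf, ok = res.x, -res.fun, bool(res.success)
            hess = numdiff.approx_hess(params, lambda b: -self._loglike_fixed(b))
            bse, ok_h = self._bse_from_hess(hess, k)
            ok = ok and ok_h and bool(np.abs(params).max() <= _SEPARATION_BOUND)
            return MixedLogitResults(params, 0.0, bse, llf, ok, self.exog_names)

        if sigma is not None:
            gamma_fix = np.log(sigma)
            nll = lambda b: -self._loglike(np.append(b, gamma_fix), nodes, weights)
            res = optimize.minimize(nll, beta0, method="BFGS", options={"maxiter": maxiter, "gtol": gtol})
            hess = numdiff.approx_hess(res.x, nll)
            bse, ok_h = self._bse_from_hess(hess, k)
            ok = bool(res.success) and ok_h and bool(np.abs(res.x).max() <= _SEPARATION_BOUND)
            return MixedLogitResults(res.x, float(sigma), bse, -res.fun, ok, self.exog_names)

        theta0 = np.append(beta0, np.log(0.5))
        nll = lambda th: -self._loglike(th, nodes, weights)
        res = optimize.minimize(
            nll,
            theta0,
            method="L-BFGS-B",
            bounds=[(None, None)] * k + [(_GAMMA_MIN, _GAMMA_MAX)],
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol},
        )
        theta = res.x
        params, gamma = theta[:-1], theta[-1]
        sigma_hat = float(np.exp(gamma))
        at_zero_boundary = gamma <= _GAMMA_MIN + 1e-6
        hess = numdiff.approx_hess(theta, nll)
        if at_zero_boundary:
            # variance estimated at zero: report fixed-effect SEs from the
            # beta block only (the gamma direction is degenerate there)
            bse, ok_h = self._bse_from_hess(hess[:k, :k], k)
            sigma_hat = 0.0
        else:
            bse, ok_h = self._bse_from_hess(hess, k)
        converged = (
            bool(res.success)
            and ok_h
            and bool(np.all(np.isfinite(params)))
            and bool(np.abs(params).max() <= _SEPARATION_BOUND)
        )
        return MixedLogitResults(params, sigma_hat, bse, -res.fun, converged, self.exog_names)

    @staticmethod
    def _bse_from_hess(hess: np.ndarray, k: int) -> tuple[np.ndarray, bool]:
        try:
            cov = np.linalg.inv(hess)
            var = np.diag(cov)[:k]
            if np.any(var <= 0) or not np.all(np.isfinite(var)):
                raise np.linalg.LinAlgError
            return np.sqrt(var), True
        except np.linalg.LinAlgError:
            return np.full(k, np.nan), False
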
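"""Maximum-likelihood logit estimation for forced-choice DCE data.

The analysis treats each alternative of each answered question as one
Bernoulli observation: ``chosen ~ logistic(alpha + sum_i beta_i x_i)``
where ``x`` is the alternative's 0/1 level vector.  Expanding a question
into its two complementary rows makes the intercept-bearing utility
``U = alpha + sum(beta x)`` directly available for the preference tables.

:class:`BinaryLogit` fits this model by Newton–Raphson with step-halving;
:class:`MixedLogit` adds a Normal respondent-level random intercept,
integrated out by Gauss–Hermite quadrature.  Both follow scikit-learn's
estimator conventions (``fit``/``predict_proba``, ``get_params``, fitted
attributes with a trailing underscore) and compose with sklearn tooling.

Two statistical caveats of the row expansion, derived and verified in
docs/methods.md: the two rows of a question are perfectly anticorrelated,
so information-based standard errors are optimistic (cluster-robust SEs
are available via ``cov_type="cluster"``), and the respondent random
intercept is unidentifiable on the full expansion (its MLE is always 0);
``MixedLogit(collapse_pairs=True)`` fits one Bernoulli per question
instead, under which the variance component is identified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .qc import RawResponseSet

__all__ = [
    "AlternativeRows",
    "LogitFit",
    "MixedLogitSpec",
    "BinaryLogit",
    "MixedLogit",
    "ConditionalLogit",
    "SeparationError",
    "RankDeficiencyError",
    "expand_to_rows",
    "fit_binary_logit",
    "fit_mixed_logit",
    "mcfadden_pseudo_r2",
]

Z95 = 1.96  # Normal multiplier for 95% Wald intervals


class SeparationError(RuntimeError):
    """Likelihood unbounded: some direction separates chosen from unchosen."""


class RankDeficiencyError(ValueError):
    """Design matrix not of full column rank."""


@dataclass
class AlternativeRows:
    """Long-format model frame: one row per respondent x question x alternative.

    ``frame`` columns: respondent_id, question_index, alternative,
    ``level_<attr>`` per attribute, chosen (0/1).
    """

    frame: pd.DataFrame
    attributes: tuple[str, ...]

    @property
    def level_columns(self) -> list[str]:
        return [f"level_{a}" for a in self.attributes]

    def design_matrix(self) -> np.ndarray:
        return self.frame[self.level_columns].to_numpy(dtype=float)

    def outcomes(self) -> np.ndarray:
        return self.frame["chosen"].to_numpy(dtype=float)

    def groups(self) -> np.ndarray:
        return self.frame["respondent_id"].to_numpy()


def expand_to_rows(responses: RawResponseSet, warn_missing: bool = True) -> AlternativeRows:
    """Expand each answered question into its two alternative rows.

    The selected side gets ``chosen = 1``, the other 0.  Questions without
    a recorded choice are skipped (with a warning unless suppressed); a
    fully QC'd input has none.
    """
    design = responses.design
    attrs = design.scheme.attributes
    rows = []
    n_missing = 0
    for rid, rec in responses.records.items():
        for q, choice in zip(design.questions, rec):
            if choice is None:
                n_missing += 1
                continue
            for side in ("A", "B"):
                rows.append(
                    (rid, q.index, side, *q.option(side), int(side == choice))
                )
    if n_missing and warn_missing:
        import warnings

        warnings.warn(f"skipped {n_missing} unanswered questions", stacklevel=2)
    frame = pd.DataFrame(
        rows,
        columns=["respondent_id", "question_index", "alternative",
                 *[f"level_{a}" for a in attrs], "chosen"],
    )
    return AlternativeRows(frame=frame, attributes=tuple(attrs))


@dataclass
class LogitFit:
    """Fit report: estimates with Wald inference and fit statistics.

    ``betas``/``se``/``ci95``/``p_values`` are keyed by attribute name,
    with the intercept under ``alpha``/``se_alpha`` etc.  ``pseudo_r2`` is
    McFadden's 1 - loglik/loglik_null.
    """

    alpha: float
    betas: dict[str, float]
    se_alpha: float
    se: dict[str, float]
    ci95_alpha: tuple[float, float]
    ci95: dict[str, tuple[float, float]]
    p_alpha: float
    p_values: dict[str, float]
    loglik: float
    loglik_null: float
    pseudo_r2: float
    converged: bool
    n_obs: int
    model: str = "binary_logit"
    sigma_re: float | None = None
    se_sigma_re: float | None = None

    def coefficient_dict(self) -> dict[str, float]:
        return {"alpha": self.alpha, **self.betas}

    def to_json(self, path: str | Path | None = None) -> str:
        data = {
            "model": self.model,
            "alpha": self.alpha,
            "betas": self.betas,
            "se": {"alpha": self.se_alpha, **self.se},
            "ci95": {"alpha": list(self.ci95_alpha),
                     **{k: list(v) for k, v in self.ci95.items()}},
            "p_values": {"alpha": self.p_alpha, **self.p_values},
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "pseudo_r2": self.pseudo_r2,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }
        if self.sigma_re is not None:
            data["sigma_re"] = self.sigma_re
            data["se_sigma_re"] = self.se_sigma_re
        text = json.dumps(data, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary_table(self) -> str:
        """Plain-text table in the published layout: coefficient (95% CI), p."""
        lines = [f"{'Attribute':<16} {'Coefficient (95% CI)':<32} P value"]
        rows = [("Intercept", self.alpha, self.ci95_alpha, self.p_alpha)]
        rows += [(a, self.betas[a], self.ci95[a], self.p_values[a]) for a in self.betas]
        for name, est, (lo, hi), p in rows:
            ptxt = "<.001" if p < 0.001 else f"{p:.3f}"
            lines.append(f"{name:<16} {est:.3f} ({lo:.3f} to {hi:.3f})".ljust(49) + ptxt)
        lines.append(f"log-likelihood: {self.loglik:.4f}   "
                     f"null: {self.loglik_null:.4f}   "
                     f"pseudo R-squared: {self.pseudo_r2:.4f}")
        if self.sigma_re is not None:
            lines.append(f"sigma_re: {self.sigma_re:.4f}")
        return "\n".join(lines)


def mcfadden_pseudo_r2(loglik: float, loglik_null: float) -> float:
    """McFadden's pseudo R-squared, ``1 - loglik/loglik_null``."""
    if loglik_null == 0:
        raise ZeroDivisionError("null log-likelihood is zero; pseudo R2 undefined")
    return 1.0 - loglik / loglik_null


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of dependent columns via QR pivoting
        from scipy.linalg import qr

        _, r, piv = qr(X, pivoting=True, mode="economic")
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        dependent = [names[piv[i]] for i in range(X.shape[1]) if diag[i] <= tol]
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {dependent}"
        )


def _null_loglik(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n = y.size
    return n * (p * np.log(p) + (1 - p) * np.log(1 - p))


class BinaryLogit(BaseEstimator):
    """Binary logit by Newton–Raphson maximum likelihood.

    Parameters
    ----------
    tol_grad : float
        Convergence when the gradient max-norm drops below this.
    tol_params : float
        ... or when the parameter update max-norm drops below this.
    max_iter : int
        Newton iteration cap.
    cov_type : {"observed", "cluster"}
        "observed" takes SEs from the inverse observed information (the
        conventional logit output, and what the published table reports);
        "cluster" uses the sandwich estimator with clusters from the
        ``groups`` argument of :meth:`fit`, which is the design-consistent
        choice for complementary row expansions.

    Attributes
    ----------
    intercept_, coef_ : fitted parameters.
    se_, ci95_, p_values_ : Wald inference, intercept first.
    loglik_, loglik_null_, pseudo_r2_, converged_, n_obs_, n_iter_.
    """

    def __init__(
        self,
        tol_grad: float = 1e-8,
        tol_params: float = 1e-10,
        max_iter: int = 100,
        cov_type: str = "observed",
    ) -> None:
        self.tol_grad = tol_grad
        self.tol_params = tol_params
        self.max_iter = max_iter
        self.cov_type = cov_type

    # -- likelihood pieces -------------------------------------------------
    @staticmethod
    def _loglik(theta: np.ndarray, Xc: np.ndarray, y: np.ndarray) -> float:
        eta = Xc @ theta
        return float(np.sum(y * log_expit(eta) + (1 - y) * log_expit(-eta)))

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per outcome")
        if y.min() < 0 or y.max() > 1 or not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("y must be binary 0/1")
        if y.sum() == 0 or y.sum() == y.size:
            raise SeparationError("outcomes are all 0 or all 1")
        n, k = X.shape
        names = ["intercept"] + [f"x{j}" for j in range(k)]
        Xc = np.column_stack([np.ones(n), X])
        _check_rank(Xc, names)

        theta = np.zeros(k + 1)
        ll = self._loglik(theta, Xc, y)
        ll_path = [ll]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            p = expit(Xc @ theta)
            g = Xc.T @ (y - p)
            W = p * (1 - p)
            H = Xc.T @ (Xc * W[:, None])
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError as exc:  # flat Hessian => separation
                raise SeparationError(
                    f"singular information matrix at iteration {it}: {exc}"
                ) from exc
            # step-halving: never decrease the log-likelihood
            scale = 1.0
            for _ in range(50):
                cand = theta + scale * step
                ll_new = self._loglik(cand, Xc, y)
                if ll_new >= ll - 1e-13:
                    break
                scale /= 2
            theta, ll = cand, ll_new
            ll_path.append(ll)
            if np.max(np.abs(g)) < self.tol_grad or np.max(np.abs(scale * step)) < self.tol_params:
                converged = True
                break
        # diverging coefficients mean the likelihood is unbounded along that
        # direction (complete or quasi-complete separation); the gradient
        # vanishing as probabilities saturate is not convergence
        big = np.abs(theta) > 25
        if big.any():
            direction = ", ".join(np.array(names)[big])
            raise SeparationError(
                "likelihood appears unbounded (separation); "
                f"diverging direction: {direction}"
            )

        p = expit(Xc @ theta)
        H = Xc.T @ (Xc * (p * (1 - p))[:, None])
        info_inv = np.linalg.inv(H)
        if self.cov_type == "cluster":
            if groups is None:
                raise ValueError("cov_type='cluster' requires groups")
            cov = info_inv @ _cluster_meat(Xc, y - p, np.asarray(groups)) @ info_inv
        elif self.cov_type == "observed":
            cov = info_inv
        else:
            raise ValueError(f"unknown cov_type {self.cov_type!r}")

        se = np.sqrt(np.diag(cov))
        z = theta / se
        self.intercept_ = float(theta[0])
        self.coef_ = theta[1:].copy()
        self.params_ = theta
        self.cov_ = cov
        self.se_ = se
        self.ci95_ = np.column_stack([theta - Z95 * se, theta + Z95 * se])
        self.p_values_ = 2 * norm.sf(np.abs(z))
        self.loglik_ = ll
        self.loglik_null_ = _null_loglik(y)
        self.pseudo_r2_ = mcfadden_pseudo_r2(ll, self.loglik_null_)
        self.converged_ = converged
        self.n_obs_ = n
        self.n_iter_ = it
        self.loglik_path_ = ll_path
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        p = expit(self.intercept_ + X @ self.coef_)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _cluster_meat(Xc: np.ndarray, resid: np.ndarray, groups: np.ndarray) -> np.ndarray:
    scores = Xc * resid[:, None]
    frame = pd.DataFrame(scores)
    sums = frame.groupby(groups).sum().to_numpy()
    return sums.T @ sums


@dataclass(frozen=True)
class MixedLogitSpec:
    """Random-effect specification: Normal respondent intercept,
    integrated by ``n_quadrature``-node Gauss–Hermite quadrature."""

    n_quadrature: int = 31
    collapse_pairs: bool = False
    fix_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.n_quadrature < 5:
            raise ValueError("n_quadrature must be >= 5")
        if self.fix_sigma is not None and self.fix_sigma < 0:
            raise ValueError("fix_sigma must be >= 0")


class MixedLogit(BaseEstimator):
    """Binary logit with a Normal respondent-level random intercept.

    The marginal likelihood integrates the intercept with probabilist's
    Gauss–Hermite quadrature, accumulated in log space so small node
    likelihoods never underflow to zero.  ``collapse_pairs=True`` keeps
    one Bernoulli per question (the option-A side) instead of the full
    two-row expansion; see the module docstring for why this is the mode
    in which the variance component is identified.

    Attributes: ``intercept_``, ``coef_``, ``sigma_re_``, ``se_`` (from
    the numerical Hessian; NaN for sigma at the 0 boundary), ``loglik_``,
    ``converged_``.
    """

    def __init__(
        self,
        n_quadrature: int = 31,
        fix_sigma: float | None = None,
        max_iter: int = 200,
        tol: float = 1e-9,
    ) -> None:
        self.n_quadrature = n_quadrature
        self.fix_sigma = fix_sigma
        self.max_iter = max_iter
        self.tol = tol

    def _prepare(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        groups = np.asarray(groups)
        codes, _ = pd.factorize(groups)
        nodes, weights = hermegauss(self.n_quadrature)  # weight e^{-z^2/2}
        logw = np.log(weights / np.sqrt(2 * np.pi))
        Xc = np.column_stack([np.ones(y.size), X])
        return Xc, y, codes, nodes, logw

    def marginal_loglik(self, params: np.ndarray, sigma: float, X, y, groups) -> float:
        """Marginal log-likelihood at given fixed effects and sigma."""
        Xc, y, codes, nodes, logw = self._prepare(X, y, groups)
        return self._mll(np.append(params, sigma), Xc, y, codes, nodes, logw)

    @staticmethod
    def _mll(theta, Xc, y, codes, nodes, logw) -> float:
        *fixed, sigma = theta
        eta = Xc @ np.asarray(fixed)
        # rows x nodes conditional log-likelihood contributions
        shift = sigma * nodes[None, :]
        sign = (2 * y - 1)[:, None]
        cll = log_expit(sign * (eta[:, None] + shift))
        n_groups = codes.max() + 1
        per_group = np.zeros((n_groups, nodes.size))
        np.add.at(per_group, codes, cll)
        return float(logsumexp(per_group + logw[None, :], axis=1).sum())

    def fit(self, X, y, groups):
        Xc, y, codes, nodes, logw = self._prepare(X, y, groups)
        k = Xc.shape[1]

        start = BinaryLogit().fit(np.asarray(X, float), y).params_

        if self.fix_sigma is not None:
            sigma0 = self.fix_sigma

            def nll(fixed):
                return -self._mll(np.append(fixed, sigma0), Xc, y, codes, nodes, logw)

            res = minimize(nll, start, method="BFGS",
                           options={"maxiter": self.max_iter, "gtol": 1e-7})
            theta = np.append(res.x, sigma0)
        else:
            def nll(t):
                return -self._mll(t, Xc, y, codes, nodes, logw)

            res = minimize(
                nll,
                np.append(start, 0.5),
                method="L-BFGS-B",
                bounds=[(None, None)] * k + [(0.0, None)],
                options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-8},
            )
            theta = res.x

        self.params_ = theta
        self.intercept_ = float(theta[0])
        self.coef_ = theta[1:k].copy()
        self.sigma_re_ = float(theta[-1])
        self.loglik_ = -float(res.fun)
        self.converged_ = bool(res.success)
        self.n_obs_ = y.size

        se = np.full(k + 1, np.nan)
        at_boundary = self.fix_sigma is None and self.sigma_re_ < 1e-6
        hess_idx = list(range(k)) if (self.fix_sigma is not None or at_boundary) else list(range(k + 1))
        H = _numerical_hessian(
            lambda t: self._mll(_merge(theta, hess_idx, t), Xc, y, codes, nodes, logw),
            theta[hess_idx],
        )
        try:
            cov = np.linalg.inv(-H)
            se[hess_idx] = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            pass
        self.se_ = se
        self.loglik_null_ = _null_loglik(y)
        self.pseudo_r2_ = mcfadden_pseudo_r2(self.loglik_, self.loglik_null_)
        return self


def _merge(theta: np.ndarray, idx: list[int], values: np.ndarray) -> np.ndarray:
    out = theta.copy()
    out[idx] = values
    return out


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    n = x.size
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h**2)
    return H


class ConditionalLogit(BaseEstimator):
    """Paired (conditional) logit on within-question level differences.

    A labelled extension, off the default pipeline path: models
    ``P(choose A) = logistic(beta . (x_A - x_B))`` with no intercept (it
    cancels within a pair).  On a complementary design the row-expanded
    binary-logit likelihood is exactly twice this likelihood at half the
    coefficient scale, so the conditional-logit estimates equal half the
    row-logit betas.
    """

    def __init__(self, tol_grad: float = 1e-8, max_iter: int = 100) -> None:
        self.tol_grad = tol_grad
        self.max_iter = max_iter

    def fit(self, X_diff, chose_a):
        X = np.asarray(X_diff, dtype=float)
        y = np.asarray(chose_a, dtype=float).ravel()
        theta = np.zeros(X.shape[1])
        ll = float(np.sum(y * log_expit(X @ theta) + (1 - y) * log_expit(-X @ theta)))
        for _ in range(self.max_iter):
            p = expit(X @ theta)
            g = X.T @ (y - p)
            H = X.T @ (X * (p * (1 - p))[:, None])
            step = np.linalg.solve(H, g)
            theta = theta + step
            if np.max(np.abs(g)) < self.tol_grad:
                break
        p = expit(X @ theta)
        H = X.T @ (X * (p * (1 - p))[:, None])
        self.coef_ = theta
        self.se_ = np.sqrt(np.diag(np.linalg.inv(H)))
        self.loglik_ = float(np.sum(y * log_expit(X @ theta) + (1 - y) * log_expit(-X @ theta)))
        return self


# -- module-level wrappers over the estimators -----------------------------

def _fit_to_report(est, attrs: tuple[str, ...], model: str,
                   sigma: float | None = None, se_sigma: float | None = None) -> LogitFit:
    se = est.se_
    theta = est.params_[: len(attrs) + 1]
    ci = np.column_stack([theta - Z95 * se[: theta.size], theta + Z95 * se[: theta.size]])
    p = 2 * norm.sf(np.abs(theta / se[: theta.size]))
    return LogitFit(
        alpha=float(theta[0]),
        betas={a: float(v) for a, v in zip(attrs, theta[1:])},
        se_alpha=float(se[0]),
        se={a: float(v) for a, v in zip(attrs, se[1 : theta.size])},
        ci95_alpha=(float(ci[0, 0]), float(ci[0, 1])),
        ci95={a: (float(lo), float(hi)) for a, (lo, hi) in zip(attrs, ci[1:])},
        p_alpha=float(p[0]),
        p_values={a: float(v) for a, v in zip(attrs, p[1:])},
        loglik=float(est.loglik_),
        loglik_null=float(est.loglik_null_),
        pseudo_r2=float(est.pseudo_r2_),
        converged=bool(est.converged_),
        n_obs=int(est.n_obs_),
        model=model,
        sigma_re=sigma,
        se_sigma_re=se_sigma,
    )


def fit_binary_logit(rows: AlternativeRows, cov_type: str = "observed") -> LogitFit:
    """Fit the plain binary logit to the alternative rows."""
    est = BinaryLogit(cov_type=cov_type)
    est.fit(rows.design_matrix(), rows.outcomes(),
            groups=rows.groups() if cov_type == "cluster" else None)
    return _fit_to_report(est, rows.attributes, "binary_logit")


def _collapse_to_choices(rows: AlternativeRows) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One Bernoulli per question: option-A levels, chose-A flag, respondent."""
    f = rows.frame
    a_side = f[f["alternative"] == "A"]
    return (
        a_side[rows.level_columns].to_numpy(dtype=float),
        a_side["chosen"].to_numpy(dtype=float),
        a_side["respondent_id"].to_numpy(),
    )


def fit_mixed_logit(rows: AlternativeRows, spec: MixedLogitSpec = MixedLogitSpec()) -> LogitFit:
    """Fit the mixed binary logit (Normal random respondent intercept)."""
    est = MixedLogit(n_quadrature=spec.n_quadrature, fix_sigma=spec.fix_sigma)
    if spec.collapse_pairs:
        X, y, g = _collapse_to_choices(rows)
    else:
        X, y, g = rows.design_matrix(), rows.outcomes(), rows.groups()
    est.fit(X, y, groups=g)
    fit = _fit_to_report(
        est, rows.attributes, "mixed_logit",
        sigma=est.sigma_re_, se_sigma=float(est.se_[-1]) if spec.fix_sigma is None else None,
    )
    return fit
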
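"""Graded response model for three-category items.

The model: for item :math:`j` with discrimination :math:`a_j` and ordered
thresholds :math:`b_{j1} < b_{j2}`, the boundary ("at least category c")
probabilities are logistic in the latent ability :math:`\\theta`,

.. math:: p^*_{jc}(\\theta) = \\frac{1}{1 + \\exp[-D a_j(\\theta - b_{jc})]},

and the category probabilities are differences of adjacent boundaries
(:math:`p^*_{j0} \\equiv 1`, :math:`p^*_{j3} \\equiv 0`).  Item parameters are
estimated by marginal maximum likelihood with a standard-normal latent prior
via an EM algorithm; abilities are scored by the posterior mean (EAP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, logsumexp
from scipy.optimize import minimize
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .config import ModelSpec, DEFAULT_D

logger = logging.getLogger(__name__)

_PFLOOR = 1e-12


class InestimableItemError(ValueError):
    """An item has a never-observed category, so a threshold is inestimable."""


# ---------------------------------------------------------------------------
# model primitives
# ---------------------------------------------------------------------------

def boundary_probability(a, b, theta, D: float = DEFAULT_D):
    """Boundary probability ``P(X >= c | theta)`` = logistic(D*a*(theta-b)).

    Vectorized over any broadcastable combination of arguments; saturates
    smoothly at extreme ``theta`` without overflow.
    """
    return expit(D * np.asarray(a) * (np.asarray(theta) - np.asarray(b)))


def category_probabilities(a, b1, b2, theta, D: float = DEFAULT_D):
    """Category probabilities ``(p0, p1, p2)`` stacked on the last axis.

    ``p0 = 1 - p*_1``, ``p1 = p*_1 - p*_2``, ``p2 = p*_2``.
    """
    b1a, b2a = np.asarray(b1, dtype=float), np.asarray(b2, dtype=float)
    if np.any(b1a >= b2a):
        raise ValueError("invalid item parameters: requires b1 < b2")
    ps1 = boundary_probability(a, b1, theta, D)
    ps2 = boundary_probability(a, b2, theta, D)
    return np.stack([1.0 - ps1, ps1 - ps2, ps2], axis=-1)


def item_information(a, b1, b2, theta, D: float = DEFAULT_D):
    """Fisher information of one graded item at ability ``theta``.

    .. math::
       I_j(\\theta) = D^2 a_j^2 \\sum_{c=0}^{2}
         \\frac{[p^*_c q^*_c - p^*_{c+1} q^*_{c+1}]^2}{p_c(\\theta)},

    with :math:`q^* = 1 - p^*` and the conventions :math:`p^*_0 = 1`,
    :math:`p^*_3 = 0` (so the first and last :math:`p^*q^*` terms vanish).
    """
    ps1 = boundary_probability(a, b1, theta, D)
    ps2 = boundary_probability(a, b2, theta, D)
    w1 = ps1 * (1.0 - ps1)
    w2 = ps2 * (1.0 - ps2)
    p = category_probabilities(a, b1, b2, theta, D)
    num = np.stack([(0.0 - w1) ** 2, (w1 - w2) ** 2, (w2 - 0.0) ** 2], axis=-1)
    terms = num / np.maximum(p, _PFLOOR)
    a2 = np.broadcast_to(np.asarray(a, dtype=float), np.asarray(ps1).shape) ** 2
    return (D * D) * a2 * terms.sum(axis=-1)


def test_information(a, b1, b2, theta, D: float = DEFAULT_D):
    """Test information: sum of item informations over an item bank.

    ``a, b1, b2`` are length-J vectors; ``theta`` may be scalar or a grid.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    if a.size == 0:
        raise ValueError("empty item bank")
    th = np.asarray(theta, dtype=float)
    info = item_information(
        a[:, None], np.atleast_1d(b1)[:, None], np.atleast_1d(b2)[:, None],
        th[None, ...] if th.ndim else th, D,
    )
    return info.sum(axis=0)


# ---------------------------------------------------------------------------
# quadrature and marginal likelihood
# ---------------------------------------------------------------------------

def _quadrature(spec: ModelSpec):
    """Fixed rectangular grid with normalized standard-normal weights."""
    lo, hi = spec.quadrature_bounds
    nodes = np.linspace(lo, hi, spec.n_quadrature)
    logw = norm.logpdf(nodes)
    logw -= logsumexp(logw)
    return nodes, logw


def _log_category_probs(a, b1, b2, nodes, D):
    """log p_jc(theta_q), shape (J, Q, 3), floored for numerical safety."""
    z1 = D * a[:, None] * (nodes[None, :] - b1[:, None])
    z2 = D * a[:, None] * (nodes[None, :] - b2[:, None])
    ps1, ps2 = expit(z1), expit(z2)
    p = np.stack([1.0 - ps1, ps1 - ps2, ps2], axis=-1)
    # boundary categories have exact stable forms; the middle one is floored
    logp = np.log(np.maximum(p, _PFLOOR))
    logp[..., 0] = log_expit(-z1)
    logp[..., 2] = log_expit(z2)
    return logp


def _case_log_likelihood(X, logp):
    """Σ_j log p_{j, x_ij}(theta_q) for every case/node, shape (n, Q)."""
    n, J = X.shape
    Q = logp.shape[1]
    out = np.zeros((n, Q))
    for c in range(3):
        mask = (X == c).astype(float)  # (n, J)
        out += mask @ logp[:, :, c]
    return out


def marginal_log_likelihood(X, a, b1, b2, spec: ModelSpec | None = None) -> float:
    """Marginal log-likelihood under a standard-normal latent prior.

    ``Σ_i log ∫ Π_j p_{j,x_ij}(θ) φ(θ) dθ``, evaluated on the spec's fixed
    quadrature with log-sum-exp underflow protection.
    """
    spec = spec or ModelSpec()
    X = np.asarray(X)
    nodes, logw = _quadrature(spec)
    logp = _log_category_probs(np.asarray(a, float), np.asarray(b1, float),
                               np.asarray(b2, float), nodes, spec.D)
    ll = _case_log_likelihood(X, logp)
    return float(logsumexp(ll + logw[None, :], axis=1).sum())


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

@dataclass
class AbilityEstimate:
    case_id: int
    theta_hat: float
    posterior_sd: float


def _validate_responses(X):
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("response matrix must be 2-D (cases x items)")
    if not np.issubdtype(X.dtype, np.integer):
        Xf = np.asarray(X, dtype=float)
        if np.any(Xf != np.round(Xf)) or np.any(~np.isfinite(Xf)):
            raise ValueError("responses must be integers in {0, 1, 2}")
        X = Xf.astype(int)
    if X.min() < 0 or X.max() > 2:
        raise ValueError("responses must lie in {0, 1, 2}")
    return X


def _check_observed_categories(X, item_ids):
    bad = []
    for j in range(X.shape[1]):
        observed = set(np.unique(X[:, j]).tolist())
        missing = {0, 1, 2} - observed
        if missing:
            bad.append((item_ids[j], sorted(missing)))
    if bad:
        detail = "; ".join(f"item {i} never shows category {m}" for i, m in bad)
        raise InestimableItemError(
            f"thresholds inestimable for {len(bad)} item(s): {detail}"
        )


class GradedResponseModel(BaseEstimator):
    """Graded response model fit by marginal maximum likelihood (EM).

    Parameters
    ----------
    model : {'2pl', '1pl'}
        '2pl' estimates one discrimination per item; '1pl' constrains a
        single discrimination shared by all items (thresholds stay free),
        giving ``2J + 1`` parameters instead of ``3J``.
    D : float
        Logistic scaling constant; the package default is 1.0 (set 1.7 to
        approximate the normal-ogive metric).
    n_quadrature, quadrature_bounds : quadrature grid for the latent prior.
    max_iter, tol : EM stopping rule — iteration ceases once the marginal
        log-likelihood improves by less than ``tol``.

    Attributes
    ----------
    discrimination_ : (J,) estimated slopes.
    thresholds_ : (J, 2) ordered category thresholds.
    loglik_ : marginal log-likelihood at the solution.
    aic_, bic_ : information criteria (``k = 3J`` or ``2J + 1``).
    converged_, n_iter_, loglik_path_ : EM diagnostics.
    """

    def __init__(self, model: str = "2pl", D: float = DEFAULT_D,
                 n_quadrature: int = 101, quadrature_bounds=(-5.0, 5.0),
                 max_iter: int = 500, tol: float = 1e-5,
                 inner_maxiter: int = 12):
        self.model = model
        self.D = D
        self.n_quadrature = n_quadrature
        self.quadrature_bounds = quadrature_bounds
        self.max_iter = max_iter
        self.tol = tol
        self.inner_maxiter = inner_maxiter

    # -- internals ---------------------------------------------------------

    def _spec(self) -> ModelSpec:
        return ModelSpec(model=self.model, D=self.D,
                         n_quadrature=self.n_quadrature,
                         quadrature_bounds=tuple(self.quadrature_bounds),
                         max_em_iterations=self.max_iter,
                         em_tolerance=self.tol)

    @staticmethod
    def _start_values(X, D):
        n, J = X.shape
        a0 = np.full(J, 1.5)
        eps = 0.5 / n
        p_ge1 = np.clip((X >= 1).mean(axis=0), eps, 1 - eps)
        p_ge2 = np.clip((X >= 2).mean(axis=0), eps, 1 - eps)
        b1 = -np.log(p_ge1 / (1 - p_ge1)) / (D * a0)
        b2 = -np.log(p_ge2 / (1 - p_ge2)) / (D * a0)
        gap = np.maximum(b2 - b1, 0.05)
        return a0, b1, np.log(gap)

    def _expected_counts(self, X, a, b1, b2, nodes, logw):
        logp = _log_category_probs(a, b1, b2, nodes, self.D)
        ll = _case_log_likelihood(X, logp)
        joint = ll + logw[None, :]
        marg = logsumexp(joint, axis=1)
        post = np.exp(joint - marg[:, None])  # (n, Q)
        r = np.empty((X.shape[1], nodes.size, 3))
        for c in range(3):
            mask = (X == c).astype(float)
            r[:, :, c] = mask.T @ post
        return float(marg.sum()), r, post

    def _mstep_objective(self, params, r, nodes, shared_a):
        """Negative expected complete-data log-likelihood and its gradient."""
        J, Q, _ = r.shape
        if shared_a:
            a = np.full(J, params[0])
            b1 = params[1:1 + J]
            g = params[1 + J:]
        else:
            a = params[0::3]
            b1 = params[1::3]
            g = params[2::3]
        gap = np.exp(g)
        b2 = b1 + gap
        z1 = self.D * a[:, None] * (nodes[None, :] - b1[:, None])
        z2 = self.D * a[:, None] * (nodes[None, :] - b2[:, None])
        P1, P2 = expit(z1), expit(z2)
        p0 = np.maximum(1.0 - P1, _PFLOOR)
        p1 = np.maximum(P1 - P2, _PFLOOR)
        p2 = np.maximum(P2, _PFLOOR)
        f = -(r[:, :, 0] * np.log(p0) + r[:, :, 1] * np.log(p1)
              + r[:, :, 2] * np.log(p2)).sum()
        # dF/dP*_1 and dF/dP*_2 (F = positive expected loglik)
        dP1 = -r[:, :, 0] / p0 + r[:, :, 1] / p1
        dP2 = -r[:, :, 1] / p1 + r[:, :, 2] / p2
        w1 = P1 * (1.0 - P1)
        w2 = P2 * (1.0 - P2)
        # chain rule through the logistic boundaries
        dF_da = (dP1 * w1 * self.D * (nodes[None, :] - b1[:, None])
                 + dP2 * w2 * self.D * (nodes[None, :] - b2[:, None])).sum(axis=1)
        dF_db1 = (-dP1 * w1 * self.D * a[:, None]).sum(axis=1)
        dF_db2 = (-dP2 * w2 * self.D * a[:, None]).sum(axis=1)
        grad = np.empty_like(params)
        if shared_a:
            grad[0] = -dF_da.sum()
            grad[1:1 + J] = -(dF_db1 + dF_db2)
            grad[1 + J:] = -dF_db2 * gap
        else:
            grad[0::3] = -dF_da
            grad[1::3] = -(dF_db1 + dF_db2)
            grad[2::3] = -dF_db2 * gap
        return f, grad

    def _mstep(self, a, b1, b2, r, nodes):
        J = a.size
        shared = self.model == "1pl"
        g = np.log(np.maximum(b2 - b1, 1e-8))
        if shared:
            x0 = np.concatenate([[a[0]], b1, g])
            bounds = [(1e-2, 100.0)] + [(None, None)] * (2 * J)
        else:
            x0 = np.empty(3 * J)
            x0[0::3], x0[1::3], x0[2::3] = a, b1, g
            bounds = []
            for _ in range(J):
                bounds.extend([(1e-2, 100.0), (None, None), (None, None)])
        res = minimize(self._mstep_objective, x0, args=(r, nodes, shared),
                       jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": self.inner_maxiter})
        x = res.x
        if shared:
            a_new = np.full(J, x[0])
            b1_new = x[1:1 + J]
            b2_new = b1_new + np.exp(x[1 + J:])
        else:
            a_new = x[0::3]
            b1_new = x[1::3]
            b2_new = b1_new + np.exp(x[2::3])
        return a_new, b1_new, b2_new

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y=None):
        """Fit by EM. ``X`` is an (n_cases, n_items) array or DataFrame of
        responses in {0, 1, 2}; DataFrame column names become item IDs."""
        if isinstance(X, pd.DataFrame):
            self.item_ids_ = list(X.columns)
            X = X.to_numpy()
        else:
            self.item_ids_ = list(range(1, np.asarray(X).shape[1] + 1))
        X = _validate_responses(X)
        _check_observed_categories(X, self.item_ids_)
        n, J = X.shape
        nodes, logw = _quadrature(self._spec())
        a, b1, g = self._start_values(X, self.D)
        b2 = b1 + np.exp(g)
        if self.model == "1pl":
            a = np.full(J, float(a.mean()))

        path = []
        prev = -np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            ll, r, _ = self._expected_counts(X, a, b1, b2, nodes, logw)
            if path and ll < path[-1] - 1e-6 * max(1.0, abs(path[-1])):
                raise RuntimeError(
                    f"EM log-likelihood decreased at iteration {it}: "
                    f"{path[-1]:.6f} -> {ll:.6f}"
                )
            path.append(ll)
            logger.debug("EM iter %d: logL = %.6f", it, ll)
            if ll - prev < self.tol and it > 1:
                converged = True
                break
            prev = ll
            a, b1, b2 = self._mstep(a, b1, b2, r, nodes)

        # final evaluation at the last parameter update
        ll, _, _ = self._expected_counts(X, a, b1, b2, nodes, logw)
        if ll >= path[-1]:
            path.append(ll)
        self.discrimination_ = a
        self.thresholds_ = np.column_stack([b1, b2])
        self.loglik_ = float(path[-1])
        self.loglik_path_ = np.asarray(path)
        self.n_iter_ = it
        self.converged_ = converged
        if not converged:
            logger.warning("EM did not converge in %d iterations", self.max_iter)
        self.n_cases_ = n
        self.n_items_ = J
        self.n_parameters_ = 3 * J if self.model == "2pl" else 2 * J + 1
        self.aic_ = -2.0 * self.loglik_ + 2.0 * self.n_parameters_
        self.bic_ = -2.0 * self.loglik_ + self.n_parameters_ * np.log(n)
        self._nodes, self._logw = nodes, logw
        return self

    def score(self, X, y=None) -> float:
        """Marginal log-likelihood of ``X`` under the fitted parameters."""
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        X = _validate_responses(X)
        b = self.thresholds_
        return marginal_log_likelihood(X, self.discrimination_, b[:, 0], b[:, 1],
                                       self._spec())

    def predict(self, X):
        """EAP ability estimates (posterior means), shape (n_cases,)."""
        return self.predict_theta(X)[0]

    def predict_theta(self, X):
        """EAP estimates and posterior standard deviations.

        Returns ``(theta_hat, posterior_sd)`` under the standard-normal prior
        evaluated on the fit's quadrature grid.
        """
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        X = _validate_responses(X)
        nodes, logw = self._nodes, self._logw
        b = self.thresholds_
        logp = _log_category_probs(self.discrimination_, b[:, 0], b[:, 1],
                                   nodes, self.D)
        ll = _case_log_likelihood(X, logp)
        joint = ll + logw[None, :]
        post = np.exp(joint - logsumexp(joint, axis=1)[:, None])
        mean = post @ nodes
        var = post @ (nodes ** 2) - mean ** 2
        return mean, np.sqrt(np.maximum(var, 0.0))

    # -- serialization ------------------------------------------------------

    def items_frame(self) -> pd.DataFrame:
        """Fitted item parameters as a ``item_id, a, b1, b2`` DataFrame."""
        return pd.DataFrame({
            "item_id": self.item_ids_,
            "a": self.discrimination_,
            "b1": self.thresholds_[:, 0],
            "b2": self.thresholds_[:, 1],
        })

    def fit_result(self) -> dict:
        """JSON-serializable summary of the fit."""
        return {
            "model": self.model,
            "D": self.D,
            "n_quadrature": self.n_quadrature,
            "items": self.items_frame().to_dict(orient="records"),
            "logL": self.loglik_,
            "k": self.n_parameters_,
            "AIC": self.aic_,
            "BIC": self.bic_,
            "n_cases_used": self.n_cases_,
            "converged": bool(self.converged_),
            "iterations": int(self.n_iter_),
        }


def fit_grm(X, spec: ModelSpec | None = None) -> GradedResponseModel:
    """Functional wrapper: fit a :class:`GradedResponseModel` under ``spec``."""
    spec = spec or ModelSpec()
    est = GradedResponseModel(model=spec.model, D=spec.D,
                              n_quadrature=spec.n_quadrature,
                              quadrature_bounds=spec.quadrature_bounds,
                              max_iter=spec.max_em_iterations,
                              tol=spec.em_tolerance)
    return est.fit(X)


def estimate_abilities(X, fit: GradedResponseModel, case_ids=None) -> pd.DataFrame:
    """EAP abilities for every case as a ``case_id, theta_hat, posterior_sd``
    DataFrame (finite for every response pattern)."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    theta, sd = fit.predict_theta(X)
    if case_ids is None:
        case_ids = np.arange(1, len(theta) + 1)
    return pd.DataFrame({"case_id": np.asarray(case_ids),
                         "theta_hat": theta, "posterior_sd": sd})
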
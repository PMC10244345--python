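"""Unidimensionality and reliability diagnostics.

Polychoric correlations (two-step estimator), eigenvalue/parallel analysis of
the polychoric matrix, and Cronbach's alpha on the raw 0/1/2 scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import owens_t
from scipy.stats import norm

logger = logging.getLogger(__name__)

_THRESH_CLAMP = 8.0  # Phi(±8) is 0/1 to within 7e-16
_RHO_BOUND = 0.999


def bvn_cdf(h, k, rho):
    """Standard bivariate normal CDF ``P(X <= h, Y <= k)`` via Owen's T.

    Vectorized over broadcastable arguments; accurate to ~1e-14 for
    ``|rho| <= 0.999``.
    """
    h, k, rho = np.broadcast_arrays(np.asarray(h, float), np.asarray(k, float),
                                    np.asarray(rho, float))
    h = np.where(np.abs(h) < 1e-12, 1e-12, h)
    k = np.where(np.abs(k) < 1e-12, 1e-12, k)
    rho = np.clip(rho, -_RHO_BOUND - 1e-6, _RHO_BOUND + 1e-6)
    s = np.sqrt(np.maximum(1.0 - rho * rho, 1e-12))
    a_h = (k - rho * h) / (h * s)
    a_k = (h - rho * k) / (k * s)
    delta = np.where(h * k > 0, 0.0, 0.5)
    out = (0.5 * (norm.cdf(h) + norm.cdf(k))
           - owens_t(h, a_h) - owens_t(k, a_k) - delta)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# polychoric correlation
# ---------------------------------------------------------------------------

def _thresholds_from_margins(x, n_categories: int = 3):
    """Normal-scale category thresholds from marginal cumulative proportions."""
    n = len(x)
    counts = np.bincount(x, minlength=n_categories).astype(float)
    if (counts > 0).sum() < 2:
        raise ValueError("variable with a single observed category: "
                         "polychoric correlation undefined")
    cum = np.cumsum(counts)[:-1] / n
    return np.clip(norm.ppf(cum), -_THRESH_CLAMP, _THRESH_CLAMP)


def _cell_log_probs(tx, ty, rho):
    """Log cell probabilities of the 3x3 table under a bivariate normal."""
    ex = np.concatenate([[-_THRESH_CLAMP * 2], tx, [_THRESH_CLAMP * 2]])
    ey = np.concatenate([[-_THRESH_CLAMP * 2], ty, [_THRESH_CLAMP * 2]])
    F = bvn_cdf(ex[:, None], ey[None, :], rho)
    p = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    return np.log(np.maximum(p, 1e-12))


def _pair_neg_loglik(rho, counts, tx, ty):
    return -float((counts * _cell_log_probs(tx, ty, rho)).sum())


def polychoric_correlation(x, y) -> float:
    """Two-step polychoric correlation of two three-category variables.

    Thresholds come from the marginal cumulative proportions via the inverse
    normal; the correlation maximizes the bivariate-normal likelihood of the
    contingency table over (-0.999, 0.999).  Deterministic.
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D category vectors")
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    tx = _thresholds_from_margins(x)
    ty = _thresholds_from_margins(y)
    counts = np.bincount(3 * x + y, minlength=9).reshape(3, 3).astype(float)
    res = minimize_scalar(_pair_neg_loglik, bounds=(-_RHO_BOUND, _RHO_BOUND),
                          args=(counts, tx, ty), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


@dataclass
class PolychoricMatrix:
    item_ids: np.ndarray
    rho: np.ndarray
    thresholds: np.ndarray  # (J, 2)
    repaired: bool = False

    def eigenvalues(self) -> np.ndarray:
        return np.sort(np.linalg.eigvalsh(self.rho))[::-1]


def polychoric_matrix(matrix) -> PolychoricMatrix:
    """Pairwise polychoric correlation matrix of a response matrix.

    Accepts a :class:`~grmsim.simulate.ResponseMatrix` or a plain array.  If
    the pairwise matrix is indefinite it is repaired by flooring negative
    eigenvalues at zero and renormalizing the diagonal (logged).
    """
    from .simulate import ResponseMatrix  # local import to avoid cycle
    if isinstance(matrix, ResponseMatrix):
        vals, item_ids = matrix.values, matrix.item_ids
    else:
        vals = np.asarray(matrix, dtype=int)
        item_ids = np.arange(1, vals.shape[1] + 1)
    J = vals.shape[1]
    thresholds = np.empty((J, 2))
    for j in range(J):
        try:
            thresholds[j] = _thresholds_from_margins(vals[:, j])
        except ValueError as exc:
            raise ValueError(f"item {item_ids[j]}: {exc}") from exc
    R = np.eye(J)
    for j in range(J):
        xj = vals[:, j]
        for k in range(j + 1, J):
            counts = np.bincount(3 * xj + vals[:, k], minlength=9)
            counts = counts.reshape(3, 3).astype(float)
            res = minimize_scalar(_pair_neg_loglik,
                                  bounds=(-_RHO_BOUND, _RHO_BOUND),
                                  args=(counts, thresholds[j], thresholds[k]),
                                  method="bounded", options={"xatol": 1e-6})
            R[j, k] = R[k, j] = float(res.x)
    repaired = False
    w = np.linalg.eigvalsh(R)
    if w[0] < -1e-8:
        logger.info("polychoric matrix indefinite (min eig %.2e); applying "
                    "nearest-PSD repair", w[0])
        w, V = np.linalg.eigh(R)
        R = (V * np.maximum(w, 0.0)) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        repaired = True
    return PolychoricMatrix(item_ids=np.asarray(item_ids), rho=R,
                            thresholds=thresholds, repaired=repaired)


# ---------------------------------------------------------------------------
# parallel analysis & reliability
# ---------------------------------------------------------------------------

@dataclass
class DimensionalityResult:
    eigenvalues: np.ndarray
    first_eigenvalue_rate: float
    second_eigenvalue: float
    kaiser_unidimensional: bool  # second eigenvalue < 1 rule
    cronbach_alpha: float
    parallel_thresholds: np.ndarray | None = None
    n_components_retained: int | None = None
    n_reps: int | None = None

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "first_eigenvalue": float(self.eigenvalues[0]),
            "first_eigenvalue_rate": self.first_eigenvalue_rate,
            "second_eigenvalue": self.second_eigenvalue,
            "kaiser_unidimensional": bool(self.kaiser_unidimensional),
            "cronbach_alpha": self.cronbach_alpha,
            "parallel_thresholds": (None if self.parallel_thresholds is None
                                    else self.parallel_thresholds.tolist()),
            "n_components_retained": self.n_components_retained,
            "n_reps": self.n_reps,
        }


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha on raw 0/1/2 scores (sample variances, n-1)."""
    from .simulate import ResponseMatrix
    vals = matrix.values if isinstance(matrix, ResponseMatrix) else np.asarray(matrix)
    vals = vals.astype(float)
    n, J = vals.shape
    if J < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    total_var = vals.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance: alpha undefined")
    item_var = vals.var(axis=0, ddof=1).sum()
    return float(J / (J - 1) * (1.0 - item_var / total_var))


def eigen_summary(matrix, poly: PolychoricMatrix | None = None) -> DimensionalityResult:
    """Eigenvalue diagnostics without the parallel-analysis resampling."""
    poly = poly or polychoric_matrix(matrix)
    eig = poly.eigenvalues()
    return DimensionalityResult(
        eigenvalues=eig,
        first_eigenvalue_rate=float(eig[0] / eig.sum()),
        second_eigenvalue=float(eig[1]) if len(eig) > 1 else float("nan"),
        kaiser_unidimensional=bool(len(eig) > 1 and eig[1] < 1.0),
        cronbach_alpha=cronbach_alpha(matrix),
    )


def parallel_analysis(matrix, n_reps: int = 100, seed: int = 0,
                      percentile: float = 95.0) -> DimensionalityResult:
    """Parallel analysis on the polychoric correlation matrix.

    Each replicate resamples every item independently from its observed
    category margins, so the replicate eigenvalues describe a local-
    independence null with the same marginal distributions.  Components whose
    observed eigenvalue exceeds the chosen percentile of the replicate
    distribution are retained (counted from the first component until the
    rule first fails).  The Kaiser-style second-eigenvalue-below-1 check is
    reported alongside.
    """
    from .simulate import ResponseMatrix
    if n_reps < 100:
        raise ValueError("parallel analysis needs n_reps >= 100")
    vals = matrix.values if isinstance(matrix, ResponseMatrix) else np.asarray(matrix)
    n, J = vals.shape
    base = eigen_summary(matrix)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    margins = [np.bincount(vals[:, j], minlength=3) / n for j in range(J)]
    rep_eigs = np.empty((n_reps, J))
    for r in range(n_reps):
        sim = np.empty((n, J), dtype=int)
        for j in range(J):
            for _ in range(100):
                col = rng.choice(3, size=n, p=margins[j])
                if len(np.unique(col)) >= 2:
                    break
            sim[:, j] = col
        rep_eigs[r] = polychoric_matrix(sim).eigenvalues()
    thresholds = np.percentile(rep_eigs, percentile, axis=0)
    exceed = base.eigenvalues > thresholds
    n_retained = int(np.argmin(exceed)) if not exceed.all() else J
    return DimensionalityResult(
        eigenvalues=base.eigenvalues,
        first_eigenvalue_rate=base.first_eigenvalue_rate,
        second_eigenvalue=base.second_eigenvalue,
        kaiser_unidimensional=base.kaiser_unidimensional,
        cronbach_alpha=base.cronbach_alpha,
        parallel_thresholds=thresholds,
        n_components_retained=n_retained,
        n_reps=n_reps,
    )
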
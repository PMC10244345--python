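"""Yen's Q3 local-dependence screening and item-exclusion strategies.

Q3 for an item pair is the Pearson correlation, across cases, of the
residuals between observed scores and their model-expected values at the
estimated ability.  Pairs with ``|Q3|`` above a threshold (default 0.2) are
flagged; three strategies then decide which member of each flagged pair to
drop before refitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import DEFAULT_D, ModelSpec
from .grm import (GradedResponseModel, category_probabilities, fit_grm,
                  item_information)
from .dimensionality import eigen_summary

logger = logging.getLogger(__name__)

STRATEGIES = ("max_cat1_prob", "item_information", "discrimination")


def expected_item_score(a, b1, b2, theta, D: float = DEFAULT_D):
    """Model-expected item score ``Σ_c c·p_c(θ)``; lies in [0, 2] and is
    increasing in θ."""
    p = category_probabilities(a, b1, b2, theta, D)
    return p[..., 1] + 2.0 * p[..., 2]


@dataclass
class Q3Result:
    item_ids: np.ndarray
    q3: np.ndarray                       # symmetric, NaN diagonal
    flagged_pairs: list                  # (item_j, item_k, q3) by desc |q3|
    threshold: float
    dropped_items: list = field(default_factory=list)  # zero-variance residuals

    @property
    def n_flagged(self) -> int:
        return len(self.flagged_pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.q3, index=self.item_ids, columns=self.item_ids)


def q3_statistic(X, fit: GradedResponseModel, theta, threshold: float = 0.2,
                 item_ids=None) -> Q3Result:
    """Pairwise Q3 residual correlations and the flagged pairs.

    ``theta`` is one ability estimate per row of ``X`` (typically the EAP
    scores from the same fit).  Items whose residual variance is zero are
    excluded from pairing with a logged warning.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if theta.shape[0] != X.shape[0]:
        raise ValueError("abilities must align with the matrix rows")
    if item_ids is None:
        item_ids = np.asarray(fit.item_ids_)
    item_ids = np.asarray(item_ids)
    a = fit.discrimination_
    b = fit.thresholds_
    expected = expected_item_score(a[None, :], b[None, :, 0], b[None, :, 1],
                                   theta[:, None], fit.D)
    resid = X - expected
    sd = resid.std(axis=0)
    dead = np.where(sd == 0)[0]
    dropped = item_ids[dead].tolist()
    if dropped:
        logger.warning("items with zero residual variance excluded from Q3 "
                       "pairing: %s", dropped)
    J = X.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        q3 = np.corrcoef(resid, rowvar=False)
    q3 = np.asarray(q3, dtype=float).reshape(J, J)
    q3[dead, :] = np.nan
    q3[:, dead] = np.nan
    np.fill_diagonal(q3, np.nan)
    flagged = []
    for j in range(J):
        for k in range(j + 1, J):
            v = q3[j, k]
            if np.isfinite(v) and abs(v) > threshold:
                flagged.append((int(item_ids[j]), int(item_ids[k]), float(v)))
    flagged.sort(key=lambda t: -abs(t[2]))
    return Q3Result(item_ids=item_ids, q3=q3, flagged_pairs=flagged,
                    threshold=threshold, dropped_items=dropped)


# ---------------------------------------------------------------------------
# exclusion strategies
# ---------------------------------------------------------------------------

_GRID = np.arange(-4.0, 4.0 + 1e-9, 0.01)


def fit_matrix(matrix, spec: ModelSpec | None = None) -> GradedResponseModel:
    """Fit a GRM to a ResponseMatrix, carrying its integer item IDs."""
    est = fit_grm(matrix.values, spec)
    est.item_ids_ = [int(i) for i in matrix.item_ids]
    return est


def _strategy_score(strategy: str, a, b1, b2, D,
                    info_at_cat1_peak: bool = False):
    """Per-item score whose *lower* value loses within a flagged pair."""
    if strategy == "max_cat1_prob":
        p = category_probabilities(a, b1, b2, _GRID, D)
        return float(p[..., 1].max())
    if strategy == "item_information":
        info = item_information(a, b1, b2, _GRID, D)
        if info_at_cat1_peak:
            p1 = category_probabilities(a, b1, b2, _GRID, D)[..., 1]
            return float(info[np.argmax(p1)])
        return float(info.max())
    if strategy == "discrimination":
        return float(a)
    raise ValueError(f"unknown exclusion strategy {strategy!r}")


@dataclass
class StrategyOutcome:
    strategy: str
    excluded_item_ids: list
    n_items_remaining: int
    refit: GradedResponseModel | None = None
    alpha: float | None = None
    first_eigenvalue: float | None = None
    first_eigenvalue_rate: float | None = None
    n_flagged_after: int | None = None

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "excluded_item_ids": list(self.excluded_item_ids),
            "n_items_remaining": self.n_items_remaining,
            "alpha": self.alpha,
            "first_eigenvalue": self.first_eigenvalue,
            "first_eigenvalue_rate": self.first_eigenvalue_rate,
            "n_flagged_after": self.n_flagged_after,
            "AIC": None if self.refit is None else self.refit.aic_,
            "BIC": None if self.refit is None else self.refit.bic_,
        }


def select_exclusions(q3: Q3Result, fit: GradedResponseModel, strategy: str,
                      D: float | None = None,
                      info_at_cat1_peak: bool = False) -> list:
    """Item IDs to exclude: the union over flagged pairs of each pair's loser.

    Within a pair the loser has the lower strategy score — (a) the lower
    maximum of the category-1 probability curve over θ ∈ [-4, 4];
    (b) the lower maximum of the item information function; (c) the lower
    discrimination.  Score ties are broken by excluding the higher item ID.
    A pair's loser is recorded even when one member already lost another
    pair, so pairs sharing an item can contribute fewer distinct exclusions.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown exclusion strategy {strategy!r}; "
                         f"expected one of {STRATEGIES}")
    D = fit.D if D is None else D
    ids = list(fit.item_ids_)
    scores = {}
    for idx, item in enumerate(ids):
        scores[item] = _strategy_score(strategy, fit.discrimination_[idx],
                                       fit.thresholds_[idx, 0],
                                       fit.thresholds_[idx, 1], D,
                                       info_at_cat1_peak)
    excluded: list = []
    for j, k, _q3 in q3.flagged_pairs:  # already sorted by descending |Q3|
        sj, sk = scores[j], scores[k]
        if sj < sk:
            loser = j
        elif sk < sj:
            loser = k
        else:
            loser = max(j, k)
        if loser not in excluded:
            excluded.append(loser)
    return excluded


def apply_exclusion_strategy(matrix, q3: Q3Result, fit: GradedResponseModel,
                             strategy: str, D: float | None = None,
                             spec: ModelSpec | None = None,
                             info_at_cat1_peak: bool = False) -> StrategyOutcome:
    """Apply one exclusion strategy and refit on the remaining items.

    Returns the exclusion list plus post-refit diagnostics: Cronbach's alpha,
    first polychoric eigenvalue and its rate, and the number of still-flagged
    pairs under the refit.
    """
    excluded = select_exclusions(q3, fit, strategy, D, info_at_cat1_peak)
    keep = [i for i in fit.item_ids_ if i not in excluded]
    sub = matrix.select_items(keep)
    spec = spec or ModelSpec(model=fit.model, D=fit.D,
                             n_quadrature=fit.n_quadrature,
                             quadrature_bounds=tuple(fit.quadrature_bounds),
                             max_em_iterations=fit.max_iter,
                             em_tolerance=fit.tol)
    refit = fit_matrix(sub, spec)
    theta = refit.predict(sub.values)
    q3_after = q3_statistic(sub.values, refit, theta, q3.threshold,
                            item_ids=np.asarray(keep))
    dim = eigen_summary(sub)
    return StrategyOutcome(
        strategy=strategy,
        excluded_item_ids=excluded,
        n_items_remaining=len(keep),
        refit=refit,
        alpha=dim.cronbach_alpha,
        first_eigenvalue=float(dim.eigenvalues[0]),
        first_eigenvalue_rate=dim.first_eigenvalue_rate,
        n_flagged_after=q3_after.n_flagged,
    )


class Q3Screener(BaseEstimator, TransformerMixin):
    """Local-independence screener usable in sklearn pipelines.

    ``fit`` fits a graded response model, computes Q3 on EAP residuals and
    derives the exclusion list for the chosen strategy; ``transform`` drops
    the excluded columns.

    Attributes: ``q3_result_``, ``excluded_items_``, ``kept_idx_``.
    """

    def __init__(self, strategy: str = "max_cat1_prob", threshold: float = 0.2,
                 model: str = "2pl", D: float = DEFAULT_D,
                 info_at_cat1_peak: bool = False):
        self.strategy = strategy
        self.threshold = threshold
        self.model = model
        self.D = D
        self.info_at_cat1_peak = info_at_cat1_peak

    def fit(self, X, y=None):
        est = GradedResponseModel(model=self.model, D=self.D).fit(X)
        theta = est.predict(X)
        self.grm_ = est
        self.q3_result_ = q3_statistic(X, est, theta, self.threshold)
        self.excluded_items_ = select_exclusions(
            self.q3_result_, est, self.strategy,
            info_at_cat1_peak=self.info_at_cat1_peak)
        ids = list(est.item_ids_)
        self.kept_idx_ = np.array([i for i, item in enumerate(ids)
                                   if item not in self.excluded_items_])
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.iloc[:, self.kept_idx_]
        return np.asarray(X)[:, self.kept_idx_]


# ---------------------------------------------------------------------------
# strategy × model comparison (study summary table)
# ---------------------------------------------------------------------------

def compare_strategies_and_models(matrix, spec: ModelSpec | None = None,
                                  threshold: float = 0.2,
                                  strategies=STRATEGIES) -> dict:
    """Grid of {no exclusion, each strategy} × {2PL, 1PL}.

    For each model the full bank is fitted, Q3 flags computed, every strategy
    applied and refitted under the *same* model.  A single winner is marked
    only when the smallest AIC and smallest BIC point at the same cell;
    otherwise both front-runners are reported (logged).  Exact ties go to the
    earlier row (2PL before 1PL, no-exclusion before strategies in order).
    """
    spec = spec or ModelSpec()
    rows = []
    for model in ("2pl", "1pl"):
        mspec = ModelSpec(model=model, D=spec.D, n_quadrature=spec.n_quadrature,
                          quadrature_bounds=spec.quadrature_bounds,
                          max_em_iterations=spec.max_em_iterations,
                          em_tolerance=spec.em_tolerance)
        fit = fit_matrix(matrix, mspec)
        theta = fit.predict(matrix.values)
        q3 = q3_statistic(matrix.values, fit, theta, threshold,
                          item_ids=matrix.item_ids)
        dim = eigen_summary(matrix)
        rows.append({
            "model": model, "strategy": "none",
            "n_items": matrix.n_items, "n_flagged": q3.n_flagged,
            "alpha": dim.cronbach_alpha,
            "first_eigenvalue": float(dim.eigenvalues[0]),
            "first_eigenvalue_rate": dim.first_eigenvalue_rate,
            "AIC": fit.aic_, "BIC": fit.bic_,
            "excluded_item_ids": [],
        })
        for strat in strategies:
            out = apply_exclusion_strategy(matrix, q3, fit, strat, spec=mspec)
            rows.append({
                "model": model, "strategy": strat,
                "n_items": out.n_items_remaining,
                "n_flagged": out.n_flagged_after,
                "alpha": out.alpha,
                "first_eigenvalue": out.first_eigenvalue,
                "first_eigenvalue_rate": out.first_eigenvalue_rate,
                "AIC": out.refit.aic_, "BIC": out.refit.bic_,
                "excluded_item_ids": out.excluded_item_ids,
            })
    table = pd.DataFrame(rows)
    i_aic = int(table["AIC"].idxmin())
    i_bic = int(table["BIC"].idxmin())
    if i_aic == i_bic:
        winner = (table.loc[i_aic, "model"], table.loc[i_aic, "strategy"])
        candidates = [winner]
    else:
        winner = None
        candidates = [(table.loc[i_aic, "model"], table.loc[i_aic, "strategy"]),
                      (table.loc[i_bic, "model"], table.loc[i_bic, "strategy"])]
        logger.warning("AIC and BIC disagree on the best model/strategy: %s",
                       candidates)
    marks = []
    for i in range(len(table)):
        cell = (table.loc[i, "model"], table.loc[i, "strategy"])
        marks.append("winner" if winner is not None and cell == winner else "")
    table["mark"] = marks
    return {"table": table, "winner": winner, "candidates": candidates}
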
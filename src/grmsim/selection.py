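"""Severity-banded item selection and monotonicity diagnostics.

Paresis severity is expressed as bands of the latent ability θ:
severe [-2.0, -0.5), moderate [-0.5, 0.5), mild [0.5, 2.0), plus an
all-patients band [-2.0, 2.0).  Within a band, items are ranked either by
their category-1 ("adequate difficulty") response-probability curve or by
their information function, and the top-k (default 7) form a short training
battery whose refit quality the two criteria compete on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .config import DEFAULT_D, ModelSpec
from .grm import (GradedResponseModel, category_probabilities,
                  item_information, boundary_probability)
from .dimensionality import eigen_summary
from .local_independence import fit_matrix

logger = logging.getLogger(__name__)

CRITERIA = ("cat1_prob", "information")


@dataclass(frozen=True)
class SeverityBand:
    label: str
    theta_lo: float
    theta_hi: float
    grid_step: float = 0.01

    def __post_init__(self):
        if not self.theta_lo < self.theta_hi:
            raise ValueError("band bounds must satisfy lo < hi")

    def grid(self) -> np.ndarray:
        return np.arange(self.theta_lo, self.theta_hi + 1e-9, self.grid_step)


def default_bands() -> tuple[SeverityBand, ...]:
    return (SeverityBand("severe", -2.0, -0.5),
            SeverityBand("moderate", -0.5, 0.5),
            SeverityBand("mild", 0.5, 2.0),
            SeverityBand("all", -2.0, 2.0))


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

@dataclass
class CurveGrid:
    item_ids: np.ndarray
    theta: np.ndarray
    boundary: np.ndarray      # (J, T, 2) cumulative p*_1, p*_2
    category: np.ndarray      # (J, T, 3) category curves (ICC per category)
    information: np.ndarray   # (J, T) item information functions
    tif: np.ndarray           # (T,) test information

    def to_long_dataframe(self) -> pd.DataFrame:
        frames = []
        for idx, item in enumerate(self.item_ids):
            for c in range(3):
                frames.append(pd.DataFrame({
                    "item_id": item, "theta": self.theta,
                    "curve_type": f"p{c}", "value": self.category[idx, :, c]}))
            frames.append(pd.DataFrame({
                "item_id": item, "theta": self.theta,
                "curve_type": "iif", "value": self.information[idx]}))
        frames.append(pd.DataFrame({
            "item_id": 0, "theta": self.theta,
            "curve_type": "tif", "value": self.tif}))
        return pd.concat(frames, ignore_index=True)


def build_curves(items: pd.DataFrame, band: SeverityBand,
                 D: float = DEFAULT_D) -> CurveGrid:
    """Evaluate ICC, category-1 curve, IIF and TIF on the band's θ grid.

    ``items`` is an ``item_id, a, b1, b2`` frame (e.g. from
    :meth:`GradedResponseModel.items_frame`).
    """
    th = band.grid()
    a = items["a"].to_numpy()[:, None]
    b1 = items["b1"].to_numpy()[:, None]
    b2 = items["b2"].to_numpy()[:, None]
    cat = category_probabilities(a, b1, b2, th[None, :], D)
    bound = np.stack([boundary_probability(a, b1, th[None, :], D),
                      boundary_probability(a, b2, th[None, :], D)], axis=-1)
    info = item_information(a, b1, b2, th[None, :], D)
    return CurveGrid(item_ids=items["item_id"].to_numpy(), theta=th,
                     boundary=bound, category=cat, information=info,
                     tif=info.sum(axis=0))


# ---------------------------------------------------------------------------
# ranking and selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    band: SeverityBand
    criterion: str
    aggregation: str
    ranked_items: list                 # (item_id, score), descending score
    top_k: int
    refit: GradedResponseModel | None = None
    alpha: float | None = None
    first_eigenvalue: float | None = None
    first_eigenvalue_rate: float | None = None

    @property
    def selected_item_ids(self) -> list:
        return [item for item, _ in self.ranked_items[:self.top_k]]

    def to_dict(self) -> dict:
        return {
            "band": self.band.label, "criterion": self.criterion,
            "aggregation": self.aggregation, "top_k": self.top_k,
            "selected_item_ids": self.selected_item_ids,
            "ranked_items": [(int(i), float(s)) for i, s in self.ranked_items],
            "alpha": self.alpha,
            "first_eigenvalue": self.first_eigenvalue,
            "first_eigenvalue_rate": self.first_eigenvalue_rate,
            "AIC": None if self.refit is None else self.refit.aic_,
            "BIC": None if self.refit is None else self.refit.bic_,
        }


def rank_items_in_band(items: pd.DataFrame, band: SeverityBand, criterion: str,
                       D: float = DEFAULT_D, aggregation: str = "mean",
                       top_k: int = 7) -> SelectionResult:
    """Rank items within a severity band.

    The per-item score aggregates (mean by default, max optionally) the
    category-1 probability curve or the item information function over the
    band's θ grid.  Descending scores; ties broken by ascending item ID.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; expected {CRITERIA}")
    if aggregation not in ("mean", "max"):
        raise ValueError("aggregation must be 'mean' or 'max'")
    if top_k > len(items):
        raise ValueError(f"top_k={top_k} exceeds bank size {len(items)}")
    th = band.grid()
    a = items["a"].to_numpy()[:, None]
    b1 = items["b1"].to_numpy()[:, None]
    b2 = items["b2"].to_numpy()[:, None]
    if criterion == "cat1_prob":
        curve = category_probabilities(a, b1, b2, th[None, :], D)[..., 1]
    else:
        curve = item_information(a, b1, b2, th[None, :], D)
    scores = curve.mean(axis=1) if aggregation == "mean" else curve.max(axis=1)
    ids = items["item_id"].to_numpy()
    order = np.lexsort((ids, -scores))  # descending score, ascending ID on ties
    ranked = [(int(ids[i]), float(scores[i])) for i in order]
    return SelectionResult(band=band, criterion=criterion,
                           aggregation=aggregation, ranked_items=ranked,
                           top_k=top_k)


def compare_selection_criteria(matrix, fit: GradedResponseModel,
                               bands=None, D: float | None = None,
                               top_k: int = 7, aggregation: str = "mean",
                               spec: ModelSpec | None = None) -> dict:
    """Band × criterion comparison of top-k selections.

    For every band and criterion the top-k items (ranked on the supplied
    fit's parameters) are refit with the 2PL model on *all* cases; each
    band's winner is the criterion with both smaller AIC and smaller BIC
    (no winner marked if they disagree).  The overall recommendation is the
    criterion winning the most bands.
    """
    bands = default_bands() if bands is None else bands
    D = fit.D if D is None else D
    items = fit.items_frame()
    spec = spec or ModelSpec(D=D)
    cells = {}
    rows = []
    for band in bands:
        for criterion in CRITERIA:
            sel = rank_items_in_band(items, band, criterion, D, aggregation,
                                     top_k)
            sub = matrix.select_items(sel.selected_item_ids)
            refit = fit_matrix(sub, spec)
            dim = eigen_summary(sub)
            sel.refit = refit
            sel.alpha = dim.cronbach_alpha
            sel.first_eigenvalue = float(dim.eigenvalues[0])
            sel.first_eigenvalue_rate = dim.first_eigenvalue_rate
            cells[(band.label, criterion)] = sel
            rows.append({"band": band.label, "criterion": criterion,
                         "items": sel.selected_item_ids,
                         "alpha": sel.alpha,
                         "first_eigenvalue": sel.first_eigenvalue,
                         "first_eigenvalue_rate": sel.first_eigenvalue_rate,
                         "AIC": refit.aic_, "BIC": refit.bic_,
                         "converged": bool(refit.converged_)})
    table = pd.DataFrame(rows)
    band_winners = {}
    for band in bands:
        sub = table[table["band"] == band.label].set_index("criterion")
        c0, c1 = CRITERIA
        if (sub.loc[c0, "items"] == sub.loc[c1, "items"]):
            band_winners[band.label] = None  # identical selections
            continue
        better_aic = c0 if sub.loc[c0, "AIC"] < sub.loc[c1, "AIC"] else c1
        better_bic = c0 if sub.loc[c0, "BIC"] < sub.loc[c1, "BIC"] else c1
        band_winners[band.label] = better_aic if better_aic == better_bic else None
    wins = {c: sum(1 for w in band_winners.values() if w == c) for c in CRITERIA}
    if wins[CRITERIA[0]] == wins[CRITERIA[1]]:
        recommendation = None
    else:
        recommendation = max(wins, key=wins.get)
    table["band_winner"] = [band_winners[b] == c for b, c in
                            zip(table["band"], table["criterion"])]
    return {"table": table, "cells": cells, "band_winners": band_winners,
            "wins": wins, "recommendation": recommendation}


# ---------------------------------------------------------------------------
# monotonicity
# ---------------------------------------------------------------------------

def monotonicity_check(matrix, theta, n_bins: int = 20,
                       rho_threshold: float = 0.95,
                       inversion_tolerance: float = 0.02) -> dict:
    """Check that the mean item score rises with estimated ability.

    Computes the Spearman correlation of (θ̂, per-case mean score) and a
    20-bin binned-mean sequence; monotone if the correlation exceeds 0.95
    and the binned means are non-decreasing up to a single inversion of
    magnitude at most 0.02.
    """
    from .simulate import ResponseMatrix
    vals = matrix.values if isinstance(matrix, ResponseMatrix) else np.asarray(matrix)
    theta = np.asarray(theta, dtype=float)
    mean_scores = vals.mean(axis=1)
    rho = float(spearmanr(theta, mean_scores).statistic)
    edges = np.linspace(theta.min(), theta.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(theta, edges) - 1, 0, n_bins - 1)
    binned = np.array([mean_scores[which == b].mean() if (which == b).any()
                       else np.nan for b in range(n_bins)])
    seq = binned[~np.isnan(binned)]
    diffs = np.diff(seq)
    inversions = diffs[diffs < 0]
    monotone = (rho > rho_threshold
                and len(inversions) <= 1
                and (len(inversions) == 0
                     or abs(float(inversions[0])) <= inversion_tolerance))
    return {"spearman_rho": rho, "binned_means": binned,
            "n_inversions": int(len(inversions)),
            "worst_inversion": float(-inversions.min()) if len(inversions) else 0.0,
            "monotone": bool(monotone)}
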
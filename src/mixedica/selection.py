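"""Model-category selection for mixed ICA/PCA.

A model category is the triple (n_sub, n_super, n_gauss) of source-type
counts.  The selection criterion is T_n, the expected out-of-sample
log-likelihood of parameters fitted on n samples.  The maximized
training log-likelihood overestimates T_n (optimism bias); AIC corrects
it by the parameter count, which fails badly here when Gaussian data are
modeled as non-Gaussian (the bias then grows like √n), so the estimator
of record is leave-one-out cross-validation: n refits each holding out
one sample, the held-out log-densities summed,

    T̂ₙ = Σⱼ [ log|det W₍₋ⱼ₎| + Σᵢ log pᵢ(Sᵢ₍₊ⱼ₎) ],

where the held-out column is centered with the training-fold means.
AIC retains two supporting roles: the all-Gaussian case has an exact
finite-n optimism (Fujikoshi–Satoh), and the AIC value — which
underestimates the true bias — gives a sound pre-screen for discarding
hopeless local optima before paying for their cross-validation.

Ranking uses evidence bands on the non-doubled log-likelihood scale:
differences below 2 from the best model are reasonable alternatives,
2–5 plausible, above 5 unlikely (these are AIC-difference bands halved).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    FittedModel,
    ModelCategory,
    ObservationMatrix,
    OptimizerSettings,
    fit,
)
from .sources import log_density

__all__ = [
    "CVResult",
    "enumerate_categories",
    "aic_param_count",
    "fs_exact_bias",
    "aic",
    "loocv",
    "dedup_optima",
    "aic_prescreen",
    "rank_models",
]


@dataclass
class CVResult:
    """Cross-validated estimate of T_n for one fitted model."""

    category: ModelCategory
    loglik_full: float
    T_hat: float
    fold_contribs: np.ndarray
    fold_indices: np.ndarray

    @property
    def bias_hat(self) -> float:
        """Implied optimism of the training log-likelihood."""
        return self.loglik_full - self.T_hat


def enumerate_categories(m: int) -> List[ModelCategory]:
    """All (n_sub, n_super, n_gauss) triples summing to m; (m+1)(m+2)/2 of them."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return [
        ModelCategory(m1, m2, m - m1 - m2)
        for m1 in range(m + 1)
        for m2 in range(m - m1 + 1)
    ]


def aic_param_count(m: int, n_gauss: int) -> int:
    """Freely adjustable parameters: K = m + m² − n_gauss·(n_gauss−1)/2.

    m centering parameters plus the m² entries of W, less the
    orthogonality constraints tying down the Gaussian rows.  For the
    all-Gaussian model this is m + m(m+1)/2.
    """
    if not 0 <= n_gauss <= m:
        raise ValueError("need 0 <= n_gauss <= m")
    return m + m * m - n_gauss * (n_gauss - 1) // 2


def fs_exact_bias(n: int, m: int) -> float:
    """Exact finite-n optimism of the all-Gaussian model's log-likelihood.

    The all-Gaussian fit is equivalent to multivariate normal regression
    on an intercept, for which the optimism is exactly
    n·(m + m(m+1)/2)/(n − m − 2), converging to the AIC parameter count
    m + m(m+1)/2 as n → ∞.
    """
    if n <= m + 2:
        raise ValueError("requires n > m + 2")
    return n * (m + m * (m + 1) / 2.0) / (n - m - 2)


def aic(loglik: float, K: int) -> float:
    """Bias-corrected log-likelihood: loglik − K (non-doubled scale)."""
    return loglik - K


def _held_out_contribution(
    model_j: FittedModel, x_raw: np.ndarray, category: ModelCategory
) -> float:
    # center the held-out sample with training-fold means, full densities per row
    s = model_j.W @ (x_raw - model_j.row_means)
    _, logabsdet = np.linalg.slogdet(model_j.W)
    total = logabsdet
    for i, kind in enumerate(category.kinds):
        total += float(log_density(s[i], kind))
    return total


def loocv(
    data: ObservationMatrix,
    category: ModelCategory,
    reference_model: FittedModel,
    fold_subset: Optional[Sequence[int]] = None,
    settings: Optional[OptimizerSettings] = None,
    on_fold_error: str = "skip",
) -> CVResult:
    """Leave-one-out cross-validated T̂ₙ for one local optimum.

    Each fold re-centers the data without one sample and refits W
    warm-started from ``reference_model`` (keeping the fold solution on
    the same optimum branch), then evaluates the held-out sample's
    log-density under the refitted parameters.  When ``fold_subset``
    retains only a random subset of the n folds, the summed
    contributions are rescaled by n/|subset|.  Fold refits that fail are
    skipped and rescaled (``on_fold_error='skip'``) or abort
    (``'raise'``).
    """
    n = data.n
    if n < data.m + 2:
        raise ValueError("leave-one-out requires n >= m + 2")
    folds = np.arange(n) if fold_subset is None else np.asarray(fold_subset, dtype=int)
    if folds.size == 0:
        raise ValueError("fold subset is empty")
    contribs, kept = [], []
    for j in folds:
        try:
            data_j = data.drop_column(int(j))
            model_j = fit(data_j, category, W_init=reference_model.W, settings=settings)
            contribs.append(
                _held_out_contribution(model_j, data.held_out_column(int(j)), category)
            )
            kept.append(int(j))
        except (np.linalg.LinAlgError, ValueError):
            if on_fold_error == "raise":
                raise
    if not kept:
        raise RuntimeError(f"every cross-validation fold failed for {category}")
    contribs = np.asarray(contribs)
    T_hat = float(contribs.sum()) * (n / len(kept))
    return CVResult(
        category=category,
        loglik_full=reference_model.loglik,
        T_hat=T_hat,
        fold_contribs=contribs,
        fold_indices=np.asarray(kept),
    )


def dedup_optima(fits: Sequence[FittedModel], decimals: int = 6) -> List[FittedModel]:
    """Collapse fits that represent the same local optimum.

    Two fits are treated as the same optimum when their uncorrected
    log-likelihoods and the determinants of their unmixing matrices
    agree to ``decimals`` decimal places; the first encountered
    representative survives.
    """
    seen = set()
    out: List[FittedModel] = []
    for f in fits:
        key = (round(f.loglik, decimals), round(float(np.linalg.det(f.W)), decimals))
        if key not in seen:
            seen.add(key)
            out.append(f)
    return out


def aic_prescreen(
    fits: Sequence[FittedModel], best_T_hat: float, margin: float = 5.0
) -> List[FittedModel]:
    """Drop optima whose AIC value already rules them out.

    Because AIC underestimates the true optimism, an optimum whose
    AIC-corrected log-likelihood falls more than ``margin`` below the
    best known cross-validated T̂ₙ cannot become competitive, and its
    cross-validation can be skipped.
    """
    out = []
    for f in fits:
        K = aic_param_count(f.m, f.category.n_gauss)
        if aic(f.loglik, K) >= best_T_hat - margin:
            out.append(f)
    return out


_BAND_REASONABLE = 2.0
_BAND_PLAUSIBLE = 5.0


def _band(delta: float) -> str:
    if delta < _BAND_REASONABLE:
        return "reasonable"
    if delta <= _BAND_PLAUSIBLE:
        return "plausible"
    return "unlikely"


def rank_models(cv_results: Sequence[CVResult]) -> pd.DataFrame:
    """Selection table sorted by T̂ₙ with evidence bands.

    Ties in T̂ₙ list the more-Gaussian (larger n_gauss) category first.
    The ``delta`` column is the drop from the best model; bands are
    reasonable (< 2), plausible (2–5), unlikely (> 5) on the non-doubled
    log-likelihood scale.
    """
    if not cv_results:
        raise ValueError("need at least one cross-validation result")
    rows = []
    for r in cv_results:
        c = r.category
        rows.append(
            {
                "n_sub": c.n_sub,
                "n_super": c.n_super,
                "n_gauss": c.n_gauss,
                "loglik": r.loglik_full,
                "T_hat": r.T_hat,
                "bias_hat": r.bias_hat,
                "K_aic": aic_param_count(c.m, c.n_gauss),
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["T_hat", "n_gauss"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)
    best = table["T_hat"].iloc[0]
    table["delta"] = best - table["T_hat"]
    table["band"] = table["delta"].map(_band)
    return table
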
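"""Scikit-learn-style estimators for mixed ICA/PCA.

:class:`MixedICA` fits one model category — a fixed count of
sub-Gaussian, super-Gaussian and Gaussian components — by multi-start
constrained maximum likelihood.  :class:`MixedICASelector` enumerates
every category for the data dimension, corrects each category's best
local optima for optimism by leave-one-out cross-validation, and ranks
the categories by the cross-validated criterion T̂ₙ.

Both follow the scikit-learn contract: ``fit(X)`` takes X with shape
(n_samples, n_features), fitted attributes carry trailing underscores,
and ``transform`` maps observations to source space, so they compose
with pipelines and model-selection utilities.  Internally the math runs
on the transposed (variables × samples) matrix, the native orientation
of the decomposition X̃ = A·S.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import selection
from .core import (
    FittedModel,
    ModelCategory,
    ObservationMatrix,
    OptimizerSettings,
    center_rows,
    fit as fit_category,
    loglik,
)
from .initialization import (
    n_permutation_inits,
    permutation_inits,
    random_orthonormal,
)

__all__ = ["MixedICA", "MixedICASelector"]


def _multi_start_fits(
    data: ObservationMatrix,
    category: ModelCategory,
    *,
    use_permutations: bool,
    n_rotations: int,
    compose_permutations: bool,
    permutation_cap: int,
    settings: OptimizerSettings,
    rng: np.random.Generator,
) -> List[FittedModel]:
    """Fit from every planned initialization; best-likelihood first is NOT
    guaranteed — callers sort."""
    m = data.m
    if use_permutations and n_permutation_inits(category) <= permutation_cap:
        perms = permutation_inits(category, cap=permutation_cap)
    else:
        perms = [np.eye(m)]
    inits = list(perms)
    for _ in range(n_rotations):
        O = random_orthonormal(m, rng)
        if compose_permutations:
            inits.extend(P @ O for P in perms)
        else:
            inits.append(O)
    fits = []
    for W0 in inits:
        try:
            fits.append(fit_category(data, category, W_init=W0, settings=settings))
        except (np.linalg.LinAlgError, ValueError):
            continue
    if not fits:
        raise RuntimeError(f"all initializations failed for category {category}")
    return fits


class MixedICA(TransformerMixin, BaseEstimator):
    """Mixed ICA/PCA decomposition for one model category.

    Parameters
    ----------
    n_sub, n_super : int
        Number of sub-Gaussian (light-tailed) and super-Gaussian
        (heavy-tailed) sources.
    n_gauss : int or None
        Number of Gaussian components; ``None`` assigns every remaining
        data dimension to the Gaussian subspace at fit time.
    use_permutations : bool
        Start the optimizer from every distinct assignment of source
        labels to data rows (column-permuted identity matrices).
    n_rotations : int
        Additional random-rotation restarts (Haar-distributed); each is
        crossed with the permutation starts when
        ``compose_permutations`` is set.
    permutation_cap : int
        Refuse permutation enumeration beyond this count and fall back
        to a single identity start plus rotations.
    max_iter, tol : optimizer iteration cap and relative objective
        tolerance for the quasi-Newton search.
    random_state : seed for the rotation draws.

    Attributes
    ----------
    components_ : (m, m) unmixing matrix W applied to centered data.
    mixing_ : (m, m) mixing matrix A = W⁻¹.
    mean_ : per-feature training means.
    loglik_ : maximized log-likelihood over all starts.
    model_ : the underlying :class:`FittedModel`.
    """

    def __init__(
        self,
        n_sub: int = 0,
        n_super: int = 0,
        n_gauss: Optional[int] = None,
        *,
        use_permutations: bool = True,
        n_rotations: int = 0,
        compose_permutations: bool = True,
        permutation_cap: int = 10**6,
        max_iter: int = 1000,
        tol: float = 1e-10,
        random_state: Optional[int] = None,
    ):
        self.n_sub = n_sub
        self.n_super = n_super
        self.n_gauss = n_gauss
        self.use_permutations = use_permutations
        self.n_rotations = n_rotations
        self.compose_permutations = compose_permutations
        self.permutation_cap = permutation_cap
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _settings(self) -> OptimizerSettings:
        return OptimizerSettings(max_iter=self.max_iter, ftol=self.tol)

    def _category(self, m: int) -> ModelCategory:
        n_gauss = self.n_gauss
        if n_gauss is None:
            n_gauss = m - self.n_sub - self.n_super
        cat = ModelCategory(self.n_sub, self.n_super, n_gauss)
        if cat.m != m:
            raise ValueError(
                f"category {cat} does not match the data dimension m={m}"
            )
        return cat

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        data = center_rows(X.T)
        category = self._category(data.m)
        rng = np.random.default_rng(self.random_state)
        fits = _multi_start_fits(
            data,
            category,
            use_permutations=self.use_permutations,
            n_rotations=self.n_rotations,
            compose_permutations=self.compose_permutations,
            permutation_cap=self.permutation_cap,
            settings=self._settings(),
            rng=rng,
        )
        best = max(fits, key=lambda f: f.loglik)
        self.model_ = best
        self.components_ = best.W
        self.mixing_ = best.A
        self.mean_ = data.row_means
        self.loglik_ = best.loglik
        self.converged_ = best.converged
        self.n_iter_ = best.n_iter
        self.category_ = category
        self.n_features_in_ = data.m
        return self

    def transform(self, X) -> np.ndarray:
        """Map observations to source space: S = W·(x − mean)."""
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, S) -> np.ndarray:
        check_is_fitted(self, "components_")
        return np.asarray(S, dtype=float) @ self.mixing_.T + self.mean_

    def score(self, X, y=None) -> float:
        """Mean per-sample log-likelihood of X under the fitted parameters."""
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        data = ObservationMatrix((X - self.mean_).T, self.mean_)
        return loglik(self.components_, data, self.category_, form="direct") / len(X)

    def sources_(self) -> np.ndarray:  # pragma: no cover - convenience alias
        check_is_fitted(self, "model_")
        return self.model_.S.T


class MixedICASelector(BaseEstimator):
    """Cross-validated selection over all mixed ICA/PCA model categories.

    For each of the (m+1)(m+2)/2 categories: multi-start fits →
    deduplication of coincident local optima → AIC pre-screen against
    the best cross-validated score seen so far → leave-one-out
    cross-validation of the surviving optima → the category's best T̂ₙ.
    Categories are then ranked with evidence bands (drop < 2 from the
    best: reasonable; 2–5: plausible; > 5: unlikely).

    Parameters mirror :class:`MixedICA` for the per-category fits, plus

    categories : 'all' or explicit list of (n_sub, n_super, n_gauss).
    cv_folds : None for full leave-one-out, or an int k to cross-validate
        a random k-subset of the folds and rescale by n/k.
    dedup_decimals : rounding used to identify coincident optima.
    prescreen_margin : AIC slack (log-likelihood units) below the best
        known T̂ₙ beyond which an optimum is discarded without
        cross-validation.
    max_cv_optima : cap on cross-validated optima per category (best
        likelihoods first); None for no cap.

    Attributes
    ----------
    selection_table_ : ranked ``DataFrame`` (category, loglik, T̂ₙ,
        implied bias, K, delta, band).
    best_category_, best_model_, results_, models_.
    """

    def __init__(
        self,
        categories: Union[str, Sequence] = "all",
        *,
        use_permutations: bool = True,
        n_rotations: int = 0,
        compose_permutations: bool = True,
        permutation_cap: int = 10**6,
        cv_folds: Optional[int] = None,
        dedup_decimals: int = 6,
        prescreen_margin: float = 5.0,
        max_cv_optima: Optional[int] = None,
        max_iter: int = 1000,
        tol: float = 1e-10,
        random_state: Optional[int] = None,
    ):
        self.categories = categories
        self.use_permutations = use_permutations
        self.n_rotations = n_rotations
        self.compose_permutations = compose_permutations
        self.permutation_cap = permutation_cap
        self.cv_folds = cv_folds
        self.dedup_decimals = dedup_decimals
        self.prescreen_margin = prescreen_margin
        self.max_cv_optima = max_cv_optima
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _category_list(self, m: int) -> List[ModelCategory]:
        if isinstance(self.categories, str):
            if self.categories != "all":
                raise ValueError("categories must be 'all' or a list of triples")
            return selection.enumerate_categories(m)
        out = []
        for c in self.categories:
            cat = c if isinstance(c, ModelCategory) else ModelCategory(*c)
            if cat.m != m:
                raise ValueError(f"category {cat} does not match m={m}")
            out.append(cat)
        return out

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        data = center_rows(X.T)
        m, n = data.m, data.n
        settings = OptimizerSettings(max_iter=self.max_iter, ftol=self.tol)
        rng = np.random.default_rng(self.random_state)
        fold_subset = None
        if self.cv_folds is not None:
            k = int(self.cv_folds)
            if not 1 <= k <= n:
                raise ValueError("cv_folds must be between 1 and n")
            if k < n:
                fold_subset = np.sort(rng.choice(n, size=k, replace=False))
        results: List[selection.CVResult] = []
        self.models_ = {}
        self.results_ = {}
        best_T = -np.inf
        for category in self._category_list(m):
            fits = _multi_start_fits(
                data,
                category,
                use_permutations=self.use_permutations,
                n_rotations=self.n_rotations,
                compose_permutations=self.compose_permutations,
                permutation_cap=self.permutation_cap,
                settings=settings,
                rng=rng,
            )
            fits.sort(key=lambda f: f.loglik, reverse=True)
            optima = selection.dedup_optima(fits, decimals=self.dedup_decimals)
            if self.max_cv_optima is not None:
                optima = optima[: self.max_cv_optima]
            best_cv: Optional[selection.CVResult] = None
            best_fit: Optional[FittedModel] = None
            for model in optima:
                screened = selection.aic_prescreen(
                    [model], best_T, margin=self.prescreen_margin
                )
                if not screened and best_cv is not None:
                    continue
                cv = selection.loocv(
                    data,
                    category,
                    model,
                    fold_subset=fold_subset,
                    settings=settings,
                )
                if best_cv is None or cv.T_hat > best_cv.T_hat:
                    best_cv, best_fit = cv, model
                best_T = max(best_T, cv.T_hat)
            assert best_cv is not None and best_fit is not None
            results.append(best_cv)
            self.results_[category] = best_cv
            self.models_[category] = best_fit
        self.selection_table_ = selection.rank_models(results)
        top = self.selection_table_.iloc[0]
        self.best_category_ = ModelCategory(
            int(top["n_sub"]), int(top["n_super"]), int(top["n_gauss"])
        )
        self.best_model_ = self.models_[self.best_category_]
        self.mean_ = data.row_means
        self.n_features_in_ = m
        return self

    def transform(self, X) -> np.ndarray:
        """Sources of the best-ranked model for new observations."""
        check_is_fitted(self, "best_model_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.best_model_.W.T
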
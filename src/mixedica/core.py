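"""Constrained maximum-likelihood engine for mixed ICA/PCA.

The model decomposes a centered m × n observation matrix X̃ into A·S with
S = W·X̃, where each of the m rows of S is an independent source drawn
from one of three fixed laws (light-tailed, heavy-tailed, or Gaussian).
The log-likelihood of the data under an unmixing matrix W is

    log P(X̃) = n·log|det W| + Σ_ij log p_i(S_ij),

and its gradient with respect to W is dW = n·(Wᵀ)⁻¹ + dS·X̃ᵀ with dS the
matrix of score-function values.

At any likelihood maximum every Gaussian source row is orthogonal to all
other source rows and has squared norm n.  Rather than letting the
optimizer discover this, the Gaussian rows of W are reconstructed
analytically (by orthogonal completion within the row space of X̃) at
every objective evaluation, and only the (n_sub + n_super)·m entries
generating the non-Gaussian sources are optimized.  Since the likelihood
is invariant to orthonormal rotation of the Gaussian source rows, the
fitted Gaussian subspace is afterwards rotated to principal-component
axes, ordered by explained variance.

Row-order convention: sources are laid out sub-Gaussian rows first, then
super-Gaussian rows, then Gaussian rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import scipy.optimize

from .sources import SourceKind, log_density, score

__all__ = [
    "ModelCategory",
    "ObservationMatrix",
    "FittedModel",
    "OptimizerSettings",
    "center_rows",
    "loglik",
    "negloglik",
    "gradient",
    "complete_gaussian_rows",
    "pca_rotate",
    "fit",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelCategory:
    """Counts of each source type: (n_sub, n_super, n_gauss)."""

    n_sub: int
    n_super: int
    n_gauss: int

    def __post_init__(self):
        for v in (self.n_sub, self.n_super, self.n_gauss):
            if int(v) != v or v < 0:
                raise ValueError("source counts must be non-negative integers")

    @property
    def m(self) -> int:
        return self.n_sub + self.n_super + self.n_gauss

    @property
    def n_free(self) -> int:
        """Number of non-Gaussian rows whose W entries are optimized."""
        return self.n_sub + self.n_super

    @property
    def kinds(self) -> Tuple[SourceKind, ...]:
        return (
            (SourceKind.SUB,) * self.n_sub
            + (SourceKind.SUPER,) * self.n_super
            + (SourceKind.GAUSS,) * self.n_gauss
        )

    @classmethod
    def from_kinds(cls, kinds: Sequence[SourceKind]) -> "ModelCategory":
        kinds = list(kinds)
        return cls(
            kinds.count(SourceKind.SUB),
            kinds.count(SourceKind.SUPER),
            kinds.count(SourceKind.GAUSS),
        )

    def __str__(self) -> str:
        return f"({self.n_sub} sub, {self.n_super} super, {self.n_gauss} gauss)"


class ObservationMatrix:
    """A centered m × n observation matrix with its row means.

    Rows are variables, columns independent samples.  The row means are
    retained so held-out samples can be centered with training-set means
    during cross-validation.  The (thin) SVD of the centered matrix is
    cached; it is reused by the Gaussian-row completion at every
    objective evaluation.
    """

    def __init__(self, values: np.ndarray, row_means: np.ndarray):
        self.values = np.asarray(values, dtype=float)
        self.row_means = np.asarray(row_means, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.row_means.shape != (self.values.shape[0],):
            raise ValueError("row_means length must equal the number of rows")
        self._svd: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = None

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def svd(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Thin SVD (U, d, Vt) of the centered matrix; validates full row rank."""
        if self._svd is None:
            U, d, Vt = np.linalg.svd(self.values, full_matrices=False)
            if d[0] <= 0 or d[-1] <= 1e-12 * d[0] * max(self.m, self.n):
                raise np.linalg.LinAlgError(
                    "rows of the centered matrix are not linearly independent"
                )
            self._svd = (U, d, Vt)
        return self._svd

    def drop_column(self, j: int) -> "ObservationMatrix":
        """Re-center the data with column ``j`` held out."""
        raw = self.values + self.row_means[:, None]
        keep = np.delete(raw, j, axis=1)
        return center_rows(keep)

    def held_out_column(self, j: int) -> np.ndarray:
        """Raw (uncentered) column ``j``."""
        return self.values[:, j] + self.row_means


def center_rows(X: np.ndarray) -> ObservationMatrix:
    """Subtract each row's mean, keeping the means for later refits."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D observation matrix")
    m, n = X.shape
    if m < 1 or n < 2:
        raise ValueError("need at least one row and two columns")
    if not np.all(np.isfinite(X)):
        raise ValueError("observation matrix contains non-finite entries")
    if m > n:
        raise ValueError(
            f"more variables ({m}) than samples ({n}); reduce dimension first"
        )
    means = X.mean(axis=1)
    centered = X - means[:, None]
    scale = np.abs(X).max() or 1.0
    if np.any(np.abs(centered).max(axis=1) <= 1e-13 * scale):
        raise ValueError("constant row: zero variance after centering")
    return ObservationMatrix(centered, means)


@dataclass
class FittedModel:
    """A fitted mixed ICA/PCA decomposition S = W·X̃, X̃ = A·S."""

    W: np.ndarray
    A: np.ndarray
    S: np.ndarray
    category: ModelCategory
    loglik: float
    converged: bool = True
    n_iter: int = 0
    row_means: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def m(self) -> int:
        return self.W.shape[0]

    @property
    def n(self) -> int:
        return self.S.shape[1]


@dataclass(frozen=True)
class OptimizerSettings:
    """Quasi-Newton settings for the likelihood maximization.

    ``gtol_per_n`` is scaled by the sample count because the likelihood
    (and hence its gradient) grows linearly with n.
    """

    max_iter: int = 1000
    gtol_per_n: float = 1e-7
    ftol: float = 1e-10
    constraint_tol: float = 1e-6


def _row_loglik_terms(S: np.ndarray, category: ModelCategory) -> float:
    """Σ log p_i(S_ij) with the full (unconstrained) densities."""
    total = 0.0
    for i, kind in enumerate(category.kinds):
        total += float(np.sum(log_density(S[i], kind)))
    return total


def _check_gaussian_constraints(
    S: np.ndarray, category: ModelCategory, n: int, tol: float
) -> None:
    k, m3 = category.n_free, category.n_gauss
    if m3 == 0:
        return
    G = S[k:]
    gram = G @ G.T
    if not np.allclose(gram, n * np.eye(m3), atol=tol * n):
        raise ValueError("Gaussian source rows violate the norm/orthogonality constraints")
    if k and np.abs(S[:k] @ G.T).max() > tol * n:
        raise ValueError("Gaussian source rows are not orthogonal to the non-Gaussian rows")


def loglik(
    W: np.ndarray,
    data: ObservationMatrix,
    category: ModelCategory,
    form: str = "constrained",
    check: bool = True,
) -> float:
    """Log-likelihood of the centered data under unmixing matrix ``W``.

    ``form='direct'`` evaluates n·log|det W| + Σ log p_i(S_ij) with the
    full densities and is valid for any invertible W.  The default
    ``form='constrained'`` replaces each Gaussian row's contribution by
    the constant −(n/2)(log 2π + 1), which is exact when the Gaussian
    rows satisfy the squared-norm-n orthogonality constraints (as they
    do by construction after :func:`complete_gaussian_rows`).
    """
    W = np.asarray(W, dtype=float)
    n = data.n
    sign, logabsdet = np.linalg.slogdet(W)
    if sign == 0 or not np.isfinite(logabsdet):
        raise np.linalg.LinAlgError("singular unmixing matrix")
    S = W @ data.values
    if form == "direct":
        return n * logabsdet + _row_loglik_terms(S, category)
    if form != "constrained":
        raise ValueError("form must be 'constrained' or 'direct'")
    if check:
        _check_gaussian_constraints(S, category, n, tol=1e-6)
    k = category.n_free
    total = n * logabsdet
    total += _row_loglik_terms(S[:k], ModelCategory(category.n_sub, category.n_super, 0))
    total += -0.5 * n * category.n_gauss * (_LOG_2PI + 1.0)
    return total


def negloglik(W, data, category, form: str = "constrained", check: bool = True) -> float:
    """Negative log-likelihood; the quantity the optimizer minimizes."""
    return -loglik(W, data, category, form=form, check=check)


def gradient(
    W: np.ndarray,
    data: ObservationMatrix,
    category: ModelCategory,
    constrained: bool = False,
) -> np.ndarray:
    """Gradient dW = n·(Wᵀ)⁻¹ + dS·X̃ᵀ of the log-likelihood.

    Rows of dS hold the score-function values of the corresponding
    source law.  With ``constrained=True`` the Gaussian rows are zeroed:
    under the orthogonal-completion parameterization those partial
    derivatives vanish identically, so only the non-Gaussian rows carry
    gradient information.
    """
    W = np.asarray(W, dtype=float)
    n = data.n
    S = W @ data.values
    dS = np.empty_like(S)
    for i, kind in enumerate(category.kinds):
        dS[i] = score(S[i], kind)
    dW = n * np.linalg.inv(W).T + dS @ data.values.T
    if constrained:
        dW[category.n_free:] = 0.0
    return dW


def complete_gaussian_rows(
    W_free: np.ndarray, data: ObservationMatrix, n_gauss: int
) -> np.ndarray:
    """Append ``n_gauss`` rows to ``W_free`` satisfying the Gaussian constraints.

    The appended rows generate sources that are mutually orthogonal,
    orthogonal to every non-Gaussian source, have squared norm n, and lie
    in the row space of X̃.  Construction: express the non-Gaussian
    sources in the orthonormal row-space basis from the SVD X̃ = U·D·Vᵀ,
    take the orthogonal complement of their span by complete QR
    factorization, scale the complement basis by √n, and map it back to
    rows of W through (U·D)⁻¹.
    """
    W_free = np.atleast_2d(np.asarray(W_free, dtype=float))
    m = data.m
    if n_gauss == 0:
        return W_free.copy()
    k = W_free.shape[0]
    if k + n_gauss != m:
        raise ValueError("free rows plus Gaussian rows must equal m")
    U, d, Vt = data.svd
    n = data.n
    if k == 0:
        G = np.eye(m)
    else:
        C = (W_free @ data.values) @ Vt.T  # k × m row-space coordinates
        Q, R = np.linalg.qr(C.T, mode="complete")
        if np.abs(np.diag(R)).min() <= 1e-10 * max(np.abs(R).max(), 1e-300):
            raise np.linalg.LinAlgError(
                "non-Gaussian sources are rank deficient; cannot complete"
            )
        G = Q[:, k:].T  # n_gauss × m orthonormal complement
        # fix signs for reproducibility
        flip = np.sign(G[np.arange(n_gauss), np.abs(G).argmax(axis=1)])
        flip[flip == 0] = 1.0
        G = G * flip[:, None]
    W_g = math.sqrt(n) * (G / d) @ U.T
    return np.vstack([W_free, W_g]) if k else W_g


def _sign_normalize(model: FittedModel) -> FittedModel:
    """Fix the sign indeterminacy of every source/component.

    Non-Gaussian sources are flipped so their skewness is positive (the
    largest-magnitude entry breaks near-zero-skew ties); Gaussian
    components so their largest-magnitude mixing loading is positive.
    """
    W, A, S = model.W.copy(), model.A.copy(), model.S.copy()
    k = model.category.n_free
    for i in range(model.m):
        if i < k:
            s = S[i]
            sk = float(np.mean(s**3)) / (float(np.mean(s**2)) ** 1.5 or 1.0)
            if abs(sk) >= 1e-3:
                flip = -1.0 if sk < 0 else 1.0
            else:
                flip = -1.0 if s[np.abs(s).argmax()] < 0 else 1.0
        else:
            col = A[:, i]
            flip = -1.0 if col[np.abs(col).argmax()] < 0 else 1.0
        if flip < 0:
            S[i] *= -1.0
            W[i] *= -1.0
            A[:, i] *= -1.0
    return replace(model, W=W, A=A, S=S)


def pca_rotate(model: FittedModel) -> FittedModel:
    """Rotate the Gaussian subspace to principal-component axes.

    The Gaussian block of the mixing matrix is decomposed as U·D·Vᵀ and
    the rotation R embedding Vᵀ over the Gaussian rows is applied
    (A ← A·Rᵀ, S ← R·S, W ← R·W).  The likelihood is unchanged and the
    rotated Gaussian components are ordered by decreasing explained
    variance.  Non-Gaussian rows are untouched.
    """
    m3 = model.category.n_gauss
    if m3 <= 1:
        return _sign_normalize(model)
    k = model.category.n_free
    A_g = model.A[:, k:]
    _, _, Vt_g = np.linalg.svd(A_g, full_matrices=False)
    R = np.eye(model.m)
    R[k:, k:] = Vt_g
    out = replace(
        model,
        W=R @ model.W,
        A=model.A @ R.T,
        S=R @ model.S,
    )
    return _sign_normalize(out)


def _pca_solution(data: ObservationMatrix, category: ModelCategory) -> FittedModel:
    """Closed-form fit for the all-Gaussian category (plain PCA).

    With every source Gaussian the constrained ML solution is
    W = √n·D⁻¹·Uᵀ from the SVD X̃ = U·D·Vᵀ, whose likelihood equals the
    multivariate-normal maximum −(n/2)(m·log 2π + log det Σ̂_ML + m).
    """
    U, d, Vt = data.svd
    n, m = data.n, data.m
    W = math.sqrt(n) * (U / d).T
    A = U * (d / math.sqrt(n))
    S = math.sqrt(n) * Vt
    ll = n * (0.5 * m * math.log(n) - float(np.sum(np.log(d)))) - 0.5 * n * m * (
        _LOG_2PI + 1.0
    )
    model = FittedModel(W, A, S, category, ll, converged=True, n_iter=0,
                        row_means=data.row_means)
    return _sign_normalize(model)


def fit(
    data: ObservationMatrix,
    category: ModelCategory,
    W_init: Optional[np.ndarray] = None,
    settings: Optional[OptimizerSettings] = None,
) -> FittedModel:
    """Maximize the likelihood over the non-Gaussian rows of W.

    Quasi-Newton (L-BFGS) minimization of the negative log-likelihood
    over the (n_sub + n_super)·m free entries; the Gaussian rows are
    completed analytically at every evaluation.  The returned model is
    rotated to principal axes within the Gaussian subspace and
    sign-normalized.  Deterministic given (data, category, W_init,
    settings).  An all-Gaussian category bypasses optimization entirely
    and returns the closed-form PCA solution.
    """
    settings = settings or OptimizerSettings()
    m, n = data.m, data.n
    if category.m != m:
        raise ValueError(f"category {category} does not match m={m}")
    if category.n_free == 0:
        return _pca_solution(data, category)
    if W_init is None:
        W_init = np.eye(m)
    W_init = np.asarray(W_init, dtype=float)
    if W_init.shape != (m, m):
        raise ValueError("W_init must be m × m")
    k = category.n_free
    x0 = W_init[:k].ravel().copy()
    penalty = 1e12

    def objective(x):
        W_free = x.reshape(k, m)
        try:
            W = complete_gaussian_rows(W_free, data, category.n_gauss)
            nll = negloglik(W, data, category, form="constrained", check=False)
        except (np.linalg.LinAlgError, ValueError):
            return penalty, np.zeros_like(x)
        if not np.isfinite(nll):
            return penalty, np.zeros_like(x)
        g = -gradient(W, data, category)[:k].ravel()
        return nll, g

    res = scipy.optimize.minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": settings.max_iter,
            "ftol": settings.ftol,
            "gtol": settings.gtol_per_n * n,
        },
    )
    x_best, f_best = res.x, res.fun
    f0, _ = objective(x0)
    if f0 < f_best:  # safeguard: never end below the starting likelihood
        x_best, f_best = x0, f0
    W = complete_gaussian_rows(x_best.reshape(k, m), data, category.n_gauss)
    model = FittedModel(
        W=W,
        A=np.linalg.inv(W),
        S=W @ data.values,
        category=category,
        loglik=-f_best,
        converged=bool(res.success) and f_best < penalty,
        n_iter=int(res.nit),
        row_means=data.row_means,
    )
    return pca_rotate(model)
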
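"""Initialization schemes for the multi-start likelihood optimization.

The likelihood surface has local optima, especially when several source
types are mixed.  The primary scheme starts the optimizer from every
distinct assignment of source labels to data rows, realized by permuting
the columns of the identity matrix used to initialize W.  The secondary
scheme pre-rotates the data by random orthonormal (Haar-distributed)
matrices, equivalent to starting from W = O_Rᵀ; it can be crossed with
the primary scheme.  A third scheme warm-starts from sources found by a
previously fitted (possibly different-category) model.
"""

from __future__ import annotations

import math
from typing import Iterator, List, Optional

import numpy as np

from .core import ModelCategory, ObservationMatrix, complete_gaussian_rows

__all__ = [
    "n_permutation_inits",
    "permutation_inits",
    "iter_permutation_inits",
    "random_orthonormal",
    "warm_start",
]


def n_permutation_inits(category: ModelCategory) -> int:
    """Multinomial count m!/(n_sub!·n_super!·n_gauss!) of distinct label assignments."""
    m = category.m
    return math.factorial(m) // (
        math.factorial(category.n_sub)
        * math.factorial(category.n_super)
        * math.factorial(category.n_gauss)
    )


def _label_patterns(category: ModelCategory) -> Iterator[tuple]:
    # distinct multiset permutations of per-data-row labels (0=sub, 1=super, 2=gauss)
    m = category.m
    counts = [category.n_sub, category.n_super, category.n_gauss]
    pattern: list = []

    def rec() -> Iterator[tuple]:
        if len(pattern) == m:
            yield tuple(pattern)
            return
        for lab in range(3):
            if counts[lab]:
                counts[lab] -= 1
                pattern.append(lab)
                yield from rec()
                pattern.pop()
                counts[lab] += 1

    yield from rec()


def iter_permutation_inits(category: ModelCategory) -> Iterator[np.ndarray]:
    """Yield one column-permuted identity matrix per distinct label assignment.

    Rows of W are laid out sub first, then super, then Gaussian; permuting
    the columns of the identity maps each data row to each label pattern
    exactly once (assignments that merely swap same-type rows are
    collapsed).
    """
    m = category.m
    for pattern in _label_patterns(category):
        W = np.zeros((m, m))
        r = 0
        for lab in range(3):
            for j in range(m):
                if pattern[j] == lab:
                    W[r, j] = 1.0
                    r += 1
        yield W


def permutation_inits(category: ModelCategory, cap: int = 10**6) -> List[np.ndarray]:
    """All permutation initializations, guarded by a count cap."""
    count = n_permutation_inits(category)
    if count > cap:
        raise ValueError(
            f"{count} permutation initializations exceed the cap {cap}; "
            "use random rotations instead"
        )
    return list(iter_permutation_inits(category))


def random_orthonormal(m: int, rng: np.random.Generator) -> np.ndarray:
    """A Haar-distributed m × m orthonormal matrix.

    QR factorization of a standard-normal matrix with the triangular
    factor's diagonal signs fixed positive — the standard construction
    of a Haar draw.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    Z = rng.standard_normal((m, m))
    Q, R = np.linalg.qr(Z)
    return Q * np.sign(np.diag(R))


def warm_start(
    prev_sources: np.ndarray,
    data: ObservationMatrix,
    atol: Optional[float] = None,
) -> np.ndarray:
    """Unmixing-matrix start reproducing previously found sources.

    The first k rows of the returned W regenerate ``prev_sources`` from
    X̃; the remaining rows complete an orthonormal (scaled) basis of the
    complement of those sources within the row space.  All rows remain
    free for subsequent optimization.  Raises if the requested sources
    do not lie in the row space of X̃.
    """
    prev_sources = np.atleast_2d(np.asarray(prev_sources, dtype=float))
    k = prev_sources.shape[0] if prev_sources.size else 0
    m, n = data.m, data.n
    if k > m:
        raise ValueError("more previous sources than data dimensions")
    if k == 0:
        return complete_gaussian_rows(np.empty((0, m)), data, m)
    if prev_sources.shape[1] != n:
        raise ValueError("previous sources must have n columns")
    U, d, Vt = data.svd
    # solve W_k @ X = prev_sources via the pseudoinverse through the SVD
    W_k = (prev_sources @ Vt.T) / d @ U.T
    recon = W_k @ data.values
    tol = atol if atol is not None else 1e-8 * max(1.0, float(np.abs(prev_sources).max()))
    if np.abs(recon - prev_sources).max() > tol * n:
        raise ValueError("previous sources do not lie in the row space of the data")
    if k == m:
        return W_k
    return complete_gaussian_rows(W_k, data, m - k)
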
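"""Delimited-matrix I/O, SVD pre-reduction, and z-score weight maps."""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import numpy as np

from .core import FittedModel, center_rows

__all__ = ["read_matrix", "svd_reduce", "zscore_weights"]


def read_matrix(path, orientation: str = "variables", delimiter: str = ",") -> np.ndarray:
    """Read a delimited numeric matrix with variables as rows.

    ``orientation='variables'`` takes file rows as variables;
    ``'samples'`` transposes.  Ragged rows, non-numeric cells or an
    empty file raise a parse error naming the offending line.
    """
    if orientation not in ("variables", "samples"):
        raise ValueError("orientation must be 'variables' or 'samples'")
    path = Path(path)
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = [c.strip() for c in line.split(delimiter)]
            # tolerate a leading label column of names
            if cells and not _is_number(cells[0]):
                cells = cells[1:]
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise ValueError(
                    f"{path.name}:{lineno}: ragged row "
                    f"({len(cells)} cells, expected {width})"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError:
                bad = next(i for i, c in enumerate(cells) if not _is_number(c))
                raise ValueError(
                    f"{path.name}:{lineno}: non-numeric cell "
                    f"{cells[bad]!r} in column {bad + 1}"
                ) from None
    if not rows:
        raise ValueError(f"{path.name}: empty matrix")
    X = np.asarray(rows, dtype=float)
    return X if orientation == "variables" else X.T


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def svd_reduce(
    X: np.ndarray, k: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Project a centered (or raw) m × n matrix onto its top-k left singular vectors.

    Returns ``(X_red, U_k, singular_values, retained)`` where
    ``X_red = U_kᵀ·X̃`` is k × n, ``U_k`` holds the top-k left singular
    vectors of the centered matrix, and ``retained`` is the fraction of
    total variance kept (sum of the top-k squared singular values over
    the total).  Reduction discards the orthogonal subspace with the
    least variance; any non-Gaussian structure inside it is lost, so
    reduce only when the full dimension is computationally out of reach.
    """
    data = center_rows(np.asarray(X, dtype=float))
    U, d, _ = data.svd
    rank = int(np.sum(d > 1e-12 * d[0] * max(data.m, data.n)))
    if not 1 <= k <= rank:
        raise ValueError(f"k must be between 1 and rank {rank}")
    U_k = U[:, :k]
    X_red = U_k.T @ data.values
    retained = float(np.sum(d[:k] ** 2) / np.sum(d**2))
    return X_red, U_k, d[:k].copy(), retained


def zscore_weights(
    model: FittedModel, U_k: np.ndarray, row_sds: np.ndarray
) -> np.ndarray:
    """Weights mapping z-scored original variables to the model's sources.

    After an m → k SVD reduction, right-multiplying the k × k unmixing
    matrix by U_kᵀ gives a k × m matrix applicable to the original
    centered variables; rescaling its columns by the original rows'
    standard deviations preserves the product against z-scored data.
    The result is laid out variables × sources (m × k): column i weights
    the m z-scored variables in source i — the heat-map representation
    of what each source measures — and ``weights.T @ Z == S`` for the
    z-scored matrix Z.
    """
    U_k = np.asarray(U_k, dtype=float)
    row_sds = np.asarray(row_sds, dtype=float)
    if U_k.shape[1] != model.m:
        raise ValueError("U_k column count must match the model dimension")
    if row_sds.shape != (U_k.shape[0],):
        raise ValueError("row_sds length must match the original variable count")
    if np.any(row_sds <= 0):
        raise ValueError("zero or negative standard deviation variable")
    return ((model.W @ U_k.T) * row_sds[None, :]).T
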
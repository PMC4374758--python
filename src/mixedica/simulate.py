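"""Synthetic mixtures with known ground truth, and the iris example data.

Every stage of the pipeline is testable against mixtures X = A_true·S_true
whose source laws, mixing matrix and seed are known.  Recovery is judged
with a permutation- and scale-invariant mixing error for non-Gaussian
sources, and by principal angles for a Gaussian subspace — individual
"sources" inside a Gaussian subspace are rotation-arbitrary, so only the
span is ever compared.

The classic 4 × 150 Fisher iris table ships as a small CSV so the worked
example needs no download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.stats

from .core import FittedModel, ModelCategory, ObservationMatrix
from .sources import SourceKind, sample

__all__ = [
    "SyntheticSpec",
    "generate",
    "amari_style_error",
    "match_sources",
    "variance_explained",
    "load_iris_matrix",
]

MixingSpec = Union[str, np.ndarray]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic mixture.

    ``mixing`` may be an explicit invertible m × m matrix or a named
    recipe: ``"identity"``, ``"rotation:<degrees>"`` (a plane rotation of
    the first two coordinates), or ``"random-cond:<c>"`` (a random matrix
    with condition number c, built from two independent Haar rotations).
    """

    kinds: Sequence[SourceKind]
    mixing: MixingSpec = "identity"
    n: int = 1000
    seed: int = 0

    @property
    def m(self) -> int:
        return len(self.kinds)


def _rotation_matrix(m: int, degrees: float) -> np.ndarray:
    if m < 2:
        raise ValueError("a rotation recipe needs m >= 2")
    th = math.radians(degrees)
    R = np.eye(m)
    R[0, 0] = R[1, 1] = math.cos(th)
    R[0, 1] = -math.sin(th)
    R[1, 0] = math.sin(th)
    return R


def _resolve_mixing(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    m = spec.m
    if isinstance(spec.mixing, str):
        name = spec.mixing.strip().lower()
        if name == "identity":
            return np.eye(m)
        if name.startswith("rotation:"):
            return _rotation_matrix(m, float(name.split(":", 1)[1]))
        if name.startswith("random-cond:"):
            from .initialization import random_orthonormal

            cond = float(name.split(":", 1)[1])
            if cond < 1:
                raise ValueError("condition number must be >= 1")
            d = np.logspace(0, -math.log10(cond), m) if m > 1 else np.ones(1)
            return random_orthonormal(m, rng) * d @ random_orthonormal(m, rng)
        raise ValueError(f"unknown mixing recipe {spec.mixing!r}")
    A = np.asarray(spec.mixing, dtype=float)
    if A.shape != (m, m):
        raise ValueError("mixing matrix must be m × m")
    if abs(np.linalg.slogdet(A)[0]) != 1:
        raise np.linalg.LinAlgError("mixing matrix is singular")
    return A


def generate(spec: SyntheticSpec) -> Tuple[np.ndarray, dict]:
    """Draw X = A_true·S_true per the spec; deterministic for a given seed.

    Returns the raw observation matrix (m × n, rows = variables) and a
    ground-truth dict with keys ``A_true``, ``S_true`` and ``category``.
    """
    rng = np.random.default_rng(spec.seed)
    A = _resolve_mixing(spec, rng)
    S = np.vstack([sample(k, spec.n, rng) for k in spec.kinds])
    X = A @ S
    truth = {
        "A_true": A,
        "S_true": S,
        "category": ModelCategory.from_kinds(spec.kinds),
    }
    return X, truth


def amari_style_error(W: np.ndarray, A_true: np.ndarray) -> float:
    """Permutation/scale-invariant recovery error of W against A_true.

    Based on the normalized row/column dominance of P = W·A_true: zero
    exactly when P is a scaled permutation matrix (perfect recovery up to
    the unavoidable order and sign/scale ambiguities), approaching 1 for
    unrelated matrices.
    """
    P = np.abs(np.asarray(W, dtype=float) @ np.asarray(A_true, dtype=float))
    m = P.shape[0]
    if P.shape != (m, m):
        raise ValueError("W·A_true must be square")
    if m == 1:
        return 0.0
    rows = (P.sum(axis=1) / P.max(axis=1) - 1.0).sum()
    cols = (P.sum(axis=0) / P.max(axis=0) - 1.0).sum()
    return float((rows + cols) / (2.0 * m * (m - 1)))


def match_sources(models: Sequence[FittedModel]) -> pd.DataFrame:
    """Pair each model's sources with the first (best) model's sources.

    Greedy maximum-|Pearson| assignment; each pair reports the signed
    Pearson and Spearman rank correlations.  Used to judge whether
    competing model categories recover the same underlying sources.
    """
    if not models:
        raise ValueError("need at least one model")
    ref = models[0]
    rows = []
    for idx, model in enumerate(models):
        if model.n != ref.n:
            raise ValueError("models must share the sample count n")
        C = np.corrcoef(ref.S, model.S)[: ref.m, ref.m:]
        avail_ref = set(range(ref.m))
        avail = set(range(model.m))
        pairs = []
        while avail_ref and avail:
            i, j = max(
                ((i, j) for i in avail_ref for j in avail),
                key=lambda ij: abs(C[ij[0], ij[1]]),
            )
            pairs.append((i, j))
            avail_ref.discard(i)
            avail.discard(j)
        for i, j in sorted(pairs):
            rho = scipy.stats.spearmanr(ref.S[i], model.S[j]).statistic
            rows.append(
                {
                    "model": idx,
                    "ref_source": i,
                    "source": j,
                    "kind": model.category.kinds[j].value,
                    "pearson": float(C[i, j]),
                    "spearman": float(rho),
                }
            )
    return pd.DataFrame(rows)


def variance_explained(model: FittedModel, data: ObservationMatrix) -> np.ndarray:
    """Percent of total variance carried by each source/component.

    Component i contributes A[:, i]·S[i, :]; its squared Frobenius norm
    is taken relative to that of X̃.  Percentages add to ~100 when the
    sources are near-orthogonal (exactly 100 for pure PCA).
    """
    total = float(np.sum(data.values**2))
    out = np.empty(model.m)
    for i in range(model.m):
        out[i] = (
            float(np.sum(np.outer(model.A[:, i], model.S[i]) ** 2)) / total * 100.0
        )
    return out


def load_iris_matrix() -> Tuple[np.ndarray, List[str]]:
    """The packaged 4 × 150 Fisher iris table (rows = variables, in cm)."""
    with resources.files("mixedica.data").joinpath("iris.csv").open() as fh:
        df = pd.read_csv(fh, header=None, index_col=0)
    return df.to_numpy(dtype=float), list(df.index)
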
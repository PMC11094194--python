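"""Spearman-maximal-relevance (SMR) eigen-feature extraction.

The trunk matrix Z is turned into two rank views: R(X) holds the
column-wise ranks of Z (each column's entries replaced by their ascending
rank within that column) and R(Y) the row-wise ranks.  After each column
of both views is centred and scaled to unit Euclidean norm, the Spearman
correlation between a pair of unit loading directions alpha (X side) and
beta (Y side) is the bilinear form ``alpha' R(X)' R(Y) beta``.  Maximising
it under the unit-norm constraints reduces to the symmetric eigenproblem
of the maximum-rank-correlation (MRR) matrix

    M = R(X)' R(Y) R(Y)' R(X),      M alpha = lambda alpha,

whose top eigenvectors are collected into the loading matrix
P = [alpha_1, ..., alpha_k].  The salient feature matrix is the projection
T = Z P, the input to band-wise feature construction.

Components are retained in descending eigenvalue order until their
cumulative contribution reaches a fraction ``theta`` of the total
(default 0.95), capped at ``k_max`` (default 7).  Eigenvector signs are
fixed so the largest-magnitude component of each alpha is positive,
making T reproducible bit-for-bit.

Loadings are computed per sample, so feature extraction is stateless and
cannot leak information across a train/test split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .data_model import DegenerateInputError, StructuralError

logger = logging.getLogger(__name__)

_NORM_TOL = 1e-12


def rank_transform(v: np.ndarray) -> np.ndarray:
    """Ascending 1-based ranks of a vector; ties get the average rank.

    ``[5, 5, 1] -> [2.5, 2.5, 1]``.  Requires at least two elements.
    """
    v = np.asarray(v, dtype=float).ravel()
    if v.size < 2:
        raise DegenerateInputError(f"need at least 2 values to rank, got {v.size}")
    return rankdata(v, method="average")


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of the rank vectors.

    Raises :class:`DegenerateInputError` when either vector is constant
    (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise StructuralError(f"length mismatch: {x.size} vs {y.size}")
    rx = rank_transform(x) - (x.size + 1) / 2.0
    ry = rank_transform(y) - (y.size + 1) / 2.0
    nx, ny = np.linalg.norm(rx), np.linalg.norm(ry)
    if nx < _NORM_TOL or ny < _NORM_TOL:
        raise DegenerateInputError("correlation undefined for a constant vector")
    return float(rx @ ry / (nx * ny))


@dataclass
class RankViews:
    """Normalized rank views of a trunk matrix.

    ``RX``: column-wise ranks of Z, each column centred and unit-norm.
    ``RY``: row-wise ranks of Z, the resulting matrix then normalized
    column-wise the same way.  Columns that were constant before
    normalization carry no order information and are left as zeros;
    their indices are recorded in ``degenerate_x`` / ``degenerate_y``.
    """

    RX: np.ndarray
    RY: np.ndarray
    degenerate_x: list[int] = field(default_factory=list)
    degenerate_y: list[int] = field(default_factory=list)


def _normalize_columns(R: np.ndarray) -> tuple[np.ndarray, list[int]]:
    out = R - R.mean(axis=0, keepdims=True)
    degenerate: list[int] = []
    for j in range(out.shape[1]):
        n = np.linalg.norm(out[:, j])
        if n < _NORM_TOL:
            out[:, j] = 0.0
            degenerate.append(j)
        else:
            out[:, j] /= n
    return out, degenerate


def build_rank_views(Z: np.ndarray) -> RankViews:
    """Build the two normalized rank views of a (preprocessed) trunk matrix.

    Constant columns or rows rank to the uniform mid-rank, which centres
    to zero; such columns are zeroed rather than raising, and flagged.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or min(Z.shape) < 2:
        raise StructuralError(f"need a 2-D matrix with both sides >= 2, got shape {Z.shape}")
    rank_cols = np.column_stack([rankdata(Z[:, j], method="average") for j in range(Z.shape[1])])
    rank_rows = np.vstack([rankdata(Z[i, :], method="average") for i in range(Z.shape[0])])
    RX, deg_x = _normalize_columns(rank_cols)
    RY, deg_y = _normalize_columns(rank_rows)
    if deg_x or deg_y:
        logger.debug("rank-degenerate columns: X-view %s, Y-view %s; "
                     "these carry no rank information and were zeroed",
                     deg_x, deg_y)
    return RankViews(RX=RX, RY=RY, degenerate_x=deg_x, degenerate_y=deg_y)


@dataclass
class SmrDecomposition:
    """Eigendecomposition of the MRR matrix with the retained loadings.

    ``eigenvalues`` holds the full non-increasing spectrum of M;
    ``loadings`` (P) the first ``k_retained`` eigenvectors as columns;
    ``paired_loadings`` the matching Y-side directions beta_k, recovered
    as the normalized image R(Y)' R(X) alpha_k.
    """

    eigenvalues: np.ndarray
    loadings: np.ndarray
    paired_loadings: np.ndarray
    contribution_threshold: float
    k_retained: int

    @property
    def contributions(self) -> np.ndarray:
        """Fraction of total spectrum mass per component."""
        return self.eigenvalues / self.eigenvalues.sum()


def mrr_decompose(views: RankViews, theta: float = 0.95, k_max: int = 7,
                  k_min: int = 1) -> SmrDecomposition:
    """Eigendecompose the MRR matrix and retain the leading components.

    Retains the smallest prefix of the descending spectrum whose
    cumulative contribution reaches ``theta``, clipped to
    ``[k_min, k_max]``.  ``k_min`` > 1 keeps the projection wide enough
    for downstream band splits that need a minimum number of columns.

    Raises :class:`DegenerateInputError` when M is (numerically) zero.
    """
    if not 0 < theta <= 1:
        raise ValueError(f"theta must be in (0, 1], got {theta}")
    if k_max < 1 or k_min < 1 or k_min > k_max:
        raise ValueError(f"need 1 <= k_min <= k_max, got k_min={k_min}, k_max={k_max}")
    RX, RY = views.RX, views.RY
    K = RX.T @ RY                       # cross-rank-correlation matrix
    M = K @ K.T                         # MRR matrix, symmetric PSD
    M = (M + M.T) / 2.0
    total = np.trace(M)
    if total < _NORM_TOL:
        raise DegenerateInputError("MRR matrix is zero: no rank structure in the input")
    eigvals, eigvecs = np.linalg.eigh(M)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    cumulative = np.cumsum(eigvals) / eigvals.sum()
    k = int(np.searchsorted(cumulative, theta) + 1)
    k = max(k_min, min(k, k_max, eigvals.size))
    P = eigvecs[:, :k].copy()
    # sign convention: largest-|component| of each alpha made positive
    for j in range(k):
        pivot = np.argmax(np.abs(P[:, j]))
        if P[pivot, j] < 0:
            P[:, j] = -P[:, j]
    beta = K.T @ P
    norms = np.linalg.norm(beta, axis=0)
    nonzero = norms > _NORM_TOL
    beta[:, nonzero] /= norms[nonzero]
    return SmrDecomposition(
        eigenvalues=eigvals,
        loadings=P,
        paired_loadings=beta,
        contribution_threshold=theta,
        k_retained=k,
    )


def salient_matrix(Z: np.ndarray, decomp: SmrDecomposition) -> np.ndarray:
    """Project the trunk matrix onto the retained loadings: T = Z P."""
    Z = np.asarray(Z, dtype=float)
    P = decomp.loadings
    if Z.ndim != 2 or Z.shape[1] != P.shape[0]:
        raise StructuralError(
            f"cannot project: Z has {Z.shape} columns-shape, P expects {P.shape[0]} columns"
        )
    return Z @ P
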
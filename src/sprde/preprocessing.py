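"""Two-stage denoising of the trunk pressure matrix.

Stage one removes sensor system error: every cell below the global mean of
the 121 trunk readings (``thre``) is zeroed.  Stage two removes redundant
readings from air springs displaced by, but not in contact with, the body:
from the stage-one output, ``f_i`` is the maximum of the nonzero entries of
row i (rows with no contact are skipped), ``nthre = 3/4 * min f_i``, and
every cell below ``nthre`` is zeroed.  Both comparisons are inclusive
(cells >= the threshold survive).

Each frame is processed independently; head and leg regions are not
touched by these filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import DegenerateInputError, validate_trunk


@dataclass
class PreprocessResult:
    """Output of the two-stage filter.

    Attributes
    ----------
    Z_filtered : 11 x 11 filtered trunk matrix.
    thre : global threshold (mean of the 121 input readings).
    nthre : neighborhood threshold (0.75 x smallest contact-row maximum).
    row_maxima : per-row maxima f_i of the stage-one output, NaN for rows
        with no surviving contact.
    """

    Z_filtered: np.ndarray
    thre: float
    nthre: float
    row_maxima: np.ndarray


def trunk_threshold(Z: np.ndarray) -> float:
    """Global threshold: arithmetic mean of all 121 trunk readings."""
    Z = validate_trunk(Z)
    return float(Z.sum() / Z.size)


def threshold_filter(Z: np.ndarray, thre: float) -> np.ndarray:
    """Keep entries >= ``thre``, zero the rest.  Shape is preserved."""
    if thre < 0:
        raise ValueError(f"threshold must be >= 0, got {thre}")
    Z = np.asarray(Z, dtype=float)
    return np.where(Z >= thre, Z, 0.0)


def neighborhood_threshold(Z: np.ndarray) -> tuple[float, np.ndarray]:
    """Neighborhood threshold from per-row contact maxima.

    f_i is the maximum of the nonzero entries in row i, defined only for
    rows that have at least one nonzero entry; the threshold is
    ``3/4 * min{f_i}``.  Returns ``(nthre, row_maxima)`` where
    ``row_maxima[i]`` is NaN for rows without contact.

    Raises
    ------
    DegenerateInputError
        if the matrix is entirely zero (no body contact).
    """
    Z = np.asarray(Z, dtype=float)
    row_maxima = np.full(Z.shape[0], np.nan)
    for i in range(Z.shape[0]):
        nz = Z[i][Z[i] != 0]
        if nz.size:
            row_maxima[i] = nz.max()
    if np.isnan(row_maxima).all():
        raise DegenerateInputError("all-zero trunk matrix: no body contact")
    nthre = 0.75 * float(np.nanmin(row_maxima))
    return nthre, row_maxima


def preprocess(Z: np.ndarray) -> PreprocessResult:
    """Run both filter stages on a trunk matrix.

    Raises :class:`DegenerateInputError` on an all-zero input.
    """
    Z = validate_trunk(Z)
    if not Z.any():
        raise DegenerateInputError("all-zero trunk matrix: no body contact")
    thre = trunk_threshold(Z)
    Z1 = threshold_filter(Z, thre)
    nthre, row_maxima = neighborhood_threshold(Z1)
    Z2 = threshold_filter(Z1, nthre)
    return PreprocessResult(Z_filtered=Z2, thre=thre, nthre=nthre, row_maxima=row_maxima)
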
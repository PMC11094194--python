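"""Band-wise boundary and ratio features from the salient matrix T.

Two complementary partitions of T drive feature construction:

* horizontal (SBWH): four row bands — shoulder, back, waist, hip — the
  body's main support areas.  Entries below ``R_Thre = 3/5 * min{M_R}``
  (M_R = per-row maxima over contact rows) are zeroed, and each band
  contributes its 4 largest surviving entries (scan order, zero-padded)
  to a boundary row a_i; A = [a_0; a_1; a_2; a_3] is 4 x 4.  Feature
  enhancement divides band vectors pairwise: the six ratio rows
  b_0 = Rat(a_0, a_1), b_1 = Rat(a_0, a_2), b_2 = Rat(a_0, a_3),
  b_3 = Rat(a_1, a_2), b_4 = Rat(a_1, a_3), b_5 = Rat(a_2, a_3)
  form the 6 x 4 matrix B.

* longitudinal (LMR): three column bands — left, middle, right — tracking
  the spinal line.  With ``C_Thre = 3/5 * min{M_C}`` over per-column
  contact maxima, each band contributes its 6 largest surviving entries
  to a boundary column c_i; C = [c_0 c_1 c_2] is 6 x 3 (18 boundary
  features in total).  The ratio columns are d_0 = Rat(c_0, c_1),
  d_1 = Rat(c_0, c_2), d_2 = Rat(c_2, c_1), forming the 6 x 3 matrix D.

The fused SE vector is the concatenation A -> B -> C -> D (row-major
within each block): 16 + 24 + 18 + 18 = 76 features, the classifier
input.  Ratios where the denominator vanishes are set to 0 (a band with
no support carries no contrast), keeping every feature finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import DegenerateInputError, StructuralError

Interval = tuple[int, int]

SE_LENGTH = 76

#: Pairing order of the six horizontal ratio rows (indices into a_0..a_3).
HORIZONTAL_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
#: Pairing order of the three longitudinal ratio columns; the last pairs
#: right over middle, as the construction prescribes.
LONGITUDINAL_PAIRS = ((0, 1), (0, 2), (2, 1))


@dataclass(frozen=True)
class BandDefinition:
    """Row and column partitions of T into SBWH and LMR bands."""

    horizontal_bands: tuple[Interval, Interval, Interval, Interval]
    longitudinal_bands: tuple[Interval, Interval, Interval]

    def __post_init__(self) -> None:
        _check_partition(self.horizontal_bands, 4, "horizontal")
        _check_partition(self.longitudinal_bands, 3, "longitudinal")

    @property
    def n_rows(self) -> int:
        return self.horizontal_bands[-1][1]

    @property
    def n_cols(self) -> int:
        return self.longitudinal_bands[-1][1]

    @classmethod
    def default(cls, n_rows: int = 11, n_cols: int = 7) -> "BandDefinition":
        """Default bands, scaled from the 11-row / 7-column reference split.

        On the reference shape the rows split at 3, 6, 9 (shoulder / back /
        waist / hip, following torso proportions) and the columns at 2, 5
        (left / middle / right).
        """
        rb = [round(b * n_rows / 11) for b in (3, 6, 9)]
        cb = [round(b * n_cols / 7) for b in (2, 5)]
        horizontal = ((0, rb[0]), (rb[0], rb[1]), (rb[1], rb[2]), (rb[2], n_rows))
        longitudinal = ((0, cb[0]), (cb[0], cb[1]), (cb[1], n_cols))
        return cls(horizontal_bands=horizontal, longitudinal_bands=longitudinal)


def _check_partition(bands: tuple[Interval, ...], expected: int, name: str) -> None:
    if len(bands) != expected:
        raise StructuralError(f"{name} partition needs {expected} bands, got {len(bands)}")
    cursor = 0
    for start, stop in bands:
        if start != cursor or stop <= start:
            raise StructuralError(
                f"{name} bands must be ordered, disjoint, non-empty and covering; got {bands}"
            )
        cursor = stop


@dataclass
class HorizontalFeatures:
    """SBWH feature subset: boundary matrix A (4 x 4) and ratio matrix B (6 x 4)."""

    A: np.ndarray
    B: np.ndarray
    r_thre: float
    row_maxima: np.ndarray


@dataclass
class LongitudinalFeatures:
    """LMR feature subset: boundary matrix C (6 x 3) and ratio matrix D (6 x 3)."""

    C: np.ndarray
    D: np.ndarray
    c_thre: float
    col_maxima: np.ndarray


def ratio_transform(m: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Elementwise ratio m_t / n_t with a zero guard.

    Where ``|n_t|`` falls below ``1e-9 * max(|m|_inf, |n|_inf, 1)`` the
    output element is 0.
    """
    m = np.asarray(m, dtype=float).ravel()
    n = np.asarray(n, dtype=float).ravel()
    if m.size != n.size:
        raise StructuralError(f"ratio vectors differ in length: {m.size} vs {n.size}")
    scale = max(np.abs(m).max(initial=0.0), np.abs(n).max(initial=0.0), 1.0)
    eps = 1e-9 * scale
    out = np.zeros_like(m)
    ok = np.abs(n) >= eps
    out[ok] = m[ok] / n[ok]
    return out


def _contact_maxima_rows(T: np.ndarray) -> np.ndarray:
    """Max of nonzero entries per contact row (rows with any nonzero entry)."""
    maxima = np.full(T.shape[0], np.nan)
    for i in range(T.shape[0]):
        nz = T[i][T[i] != 0]
        if nz.size:
            maxima[i] = nz.max()
    return maxima


def _top_k_scan_order(band: np.ndarray, thre: float, k: int, order: str) -> np.ndarray:
    """Threshold a band and take its k largest survivors in scan order.

    Entries >= ``thre`` survive; among survivors the k largest values are
    chosen (ties resolved toward earlier scan positions) and emitted in
    scan order — row-major for ``order='C'``, column-major for ``'F'``.
    Fewer than k survivors zero-pad the tail.
    """
    flat = band.ravel(order=order)
    surviving = np.flatnonzero(flat >= thre)
    if surviving.size == 0:
        return np.zeros(k)
    # stable sort on -value keeps scan order among ties
    by_value = surviving[np.argsort(-flat[surviving], kind="stable")]
    chosen = np.sort(by_value[:k])
    out = np.zeros(k)
    out[: chosen.size] = flat[chosen]
    return out


def horizontal_features(T: np.ndarray, bands: BandDefinition) -> HorizontalFeatures:
    """Build the SBWH subset from T's four row bands."""
    T = np.asarray(T, dtype=float)
    if T.shape[0] < 4:
        raise StructuralError(f"horizontal split needs >= 4 rows, T has {T.shape[0]}")
    if T.shape[0] != bands.n_rows:
        raise StructuralError(f"band definition covers {bands.n_rows} rows, T has {T.shape[0]}")
    if not T.any():
        raise DegenerateInputError("all-zero salient matrix")
    row_maxima = _contact_maxima_rows(T)
    r_thre = 0.6 * float(np.nanmin(row_maxima))
    A = np.vstack([
        _top_k_scan_order(T[start:stop, :], r_thre, 4, order="C")
        for start, stop in bands.horizontal_bands
    ])
    B = np.vstack([ratio_transform(A[i], A[j]) for i, j in HORIZONTAL_PAIRS])
    return HorizontalFeatures(A=A, B=B, r_thre=r_thre, row_maxima=row_maxima)


def longitudinal_features(T: np.ndarray, bands: BandDefinition) -> LongitudinalFeatures:
    """Build the LMR subset from T's three column bands."""
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[1] < 3:
        raise StructuralError(f"longitudinal split needs >= 3 columns, T has shape {T.shape}")
    if T.shape[1] != bands.n_cols:
        raise StructuralError(f"band definition covers {bands.n_cols} columns, T has {T.shape[1]}")
    if not T.any():
        raise DegenerateInputError("all-zero salient matrix")
    col_maxima = _contact_maxima_rows(T.T)
    c_thre = 0.6 * float(np.nanmin(col_maxima))
    C = np.column_stack([
        _top_k_scan_order(T[:, start:stop], c_thre, 6, order="F")
        for start, stop in bands.longitudinal_bands
    ])
    D = np.column_stack([ratio_transform(C[:, i], C[:, j]) for i, j in LONGITUDINAL_PAIRS])
    return LongitudinalFeatures(C=C, D=D, c_thre=c_thre, col_maxima=col_maxima)


def fuse_se(h: HorizontalFeatures, l: LongitudinalFeatures) -> np.ndarray:
    """Fuse SBWH and LMR into the SE vector: concat A, B, C, D row-major."""
    se = np.concatenate([h.A.ravel(), h.B.ravel(), l.C.ravel(), l.D.ravel()])
    if se.size != SE_LENGTH:
        raise StructuralError(f"SE vector must have {SE_LENGTH} entries, got {se.size}")
    return se


def se_block_slices() -> dict[str, slice]:
    """Index map from SE vector positions back to the A/B/C/D blocks."""
    return {
        "A": slice(0, 16),
        "B": slice(16, 40),
        "C": slice(40, 58),
        "D": slice(58, 76),
    }
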
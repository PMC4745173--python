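"""Haar wavelet matrices and the 2-D scale-mixing transform.

The transform used throughout is ``Z = W_rows @ Ystar @ W_cols.T`` where
both W's are orthogonal Haar analysis matrices with rows ordered
coarsest-first: scaling rows, then detail rows from the coarsest level
down to the finest.  For depth 2 and size 4 this is exactly

    [ 1/2   1/2   1/2   1/2 ]
    [ 1/2   1/2  -1/2  -1/2 ]
    [ s2   -s2    0     0   ]      s2 = sqrt(2)/2
    [ 0     0     s2   -s2  ]

Left-multiplication mixes the row scales (the four indicator rows),
right-multiplication by the transpose mixes the column scales (sequence
positions); mixing the two is what "scale-mixing" refers to.

For long sequences the column-side transform is done by Mallat's
pyramidal filtering instead of an explicit N x N matrix product; the two
paths agree to floating-point accuracy and tests pin that equivalence.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

INV_SQRT2 = 1.0 / np.sqrt(2.0)

#: Column length above which the pyramidal filtering path is used.
DEFAULT_MALLAT_THRESHOLD = 2 ** 11


class WaveletConstructionError(ValueError):
    """Invalid size/depth request for a Haar matrix."""


class ShapeError(ValueError):
    """Operand shapes incompatible with the requested transform."""


def _is_pow2(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@lru_cache(maxsize=None)
def build_haar_matrix(m: int, depth: int) -> np.ndarray:
    """Orthogonal m x m Haar analysis matrix of the given depth.

    Rows are ordered coarsest-first: ``m / 2**depth`` scaling rows, then
    detail rows for level ``depth`` (coarsest) down to level 1 (finest).
    The finest-level detail row k has entries +-sqrt(2)/2 on the adjacent
    column pair (2k-1, 2k).  Built by composing Mallat filtering steps,
    so orthogonality is inherited rather than asserted.
    """
    if not _is_pow2(m) or m < 2:
        raise WaveletConstructionError(f"size {m} is not a power of 2 (>= 2)")
    max_depth = int(np.log2(m))
    if not 1 <= depth <= max_depth:
        raise WaveletConstructionError(
            f"depth {depth} out of range [1, {max_depth}] for size {m}"
        )
    W = np.eye(m)
    size = m
    for _ in range(depth):
        half = size // 2
        step = np.zeros((size, size))
        idx = np.arange(half)
        step[idx, 2 * idx] = INV_SQRT2
        step[idx, 2 * idx + 1] = INV_SQRT2
        step[half + idx, 2 * idx] = INV_SQRT2
        step[half + idx, 2 * idx + 1] = -INV_SQRT2
        W[:size] = step @ W[:size]
        size = half
    W.setflags(write=False)
    return W


def dwt_rows(X: np.ndarray, depth: int) -> np.ndarray:
    """Haar transform along the last axis by Mallat filtering.

    Output layout matches ``X @ build_haar_matrix(n, depth).T``:
    smooth coefficients first, then details coarsest to finest.  Only
    requires the last-axis length to be divisible by ``2**depth`` (the
    explicit matrix needs a full power of two).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[-1]
    if n % (1 << depth):
        raise ShapeError(f"length {n} not divisible by 2**{depth}")
    out = np.empty_like(X)
    cur = X
    width = n
    for _ in range(depth):
        half = width // 2
        even = cur[..., 0::2]
        odd = cur[..., 1::2]
        out[..., half:width] = (even - odd) * INV_SQRT2
        cur = (even + odd) * INV_SQRT2
        width = half
    out[..., :width] = cur
    return out


def column_transform(Ystar: np.ndarray, W: np.ndarray) -> np.ndarray:
    """D = W @ Ystar: Haar-transform the columns of a cumulative matrix."""
    Ystar = np.asarray(Ystar, dtype=float)
    if W.shape[1] != Ystar.shape[0]:
        raise ShapeError(
            f"wavelet matrix size {W.shape[1]} != row count {Ystar.shape[0]}"
        )
    return W @ Ystar


def scale_mixing_transform(
    Ystar: np.ndarray,
    col_depth: int = 2,
    row_depth: int = 2,
    mallat_threshold: int = DEFAULT_MALLAT_THRESHOLD,
) -> np.ndarray:
    """2-D scale-mixing transform ``Z = W_rows @ Ystar @ W_N.T``.

    The row transform always uses the explicit (small) Haar matrix at
    ``row_depth``; the column transform uses the explicit N x N matrix for
    short power-of-two N and Mallat filtering otherwise.  Both transforms
    are orthogonal, so Z has the same Frobenius energy as Ystar.
    """
    Ystar = np.asarray(Ystar, dtype=float)
    if Ystar.ndim != 2:
        raise ShapeError(f"expected a 2-D matrix, got shape {Ystar.shape}")
    rows, n = Ystar.shape
    if n % (1 << col_depth):
        raise ShapeError(f"width {n} not divisible by 2**{col_depth}")
    Wr = build_haar_matrix(rows, row_depth)
    D = Wr @ Ystar
    if _is_pow2(n) and n <= mallat_threshold:
        Wn = build_haar_matrix(n, col_depth)
        return D @ Wn.T
    return dwt_rows(D, col_depth)


def energy(A: np.ndarray) -> float:
    """Squared Frobenius norm (total energy) of a matrix."""
    A = np.asarray(A, dtype=float)
    return float(np.sum(A * A))
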
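"""Half-vectorization of symmetric matrices.

The fixed convention throughout the package is the row-major lower triangle
including the diagonal: for an m x m matrix the order is
(0,0), (1,0), (1,1), (2,0), (2,1), (2,2), ...
This order tag is written into every S/V file so a silent mismatch between
producers and consumers of V is impossible.
"""

from __future__ import annotations

import numpy as np

VECH_ORDER_TAG = "lower-row-major"


def vech_indices(m: int) -> list[tuple[int, int]]:
    """(row, col) pairs of the lower triangle in row-major order."""
    return [(i, j) for i in range(m) for j in range(i + 1)]


def vech(mat: np.ndarray) -> np.ndarray:
    """Stack the lower triangle (incl. diagonal) of a symmetric matrix."""
    mat = np.asarray(mat, dtype=float)
    m = mat.shape[0]
    rows, cols = zip(*vech_indices(m))
    return mat[list(rows), list(cols)]


def unvech(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vech`; returns the full symmetric matrix."""
    v = np.asarray(v, dtype=float)
    p = v.shape[0]
    m = int(round((np.sqrt(8 * p + 1) - 1) / 2))
    if m * (m + 1) // 2 != p:
        raise ValueError(f"length {p} is not a triangular number")
    out = np.zeros((m, m))
    for k, (i, j) in enumerate(vech_indices(m)):
        out[i, j] = v[k]
        out[j, i] = v[k]
    return out


def vech_index_of(i: int, j: int) -> int:
    """Position of element (i, j) (i >= j after swapping) in the vech vector."""
    if i < j:
        i, j = j, i
    return i * (i + 1) // 2 + j
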
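"""Numba kernel: Z2 reduction of the triangle boundary matrix.

Columns (one per triangle, already in filtration order) are bit-packed over
edge-rank rows into uint64 words; the standard left-to-right reduction with
pivot lookup runs in nopython mode.  This is the hot loop of the sliding
window persistent-entropy track.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def reduce_triangle_boundary(tri_edge_ranks: np.ndarray, n_edges: int):
    """Reduce the triangle boundary matrix; return (pivot_rank, pivot_tri).

    ``tri_edge_ranks`` is (n_tri, 3): the filtration ranks of the three
    boundary edges of each triangle, triangles sorted by filtration.
    Returns parallel arrays: for each pivot, the edge rank (birth simplex)
    and the triangle index in the sorted order (death simplex).
    """
    n_tri = tri_edge_ranks.shape[0]
    words = (n_edges + 63) >> 6
    cols = np.zeros((n_tri, words), dtype=np.uint64)
    owner = np.full(n_edges, -1, dtype=np.int64)

    for t in range(n_tri):
        for s in range(3):
            r = tri_edge_ranks[t, s]
            cols[t, r >> 6] ^= np.uint64(1) << np.uint64(r & 63)
        while True:
            # find the highest set bit (the pivot row)
            low = -1
            for wi in range(words - 1, -1, -1):
                w = cols[t, wi]
                if w != np.uint64(0):
                    b = 63
                    while (w >> np.uint64(b)) & np.uint64(1) == np.uint64(0):
                        b -= 1
                    low = (wi << 6) + b
                    break
            if low < 0:
                break
            prev = owner[low]
            if prev < 0:
                owner[low] = t
                break
            for wi in range(words):
                cols[t, wi] ^= cols[prev, wi]

    n_piv = 0
    for r in range(n_edges):
        if owner[r] >= 0:
            n_piv += 1
    pivot_rank = np.empty(n_piv, dtype=np.int64)
    pivot_tri = np.empty(n_piv, dtype=np.int64)
    k = 0
    for r in range(n_edges):
        if owner[r] >= 0:
            pivot_rank[k] = r
            pivot_tri[k] = owner[r]
            k += 1
    return pivot_rank, pivot_tri
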
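"""Persistent entropy of sliding-window point clouds.

Each window of ``N`` consecutive residues is embedded on the unit cylinder
in R^3: residue ``m`` (1-based in the window) with canonical alphabet index
``I`` maps to ``(cos(2*pi*I/20), sin(2*pi*I/20), (m-1)/(N-1))``, so the
angular coordinate encodes identity and the height encodes position.  The
Vietoris-Rips filtration of that cloud is computed under the
ball-intersection convention: two epsilon-balls intersect iff the centre
distance is at most ``2*epsilon``, so a simplex enters the filtration at
half its longest pairwise distance.  The persistent entropy of the
resulting diagram,

    E = -sum_i p_i log2 p_i,   p_i = l_i / sum_j l_j,   l_i = death_i - birth_i,

is the per-residue feature value.

Homology dimensions 0 and 1 are pooled by default: dimension 0 tracks the
merge structure of the window and dimension 1 the loops that the circular
residue embedding creates.  Infinite bars are truncated at the filtration
cap ``K`` (default: half the cloud diameter, i.e. the scale at which the
complex becomes a full simplex); zero-length bars are dropped.

Dimension-0 persistence is computed by Kruskal union-find over the edge
filtration; dimension-1 by reduction of the triangle boundary matrix with
bit-packed columns (numba-accelerated when available, with a pure-Python
fallback).  Dimensions >= 2 fall back to a generic full boundary-matrix
reduction and are supported for completeness, not speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .alphabet import AA_INDEX, AMINO_ACIDS, is_standard
from .errors import DataError
from .seq_io import ProteinRecord

__all__ = [
    "PersistenceDiagram",
    "embed_window",
    "rips_persistence",
    "persistent_entropy",
    "persistent_entropy_track",
]

try:  # pragma: no cover - exercised implicitly
    from ._rips_kernel import reduce_triangle_boundary as _reduce_nb

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class PersistenceDiagram:
    """A persistence diagram: parallel arrays of dimension, birth, death.

    All retained bars have positive length and death <= cap.  ``n_dim0_raw``
    records the number of dimension-0 bars before zero-length bars were
    dropped (always the number of points of the cloud).
    """

    dims: np.ndarray
    births: np.ndarray
    deaths: np.ndarray
    cap: float
    n_dim0_raw: int = 0

    def __len__(self) -> int:
        return len(self.dims)

    @property
    def lengths(self) -> np.ndarray:
        return self.deaths - self.births

    def bars(self) -> list[tuple[int, float, float]]:
        return [
            (int(d), float(b), float(e))
            for d, b, e in zip(self.dims, self.births, self.deaths)
        ]


def embed_window(window: str, n: int | None = None) -> np.ndarray:
    """Embed a residue window as an ordered point cloud on the unit cylinder.

    Point ``m`` (1-based) is ``(cos(2 pi I/20), sin(2 pi I/20), (m-1)/(N-1))``
    with ``I`` the 1-based canonical index of the residue.  All residues must
    be standard; callers substitute nonstandard residues beforehand.
    """
    if n is None:
        n = len(window)
    if len(window) != n:
        raise DataError(f"window length {len(window)} != N={n}")
    if n < 2:
        raise DataError("window embedding needs N >= 2")
    for c in window:
        if not is_standard(c):
            raise DataError(f"nonstandard residue {c!r} in window (substitute first)")
    idx = np.array([AA_INDEX[c] for c in window], dtype=np.float64)
    theta = 2.0 * np.pi * idx / 20.0
    z = np.arange(n, dtype=np.float64) / (n - 1)
    return np.column_stack([np.cos(theta), np.sin(theta), z])


# ---------------------------------------------------------------------------
# Rips persistence
# ---------------------------------------------------------------------------

def _edge_filtration(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Edge list (i, j) with filtration value = half Euclidean distance."""
    n = len(points)
    iu, ju = np.triu_indices(n, 1)
    fil = pdist(points) / 2.0
    return np.column_stack([iu, ju]), fil


def _dim0_bars(n: int, edges: np.ndarray, fil: np.ndarray) -> tuple[list[tuple[float, float]], np.ndarray]:
    """Kruskal union-find: (birth=0, death) per merge + one essential bar.

    Returns the finite dim-0 bars and a boolean mask of 'negative' edges
    (edges that merged two components, i.e. the minimum spanning forest).
    """
    order = np.lexsort((edges[:, 1], edges[:, 0], fil))
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    bars: list[tuple[float, float]] = []
    negative = np.zeros(len(fil), dtype=bool)
    for e in order:
        a, b = find(int(edges[e, 0])), find(int(edges[e, 1]))
        if a != b:
            parent[a] = b
            bars.append((0.0, float(fil[e])))
            negative[e] = True
            if len(bars) == n - 1:
                break
    return bars, negative


def _reduce_py(columns: list[int], n_rows: int) -> dict[int, int]:
    """Pure-Python boundary reduction over Z2; columns are int bitmasks.

    Columns must be in filtration order.  Returns pivot row -> column index.
    Mutates ``columns`` in place to the reduced matrix.
    """
    owner: dict[int, int] = {}
    for t in range(len(columns)):
        col = columns[t]
        while col:
            low = col.bit_length() - 1
            prev = owner.get(low)
            if prev is None:
                owner[low] = t
                break
            col ^= columns[prev]
        columns[t] = col
    return owner


def _dim1_bars(
    points: np.ndarray, edges: np.ndarray, fil: np.ndarray, negative: np.ndarray
) -> list[tuple[float, float]]:
    """Dimension-1 bars by reduction of the triangle boundary matrix.

    Uses the twist/clearing observation: the pivots of the reduced
    triangle-boundary matrix pair a killing triangle with the cycle-creating
    edge that is the bar's birth; edges outside the spanning forest that are
    never paired carry essential classes (death = +inf, truncated later).
    """
    n = len(points)
    if n < 3:
        return []
    # Rank edges by filtration (ties by vertex order) — pivot = max rank.
    edge_order = np.lexsort((edges[:, 1], edges[:, 0], fil))
    rank_of_edge = np.empty(len(fil), dtype=np.int64)
    rank_of_edge[edge_order] = np.arange(len(fil))
    eid = np.full((n, n), -1, dtype=np.int64)
    for k, (i, j) in enumerate(edges):
        eid[i, j] = eid[j, i] = k

    tris = np.array(list(combinations(range(n), 3)), dtype=np.int64)
    e1 = eid[tris[:, 0], tris[:, 1]]
    e2 = eid[tris[:, 0], tris[:, 2]]
    e3 = eid[tris[:, 1], tris[:, 2]]
    tri_fil = np.maximum(np.maximum(fil[e1], fil[e2]), fil[e3])
    tri_order = np.lexsort((tris[:, 2], tris[:, 1], tris[:, 0], tri_fil))

    tri_edge_ranks = np.column_stack(
        [rank_of_edge[e1], rank_of_edge[e2], rank_of_edge[e3]]
    )[tri_order]
    tri_fil_sorted = tri_fil[tri_order]

    if _HAVE_NUMBA:
        pivot_rank, pivot_tri = _reduce_nb(tri_edge_ranks, len(fil))
    else:
        cols = [
            (1 << int(r[0])) | (1 << int(r[1])) | (1 << int(r[2]))
            for r in tri_edge_ranks
        ]
        owner = _reduce_py(cols, len(fil))
        pivot_rank = np.array(list(owner.keys()), dtype=np.int64)
        pivot_tri = np.array(list(owner.values()), dtype=np.int64)

    fil_by_rank = fil[edge_order]
    bars = []
    paired = np.zeros(len(fil), dtype=bool)
    for r, t in zip(pivot_rank, pivot_tri):
        paired[r] = True
        birth = float(fil_by_rank[r])
        death = float(tri_fil_sorted[t])
        bars.append((birth, death))
    # Cycle-creating (positive) edges never paired carry essential classes.
    for k in range(len(fil)):
        if not negative[k] and not paired[rank_of_edge[k]]:
            bars.append((float(fil[k]), math.inf))
    return bars


def _generic_diagram(points: np.ndarray, max_dim: int) -> list[tuple[int, float, float]]:
    """Full boundary-matrix reduction over all simplices up to max_dim+1.

    Quadratic-ish and only intended for small clouds / dimensions >= 2.
    """
    n = len(points)
    dmat = squareform(pdist(points)) / 2.0
    simplices: list[tuple[float, int, tuple[int, ...]]] = []
    for d in range(0, max_dim + 2):
        for verts in combinations(range(n), d + 1):
            f = max((dmat[a][b] for a, b in combinations(verts, 2)), default=0.0)
            simplices.append((f, d, verts))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index_of = {s[2]: i for i, s in enumerate(simplices)}
    columns: list[int] = []
    for f, d, verts in simplices:
        col = 0
        if d > 0:
            for face in combinations(verts, d):
                col ^= 1 << index_of[face]
        columns.append(col)
    owner: dict[int, int] = {}
    reduced: list[int] = []
    for t, col in enumerate(columns):
        while col:
            low = col.bit_length() - 1
            prev = owner.get(low)
            if prev is None:
                owner[low] = t
                break
            col ^= reduced[prev]
        reduced.append(col)
    bars: list[tuple[int, float, float]] = []
    paired = set()
    for low, t in owner.items():
        paired.add(low)
        paired.add(t)
        birth_f, birth_d, _ = simplices[low]
        death_f, _, _ = simplices[t]
        if birth_d <= max_dim:
            bars.append((birth_d, birth_f, death_f))
    for t, (f, d, _) in enumerate(simplices):
        if t not in paired and reduced[t] == 0 and d <= max_dim:
            bars.append((d, f, math.inf))
    return bars


def rips_persistence(
    points: np.ndarray, max_dim: int = 1, cap: float | str = "auto"
) -> PersistenceDiagram:
    """Persistence diagram of the Vietoris-Rips filtration of a point cloud.

    Filtration values follow the ball-intersection convention (a simplex
    enters at half its longest pairwise distance).  ``cap="auto"`` resolves
    to half the cloud diameter, the scale at which the complex is complete;
    classes still alive there are truncated to death ``cap``.  Bars born at
    or after the cap, and zero-length bars, are dropped; the diagram is
    deterministic given its input.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2:
        raise DataError("point cloud must be a 2-D array")
    n = len(points)
    if n == 0:
        raise DataError("empty point cloud")
    if max_dim < 0:
        raise DataError("max_dim must be >= 0")
    if n == 1:
        k = 1.0 if cap == "auto" else float(cap)
        return PersistenceDiagram(
            dims=np.array([0]), births=np.array([0.0]), deaths=np.array([k]),
            cap=k, n_dim0_raw=1,
        )

    edges, fil = _edge_filtration(points)
    k = float(fil.max()) if cap == "auto" else float(cap)
    if k <= 0:
        raise DataError("filtration cap K must be positive")

    raw: list[tuple[int, float, float]] = []
    if max_dim <= 1:
        finite0, negative = _dim0_bars(n, edges, fil)
        raw.extend((0, b, d) for b, d in finite0)
        raw.append((0, 0.0, math.inf))  # the never-dying component
        if max_dim >= 1:
            raw.extend((1, b, d) for b, d in _dim1_bars(points, edges, fil, negative))
    else:
        raw = _generic_diagram(points, max_dim)

    dims, births, deaths = [], [], []
    n_dim0_raw = 0
    for d, b, e in raw:
        if b >= k:
            continue
        e = min(e, k)
        if d == 0:
            n_dim0_raw += 1
        if e > b:
            dims.append(d)
            births.append(b)
            deaths.append(e)
    return PersistenceDiagram(
        dims=np.array(dims, dtype=np.int64),
        births=np.array(births, dtype=np.float64),
        deaths=np.array(deaths, dtype=np.float64),
        cap=k,
        n_dim0_raw=n_dim0_raw,
    )


def persistent_entropy(diagram: PersistenceDiagram, dims: Iterable[int] | None = None) -> float:
    """Shannon entropy (base 2) of the normalised bar lengths of a diagram.

    ``dims`` restricts the bars entering the entropy (default: all).  The
    empty diagram has entropy 0 by convention.
    """
    lengths = diagram.lengths
    if dims is not None:
        keep = np.isin(diagram.dims, list(dims))
        lengths = lengths[keep]
    lengths = lengths[lengths > 0]
    if lengths.size == 0:
        return 0.0
    p = lengths / lengths.sum()
    return float(-(p * np.log2(p)).sum())


def _substitute_nonstandard(window: str) -> str:
    """Replace nonstandard residues by the window's most frequent standard one.

    Ties break toward the lowest canonical index; a window with no standard
    residue at all falls back to alanine.
    """
    if all(is_standard(c) for c in window):
        return window
    counts = {aa: 0 for aa in AMINO_ACIDS}
    for c in window:
        if c in counts:
            counts[c] += 1
    best = max(AMINO_ACIDS, key=lambda aa: (counts[aa], -AA_INDEX[aa]))
    if counts[best] == 0:
        best = "A"
    return "".join(c if is_standard(c) else best for c in window)


def persistent_entropy_track(
    record: ProteinRecord,
    window: int = 33,
    max_dim: int = 1,
    cap: float | str = "auto",
    dims: Iterable[int] | None = None,
) -> np.ndarray:
    """Per-residue persistent entropy over sliding windows of odd size.

    The sequence is padded with ``(window-1)/2`` copies of its terminal
    residues on each end, so every residue is the centre of one window.
    Identical windows are computed once (memoised per call).
    """
    n = window
    L = len(record)
    if n % 2 == 0:
        raise DataError("window size must be odd")
    if n >= L:
        raise DataError(f"window size {n} must be smaller than sequence length {L}")
    half = (n - 1) // 2
    padded = record.sequence[0] * half + record.sequence + record.sequence[-1] * half
    cache: dict[str, float] = {}
    values = np.empty(L, dtype=np.float64)
    for j in range(L):
        win = padded[j : j + n]
        e = cache.get(win)
        if e is None:
            cloud = embed_window(_substitute_nonstandard(win), n)
            e = persistent_entropy(rips_persistence(cloud, max_dim=max_dim, cap=cap), dims=dims)
            cache[win] = e
        values[j] = e
    return values
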
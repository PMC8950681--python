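"""Independent brute-force persistence oracle for small point clouds.

Enumerates every simplex up to the requested dimension plus one, sorts the
whole filtration by (value, dimension, vertex tuple), and performs the
textbook left-to-right boundary-matrix reduction over Z2 with columns kept
as sets of simplex indices.  Written for clarity, not speed; intended for
clouds of at most ~7 points.
"""

from itertools import combinations
from math import dist, inf


def rips_diagram_bruteforce(points, max_dim, cap):
    """Multiset of (dim, birth, death) bars, truncated at ``cap``.

    Filtration value of a simplex is half its longest pairwise vertex
    distance (ball-intersection convention); infinite bars are truncated
    to die at ``cap``, bars born at or after ``cap`` and zero-length bars
    are discarded.
    """
    pts = [tuple(p) for p in points]
    n = len(pts)
    simplices = []
    for d in range(max_dim + 2):
        for verts in combinations(range(n), d + 1):
            value = 0.0
            for a, b in combinations(verts, 2):
                value = max(value, dist(pts[a], pts[b]) / 2.0)
            simplices.append((value, d, verts))
    simplices.sort()
    position = {s[2]: i for i, s in enumerate(simplices)}

    columns = []
    for value, d, verts in simplices:
        faces = set()
        if d > 0:
            for face in combinations(verts, d):
                faces.add(position[face])
        columns.append(faces)

    pivot_owner = {}
    for j in range(len(columns)):
        while columns[j]:
            low = max(columns[j])
            if low not in pivot_owner:
                pivot_owner[low] = j
                break
            columns[j] = columns[j] ^ columns[pivot_owner[low]]

    paired = set()
    bars = []
    for low, j in pivot_owner.items():
        paired.add(low)
        paired.add(j)
        birth_value, birth_dim, _ = simplices[low]
        death_value = simplices[j][0]
        if birth_dim <= max_dim:
            bars.append((birth_dim, birth_value, death_value))
    for j, (value, d, _) in enumerate(simplices):
        if j not in paired and not columns[j] and d <= max_dim:
            bars.append((d, value, inf))

    out = []
    for d, b, e in bars:
        if b >= cap:
            continue
        e = min(e, cap)
        if e > b:
            out.append((d, b, e))
    return out
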
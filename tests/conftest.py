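import numpy as np
import pytest

from ksdesign import (build_ideal_helix, build_ideal_strand,
                      build_toy_complex)
from ksdesign.structure import assign_all_secondary_structure


@pytest.fixture(scope="session")
def ideal_helix():
    st = build_ideal_helix(n_residues=15)
    assign_all_secondary_structure(st)
    return st


@pytest.fixture(scope="session")
def ideal_strand():
    st = build_ideal_strand(n_residues=10)
    assign_all_secondary_structure(st)
    return st


@pytest.fixture(scope="session")
def toy_complex():
    toy = build_toy_complex()
    assign_all_secondary_structure(toy.structure)
    return toy


def brute_force_delaunay_pairs(points: np.ndarray) -> set[tuple[int, int]]:
    """Independent Delaunay-adjacency oracle by direct empty-circumsphere
    checks: points a, b are neighbours iff some tetrahedron (a, b, c, d)
    has a circumsphere containing no other point.  O(n^4), vectorised."""
    from itertools import combinations

    pts = np.asarray(points, dtype=float)
    n = len(pts)
    quads = np.array(list(combinations(range(n), 4)))
    p = pts[quads]  # (m, 4, 3)
    # circumcenter: solve 2(p_i - p_0) . c = |p_i|^2 - |p_0|^2 for i=1..3
    a = 2.0 * (p[:, 1:, :] - p[:, :1, :])  # (m, 3, 3)
    sq = np.einsum("mij,mij->mi", p, p)
    b = sq[:, 1:] - sq[:, :1]
    det = np.linalg.det(a)
    ok = np.abs(det) > 1e-9  # skip (near-)coplanar quadruples
    centers = np.full((len(quads), 3), np.nan)
    centers[ok] = np.linalg.solve(a[ok], b[ok][..., None])[..., 0]
    r2 = np.einsum("mi,mi->m", pts[quads[:, 0]] - centers,
                   pts[quads[:, 0]] - centers)
    # empty-sphere test against all points, tolerant to rounding
    d2 = np.einsum("mni,mni->mn",
                   pts[None, :, :] - centers[:, None, :],
                   pts[None, :, :] - centers[:, None, :])
    inside = d2 < r2[:, None] - 1e-9
    inside[np.arange(len(quads))[:, None], quads] = False
    empty = ok & ~inside.any(axis=1)
    pairs: set[tuple[int, int]] = set()
    for quad in quads[empty]:
        for i in range(4):
            for j in range(i + 1, 4):
                pairs.add((int(quad[i]), int(quad[j])))
    return pairs


@pytest.fixture(scope="session")
def delaunay_oracle():
    return brute_force_delaunay_pairs
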
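"""Independent reference implementations used only to check the package.

Each oracle takes a deliberately different route from the implementation it
validates: exhaustive enumeration, brute-force recursion, or grid search.
"""
from __future__ import annotations

import itertools
import sys
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_mbc() -> dict[tuple[str, str], int]:
    """Min base change per amino-acid pair by scanning all 61×61 codon pairs."""
    coding = [(c, aa) for c, aa in standard_dna_table.forward_table.items()]
    best: dict[tuple[str, str], int] = {}
    for (c1, a1), (c2, a2) in itertools.product(coding, coding):
        h = sum(x != y for x, y in zip(c1, c2))
        key = (a1, a2)
        if key not in best or h < best[key]:
            best[key] = h
    return best


def brute_force_pairing(dist: np.ndarray, cutoff: float):
    """Optimal order-preserving pairing by exhaustive recursion.

    Returns (count, total_separation) of the pairing maximising count and,
    among those, minimising total separation.  Feasible only for small
    matrices (≤ ~30×30).
    """
    na, nb = dist.shape
    sys.setrecursionlimit(10000)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> tuple[int, float]:
        if i >= na or j >= nb:
            return (0, 0.0)
        c1, s1 = best(i + 1, j)
        c2, s2 = best(i, j + 1)
        cand = max((c1, -s1), (c2, -s2))
        if dist[i, j] <= cutoff:
            c3, s3 = best(i + 1, j + 1)
            cand = max(cand, (c3 + 1, -(s3 + dist[i, j])))
        return (cand[0], -cand[1])

    return best(0, 0)


def grid_refine_rmsd(A: np.ndarray, B: np.ndarray, n_grid: int = 8) -> float:
    """Minimum RMSD over proper rotations by Euler-angle grid + simplex refine.

    The optimal translation aligns the centroids, so only the rotation is
    searched.
    """
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)

    def f(euler):
        R = Rotation.from_euler("xyz", euler).as_matrix()
        d = A0 - B0 @ R.T
        return float(np.sqrt((d * d).sum(axis=1).mean()))

    grid = np.linspace(0.0, 2 * np.pi, n_grid, endpoint=False)
    starts = sorted(
        (f((x, y, z)), (x, y, z))
        for x in grid for y in grid for z in grid
    )[:5]
    best = np.inf
    for _, x0 in starts:
        res = minimize(f, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, float(res.fun))
    return best


# rooted 4-leaf shapes: slot-permutation symmetry groups
_BALANCED_GENS = [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]
_CATERPILLAR_GENS = [(1, 0, 2, 3)]


def _close_group(generators):
    group = {(0, 1, 2, 3)}
    frontier = list(group)
    while frontier:
        g = frontier.pop()
        for h in generators:
            composed = tuple(g[h[i]] for i in range(4))
            if composed not in group:
                group.add(composed)
                frontier.append(composed)
    return sorted(group)


def brute_force_varieties(shape: str, labels) -> set[tuple[str, ...]]:
    """Distinct leaf assignments of a shape by explicit orbit canonicalisation."""
    gens = _BALANCED_GENS if shape == "balanced" else _CATERPILLAR_GENS
    group = _close_group(gens)
    canon = set()
    for perm in itertools.permutations(labels):
        orbit = {tuple(perm[g[i]] for i in range(4)) for g in group}
        canon.add(min(orbit))
    return canon
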
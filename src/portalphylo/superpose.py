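"""Sequence-independent pairwise structural alignment.

Two Cα chains are compared without using any sequence information:

1. *Seeding* — every gapless window of one chain is rigidly superposed on
   every gapless window of the other; the window pair with the lowest RMSD
   initialises the residue pairing.
2. *Iterative equivalencing* — alternate (a) a least-squares rigid-body
   superposition (Kabsch) on the current residue pairs and (b) recomputation
   of the maximal order-preserving pairing whose post-superposition Cα–Cα
   separations are all within a distance cutoff.  The loop stops when the
   pair set repeats or an iteration cap is hit.

The size of the final pairing, ``r``, is the raw structural-similarity
measure that feeds the evolutionary-distance schemes: the larger the common
rigid core of two folds, the more recently they diverged.

The order-preserving pairing (no crossings, each residue used once) is the
maximum-cardinality chain over candidate pairs within the cutoff, ties
broken by smaller total Cα separation; it is computed by dynamic programming
with a Fenwick (binary-indexed) prefix-maximum over columns.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import CaChain

DEFAULT_CUTOFF = 3.8  # Å — one Cα–Cα virtual bond length
DEFAULT_WINDOW = 9
DEFAULT_MAX_ITER = 50


class AlignmentError(ValueError):
    pass


class DegenerateGeometryError(AlignmentError):
    pass


@dataclass(frozen=True)
class Superposition:
    """Proper rigid-body transform of B onto A: x_A ≈ R·x_B + t."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class EquivalenceSet:
    """Order-preserving residue pairing between two chains.

    ``pairs`` holds (index_in_A, index_in_B) with both index sequences
    strictly increasing; ``separations`` are post-superposition Cα distances.
    ``r = len(pairs)`` is the structural-similarity count.
    """

    pairs: list[tuple[int, int]]
    separations: np.ndarray
    superposition: Superposition
    n_iterations: int = 0

    @property
    def r(self) -> int:
        return len(self.pairs)

    def __post_init__(self) -> None:
        ia = [p[0] for p in self.pairs]
        ib = [p[1] for p in self.pairs]
        if any(x2 <= x1 for x1, x2 in zip(ia, ia[1:])) or \
           any(x2 <= x1 for x1, x2 in zip(ib, ib[1:])):
            raise AlignmentError("equivalence indices must be strictly increasing")


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares proper rigid transform of paired points B onto A.

    Standard Kabsch algorithm: SVD of the cross-covariance of the centred
    point sets, with the reflection corrected so det(R) = +1.  Raises on
    length mismatch, fewer than 3 points, or (near-)collinear geometry, for
    which the rotation about the line is undetermined.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise AlignmentError(f"paired coordinate sets must both be (n, 3); got {A.shape} vs {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise AlignmentError(f"need ≥ 3 paired points, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    for label, X0 in (("A", A0), ("B", B0)):
        sv = np.linalg.svd(X0, compute_uv=False)
        if sv[0] == 0 or sv[1] / sv[0] < 1e-10:
            raise DegenerateGeometryError(
                f"point set {label} is (near-)collinear; rotation is undetermined"
            )
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ca - R @ cb
    diff = A - (B @ R.T + t)
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def _window_rmsds(A: np.ndarray, B: np.ndarray, w: int) -> np.ndarray:
    """RMSD of the optimal superposition for every gapless window pair.

    Returns an (nA−w+1, nB−w+1) array.  Uses the closed form
    rmsd² = (E0 − 2·Σσᵢ)/w where σᵢ are the singular values of the windowed
    cross-covariance (smallest negated when the optimum is a reflection),
    batched over all window pairs.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    Aw = sliding_window_view(A, (w, 3)).reshape(-1, w, 3)  # (na, w, 3)
    Bw = sliding_window_view(B, (w, 3)).reshape(-1, w, 3)
    Ac = Aw - Aw.mean(axis=1, keepdims=True)
    Bc = Bw - Bw.mean(axis=1, keepdims=True)
    e0 = (Ac**2).sum(axis=(1, 2))[:, None] + (Bc**2).sum(axis=(1, 2))[None, :]
    # cross-covariance for every (i, j): H_ij = Bc_j^T · Ac_i
    H = np.einsum("jwp,iwq->ijpq", Bc, Ac)  # (na, nb, 3, 3)
    S = np.linalg.svd(H, compute_uv=False)
    det = np.linalg.det(H)
    trace = S[..., 0] + S[..., 1] + np.where(det < 0, -S[..., 2], S[..., 2])
    ms = np.maximum(e0 - 2.0 * trace, 0.0) / w
    return np.sqrt(ms)


def seed_alignment(a: CaChain, b: CaChain, window: int = DEFAULT_WINDOW) -> EquivalenceSet:
    """Best gapless window-vs-window superposition as an initial pairing.

    Scans all window offsets in both chains, superposes each pair and keeps
    the seed with the lowest RMSD (ties: smallest offsets).
    """
    if window < 3:
        raise AlignmentError(f"window must be ≥ 3, got {window}")
    if len(a) < window or len(b) < window:
        raise AlignmentError(
            f"chains of length {len(a)}, {len(b)} are shorter than window {window}"
        )
    rmsds = _window_rmsds(a.coords, b.coords, window)
    i, j = np.unravel_index(np.argmin(rmsds), rmsds.shape)
    pairs = [(int(i) + k, int(j) + k) for k in range(window)]
    sup = kabsch_superpose(a.coords[[p[0] for p in pairs]],
                           b.coords[[p[1] for p in pairs]])
    sep = np.linalg.norm(
        a.coords[[p[0] for p in pairs]] - sup.apply(b.coords[[p[1] for p in pairs]]),
        axis=1,
    )
    return EquivalenceSet(pairs=pairs, separations=sep, superposition=sup)


class _MaxFenwick:
    """Prefix-maximum Fenwick tree over column indices, values (score, idx)."""

    def __init__(self, n: int):
        self.n = n
        self.tree = [(-np.inf, -1)] * (n + 1)

    def update(self, i: int, value: tuple[float, int]) -> None:
        i += 1
        while i <= self.n:
            if value > self.tree[i]:
                self.tree[i] = value
            i += i & (-i)

    def query(self, i: int) -> tuple[float, int]:
        """Max over columns [0, i]."""
        i += 1
        best = (-np.inf, -1)
        while i > 0:
            if self.tree[i] > best:
                best = self.tree[i]
            i -= i & (-i)
        return best


def max_order_preserving_pairing(
    dist: np.ndarray, cutoff: float
) -> list[tuple[int, int]]:
    """Maximal no-crossing pairing among cells of ``dist`` that are ≤ cutoff.

    Maximises pair count; ties broken by smaller total separation.  Each row
    and column is used at most once and selected (i, j) are strictly
    increasing in both indices.
    """
    na, nb = dist.shape
    cand_i, cand_j = np.nonzero(dist <= cutoff)
    if cand_i.size == 0:
        return []
    # lexicographic (count, -total_sep) encoded as count*W - sep; sep bounded
    # by n*cutoff so any W above that keeps the orders separated
    W = float(max(na, nb) * max(cutoff, 1.0) * 10.0 + 1.0)
    order = np.lexsort((cand_j, cand_i))
    cand_i, cand_j = cand_i[order], cand_j[order]
    seps = dist[cand_i, cand_j]
    fen = _MaxFenwick(nb)
    score = np.empty(cand_i.size)
    parent = np.full(cand_i.size, -1, dtype=int)
    k = 0
    while k < cand_i.size:
        row = cand_i[k]
        row_end = k
        while row_end < cand_i.size and cand_i[row_end] == row:
            row_end += 1
        # query before inserting this row: predecessors need i' < i
        for m in range(k, row_end):
            j = cand_j[m]
            if j > 0:
                best, bidx = fen.query(int(j) - 1)
            else:
                best, bidx = -np.inf, -1
            base = best if bidx >= 0 else 0.0
            score[m] = base + W - seps[m]
            parent[m] = bidx
        for m in range(k, row_end):
            fen.update(int(cand_j[m]), (float(score[m]), m))
        k = row_end
    end = int(np.argmax(score))
    chain: list[tuple[int, int]] = []
    m = end
    while m >= 0:
        chain.append((int(cand_i[m]), int(cand_j[m])))
        m = parent[m]
    chain.reverse()
    return chain


def iterative_equivalence(
    a: CaChain,
    b: CaChain,
    cutoff: float = DEFAULT_CUTOFF,
    max_iter: int = DEFAULT_MAX_ITER,
    window: int = DEFAULT_WINDOW,
    seed: EquivalenceSet | None = None,
) -> EquivalenceSet:
    """Iteratively refine a structural equivalence between two chains.

    Starting from ``seed`` (or the best window seed), alternately superpose
    on the current pairs and recompute the maximal order-preserving pairing
    with all separations ≤ ``cutoff``.  Stops on pair-set repetition (cycle
    detection over the last three sets) or after ``max_iter`` rounds.
    """
    if cutoff <= 0:
        raise AlignmentError(f"cutoff must be positive, got {cutoff}")
    current = seed if seed is not None else seed_alignment(a, b, window=window)
    ca_all, cb_all = a.coords, b.coords
    history: list[frozenset[tuple[int, int]]] = [frozenset(current.pairs)]
    pairs = current.pairs
    sup = current.superposition
    sep = current.separations
    for it in range(1, max_iter + 1):
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        sup = kabsch_superpose(ca_all[ia], cb_all[ib])
        moved = sup.apply(cb_all)
        dist = np.linalg.norm(ca_all[:, None, :] - moved[None, :, :], axis=2)
        pairs = max_order_preserving_pairing(dist, cutoff)
        if len(pairs) < 3:
            raise AlignmentError(
                f"no usable pairing survives cutoff {cutoff} Å "
                f"({len(pairs)} pair(s) left)"
            )
        # separations under the superposition the pairing was computed from,
        # so every returned separation respects the cutoff by construction
        sep = dist[[p[0] for p in pairs], [p[1] for p in pairs]]
        key = frozenset(pairs)
        if key in history[-3:]:
            break
        history.append(key)
    return EquivalenceSet(pairs=list(pairs), separations=sep,
                          superposition=sup, n_iterations=it)
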
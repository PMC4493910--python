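"""Exhaustive rooted 4-taxon tree fitting by constrained linear least squares.

Given evolutionary distances between four structures (derived from the count
``r`` of structurally equivalenced residues via either the subtractive
``P − r`` or the ratio ``100·P/r`` scheme), every distinct rooted 4-taxon
topology is fitted and ranked.

There are two rooted binary shapes on four leaves:

* **balanced** ``((L1,L2),(L3,L4))`` — two cherries off the root.  The
  shape's symmetry (swapping within each cherry and swapping the cherries)
  leaves 3 distinct leaf arrangements.
* **caterpillar** ``(((L1,L2),L3),L4)`` — symmetry only in the basal cherry,
  leaving 12 distinct arrangements.

For each of the 15 varieties the six branch lengths ``a–f`` and a
root-to-leaf distance ``g`` are estimated by linear least squares over

1. six *pairwise* equations — each observed distance equals the sum of the
   branches on the leaf-to-leaf path, and
2. four *root* equations — each root-to-leaf path sum equals ``g``
   (molecular-clock / ultrametric constraint: equal rate of structural
   divergence along every lineage).

With the root rows that is 10 equations in 7 unknowns.  The fit is ranked by
an R factor — the relative absolute residual Σ|obs − calc| / Σ obs over the
six pairwise distances — with ``R_all`` computed from the 10-equation
(clock-constrained) fit and ``R_pair`` from the 6-equation fit that drops
the clock.  Trees with negative fitted branch lengths are flagged as
physically infeasible; ranking puts feasible trees first, then ascending
``R_all``.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .superpose import EquivalenceSet

BRANCH_NAMES = ("a", "b", "c", "d", "e", "f")
PARAM_NAMES = BRANCH_NAMES + ("g",)

#: default scheme constant — roughly the residue count of a functioning portal
DEFAULT_P = 600.0

FEASIBILITY_TOL = 1e-9

BALANCED = "balanced"
CATERPILLAR = "caterpillar"

# Branch layout by leaf slot (0-based slot indices into branch names a..f):
#   balanced  ((L1,L2),(L3,L4)): a=L1, b=L2, c=cherry1→root, d=L3, e=L4,
#                                f=cherry2→root
#   caterpillar (((L1,L2),L3),L4): a=L1, b=L2, c=cherry→inner, d=L3,
#                                  e=inner→root, f=L4
_PAIR_PATHS = {
    BALANCED: {
        (0, 1): (0, 1),
        (0, 2): (0, 2, 5, 3),
        (0, 3): (0, 2, 5, 4),
        (1, 2): (1, 2, 5, 3),
        (1, 3): (1, 2, 5, 4),
        (2, 3): (3, 4),
    },
    CATERPILLAR: {
        (0, 1): (0, 1),
        (0, 2): (0, 2, 3),
        (0, 3): (0, 2, 4, 5),
        (1, 2): (1, 2, 3),
        (1, 3): (1, 2, 4, 5),
        (2, 3): (3, 4, 5),
    },
}
_ROOT_PATHS = {
    BALANCED: {0: (0, 2), 1: (1, 2), 2: (3, 5), 3: (4, 5)},
    CATERPILLAR: {0: (0, 2, 4), 1: (1, 2, 4), 2: (3, 4), 3: (5,)},
}


class TreeInferenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def evolutionary_distance(P: float, r: int, scheme: str) -> float:
    """Evolutionary distance from the equivalenced-residue count ``r``.

    ``subtractive`` gives ``P − r``; ``ratio`` gives ``100·P/r``.  ``P`` is a
    constant approximating the residue count of the ancestral (functioning)
    protein; the ratio scheme has a floor of 100 at r = P.
    """
    if P <= 0:
        raise TreeInferenceError(f"P must be positive, got {P}")
    if scheme == "subtractive":
        if r > P:
            raise TreeInferenceError(
                f"r = {r} exceeds P = {P}: subtractive distance would be negative; "
                "increase P or use the ratio scheme"
            )
        return float(P - r)
    if scheme == "ratio":
        if r <= 0:
            raise TreeInferenceError("ratio scheme requires r > 0")
        return float(100.0 * P / r)
    raise TreeInferenceError(f"unknown distance scheme {scheme!r}")


@dataclass
class DistanceMatrix:
    """Labeled symmetric evolutionary distances between taxa."""

    labels: list[str]
    d: np.ndarray
    scheme: str = "user"
    P: float = DEFAULT_P

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise TreeInferenceError("taxon labels must be unique")
        if self.d.shape != (n, n):
            raise TreeInferenceError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise TreeInferenceError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise TreeInferenceError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise TreeInferenceError("distances must be non-negative")

    def get(self, t1: str, t2: str) -> float:
        return float(self.d[self.labels.index(t1), self.labels.index(t2)])

    # -- text formats -------------------------------------------------------
    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab.ljust(10) + " ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_phylip(cls, path: str | Path, scheme: str = "user",
                    P: float = DEFAULT_P) -> "DistanceMatrix":
        """Read a PHYLIP square or lower-triangle distance matrix."""
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        n = int(lines[0].split()[0])
        labels, rows = [], []
        for ln in lines[1: n + 1]:
            parts = ln.split()
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
        d = np.zeros((n, n))
        for i, row in enumerate(rows):
            if len(row) == n:            # square
                d[i, :] = row
            elif len(row) == i:          # strict lower triangle
                d[i, :i] = row
            else:
                raise TreeInferenceError(
                    f"row {labels[i]!r} has {len(row)} values; expected {n} or {i}"
                )
        d = np.where(d != 0, d, d.T)
        return cls(labels=labels, d=d, scheme=scheme, P=P)


def distance_matrix_from_alignments(
    equivs: dict[frozenset, "EquivalenceSet | int"],
    P: float = DEFAULT_P,
    scheme: str = "subtractive",
) -> DistanceMatrix:
    """Distance matrix from pairwise equivalence results.

    ``equivs`` maps unordered label pairs to either an
    :class:`~portalphylo.superpose.EquivalenceSet` or directly to an integer
    ``r``.  All 6 pairs of the 4 taxa must be present.
    """
    labels = sorted({lab for pair in equivs for lab in pair})
    if len(labels) != 4:
        raise TreeInferenceError(f"expected 4 taxa, found {len(labels)}: {labels}")
    d = np.zeros((4, 4))
    for t1, t2 in itertools.combinations(labels, 2):
        key = frozenset((t1, t2))
        if key not in equivs:
            raise TreeInferenceError(f"missing pair {t1}/{t2}")
        val = equivs[key]
        r = val if isinstance(val, int) else val.r
        i, j = labels.index(t1), labels.index(t2)
        d[i, j] = d[j, i] = evolutionary_distance(P, r, scheme)
    return DistanceMatrix(labels=labels, d=d, scheme=scheme, P=P)


# ---------------------------------------------------------------------------
# topology enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RootedTopology:
    """One leaf-labeled rooted 4-taxon tree variety.

    ``leaves`` assigns taxa to the shape's leaf slots (canonical form under
    the shape's symmetry group); branches ``a–f`` are tied to slots as
    documented in the module header.
    """

    shape: str
    leaves: tuple[str, str, str, str]
    variety_id: str

    def describe(self) -> str:
        l1, l2, l3, l4 = self.leaves
        if self.shape == BALANCED:
            return f"(({l1},{l2}),({l3},{l4}))"
        return f"((({l1},{l2}),{l3}),{l4})"

    def pair_path(self, slot_i: int, slot_j: int) -> tuple[int, ...]:
        key = (min(slot_i, slot_j), max(slot_i, slot_j))
        return _PAIR_PATHS[self.shape][key]

    def root_path(self, slot: int) -> tuple[int, ...]:
        return _ROOT_PATHS[self.shape][slot]


def canonical_leaves(shape: str, leaves: tuple[str, str, str, str]) -> tuple[str, ...]:
    """Canonical slot assignment under the shape's symmetry group.

    Balanced: each cherry sorted internally, cherries sorted by first leaf.
    Caterpillar: basal cherry sorted; slots 3 and 4 are asymmetric.
    """
    l1, l2, l3, l4 = leaves
    if shape == BALANCED:
        c1, c2 = tuple(sorted((l1, l2))), tuple(sorted((l3, l4)))
        if c2 < c1:
            c1, c2 = c2, c1
        return c1 + c2
    if shape == CATERPILLAR:
        return tuple(sorted((l1, l2))) + (l3, l4)
    raise TreeInferenceError(f"unknown shape {shape!r}")


def enumerate_varieties(labels) -> list[RootedTopology]:
    """All distinct rooted 4-taxon tree varieties: 3 balanced + 12 caterpillar.

    Deterministic order: balanced varieties first (``1.1``–``1.3``), then
    caterpillar (``2.1``–``2.12``), each lexicographic in the canonical leaf
    assignment.  The variety id is a stable name; reports should always show
    the full leaf arrangement alongside it.
    """
    labels = tuple(labels)
    if len(labels) != 4 or len(set(labels)) != 4:
        raise TreeInferenceError(f"need exactly 4 distinct taxon labels, got {labels!r}")
    out: list[RootedTopology] = []
    for shape, prefix in ((BALANCED, "1"), (CATERPILLAR, "2")):
        seen = sorted({
            canonical_leaves(shape, perm)
            for perm in itertools.permutations(sorted(labels))
        })
        for k, leaves in enumerate(seen, start=1):
            out.append(RootedTopology(shape=shape, leaves=leaves,
                                      variety_id=f"{prefix}.{k}"))
    return out


# ---------------------------------------------------------------------------
# design system and least-squares fit
# ---------------------------------------------------------------------------

@dataclass
class DesignSystem:
    """Linear observational equations A·x = y for one topology.

    Columns are (a, b, c, d, e, f, g).  Pairwise rows carry branch-path
    indicators with y = observed distance; root rows carry root-to-leaf
    indicators with −1 in the g column and y = 0.
    """

    A: np.ndarray
    y: np.ndarray
    row_kind: list[str]
    topology: RootedTopology
    pair_order: list[tuple[str, str]]


def build_design(topology: RootedTopology, D: DistanceMatrix,
                 include_root_rows: bool = True) -> DesignSystem:
    """Observational equations for a topology against observed distances.

    Row order: the six unordered pairs in lexicographic label order, then
    (if requested) one root row per leaf in alphabetical order.
    """
    missing = set(topology.leaves) - set(D.labels)
    if missing:
        raise TreeInferenceError(f"taxa {sorted(missing)} absent from distance matrix")
    slot_of = {lab: i for i, lab in enumerate(topology.leaves)}
    taxa = sorted(topology.leaves)
    rows, y, kinds, pair_order = [], [], [], []
    for t1, t2 in itertools.combinations(taxa, 2):
        row = np.zeros(7)
        for br in topology.pair_path(slot_of[t1], slot_of[t2]):
            row[br] = 1.0
        rows.append(row)
        y.append(D.get(t1, t2))
        kinds.append("pairwise")
        pair_order.append((t1, t2))
    if include_root_rows:
        for t in taxa:
            row = np.zeros(7)
            for br in topology.root_path(slot_of[t]):
                row[br] = 1.0
            row[6] = -1.0
            rows.append(row)
            y.append(0.0)
            kinds.append("root")
    return DesignSystem(A=np.array(rows), y=np.array(y), row_kind=kinds,
                        topology=topology, pair_order=pair_order)


@dataclass
class FitSolution:
    params: np.ndarray          # (7,) a..f, g
    rank: int
    rank_deficient: bool
    residuals: np.ndarray


def solve_fit(system: DesignSystem) -> FitSolution:
    """Least-squares solution of the observational equations.

    Uses the minimum-norm solution when the system is rank-deficient (the
    pairwise-only system leaves the two root-adjacent branches identifiable
    only through their sum, and g unconstrained); deficiency is flagged,
    never silent.
    """
    x, _, rank, _ = np.linalg.lstsq(system.A, system.y, rcond=None)
    resid = system.y - system.A @ x
    return FitSolution(params=x, rank=int(rank),
                       rank_deficient=rank < system.A.shape[1],
                       residuals=resid)


def r_factor(observed_pairwise, calculated_pairwise) -> float:
    """Relative absolute residual Σ|obs − calc| / Σ obs over pairwise distances.

    The crystallographic-style R factor used to rank tree varieties; kept as
    a single function so an alternative residual form is a one-line swap.
    """
    obs = np.asarray(observed_pairwise, dtype=float)
    calc = np.asarray(calculated_pairwise, dtype=float)
    if obs.shape != calc.shape:
        raise TreeInferenceError("observed/calculated length mismatch")
    denom = obs.sum()
    if denom <= 0:
        raise TreeInferenceError("R factor undefined: non-positive Σ of observed distances")
    return float(np.abs(obs - calc).sum() / denom)


@dataclass
class TreeFit:
    """Fit of one tree variety to the observed distances.

    ``params`` comes from the 10-equation (clock-constrained) fit; ``r_all``
    is its pairwise R factor, ``r_pair`` the R factor of the unconstrained
    6-equation fit.  ``feasible`` means no negative branch length (within
    tolerance) in the constrained fit; negative branches are reported as
    fitted, never clamped.
    """

    topology: RootedTopology
    params: dict[str, float]
    params_pair: dict[str, float]
    fitted_pairwise: np.ndarray
    observed_pairwise: np.ndarray
    pair_order: list[tuple[str, str]]
    r_all: float
    r_pair: float
    feasible: bool
    pair_rank_deficient: bool

    @property
    def variety_id(self) -> str:
        return self.topology.variety_id

    @property
    def branch_lengths(self) -> np.ndarray:
        return np.array([self.params[b] for b in BRANCH_NAMES])


def fit_tree(topology: RootedTopology, D: DistanceMatrix) -> TreeFit:
    """Fit one variety in both modes (with and without the clock constraint)."""
    sys_all = build_design(topology, D, include_root_rows=True)
    sys_pair = build_design(topology, D, include_root_rows=False)
    sol_all = solve_fit(sys_all)
    sol_pair = solve_fit(sys_pair)
    A_pair = sys_pair.A
    obs = sys_pair.y
    fitted_all = A_pair @ sol_all.params
    fitted_pair = A_pair @ sol_pair.params
    branches = sol_all.params[:6]
    return TreeFit(
        topology=topology,
        params=dict(zip(PARAM_NAMES, sol_all.params)),
        params_pair=dict(zip(PARAM_NAMES, sol_pair.params)),
        fitted_pairwise=fitted_all,
        observed_pairwise=obs,
        pair_order=sys_pair.pair_order,
        r_all=r_factor(obs, fitted_all),
        r_pair=r_factor(obs, fitted_pair),
        feasible=bool(branches.min() >= -FEASIBILITY_TOL),
        pair_rank_deficient=sol_pair.rank_deficient,
    )


def rank_trees(D: DistanceMatrix) -> list[TreeFit]:
    """Fit all 15 varieties and rank: feasible first, then ascending R_all.

    Ties resolve on variety id, so the ordering is fully deterministic.
    """
    if len(D.labels) != 4:
        raise TreeInferenceError(f"tree ranking requires 4 taxa, got {len(D.labels)}")
    fits = [fit_tree(t, D) for t in enumerate_varieties(D.labels)]
    # R_all is a relative quantity of order 1; rounding to 1e-12 keeps exact
    # symmetry ties from being broken by floating-point noise, so tied
    # varieties always resolve by id
    fits.sort(key=lambda f: (not f.feasible, round(f.r_all, 12),
                             (int(f.variety_id.split(".")[0]),
                              int(f.variety_id.split(".")[1]))))
    return fits


# ---------------------------------------------------------------------------
# Newick output
# ---------------------------------------------------------------------------

def to_newick(fit: TreeFit) -> str:
    """Rooted Newick string with the fitted branch lengths.

    Infeasible fits (some negative branch) are still emitted but carry a
    ``[&infeasible]`` comment flag after the final semicolon-free tree.
    """
    p = fit.params
    l1, l2, l3, l4 = fit.topology.leaves
    if fit.topology.shape == BALANCED:
        s = (f"(({l1}:{p['a']:.10g},{l2}:{p['b']:.10g}):{p['c']:.10g},"
             f"({l3}:{p['d']:.10g},{l4}:{p['e']:.10g}):{p['f']:.10g});")
    else:
        s = (f"((({l1}:{p['a']:.10g},{l2}:{p['b']:.10g}):{p['c']:.10g},"
             f"{l3}:{p['d']:.10g}):{p['e']:.10g},{l4}:{p['f']:.10g});")
    if not fit.feasible:
        s = "[&infeasible]" + s
    return s


def ranking_table(fits: list[TreeFit]):
    """Ranking report as a pandas DataFrame (one row per variety)."""
    import pandas as pd

    rows = []
    for rank, f in enumerate(fits, start=1):
        row = {
            "rank": rank,
            "variety_id": f.variety_id,
            "arrangement": f.topology.describe(),
            **{k: f.params[k] for k in PARAM_NAMES},
            "r_all": f.r_all,
            "r_pair": f.r_pair,
            "feasible": f.feasible,
        }
        rows.append(row)
    return pd.DataFrame(rows)
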
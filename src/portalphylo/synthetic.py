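"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, all deterministic under a fixed seed:

* ``distances_from_tree`` — additive (optionally ultrametric) pairwise
  distances from a known rooted 4-taxon tree, with optional Gaussian noise,
  for exercising the tree-fitting and ranking machinery.
* ``ca_family`` — a family of Cα chains sharing a perturbed common core
  (a self-avoiding random walk with 3.8 Å steps) embedded in unrelated
  random-walk flanks, with the true core residue correspondence recorded,
  for exercising superposition and equivalencing.
* ``sequences_with_decay`` — residue identities whose conservation decays
  with the true structural separation of core positions, for exercising the
  identity / minimum-base-change statistics.

These emulate the statistical structure the analysis assumes (a conserved
rigid core, clock-like divergence), not realistic protein folds or
evolutionary sequence models.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .structures import CaChain, Residue
from .trees import (
    BALANCED,
    BRANCH_NAMES,
    CATERPILLAR,
    DistanceMatrix,
    RootedTopology,
    TreeInferenceError,
    canonical_leaves,
)

STEP_LENGTH = 3.8          # Å, Cα virtual bond
SELF_AVOID_RADIUS = 3.0    # Å, minimum distance to previously placed Cα
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


class SyntheticDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tree distances
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTreeSpec:
    """A known rooted 4-taxon tree plus a noise level for its distances.

    ``branches`` maps the six branch names ``a``–``f`` (layout as in
    :mod:`portalphylo.trees`) to positive lengths.  ``noise_sigma`` is a
    fraction of the mean pairwise distance.  If ``ultrametric`` the
    root-to-leaf sums must agree (validated at construction).
    """

    shape: str
    leaves: tuple[str, str, str, str]
    branches: dict[str, float]
    ultrametric: bool = True
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.branches) != set(BRANCH_NAMES):
            raise SyntheticDataError(f"branches must name exactly {BRANCH_NAMES}")
        if any(v <= 0 for v in self.branches.values()):
            raise SyntheticDataError("all branch lengths must be positive")
        if self.noise_sigma < 0:
            raise SyntheticDataError("noise_sigma must be ≥ 0")
        self.leaves = tuple(self.leaves)
        if len(set(self.leaves)) != 4:
            raise SyntheticDataError("need 4 distinct leaf labels")
        if self.ultrametric:
            sums = self.root_to_leaf_sums()
            if max(sums) - min(sums) > 1e-9:
                raise SyntheticDataError(
                    f"ultrametric spec has unequal root-to-leaf sums: {sums}"
                )

    @property
    def topology(self) -> RootedTopology:
        return RootedTopology(
            shape=self.shape,
            leaves=canonical_leaves(self.shape, self.leaves),
            variety_id="truth",
        )

    def _slot_branches(self) -> np.ndarray:
        return np.array([self.branches[b] for b in BRANCH_NAMES])

    def root_to_leaf_sums(self) -> list[float]:
        b = self._slot_branches()
        topo = RootedTopology(self.shape, self.leaves, "truth")
        return [float(sum(b[i] for i in topo.root_path(s))) for s in range(4)]

    def pairwise_distance(self, t1: str, t2: str) -> float:
        b = self._slot_branches()
        topo = RootedTopology(self.shape, self.leaves, "truth")
        s1, s2 = self.leaves.index(t1), self.leaves.index(t2)
        return float(sum(b[i] for i in topo.pair_path(s1, s2)))


def ultrametric_branches(shape: str, heights: tuple[float, float, float]) -> dict[str, float]:
    """Branch lengths for a clock-like tree from node heights.

    ``heights`` = (h1, h2, g): for the balanced shape h1/h2 are the two
    cherry heights; for the caterpillar h1 < h2 are the two internal-node
    heights.  ``g`` is the root height (root-to-leaf distance).
    """
    h1, h2, g = heights
    if shape == BALANCED:
        if not (0 < h1 < g and 0 < h2 < g):
            raise SyntheticDataError("need 0 < h1, h2 < g")
        return dict(zip(BRANCH_NAMES, (h1, h1, g - h1, h2, h2, g - h2)))
    if shape == CATERPILLAR:
        if not (0 < h1 < h2 < g):
            raise SyntheticDataError("need 0 < h1 < h2 < g")
        return dict(zip(BRANCH_NAMES, (h1, h1, h2 - h1, h2, g - h2, g)))
    raise SyntheticDataError(f"unknown shape {shape!r}")


def random_tree_spec(rng: np.random.Generator, labels=("A", "B", "C", "D"),
                     shape: str | None = None, noise_sigma: float = 0.0,
                     scale: float = 100.0) -> SyntheticTreeSpec:
    """Random ultrametric 4-taxon tree with a random leaf arrangement.

    Heights are drawn so the distances land at magnitudes comparable to the
    evolutionary-distance schemes (order ``scale``).
    """
    if shape is None:
        shape = rng.choice([BALANCED, CATERPILLAR])
    g = scale * rng.uniform(1.0, 2.0)
    if shape == BALANCED:
        h1, h2 = rng.uniform(0.15, 0.85, size=2) * g
        heights = (float(h1), float(h2), float(g))
    else:
        u = np.sort(rng.uniform(0.15, 0.85, size=2)) * g
        heights = (float(u[0]), float(u[1]), float(g))
    leaves = tuple(rng.permutation(list(labels)))
    return SyntheticTreeSpec(
        shape=shape, leaves=leaves,
        branches=ultrametric_branches(shape, heights),
        ultrametric=True, noise_sigma=noise_sigma,
        seed=int(rng.integers(2**31 - 1)),
    )


@dataclass
class TreeTruth:
    """Ground-truth record accompanying a generated distance matrix."""

    spec: SyntheticTreeSpec

    @property
    def canonical_leaves(self) -> tuple[str, ...]:
        return canonical_leaves(self.spec.shape, self.spec.leaves)

    @property
    def shape(self) -> str:
        return self.spec.shape

    def matches(self, topology: RootedTopology) -> bool:
        """Is this topology the generating variety (up to shape symmetry)?"""
        return (topology.shape == self.spec.shape
                and topology.leaves == self.canonical_leaves)


def distances_from_tree(spec: SyntheticTreeSpec) -> tuple[DistanceMatrix, TreeTruth]:
    """Pairwise path-sum distances from a known tree, with optional noise.

    Noise is i.i.d. Gaussian per pair with σ = ``noise_sigma`` × mean
    distance; draws producing non-positive distances are resampled.
    """
    labels = sorted(spec.leaves)
    d = np.zeros((4, 4))
    for t1, t2 in itertools.combinations(labels, 2):
        i, j = labels.index(t1), labels.index(t2)
        d[i, j] = d[j, i] = spec.pairwise_distance(t1, t2)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = spec.noise_sigma * d[np.triu_indices(4, 1)].mean()
        for i, j in zip(*np.triu_indices(4, 1)):
            val = -1.0
            while val <= 0:
                val = d[i, j] + rng.normal(0.0, sigma)
            d[i, j] = d[j, i] = val
    D = DistanceMatrix(labels=labels, d=d, scheme="user")
    return D, TreeTruth(spec=spec)


# ---------------------------------------------------------------------------
# Cα structure families
# ---------------------------------------------------------------------------

@dataclass
class SyntheticFamilySpec:
    """Family of Cα chains sharing a conserved core.

    ``core_noise`` is a per-taxon Gaussian coordinate perturbation (Å) of the
    shared core; the RMS Cα separation between the cores of taxa s and t is
    then ≈ sqrt(3·(σ_s² + σ_t²)) before superposition error.  Flank lengths
    are (N-terminal, C-terminal) per taxon.  ``identity_lambda`` (Å) sets the
    decay scale of core sequence identity with structural separation.
    """

    labels: tuple[str, ...] = ("A", "B", "C", "D")
    core_length: int = 60
    flank_lengths: dict[str, tuple[int, int]] = field(default_factory=dict)
    core_noise: dict[str, float] = field(default_factory=dict)
    identity_lambda: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_length < 10:
            raise SyntheticDataError("core_length must be ≥ 10")
        self.labels = tuple(self.labels)
        for t in self.labels:
            self.flank_lengths.setdefault(t, (20, 20))
            self.core_noise.setdefault(t, 0.3)
        for t, (nf, cf) in self.flank_lengths.items():
            if nf < 0 or cf < 0:
                raise SyntheticDataError(f"negative flank length for {t}")
        for t, s in self.core_noise.items():
            if s < 0:
                raise SyntheticDataError(f"negative core noise for {t}")


def _self_avoiding_walk(rng: np.random.Generator, n: int,
                        start: np.ndarray | None = None,
                        avoid: np.ndarray | None = None,
                        max_restarts: int = 20) -> np.ndarray:
    """Random walk with fixed 3.8 Å steps avoiding previously placed points."""
    base = [] if avoid is None else [np.asarray(avoid, float).reshape(-1, 3)]
    for _ in range(max_restarts):
        pts = [np.zeros(3) if start is None else np.asarray(start, float)]
        ok = True
        steps_needed = n if start is not None else n - 1
        for _ in range(steps_needed):
            placed = False
            for _ in range(100):
                v = rng.normal(size=3)
                v *= STEP_LENGTH / np.linalg.norm(v)
                cand = pts[-1] + v
                prior_list = base + ([np.asarray(pts[:-1])] if len(pts) > 1 else [])
                if prior_list:
                    prior = np.vstack(prior_list)
                    if np.min(np.linalg.norm(prior - cand, axis=1)) < SELF_AVOID_RADIUS:
                        continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            out = np.array(pts)
            return out if start is None else out[1:]
    raise SyntheticDataError(
        f"self-avoiding walk of length {n} failed after {max_restarts} restarts"
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


@dataclass
class FamilyTruth:
    """Chains plus the ground-truth core correspondence of a synthetic family."""

    spec: SyntheticFamilySpec
    chains: dict[str, CaChain]
    core_start: dict[str, int]           # 0-based index of first core residue
    perturbed_cores: dict[str, np.ndarray]   # cores in the shared frame

    def core_pairs(self, t1: str, t2: str) -> list[tuple[int, int]]:
        s1, s2 = self.core_start[t1], self.core_start[t2]
        return [(s1 + k, s2 + k) for k in range(self.spec.core_length)]

    def core_separations(self, t1: str, t2: str) -> np.ndarray:
        """True per-position Cα separation of the two cores (shared frame)."""
        return np.linalg.norm(
            self.perturbed_cores[t1] - self.perturbed_cores[t2], axis=1
        )


def ca_family(spec: SyntheticFamilySpec) -> FamilyTruth:
    """Generate a family of Cα chains with a shared, per-taxon-perturbed core.

    One core trace is drawn once; each taxon receives an independently
    perturbed copy flanked by unrelated self-avoiding walks, then a random
    rigid placement.  Sequences follow :func:`sequences_with_decay`.
    """
    rng = np.random.default_rng(spec.seed)
    core = _self_avoiding_walk(rng, spec.core_length)
    chains: dict[str, CaChain] = {}
    core_start: dict[str, int] = {}
    perturbed: dict[str, np.ndarray] = {}
    for t in spec.labels:
        sigma = spec.core_noise[t]
        pcore = core + rng.normal(0.0, sigma, size=core.shape) if sigma > 0 else core.copy()
        nf, cf = spec.flank_lengths[t]
        parts = []
        if nf > 0:
            nfl = _self_avoiding_walk(rng, nf, start=pcore[0], avoid=pcore)
            parts.append(nfl[::-1])
        parts.append(pcore)
        if cf > 0:
            prior = np.vstack(parts)
            cfl = _self_avoiding_walk(rng, cf, start=pcore[-1], avoid=prior)
            parts.append(cfl)
        coords = np.vstack(parts)
        R = _random_rotation(rng)
        tvec = rng.uniform(-50.0, 50.0, size=3)
        coords = coords @ R.T + tvec
        core_start[t] = nf
        perturbed[t] = pcore
        chains[t] = CaChain(
            [Residue(chain_label=t, seq_position=i + 1, aa="A",
                     ca_xyz=tuple(coords[i]))
             for i in range(len(coords))],
            source_id=f"synthetic:{t}:seed{spec.seed}",
        )
    truth = FamilyTruth(spec=spec, chains=chains, core_start=core_start,
                        perturbed_cores=perturbed)
    sequences_with_decay(truth, rng)
    return truth


def sequences_with_decay(truth: FamilyTruth,
                         rng: np.random.Generator | None = None) -> dict[str, str]:
    """Assign residue identities whose core conservation decays with separation.

    The first taxon gets a uniform random sequence.  Every other taxon copies
    the reference residue at core position k with probability
    ``exp(−sep_k / λ)``, where ``sep_k`` is the true structural separation
    from the reference core at that position; otherwise (and on all flanks)
    residues are uniform over the 20 amino acids.  Chains are updated in
    place; the sequences are returned.
    """
    spec = truth.spec
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    lam = spec.identity_lambda
    ref = spec.labels[0]
    seqs: dict[str, str] = {}
    ref_core_aa = [ _AA20[i] for i in rng.integers(0, 20, size=spec.core_length) ]
    for t in spec.labels:
        chain = truth.chains[t]
        n = len(chain)
        aa = [_AA20[i] for i in rng.integers(0, 20, size=n)]
        s = truth.core_start[t]
        if t == ref:
            aa[s: s + spec.core_length] = ref_core_aa
        else:
            seps = truth.core_separations(ref, t)
            p = np.exp(-seps / lam) if lam > 0 else np.zeros_like(seps)
            keep = rng.uniform(size=spec.core_length) < p
            for k in range(spec.core_length):
                if keep[k]:
                    aa[s + k] = ref_core_aa[k]
        truth.chains[t] = CaChain(
            [Residue(chain_label=r.chain_label, seq_position=r.seq_position,
                     aa=aa[i], ca_xyz=r.ca_xyz, icode=r.icode)
             for i, r in enumerate(chain.residues)],
            source_id=chain.source_id,
        )
        seqs[t] = "".join(aa)
    return seqs
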
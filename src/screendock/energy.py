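"""Pose scoring: grid-based intermolecular energy plus a simple internal term.

The intermolecular energy is the AutoDock-style grid score

    sum_i  M_type(i)(x_i) + q_i * M_e(x_i) + |q_i| * M_d(x_i)

with each map evaluated by trilinear interpolation; an atom outside the
grid box contributes a single fixed out-of-grid penalty instead.  The
internal (intramolecular) term is a deliberately simple 12-6 Lennard-Jones
plus Coulomb with distance-dependent dielectric eps_r = 4r, summed over
"eligible" nonbonded pairs: atoms at least three bonds apart that sit in
different rigid groups, so a rigid ligand has an internal energy of exactly
zero and the term only shapes the torsional search.

Bonds are inferred from the input geometry by a covalent distance cutoff
(plus the declared rotatable bonds), the standard approach for formats that
carry no explicit bond table.

One "energy evaluation" — the unit of the GA's ``ga_num_evals`` budget — is
one full-pose score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from . import _kernels
from ._kernels import COULOMB_K, OUT_OF_GRID_PENALTY
from .conformation import GenomeState, apply_state, ligand_arrays
from .errors import MissingMapError
from .formats import LigandStructure
from .gridmaps import DESOLVATION_LABEL, ELECTROSTATIC_LABEL, MapCache

__all__ = [
    "EnergyBreakdown",
    "EvalCounter",
    "PoseEvaluator",
    "eligible_pairs",
    "intermolecular_energy",
    "internal_energy",
    "score",
    "DEFAULT_EPSILON",
    "DEFAULT_SIGMA",
    "BOND_DISTANCE_CUTOFF",
]

DEFAULT_EPSILON = 0.1  # kcal/mol, LJ well depth for all type pairs
DEFAULT_SIGMA = 3.4  # Å, LJ zero-crossing distance for all type pairs
BOND_DISTANCE_CUTOFF = 1.9  # Å, covalent-bond inference cutoff


@dataclass(frozen=True)
class EnergyBreakdown:
    """Scored pose: intermolecular (grid) + internal (pairwise) = total,
    one evaluation-budget unit per scored pose."""

    intermolecular: float
    internal: float

    @property
    def total(self) -> float:
        return self.intermolecular + self.internal


class EvalCounter:
    """Counts energy evaluations against the GA budget."""

    __slots__ = ("count",)

    def __init__(self):
        self.count = 0

    def tick(self) -> None:
        self.count += 1


def eligible_pairs(
    ligand: LigandStructure,
    lj_table: Mapping[tuple[str, str], tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Precompute the internal-energy pair list.

    Returns (i, j, epsilon, sigma) arrays for every atom pair whose
    bond-graph distance is >= 3 (or disconnected) and whose members lie in
    different rigid groups.  ``lj_table`` may override the uniform default
    (epsilon, sigma) per unordered type pair.
    """
    n = ligand.n_atoms
    base = ligand.coords_array()
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(base[i] - base[j]) < BOND_DISTANCE_CUTOFF:
                rows += [i, j]
                cols += [j, i]
    for bond in ligand.bonds:  # declared rotatable bonds are always bonds
        rows += [bond.a, bond.b]
        cols += [bond.b, bond.a]
    adj = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    dist = shortest_path(adj, method="D", unweighted=True)
    pi, pj, eps, sig = [], [], [], []
    group = ligand.group_of
    types = [a.atom_type for a in ligand.atoms]
    for i in range(n):
        for j in range(i + 1, n):
            if group[i] == group[j]:
                continue
            if dist[i, j] < 3:
                continue
            pi.append(i)
            pj.append(j)
            e, s = DEFAULT_EPSILON, DEFAULT_SIGMA
            if lj_table:
                key = (types[i], types[j])
                if key in lj_table:
                    e, s = lj_table[key]
                elif (key[1], key[0]) in lj_table:
                    e, s = lj_table[(key[1], key[0])]
            eps.append(e)
            sig.append(s)
    return (
        np.array(pi, dtype=np.int64),
        np.array(pj, dtype=np.int64),
        np.array(eps, dtype=np.float64),
        np.array(sig, dtype=np.float64),
    )


class PoseEvaluator:
    """Bundles the immutable per-docking scoring data (ligand arrays, the
    stacked map lattices, the pair list) with a per-run evaluation counter.

    The heavy arrays can be shared across the independent GA runs of one
    docking via :meth:`sibling`, which clones the evaluator with a fresh
    counter; scoring itself is a pure function of (genome, ligand, maps),
    so sharing never changes any returned energy.
    """

    def __init__(self, ligand: LigandStructure, cache: MapCache,
                 lj_table=None, _shared=None):
        self.ligand = ligand
        self.counter = EvalCounter()
        if _shared is not None:
            (self._arr, self._maps, self._map_index, self._e_idx,
             self._d_idx, self._origin, self._spacing, self._npts,
             self._pairs, self._charges) = _shared
            self._scratch = np.empty_like(self._arr.base)
            return
        self._arr = ligand_arrays(ligand)
        self._charges = ligand.charges_array()
        affinity_types = sorted(ligand.atom_types)
        labels = affinity_types + [ELECTROSTATIC_LABEL, DESOLVATION_LABEL]
        gmaps = [cache.get(t) for t in labels]
        ref = gmaps[0]
        for g in gmaps[1:]:
            if (g.header.npts != ref.header.npts
                    or g.header.spacing != ref.header.spacing
                    or g.header.center != ref.header.center):
                raise MissingMapError(
                    g.header.atom_type, "grid geometry differs between maps"
                )
        self._maps = np.stack([g.values for g in gmaps])
        type_pos = {t: k for k, t in enumerate(affinity_types)}
        self._map_index = np.array(
            [type_pos[a.atom_type] for a in ligand.atoms], dtype=np.int64
        )
        self._e_idx = len(affinity_types)
        self._d_idx = len(affinity_types) + 1
        self._origin = ref.origin
        self._spacing = ref.header.spacing
        self._npts = ref.header.npts
        self._pairs = eligible_pairs(ligand, lj_table)
        self._scratch = np.empty_like(self._arr.base)

    def sibling(self) -> "PoseEvaluator":
        shared = (self._arr, self._maps, self._map_index, self._e_idx,
                  self._d_idx, self._origin, self._spacing, self._npts,
                  self._pairs, self._charges)
        return PoseEvaluator(self.ligand, None, _shared=shared)

    @property
    def box_low(self) -> np.ndarray:
        return self._origin

    @property
    def box_high(self) -> np.ndarray:
        return self._origin + self._npts * self._spacing

    @property
    def n_genes(self) -> int:
        return 7 + self._arr.tor_a.shape[0]

    def score_vector(self, vec: np.ndarray) -> tuple[float, float]:
        """Score one genome vector; consumes one evaluation unit."""
        vec = np.asarray(vec, dtype=np.float64)
        if vec.shape != (self.n_genes,):
            raise ValueError(
                f"genome vector shape {vec.shape} does not match ligand "
                f"({self.n_genes} genes)"
            )
        inter, intra = _kernels.score_pose_kernel(
            vec,
            self._arr.base, self._arr.root_centroid,
            self._arr.tor_a, self._arr.tor_b, self._arr.tor_moved,
            self._charges, self._map_index, self._maps,
            self._e_idx, self._d_idx,
            self._origin[0], self._origin[1], self._origin[2],
            self._spacing, self._npts,
            *self._pairs, self._scratch,
        )
        self.counter.tick()
        return float(inter), float(intra)

    def score_total(self, vec: np.ndarray) -> float:
        inter, intra = self.score_vector(vec)
        return inter + intra

    def score_population(self, pop: np.ndarray) -> np.ndarray:
        """Score a (n_individuals, n_genes) population; consumes one unit
        per row.  Returns total energies."""
        pop = np.ascontiguousarray(pop, dtype=np.float64)
        if pop.ndim != 2 or pop.shape[1] != self.n_genes:
            raise ValueError(
                f"population shape {pop.shape} does not match ligand "
                f"({self.n_genes} genes)"
            )
        out_inter = np.empty(pop.shape[0])
        out_intra = np.empty(pop.shape[0])
        _kernels.score_population_kernel(
            pop, self._arr.base, self._arr.root_centroid,
            self._arr.tor_a, self._arr.tor_b, self._arr.tor_moved,
            self._charges, self._map_index, self._maps,
            self._e_idx, self._d_idx,
            self._origin[0], self._origin[1], self._origin[2],
            self._spacing, self._npts,
            *self._pairs, self._scratch, out_inter, out_intra,
        )
        self.counter.count += pop.shape[0]
        return out_inter + out_intra


def intermolecular_energy(coords: np.ndarray, ligand: LigandStructure,
                          cache: MapCache) -> float:
    """Grid score of explicit coordinates (Å) against the cached maps."""
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    affinity_types = sorted(ligand.atom_types)
    labels = affinity_types + [ELECTROSTATIC_LABEL, DESOLVATION_LABEL]
    gmaps = [cache.get(t) for t in labels]
    ref = gmaps[0]
    maps = np.stack([g.values for g in gmaps])
    type_pos = {t: k for k, t in enumerate(affinity_types)}
    map_index = np.array(
        [type_pos[a.atom_type] for a in ligand.atoms], dtype=np.int64
    )
    o = ref.origin
    return float(
        _kernels.intermolecular_kernel(
            coords, ligand.charges_array(), map_index, maps,
            len(affinity_types), len(affinity_types) + 1,
            o[0], o[1], o[2], ref.header.spacing, ref.header.npts,
        )
    )


def internal_energy(coords: np.ndarray, ligand: LigandStructure,
                    lj_table=None) -> float:
    """Pairwise internal energy of explicit coordinates (Å)."""
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    pi, pj, eps, sig = eligible_pairs(ligand, lj_table)
    return float(
        _kernels.internal_kernel(coords, ligand.charges_array(),
                                 pi, pj, eps, sig)
    )


def score(state: GenomeState, ligand: LigandStructure, cache: MapCache,
          counter: EvalCounter | None = None) -> EnergyBreakdown:
    """Score one pose; increments ``counter`` by exactly one when given."""
    state.validate(ligand)
    coords = apply_state(ligand, state)
    breakdown = EnergyBreakdown(
        intermolecular_energy(coords, ligand, cache),
        internal_energy(coords, ligand),
    )
    if counter is not None:
        counter.tick()
    return breakdown
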
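"""Pose parameterization and geometry.

A ligand pose is encoded by a :class:`GenomeState`: the Cartesian position
of the root rigid group's centroid, a unit quaternion for the rigid-body
orientation, and one angle per rotatable bond.  Torsion genes are measured
relative to the input conformation, so the identity state (translation at
the input centroid, identity quaternion, all torsions zero) reproduces the
input coordinates exactly.

Torsion rotation follows the right-hand rule looking from the proximal to
the distal bond atom, applied in tree order from the root outward; the
rigid-body transform is then applied to every atom.  Pose RMSD is the plain
root-mean-square deviation over matched atoms in the shared receptor frame
— no superposition and no symmetry correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import apply_state_kernel
from .errors import StateMismatchError
from .formats import LigandStructure

__all__ = [
    "GenomeState",
    "apply_state",
    "rmsd",
    "wrap_angle",
    "quat_normalize",
    "quat_multiply",
    "quat_from_axis_angle",
    "random_unit_quaternion",
    "ligand_arrays",
]


def wrap_angle(deg):
    """Wrap an angle in degrees into (-180, 180]."""
    wrapped = np.mod(np.asarray(deg, dtype=np.float64) + 180.0, 360.0) - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return float(wrapped) if np.isscalar(deg) else wrapped


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=np.float64)
    n = np.linalg.norm(q)
    if n == 0:
        raise ValueError("cannot normalize a zero quaternion")
    return q / n


def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product p*q, both (w, x, y, z)."""
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ]
    )


def quat_from_axis_angle(axis, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=np.float64)
    n = np.linalg.norm(axis)
    if n == 0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    axis = axis / n
    half = 0.5 * angle_rad
    return np.concatenate(([np.cos(half)], np.sin(half) * axis))


def random_unit_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform orientation: normalized 4-D gaussian."""
    while True:
        q = rng.normal(size=4)
        n = np.linalg.norm(q)
        if n > 1e-12:
            return q / n


@dataclass
class GenomeState:
    """One pose: root-centroid translation (Å), orientation quaternion
    (w, x, y, z; unit norm to 1e-9), and torsion angles in degrees, each in
    (-180, 180], relative to the input conformation."""

    translation: np.ndarray
    quaternion: np.ndarray
    torsions: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        self.quaternion = np.asarray(self.quaternion, dtype=np.float64).reshape(4)
        self.torsions = np.asarray(self.torsions, dtype=np.float64).reshape(-1)

    def validate(self, ligand: LigandStructure | None = None) -> None:
        if abs(np.linalg.norm(self.quaternion) - 1.0) > 1e-9:
            raise ValueError("quaternion is not unit norm")
        if ligand is not None and len(self.torsions) != ligand.n_torsions:
            raise StateMismatchError(
                f"state has {len(self.torsions)} torsions, "
                f"ligand has {ligand.n_torsions}"
            )

    @classmethod
    def identity(cls, ligand: LigandStructure) -> "GenomeState":
        """The state reproducing the ligand's input coordinates."""
        base = ligand.coords_array()
        centroid = base[ligand.groups[0]].mean(axis=0)
        return cls(centroid, np.array([1.0, 0.0, 0.0, 0.0]),
                   np.zeros(ligand.n_torsions))

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.quaternion, self.torsions])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "GenomeState":
        # The quaternion is taken verbatim (callers maintain unit norm);
        # renormalizing here would perturb the genome's last bits and break
        # exact re-scoring of stored genomes.
        vec = np.asarray(vec, dtype=np.float64)
        return cls(vec[:3].copy(), vec[3:7].copy(), vec[7:].copy())

    def format(self) -> str:
        return " ".join(repr(float(v)) for v in self.to_vector())


class _LigandArrays:
    """Precomputed array view of a ligand for the geometry kernels."""

    def __init__(self, ligand: LigandStructure):
        self.base = ligand.coords_array()
        self.root_centroid = self.base[ligand.groups[0]].mean(axis=0)
        T = ligand.n_torsions
        n = ligand.n_atoms
        self.tor_a = np.array([b.a for b in ligand.bonds], dtype=np.int64)
        self.tor_b = np.array([b.b for b in ligand.bonds], dtype=np.int64)
        self.tor_moved = np.zeros((T, n), dtype=np.bool_)
        for t, bond in enumerate(ligand.bonds):
            for i in bond.moved:
                self.tor_moved[t, i] = True


def ligand_arrays(ligand: LigandStructure) -> _LigandArrays:
    # cached on the ligand itself so the cache lifetime is exactly the
    # ligand's (a global id()-keyed cache would go stale on id reuse)
    arr = getattr(ligand, "_geometry_arrays", None)
    if arr is None:
        arr = _LigandArrays(ligand)
        ligand._geometry_arrays = arr
    return arr


def apply_state(ligand: LigandStructure, state: GenomeState) -> np.ndarray:
    """Return the ligand coordinates the state describes; the input
    coordinates are never modified."""
    state.validate(ligand)
    arr = ligand_arrays(ligand)
    out = np.empty_like(arr.base)
    apply_state_kernel(
        state.to_vector(), arr.base, arr.root_centroid,
        arr.tor_a, arr.tor_b, arr.tor_moved, out,
    )
    return out


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation over matched atoms (Å), no fitting."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
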
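"""Synthetic fixtures: complete toy screens with no external inputs.

Real screens need a prepared receptor, autogrid-style map calculation, and
a compound library.  For desk-scale testing this module manufactures all
three from scratch:

* **toy receptors** — a handful of point atoms with charges and types;
* **analytic grid maps** — affinity maps built from 12-6 Lennard-Jones
  sums over the receptor atoms plus a constructed Gaussian binding funnel
  and harmonic confinement centred on a known ``well_center``, so the
  single-atom pose-energy landscape has its global lattice minimum exactly
  at the well centre (placed on a lattice point; since trilinear
  interpolation attains its cell extrema at cell corners, the interpolated
  landscape's global minimum is that same point);
* **toy ligands** — zig-zag PDBQT chains of 1-8 atoms with 0-6 nested
  torsions, Gasteiger-like small alternating charges, and types drawn from
  the receptor-compatible set.

Everything is deterministic given the spec's seed, so regenerating a
fixture is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import formats
from .formats import (
    Atom,
    DockingParameters,
    GridHeader,
    LigandStructure,
    TorsionBond,
    serialize_parameters,
    write_fld,
    write_map,
    write_pdbqt,
)

__all__ = [
    "ToyLigandSpec",
    "ToyComplexSpec",
    "build_toy_ligand",
    "make_toy_ligand",
    "make_toy_maps",
    "make_screen",
    "affinity_lattice",
    "electrostatic_lattice",
    "desolvation_lattice",
]

MAP_CLAMP = 1.0e3  # kcal/mol cap keeps map text finite and interpolation sane
WELL_DEPTH = 10.0  # kcal/mol, constructed Gaussian funnel depth
WELL_WIDTH = 3.0  # Å, funnel standard deviation
CONFINE_K = 0.1  # kcal/mol/Å^2 harmonic confinement about the well
LJ_EPSILON = 0.1  # kcal/mol, receptor-probe well depth
LJ_SIGMA = 3.4  # Å
COULOMB_K = 332.0636
DESOLV_WEIGHT = 0.25
DESOLV_WIDTH = 3.5  # Å
BOND_LENGTH = 1.4  # Å, toy-chain bond length
ZIGZAG_STEP = (1.15, 0.75)  # Å in-plane zig-zag offsets (bond ~1.37 Å)


@dataclass(frozen=True)
class ToyLigandSpec:
    """Shape of a generated ligand: atom count, nested torsion count,
    atom-type cycle, and charge pattern (``alternating`` ±0.1 e or
    ``zero``)."""

    n_atoms: int = 4
    n_torsions: int = 1
    atom_types: tuple[str, ...] = ("C",)
    charge_pattern: str = "alternating"

    def validate(self) -> None:
        if self.n_atoms < 1:
            raise ValueError("ligand needs at least one atom")
        if self.n_torsions < 0 or self.n_torsions > max(self.n_atoms - 2, 0):
            raise ValueError(
                f"cannot fit {self.n_torsions} torsions in "
                f"{self.n_atoms} atoms (need torsions <= atoms - 2)"
            )
        if self.charge_pattern not in ("alternating", "zero"):
            raise ValueError(f"unknown charge pattern {self.charge_pattern!r}")


@dataclass(frozen=True)
class ToyComplexSpec:
    """A complete toy docking problem.

    ``receptor_atoms`` are (position Å, charge e, type) triples;
    ``well_center`` is the constructed pose optimum (must lie strictly
    inside — and, for an exact lattice argmin, on — the grid lattice);
    ``grid`` fixes the box geometry; ``ligand`` the companion ligand.
    """

    receptor_atoms: tuple[tuple[tuple[float, float, float], float, str], ...] = (
        # Placed outside the default 7.5 Å box: their Lennard-Jones walls
        # rise toward the ±x/±y box faces while the constructed funnel
        # keeps the global lattice minimum exactly at the well centre.
        ((6.0, 0.0, 0.0), 0.3, "C"),
        ((-6.0, 0.0, 0.0), -0.3, "C"),
        ((0.0, 6.0, 0.0), 0.3, "C"),
        ((0.0, -6.0, 0.0), -0.3, "C"),
    )
    well_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    spacing: float = 0.375
    npts: int = 20
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ligand: ToyLigandSpec = field(default_factory=ToyLigandSpec)
    seed: int = 0

    def header(self, atom_type: str) -> GridHeader:
        return GridHeader(self.spacing, self.npts, self.center, atom_type)

    def lattice(self) -> np.ndarray:
        """(n, n, n, 3) Cartesian coordinates of the lattice points."""
        n = self.npts + 1
        half = self.npts * self.spacing / 2.0
        axes = [
            np.asarray(self.center)[k] - half + self.spacing * np.arange(n)
            for k in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def validate(self) -> None:
        half = self.npts * self.spacing / 2.0
        w = np.asarray(self.well_center) - np.asarray(self.center)
        if np.any(np.abs(w) >= half):
            raise ValueError("well_center must lie strictly inside the grid box")
        self.ligand.validate()


def _distances_to(points: np.ndarray, target) -> np.ndarray:
    return np.linalg.norm(points - np.asarray(target, dtype=np.float64),
                          axis=-1)


def affinity_lattice(spec: ToyComplexSpec, atom_type: str) -> np.ndarray:
    """Affinity map for one probe type: receptor Lennard-Jones sum (clamped)
    plus the constructed funnel and confinement about the well centre."""
    pts = spec.lattice()
    values = np.zeros(pts.shape[:3])
    for pos, _q, _t in spec.receptor_atoms:
        r = np.maximum(_distances_to(pts, pos), 1e-6)
        sr6 = (LJ_SIGMA / r) ** 6
        values += 4.0 * LJ_EPSILON * (sr6**2 - sr6)
    d = _distances_to(pts, spec.well_center)
    values += -WELL_DEPTH * np.exp(-(d**2) / (2.0 * WELL_WIDTH**2))
    values += CONFINE_K * d**2
    return np.clip(values, -MAP_CLAMP, MAP_CLAMP)


def electrostatic_lattice(spec: ToyComplexSpec) -> np.ndarray:
    """Electrostatic potential map with distance-dependent dielectric 4r."""
    pts = spec.lattice()
    values = np.zeros(pts.shape[:3])
    for pos, q, _t in spec.receptor_atoms:
        r = np.maximum(_distances_to(pts, pos), 1e-6)
        values += COULOMB_K * q / (4.0 * r * r)
    return np.clip(values, -MAP_CLAMP, MAP_CLAMP)


def desolvation_lattice(spec: ToyComplexSpec) -> np.ndarray:
    """Smooth receptor-occupancy surrogate for the desolvation map."""
    pts = spec.lattice()
    values = np.zeros(pts.shape[:3])
    for pos, _q, _t in spec.receptor_atoms:
        r = _distances_to(pts, pos)
        values += DESOLV_WEIGHT * np.exp(-(r**2) / (2.0 * DESOLV_WIDTH**2))
    return values


def make_toy_maps(spec: ToyComplexSpec, out_dir: str | Path,
                  atom_types: tuple[str, ...] | None = None,
                  stem: str = "receptor") -> dict[str, Path]:
    """Write one affinity map per atom type plus the electrostatic and
    desolvation maps, and return the label -> path index."""
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    types = tuple(atom_types) if atom_types is not None else tuple(
        sorted(spec.ligand.atom_types)
    )
    index: dict[str, Path] = {}
    for t in types:
        path = out / f"{stem}.{t}.map"
        write_map(spec.header(t), affinity_lattice(spec, t), path)
        index[t] = path
    e_path = out / f"{stem}.e.map"
    write_map(spec.header("e"), electrostatic_lattice(spec), e_path)
    index["e"] = e_path
    d_path = out / f"{stem}.d.map"
    write_map(spec.header("d"), desolvation_lattice(spec), d_path)
    index["d"] = d_path
    return index


def build_toy_ligand(spec: ToyLigandSpec) -> LigandStructure:
    """Construct a zig-zag chain ligand with nested terminal torsions.

    The first ``n_atoms - n_torsions`` atoms form the root rigid group;
    each remaining atom hangs off the previous one through its own
    rotatable bond, giving a nested torsion tree of the requested depth.
    Consecutive atoms sit ~1.4 Å apart (within covalent-bond inference
    range) and second neighbours well outside it.
    """
    spec.validate()
    dx, dy = ZIGZAG_STEP
    coords = [(i * dx, dy * (i % 2), 0.0) for i in range(spec.n_atoms)]
    charges = (
        [0.0] * spec.n_atoms
        if spec.charge_pattern == "zero"
        else [0.1 if i % 2 == 0 else -0.1 for i in range(spec.n_atoms)]
    )
    types = [spec.atom_types[i % len(spec.atom_types)]
             for i in range(spec.n_atoms)]
    atoms = [
        Atom(f"{types[i]}{i + 1}", coords[i], charges[i], types[i])
        for i in range(spec.n_atoms)
    ]
    n_root = spec.n_atoms - spec.n_torsions
    groups = [list(range(n_root))]
    bonds: list[TorsionBond] = []
    for t in range(spec.n_torsions):
        atom_idx = n_root + t
        groups.append([atom_idx])
        bonds.append(
            TorsionBond(
                a=atom_idx - 1,
                b=atom_idx,
                moved=frozenset(range(atom_idx, spec.n_atoms)),
                group=t + 1,
                parent_group=t,
            )
        )
    group_of = [0] * n_root + [t + 1 for t in range(spec.n_torsions)]
    lig = LigandStructure(atoms, groups, bonds, group_of, source_id="toy")
    lig.validate()
    return lig


def make_toy_ligand(spec: ToyLigandSpec) -> str:
    """PDBQT text of the toy ligand; parses back to the requested torsion
    count under :func:`screendock.formats.read_pdbqt`."""
    import io

    buf = io.StringIO()
    write_pdbqt(build_toy_ligand(spec), buf)
    return buf.getvalue()


_VARIED_TYPE_SETS = (("C",), ("C", "N"), ("C", "N", "O"))
_VARIED_TORSIONS = (0, 1, 2, 3)

DEFAULT_SCREEN_PARAMS = dict(
    ga_runs=4, ga_popsize=30, ga_num_evals=2000, ga_num_generations=50
)


def make_screen(out_root: str | Path, n_jobs: int, mode: str = "replicated",
                seed: int = 0, complex_spec: ToyComplexSpec | None = None,
                params_overrides: dict | None = None,
                fail_jobs: tuple[int, ...] = ()) -> Path:
    """Generate ``n_jobs`` complete docking directories plus a job list.

    ``mode="replicated"`` writes the identical ligand into every job (the
    replicated-library screen design); ``mode="varied"`` cycles torsion
    counts and atom-type sets so successive dockings introduce previously
    unused types and exercise lazy map loading.  Grid maps are shared in
    ``maps/`` and referenced relatively from each job's grid descriptor.
    Jobs listed in ``fail_jobs`` reference an affinity map that does not
    exist, and so fail with a missing-map error when docked.

    Returns the path of the job-list file.
    """
    if n_jobs < 0:
        raise ValueError("n_jobs must be >= 0")
    if mode not in ("replicated", "varied"):
        raise ValueError(f"unknown screen mode {mode!r}")
    root = Path(out_root)
    root.mkdir(parents=True, exist_ok=True)
    spec = complex_spec or ToyComplexSpec(seed=seed)
    params = DockingParameters(**{**DEFAULT_SCREEN_PARAMS,
                                  **(params_overrides or {})})
    params = params.copy(rng_base_seed=seed if params.rng_base_seed == "time"
                         else params.rng_base_seed)

    all_types = (
        tuple(sorted({t for ts in _VARIED_TYPE_SETS for t in ts}))
        if mode == "varied" else tuple(sorted(spec.ligand.atom_types))
    )
    map_index = make_toy_maps(spec, root / "maps", atom_types=all_types)

    job_dirs: list[Path] = []
    for j in range(n_jobs):
        job_dir = root / f"job_{j:03d}"
        job_dir.mkdir(parents=True, exist_ok=True)
        if mode == "replicated":
            lig_spec = spec.ligand
        else:
            lig_spec = replace(
                spec.ligand,
                atom_types=_VARIED_TYPE_SETS[j % len(_VARIED_TYPE_SETS)],
                n_torsions=min(_VARIED_TORSIONS[j % len(_VARIED_TORSIONS)],
                               max(spec.ligand.n_atoms - 2, 0)),
            )
        if j in fail_jobs:
            lig_spec = replace(lig_spec, atom_types=("X",))
        (job_dir / "ligand.pdbqt").write_text(make_toy_ligand(lig_spec))
        (job_dir / "dock.dpf").write_text(serialize_parameters(params))
        fld = {
            label: Path("..") / "maps" / path.name
            for label, path in map_index.items()
        }
        if j in fail_jobs:
            fld["X"] = Path("..") / "maps" / "receptor.X.map"  # never written
        write_fld(fld, job_dir / "grid.fld")
        job_dirs.append(job_dir)

    joblist = root / "joblist.txt"
    joblist.write_text("".join(f"{d}\n" for d in job_dirs))
    return joblist
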
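"""Text formats for a virtual screen.

The screen's on-disk world is entirely plain text, in dialects modelled on
the AutoDock family of formats:

* **PDBQT** ligands — PDB-like ``ATOM``/``HETATM`` records carrying partial
  charges and atom types in the final two columns, wrapped in a
  ``ROOT``/``BRANCH`` torsion-tree block structure.
* **DPF**-like docking parameter files — one ``key value`` pair per line.
* **.map**-like grid maps — a small keyword header followed by one energy
  per line, x-fastest.
* **.fld**-like grid indexes — one ``atom_type filename`` pair per line.
* **DLG**-like docking logs — per-run sections written en bloc, followed by
  clustering and ranking.
* job lists — one docking directory per line.

The PDBQT charge and type are read positionally from the last two
whitespace-delimited columns of each atom record (a deliberate dialect
choice tolerant of preparation-tool variation).  The DLG layout is our own
declared grammar, stable and machine-parseable; byte compatibility with
AutoDock 4.2 logs is a non-goal.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Mapping

import numpy as np

from .errors import (
    FieldParseError,
    HeaderError,
    IncompleteResultError,
    ParameterError,
    RangeError,
    StructuralParseError,
    TruncatedMapError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "TorsionBond",
    "LigandStructure",
    "DockingParameters",
    "GridHeader",
    "read_pdbqt",
    "write_pdbqt",
    "parse_parameters",
    "serialize_parameters",
    "read_map",
    "write_map",
    "read_fld",
    "write_fld",
    "write_dlg",
    "read_joblist",
]


def _as_text_lines(source) -> list[str]:
    """Accept a path, an open text stream, or raw text, and return lines."""
    if hasattr(source, "read"):
        return source.read().splitlines()
    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        return Path(source).read_text().splitlines()
    if isinstance(source, str):
        return source.splitlines()
    raise TypeError(f"cannot read from {type(source).__name__}")


def _as_sink(sink) -> tuple[IO[str], bool]:
    if hasattr(sink, "write"):
        return sink, False
    return open(sink, "w"), True


# ---------------------------------------------------------------------------
# Ligands
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """One ligand atom: name, Cartesian position (Å), partial charge (e),
    and the probe atom type naming its affinity grid map."""

    name: str
    coords: tuple[float, float, float]
    charge: float
    atom_type: str


@dataclass(frozen=True)
class TorsionBond:
    """A rotatable bond: the proximal/distal atom indices defining its axis,
    the set of atom indices it moves, and the rigid group it creates."""

    a: int  # proximal (parent-side) atom index, 0-based
    b: int  # distal (child-side) atom index, 0-based
    moved: frozenset[int]
    group: int  # rigid-group id created by this bond
    parent_group: int


@dataclass
class LigandStructure:
    """A ligand as a torsion tree over rigid groups of atoms.

    ``groups[0]`` is the root rigid group; every other group is created by
    exactly one rotatable bond in ``bonds`` (one per torsion, in
    root-outward order).  ``group_of[i]`` maps each atom to its rigid
    group.
    """

    atoms: list[Atom]
    groups: list[list[int]]
    bonds: list[TorsionBond]
    group_of: list[int]
    source_id: str = ""

    @property
    def n_torsions(self) -> int:
        return len(self.bonds)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=np.float64)

    def charges_array(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=np.float64)

    @property
    def atom_types(self) -> set[str]:
        return {a.atom_type for a in self.atoms}

    def validate(self) -> None:
        n = self.n_atoms
        seen: set[int] = set()
        for g in self.groups:
            for i in g:
                if i in seen:
                    raise StructuralParseError(
                        f"atom index {i} appears in more than one rigid group"
                    )
                seen.add(i)
        if seen != set(range(n)):
            raise StructuralParseError(
                "rigid groups do not partition the atom set"
            )
        if len(self.bonds) != len(self.groups) - 1:
            raise StructuralParseError(
                "torsion count does not match non-root group count"
            )
        root = set(self.groups[0])
        for bond in self.bonds:
            if bond.moved & root:
                raise StructuralParseError(
                    "a rotatable bond moves atoms of the root group"
                )
        # nesting consistency: each bond's moved-set must contain its own
        # group and every descendant group, nothing else
        children: dict[int, list[int]] = {}
        for bond in self.bonds:
            children.setdefault(bond.parent_group, []).append(bond.group)
        for bond in self.bonds:
            expect: set[int] = set()
            stack = [bond.group]
            while stack:
                g = stack.pop()
                expect.update(self.groups[g])
                stack.extend(children.get(g, []))
            if bond.moved != expect:
                raise StructuralParseError(
                    "rotatable-bond moved-set inconsistent with tree nesting"
                )
        for atom in self.atoms:
            if not all(np.isfinite(atom.coords)):
                raise FieldParseError(f"non-finite coordinates for {atom.name}")


def read_pdbqt(source, source_id: str = "") -> LigandStructure:
    """Parse a PDBQT ligand into its atoms and torsion tree.

    Atom order is preserved.  The partial charge and atom type are taken
    from the last two whitespace-delimited columns of each atom record.
    Raises :class:`StructuralParseError` on unbalanced ``BRANCH`` nesting
    and :class:`FieldParseError` on malformed atom fields, both naming the
    offending line.
    """
    lines = _as_text_lines(source)
    atoms: list[Atom] = []
    serial_to_index: dict[int, int] = {}
    groups: list[list[int]] = [[]]
    parent_of_group = [-1]
    # stack of (group_id, a_serial, b_serial); root sentinel has no bond
    stack: list[tuple[int, int | None, int | None]] = []
    root_seen = False
    root_closed = False
    raw_bonds: list[tuple[int, int, int, int]] = []  # (a_ser, b_ser, group, parent)

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        rec = line.split(None, 1)[0].upper()
        if rec in ("ATOM", "HETATM"):
            tok = line.split()
            if len(tok) < 9:
                raise FieldParseError("atom record has too few columns", lineno)
            if not stack:
                raise StructuralParseError(
                    "atom record outside ROOT/BRANCH block", lineno
                )
            try:
                serial = int(line[6:11]) if len(line) >= 11 and line[6:11].strip() else int(tok[1])
            except ValueError:
                raise FieldParseError("non-numeric atom serial", lineno) from None
            name = line[12:16].strip() if len(line) >= 16 else tok[2]
            if not name:
                name = tok[2]
            try:
                x, y, z = (float(tok[-7]), float(tok[-6]), float(tok[-5]))
            except ValueError:
                raise FieldParseError("non-numeric coordinates", lineno) from None
            try:
                charge = float(tok[-2])
            except ValueError:
                raise FieldParseError(
                    f"non-numeric partial charge {tok[-2]!r}", lineno
                ) from None
            atom_type = tok[-1]
            idx = len(atoms)
            atoms.append(Atom(name, (x, y, z), charge, atom_type))
            if serial in serial_to_index:
                raise StructuralParseError(
                    f"duplicate atom serial {serial}", lineno
                )
            serial_to_index[serial] = idx
            groups[stack[-1][0]].append(idx)
        elif rec == "ROOT":
            if root_seen:
                raise StructuralParseError("duplicate ROOT record", lineno)
            root_seen = True
            stack.append((0, None, None))
        elif rec == "ENDROOT":
            if not stack or stack[-1][0] != 0:
                raise StructuralParseError(
                    "ENDROOT without matching ROOT", lineno
                )
            stack.pop()
            root_closed = True
        elif rec == "BRANCH":
            tok = line.split()
            if len(tok) != 3:
                raise StructuralParseError("malformed BRANCH record", lineno)
            if not root_seen:
                raise StructuralParseError("BRANCH before ROOT", lineno)
            try:
                a_ser, b_ser = int(tok[1]), int(tok[2])
            except ValueError:
                raise FieldParseError("non-numeric BRANCH serials", lineno) from None
            parent = stack[-1][0] if stack else 0
            gid = len(groups)
            groups.append([])
            parent_of_group.append(parent)
            raw_bonds.append((a_ser, b_ser, gid, parent))
            stack.append((gid, a_ser, b_ser))
        elif rec == "ENDBRANCH":
            tok = line.split()
            if not stack or stack[-1][1] is None:
                raise StructuralParseError(
                    "ENDBRANCH without matching BRANCH", lineno
                )
            if len(tok) == 3:
                try:
                    a_ser, b_ser = int(tok[1]), int(tok[2])
                except ValueError:
                    raise FieldParseError(
                        "non-numeric ENDBRANCH serials", lineno
                    ) from None
                if (a_ser, b_ser) != (stack[-1][1], stack[-1][2]):
                    raise StructuralParseError(
                        f"ENDBRANCH {a_ser} {b_ser} does not match open "
                        f"BRANCH {stack[-1][1]} {stack[-1][2]}",
                        lineno,
                    )
            stack.pop()
        else:
            # REMARK, TORSDOF, and anything unrecognized are ignored
            continue

    if stack:
        kind = "ROOT" if stack[-1][1] is None else "BRANCH"
        raise StructuralParseError(
            f"unclosed {kind} block at end of input", len(lines)
        )
    if not root_seen or not root_closed:
        raise StructuralParseError("missing ROOT/ENDROOT block", len(lines))
    if not atoms:
        raise StructuralParseError("no atom records found", len(lines))

    # resolve serials and compute moved-sets bottom-up
    children: dict[int, list[int]] = {}
    for _, _, gid, parent in raw_bonds:
        children.setdefault(parent, []).append(gid)

    def subtree_atoms(gid: int) -> frozenset[int]:
        out: set[int] = set()
        stack2 = [gid]
        while stack2:
            g = stack2.pop()
            out.update(groups[g])
            stack2.extend(children.get(g, []))
        return frozenset(out)

    bonds: list[TorsionBond] = []
    for a_ser, b_ser, gid, parent in raw_bonds:
        try:
            a_idx = serial_to_index[a_ser]
            b_idx = serial_to_index[b_ser]
        except KeyError as exc:
            raise StructuralParseError(
                f"BRANCH references unknown atom serial {exc.args[0]}"
            ) from None
        bonds.append(
            TorsionBond(a_idx, b_idx, subtree_atoms(gid), gid, parent)
        )

    group_of = [0] * len(atoms)
    for gid, members in enumerate(groups):
        for i in members:
            group_of[i] = gid

    lig = LigandStructure(atoms, groups, bonds, group_of, source_id=source_id)
    lig.validate()
    return lig


def write_pdbqt(ligand: LigandStructure, sink) -> None:
    """Serialize a ligand back to PDBQT, emitting the torsion tree depth
    first in parse order.  Atom serials are 1-based original indices."""
    out, close = _as_sink(sink)
    try:
        children: dict[int, list[TorsionBond]] = {}
        for bond in ligand.bonds:
            children.setdefault(bond.parent_group, []).append(bond)

        def atom_line(idx: int) -> str:
            a = ligand.atoms[idx]
            x, y, z = a.coords
            return (
                f"ATOM  {idx + 1:>5} {a.name:<4} LIG A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00    "
                f"{a.charge:6.3f} {a.atom_type}"
            )

        def emit_group(gid: int) -> None:
            for idx in ligand.groups[gid]:
                out.write(atom_line(idx) + "\n")
            for bond in children.get(gid, []):
                out.write(f"BRANCH {bond.a + 1} {bond.b + 1}\n")
                emit_group(bond.group)
                out.write(f"ENDBRANCH {bond.a + 1} {bond.b + 1}\n")

        out.write("ROOT\n")
        for idx in ligand.groups[0]:
            out.write(atom_line(idx) + "\n")
        out.write("ENDROOT\n")
        for bond in children.get(0, []):
            out.write(f"BRANCH {bond.a + 1} {bond.b + 1}\n")
            emit_group(bond.group)
            out.write(f"ENDBRANCH {bond.a + 1} {bond.b + 1}\n")
        out.write(f"TORSDOF {ligand.n_torsions}\n")
    finally:
        if close:
            out.close()


# ---------------------------------------------------------------------------
# Docking parameters
# ---------------------------------------------------------------------------

_COUNT_KEYS = ("ga_runs", "ga_popsize", "ga_num_evals", "ga_num_generations")


@dataclass
class DockingParameters:
    """Tunable docking parameters with AutoDock-style defaults.

    ``ga_runs`` independent GA executions per docking; population size
    ``ga_popsize``; termination by whichever of ``ga_num_evals`` energy
    evaluations or ``ga_num_generations`` generations is hit first;
    ``ls_frequency`` is the per-individual local-search probability;
    ``cluster_tolerance`` the pose-clustering RMSD cutoff in Å;
    ``map_policy`` selects persistent (``reuse``) or per-docking
    (``reload``) grid-map caching; ``rng_base_seed`` is an integer or
    ``"time"`` for a once-per-docking wall-clock base.
    """

    ga_runs: int = 20
    ga_popsize: int = 150
    ga_num_evals: int = 250000
    ga_num_generations: int = 27000
    ls_frequency: float = 0.06
    cluster_tolerance: float = 2.0
    map_policy: str = "reuse"
    rng_base_seed: int | str = "time"
    extras: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.ga_runs < 1 or self.ga_popsize < 1:
            raise ParameterError("ga_runs and ga_popsize must be >= 1")
        if self.ga_num_evals < 0 or self.ga_num_generations < 0:
            raise ParameterError("evaluation/generation budgets must be >= 0")
        if not 0.0 <= self.ls_frequency <= 1.0:
            raise RangeError("ls_frequency must lie in [0, 1]")
        if self.cluster_tolerance <= 0:
            raise RangeError("cluster_tolerance must be positive")
        if self.map_policy not in ("reuse", "reload"):
            raise ParameterError(f"unknown map_policy {self.map_policy!r}")
        if self.rng_base_seed != "time" and not isinstance(
            self.rng_base_seed, int
        ):
            raise ParameterError("seed must be an integer or 'time'")

    def copy(self, **overrides) -> "DockingParameters":
        return replace(self, **overrides)


def parse_parameters(source) -> DockingParameters:
    """Parse a DPF-like ``key value`` stream into :class:`DockingParameters`.

    Later occurrences of a key override earlier ones; unknown keys are kept
    in ``extras`` and logged, never rejected.
    """
    params = DockingParameters()
    for lineno, raw in enumerate(_as_text_lines(source), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) == 1:
            raise FieldParseError(f"key {parts[0]!r} has no value", lineno)
        key, value = parts[0], parts[1].strip()
        if key in _COUNT_KEYS:
            try:
                ivalue = int(value)
            except ValueError:
                raise FieldParseError(
                    f"non-integer value {value!r} for count key {key!r}", lineno
                ) from None
            if ivalue < 0:
                raise RangeError(f"negative value for {key}: {ivalue}")
            setattr(params, key, ivalue)
        elif key == "ls_frequency":
            try:
                params.ls_frequency = float(value)
            except ValueError:
                raise FieldParseError(
                    f"non-numeric ls_frequency {value!r}", lineno
                ) from None
        elif key == "cluster_tolerance":
            try:
                params.cluster_tolerance = float(value)
            except ValueError:
                raise FieldParseError(
                    f"non-numeric cluster_tolerance {value!r}", lineno
                ) from None
        elif key == "map_policy":
            params.map_policy = value
        elif key == "seed":
            if value == "time":
                params.rng_base_seed = "time"
            else:
                try:
                    params.rng_base_seed = int(value)
                except ValueError:
                    raise FieldParseError(
                        f"seed must be an integer or 'time', got {value!r}",
                        lineno,
                    ) from None
        else:
            logger.warning("ignoring unknown parameter key %r", key)
            params.extras[key] = value
    params.validate()
    return params


def serialize_parameters(params: DockingParameters) -> str:
    lines = [
        f"ga_runs {params.ga_runs}",
        f"ga_popsize {params.ga_popsize}",
        f"ga_num_evals {params.ga_num_evals}",
        f"ga_num_generations {params.ga_num_generations}",
        f"ls_frequency {params.ls_frequency!r}",
        f"cluster_tolerance {params.cluster_tolerance!r}",
        f"map_policy {params.map_policy}",
        f"seed {params.rng_base_seed}",
    ]
    lines += [f"{k} {v}" for k, v in params.extras.items()]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Grid maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridHeader:
    """Geometry of one grid map: ``spacing`` Å per interval, ``npts`` even
    intervals per axis (``npts + 1`` lattice points per axis), the box
    ``center`` in Å, and the probe ``atom_type`` label (``"e"``
    electrostatic, ``"d"`` desolvation, anything else an affinity type)."""

    spacing: float
    npts: int
    center: tuple[float, float, float]
    atom_type: str

    def __post_init__(self):
        if self.spacing <= 0:
            raise HeaderError(f"SPACING must be positive, got {self.spacing}")
        if self.npts < 2 or self.npts % 2:
            raise HeaderError(f"NELEMENTS must be even and >= 2, got {self.npts}")

    @property
    def points_per_axis(self) -> int:
        return self.npts + 1

    @property
    def n_values(self) -> int:
        return self.points_per_axis**3


def read_map(source) -> tuple[GridHeader, np.ndarray]:
    """Read an ASCII grid map.

    Header keywords (``SPACING``, ``NELEMENTS``, ``CENTER``, ``TYPE``) may
    appear in any order before the data; the data is one value per line in
    x-fastest, z-slowest order.  The returned array is indexed
    ``values[ix, iy, iz]``.
    """
    lines = _as_text_lines(source)
    spacing = None
    npts = None
    center = None
    atom_type = None
    data_start = None
    for i, raw in enumerate(lines):
        line = raw.strip()
        if not line:
            continue
        key = line.split(None, 1)[0].upper()
        if key == "SPACING":
            spacing = float(line.split()[1])
        elif key == "NELEMENTS":
            tok = line.split()[1:]
            if len(tok) != 3:
                raise HeaderError("NELEMENTS requires three counts")
            nx, ny, nz = (int(t) for t in tok)
            if not nx == ny == nz:
                raise HeaderError(f"NELEMENTS must be equal, got {nx} {ny} {nz}")
            if nx % 2 or nx < 2:
                raise HeaderError(f"NELEMENTS must be even and >= 2, got {nx}")
            npts = nx
        elif key == "CENTER":
            tok = line.split()[1:]
            center = (float(tok[0]), float(tok[1]), float(tok[2]))
        elif key == "TYPE":
            atom_type = line.split()[1]
        else:
            data_start = i
            break
    if spacing is None or npts is None or center is None or atom_type is None:
        raise HeaderError("grid-map header incomplete (need SPACING, NELEMENTS, CENTER, TYPE)")
    header = GridHeader(spacing, npts, center, atom_type)
    raw_values = [
        ln.strip() for ln in (lines[data_start:] if data_start is not None else [])
        if ln.strip()
    ]
    if len(raw_values) != header.n_values:
        raise TruncatedMapError(header.n_values, len(raw_values))
    flat = np.array([float(v) for v in raw_values], dtype=np.float64)
    n = header.points_per_axis
    values = flat.reshape((n, n, n)).transpose(2, 1, 0)  # -> [ix, iy, iz]
    return header, values


def write_map(header: GridHeader, values: np.ndarray, sink) -> None:
    """Write a grid map in the canonical dialect: ``repr`` of each float,
    x-fastest.  ``write_map(*read_map(f))`` reproduces the numeric lines of
    any file this writer produced byte-for-byte."""
    n = header.points_per_axis
    if values.shape != (n, n, n):
        raise TruncatedMapError(header.n_values, int(np.size(values)))
    out, close = _as_sink(sink)
    try:
        out.write(f"SPACING {header.spacing!r}\n")
        out.write(f"NELEMENTS {header.npts} {header.npts} {header.npts}\n")
        cx, cy, cz = header.center
        out.write(f"CENTER {cx!r} {cy!r} {cz!r}\n")
        out.write(f"TYPE {header.atom_type}\n")
        flat = values.transpose(2, 1, 0).ravel()
        out.write("\n".join(repr(float(v)) for v in flat))
        out.write("\n")
    finally:
        if close:
            out.close()


def read_fld(source, base_dir: str | os.PathLike | None = None) -> dict[str, Path]:
    """Read a grid-index file mapping atom-type labels to map-file paths.

    Relative paths are resolved against ``base_dir`` (defaulting to the
    .fld file's own directory when ``source`` is a path).
    """
    if base_dir is None and isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        base_dir = Path(source).parent
    base = Path(base_dir) if base_dir is not None else Path(".")
    mapping: dict[str, Path] = {}
    for lineno, raw in enumerate(_as_text_lines(source), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FieldParseError("grid-index line must be 'atom_type path'", lineno)
        label, path = parts
        p = Path(path)
        mapping[label] = p if p.is_absolute() else base / p
    return mapping


def write_fld(mapping: Mapping[str, str | os.PathLike], sink) -> None:
    out, close = _as_sink(sink)
    try:
        for label, path in mapping.items():
            out.write(f"{label} {path}\n")
    finally:
        if close:
            out.close()


# ---------------------------------------------------------------------------
# Docking logs (DLG dialect)
# ---------------------------------------------------------------------------


def write_dlg(result, sink) -> None:
    """Write a docking log: one contiguous section per run, in run-index
    order, then clustering and ranking.

    Each run's buffered log is emitted en bloc — lines from different runs
    never interleave regardless of how many threads produced them.  Raises
    :class:`IncompleteResultError` when any run log is missing.
    """
    runs = list(result.runs)
    if len(runs) != result.expected_runs or any(
        r is None or r.log_buffer is None for r in runs
    ):
        raise IncompleteResultError(
            f"docking {result.job_id!r} has "
            f"{sum(r is not None for r in runs)}/{result.expected_runs} run logs"
        )
    out, close = _as_sink(sink)
    try:
        out.write("SCREENDOCK DOCKING LOG\n")
        out.write(f"job {result.job_id}\n")
        out.write(f"runs {len(runs)}\n")
        for run in runs:
            out.write(f"Run {run.run_index}\n")
            out.write(f"seed {run.seed}\n")
            buf = run.log_buffer
            out.write(buf if buf.endswith("\n") or not buf else buf + "\n")
            out.write(f"best_energy {run.best_energy!r}\n")
            out.write(f"best_state {run.best_state.format()}\n")
            out.write(f"generations {run.generations_done} evals {run.evals_used}\n")
        out.write("CLUSTERING\n")
        for ci, cluster in enumerate(result.clusters, start=1):
            best = result.run_by_index(cluster[0]).best_energy
            members = ",".join(str(i) for i in cluster)
            out.write(
                f"cluster {ci} size {len(cluster)} "
                f"best_energy {best!r} runs {members}\n"
            )
        out.write("RANKING\n")
        for rank, cluster in enumerate(result.clusters, start=1):
            lead = result.run_by_index(cluster[0])
            out.write(
                f"rank {rank} cluster {rank} run {lead.run_index} "
                f"energy {lead.best_energy!r}\n"
            )
        out.write("END\n")
    finally:
        if close:
            out.close()


# ---------------------------------------------------------------------------
# Job lists
# ---------------------------------------------------------------------------


def read_joblist(path) -> list[Path]:
    """Read a screen job list: one docking directory per line, blank lines
    and ``#`` comments skipped, order preserved."""
    jobs: list[Path] = []
    for raw in _as_text_lines(path):
        line = raw.split("#", 1)[0].strip()
        if line:
            jobs.append(Path(line))
    return jobs
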
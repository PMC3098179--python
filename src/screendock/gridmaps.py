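"""In-memory grid maps, trilinear interpolation, and the persistence-policy
map cache.

A :class:`GridMap` holds one probe atom type's precomputed interaction
energies on a regular cubic lattice.  Scoring interpolates these lattices
instead of evaluating pairwise potentials, so loading maps is the dominant
file I/O of a screen.  :class:`MapCache` embodies the two I/O policies a
worker can run under:

* ``reuse`` — a map, once read, persists in worker memory for the worker's
  lifetime; later dockings that need the same atom type trigger no file
  access, and a previously unused atom type is loaded lazily on first use.
* ``reload`` — the cache is emptied after every docking, so each docking
  re-reads every map it needs (the classic one-docking-at-a-time behaviour).

Both policies return identical map contents; they differ only in how many
file reads a screen performs, which the cache's ``load_counter`` exposes
for tests and profiling.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from . import formats
from ._kernels import OUT_OF_GRID_PENALTY, trilinear_kernel
from .errors import MissingMapError
from .formats import GridHeader

__all__ = [
    "GridMap",
    "MapCache",
    "interpolate",
    "cache_get",
    "cache_begin_docking",
    "OUT_OF_GRID_PENALTY",
    "ELECTROSTATIC_LABEL",
    "DESOLVATION_LABEL",
]

# Reserved cache labels; treated exactly like affinity maps.
ELECTROSTATIC_LABEL = "e"
DESOLVATION_LABEL = "d"


@dataclass
class GridMap:
    """One atom type's potential on a cubic lattice of
    ``(npts+1)**3`` points with origin ``center - npts*spacing/2``."""

    header: GridHeader
    values: np.ndarray  # [ix, iy, iz], kcal/mol

    def __post_init__(self):
        n = self.header.points_per_axis
        if self.values.shape != (n, n, n):
            raise ValueError(
                f"value lattice shape {self.values.shape} does not match "
                f"header ({n} points per axis)"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid map contains non-finite values")

    @property
    def origin(self) -> np.ndarray:
        half = self.header.npts * self.header.spacing / 2.0
        return np.asarray(self.header.center, dtype=np.float64) - half

    @property
    def opposite_corner(self) -> np.ndarray:
        return self.origin + self.header.npts * self.header.spacing

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=np.float64)
        return bool(np.all(p >= self.origin) and np.all(p <= self.opposite_corner))


def interpolate(gmap: GridMap, point) -> float:
    """Trilinear interpolation of the map at a Cartesian point (Å).

    Inside the box this is the 8-corner blend of the surrounding lattice
    values (exactly the stored value at lattice points, and exact for
    affine fields).  Outside the box it returns the declared out-of-grid
    penalty constant.
    """
    p = np.asarray(point, dtype=np.float64)
    if p.shape != (3,) or not np.all(np.isfinite(p)):
        raise ValueError(f"interpolation point must be a finite 3-vector, got {point!r}")
    o = gmap.origin
    return float(
        trilinear_kernel(
            gmap.values, o[0], o[1], o[2],
            gmap.header.spacing, gmap.header.npts,
            p[0], p[1], p[2],
        )
    )


class MapCache:
    """Per-worker grid-map store with ``reuse``/``reload`` persistence.

    ``load_counter[t]`` counts file reads performed for atom type ``t``
    over the cache's lifetime; under ``reuse`` it never exceeds 1 per type.
    """

    def __init__(self, policy: str = "reuse",
                 sources: Mapping[str, os.PathLike | str] | None = None):
        if policy not in ("reuse", "reload"):
            raise ValueError(f"unknown map policy {policy!r}")
        self.policy = policy
        self.loaded: dict[str, GridMap] = {}
        self.load_counter: dict[str, int] = {}
        self.sources: dict[str, Path] = (
            {k: Path(v) for k, v in sources.items()} if sources else {}
        )

    def attach_sources(self, sources: Mapping[str, os.PathLike | str]) -> None:
        """Register (or update) the atom-type -> map-file index, e.g. from a
        grid descriptor read at the start of a docking."""
        self.sources.update({k: Path(v) for k, v in sources.items()})

    @property
    def total_reads(self) -> int:
        return sum(self.load_counter.values())

    def _read(self, atom_type: str, path: Path) -> GridMap:
        if not path.exists():
            raise MissingMapError(atom_type, f"no such file {path}")
        header, values = formats.read_map(path)
        self.load_counter[atom_type] = self.load_counter.get(atom_type, 0) + 1
        gmap = GridMap(header, values)
        self.loaded[atom_type] = gmap
        return gmap

    def get(self, atom_type: str, source: os.PathLike | str | None = None) -> GridMap:
        """Return the map for ``atom_type``, reading its file only when the
        type is not already resident."""
        if atom_type in self.loaded:
            return self.loaded[atom_type]
        path = Path(source) if source is not None else self.sources.get(atom_type)
        if path is None:
            raise MissingMapError(atom_type, "no source registered")
        return self._read(atom_type, path)

    def begin_docking(self, required_types: Iterable[str],
                      sources: Mapping[str, os.PathLike | str] | None = None) -> None:
        """Make every map a docking needs resident: the ligand's affinity
        types plus the electrostatic and desolvation maps.  Under ``reuse``
        only previously unseen types cause file reads."""
        if sources is not None:
            self.attach_sources(sources)
        for t in sorted(set(required_types)) + [ELECTROSTATIC_LABEL,
                                                DESOLVATION_LABEL]:
            self.get(t)

    def end_docking(self) -> None:
        """Called when a docking finishes; under ``reload`` the resident
        maps are dropped so the next docking re-reads its files."""
        if self.policy == "reload":
            self.loaded.clear()


def cache_get(cache: MapCache, atom_type: str,
              source: os.PathLike | str | None = None) -> GridMap:
    """Functional alias for :meth:`MapCache.get`."""
    return cache.get(atom_type, source)


def cache_begin_docking(cache: MapCache, required_types: Iterable[str],
                        sources: Mapping[str, os.PathLike | str] | None = None) -> None:
    """Functional alias for :meth:`MapCache.begin_docking`."""
    cache.begin_docking(required_types, sources)
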
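"""Shared fixtures: one toy complex (maps on disk, session-scoped) and
ligands of assorted torsion counts, all generated programmatically."""

from __future__ import annotations

import io

import pytest

import screendock as sd


@pytest.fixture(scope="session")
def toy_complex(tmp_path_factory):
    """A default toy complex with affinity maps for C, N and O plus the
    electrostatic and desolvation maps written to disk."""
    spec = sd.ToyComplexSpec()
    map_dir = tmp_path_factory.mktemp("maps")
    index = sd.make_toy_maps(spec, map_dir, atom_types=("C", "N", "O"))
    return spec, index


@pytest.fixture()
def cache(toy_complex):
    _, index = toy_complex
    return sd.MapCache("reuse", sources=index)


def parse_toy_ligand(n_atoms: int, n_torsions: int, **kw) -> sd.LigandStructure:
    spec = sd.ToyLigandSpec(n_atoms=n_atoms, n_torsions=n_torsions, **kw)
    return sd.read_pdbqt(io.StringIO(sd.make_toy_ligand(spec)))


@pytest.fixture(scope="session")
def chain_ligand() -> sd.LigandStructure:
    """Five-atom zig-zag chain with two nested torsions."""
    return parse_toy_ligand(5, 2)


@pytest.fixture(scope="session")
def rigid_ligand() -> sd.LigandStructure:
    """Three-atom rigid ligand (no rotatable bonds)."""
    return parse_toy_ligand(3, 0)


@pytest.fixture(scope="session")
def probe_ligand() -> sd.LigandStructure:
    """Single uncharged atom: its grid score is pure affinity, which makes
    exhaustive lattice enumeration an exact oracle."""
    return parse_toy_ligand(1, 0, charge_pattern="zero")
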
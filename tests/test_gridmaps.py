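"""Trilinear interpolation against an independent corner-sum oracle, and
the reuse/reload cache contracts."""

import io

import numpy as np
import pytest

import screendock as sd
from screendock.errors import MissingMapError
from screendock.gridmaps import OUT_OF_GRID_PENALTY


def _make_map(values, spacing=0.5, center=(0.0, 0.0, 0.0), atom_type="C"):
    npts = values.shape[0] - 1
    return sd.GridMap(sd.GridHeader(spacing, npts, center, atom_type),
                      np.asarray(values, dtype=np.float64))


def corner_sum_oracle(gmap, point):
    """Independent 8-corner weighted sum: weight of corner (i+dx, j+dy,
    k+dz) is prod of (1-t) or t per axis."""
    p = (np.asarray(point) - gmap.origin) / gmap.header.spacing
    base = np.minimum(np.floor(p).astype(int), gmap.header.npts - 1)
    t = p - base
    total = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = ((t[0] if dx else 1 - t[0])
                     * (t[1] if dy else 1 - t[1])
                     * (t[2] if dz else 1 - t[2]))
                total += w * gmap.values[base[0] + dx, base[1] + dy,
                                         base[2] + dz]
    return total


class TestInterpolation:
    def test_constant_map_returns_constant_everywhere(self):
        gmap = _make_map(np.full((5, 5, 5), 2.5))
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(gmap.origin, gmap.opposite_corner)
            assert sd.interpolate(gmap, p) == pytest.approx(2.5, abs=1e-12)

    def test_affine_field_reproduced_exactly(self):
        # trilinear interpolation is exact for f(x,y,z) = 2x - y + 3z
        header = sd.GridHeader(0.5, 4, (0.0, 0.0, 0.0), "C")
        n = header.points_per_axis
        axis = -1.0 + 0.5 * np.arange(n)
        gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
        gmap = sd.GridMap(header, 2 * gx - gy + 3 * gz)
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(gmap.origin, gmap.opposite_corner)
            expected = 2 * p[0] - p[1] + 3 * p[2]
            assert sd.interpolate(gmap, p) == pytest.approx(expected, abs=1e-12)

    def test_matches_corner_sum_oracle_on_random_maps(self):
        rng = np.random.default_rng(2)
        gmap = _make_map(rng.normal(size=(5, 5, 5)), spacing=0.7,
                         center=(1.0, -2.0, 0.5))
        for _ in range(50):
            p = rng.uniform(gmap.origin, gmap.opposite_corner)
            assert sd.interpolate(gmap, p) == pytest.approx(
                corner_sum_oracle(gmap, p), abs=1e-12
            )

    def test_lattice_points_return_stored_values(self):
        rng = np.random.default_rng(3)
        gmap = _make_map(rng.normal(size=(5, 5, 5)))
        for idx in [(0, 0, 0), (4, 4, 4), (1, 2, 3), (4, 0, 2)]:
            p = gmap.origin + np.array(idx) * gmap.header.spacing
            assert sd.interpolate(gmap, p) == pytest.approx(
                gmap.values[idx], abs=1e-12
            )

    def test_outside_box_scores_declared_penalty(self):
        gmap = _make_map(np.zeros((3, 3, 3)))
        assert sd.interpolate(gmap, (10.0, 0.0, 0.0)) == OUT_OF_GRID_PENALTY

    def test_non_finite_point_rejected(self):
        gmap = _make_map(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            sd.interpolate(gmap, (np.nan, 0.0, 0.0))


class TestMapCache:
    def test_reuse_policy_reads_each_type_once(self, toy_complex):
        _, index = toy_complex
        cache = sd.MapCache("reuse", sources=index)
        for _ in range(5):  # five consecutive dockings of the same ligand
            cache.begin_docking({"C"})
            cache.end_docking()
        assert cache.load_counter["C"] == 1
        assert cache.load_counter["e"] == 1

    def test_reload_policy_rereads_every_docking(self, toy_complex):
        _, index = toy_complex
        cache = sd.MapCache("reload", sources=index)
        for _ in range(5):
            cache.begin_docking({"C"})
            cache.end_docking()
        assert cache.load_counter["C"] == 5
        assert cache.load_counter["e"] == 5

    def test_screen_reads_equal_union_of_type_sets_plus_two(self, toy_complex):
        _, index = toy_complex
        cache = sd.MapCache("reuse", sources=index)
        screen = [{"C", "N"}, {"C"}, {"C", "O"}]
        for types in screen:
            cache.begin_docking(types)
            cache.end_docking()
        union = set().union(*screen)
        assert cache.total_reads == len(union) + 2 == 5

    def test_begin_docking_loads_lazily_under_reuse(self, toy_complex):
        _, index = toy_complex
        cache = sd.MapCache("reuse", sources=index)
        cache.begin_docking({"C"})
        assert cache.total_reads == 3  # C + e + d
        cache.end_docking()
        cache.begin_docking({"C"})
        assert cache.total_reads == 3  # nothing new
        cache.end_docking()
        cache.begin_docking({"C", "N"})
        assert cache.total_reads == 4  # only the previously unused N

    def test_missing_map_error_names_the_atom_type(self, toy_complex):
        _, index = toy_complex
        cache = sd.MapCache("reuse", sources=index)
        with pytest.raises(MissingMapError) as err:
            cache.begin_docking({"Zn"})
        assert err.value.atom_type == "Zn"

    def test_reuse_reads_never_exceed_reload_reads(self, toy_complex):
        # monotone containment over random screens, equality only when
        # every docking introduces exclusively unseen types
        _, index = toy_complex
        rng = np.random.default_rng(7)
        pool = ["C", "N", "O"]
        for _ in range(20):
            screen = [
                set(rng.choice(pool, size=rng.integers(1, 4), replace=False))
                for _ in range(rng.integers(1, 6))
            ]
            reuse = sd.MapCache("reuse", sources=index)
            reload_ = sd.MapCache("reload", sources=index)
            for types in screen:
                for c in (reuse, reload_):
                    c.begin_docking(types)
                    c.end_docking()
            assert reuse.total_reads <= reload_.total_reads
            seen: set[str] = set()
            only_fresh = True
            for types in screen:
                if (types | {"e", "d"}) & seen:
                    only_fresh = False
                seen |= types | {"e", "d"}
            if reuse.total_reads == reload_.total_reads:
                assert only_fresh

    def test_cache_policy_never_changes_energies(self, toy_complex,
                                                 chain_ligand):
        _, index = toy_complex
        rng = np.random.default_rng(11)
        reuse = sd.MapCache("reuse", sources=index)
        reload_ = sd.MapCache("reload", sources=index)
        for c in (reuse, reload_):
            c.begin_docking(chain_ligand.atom_types)
        for _ in range(10):
            state = sd.GenomeState(
                rng.uniform(-2, 2, 3),
                sd.conformation.quat_normalize(rng.normal(size=4)),
                rng.uniform(-180, 180, chain_ligand.n_torsions),
            )
            ea = sd.score(state, chain_ligand, reuse).total
            eb = sd.score(state, chain_ligand, reload_).total
            assert ea == eb  # bitwise: policy is I/O-only
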
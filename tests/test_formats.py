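"""Format round trips, torsion-tree parsing, and the DLG contract."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import screendock as sd
from screendock.errors import (
    FieldParseError,
    HeaderError,
    RangeError,
    StructuralParseError,
    TruncatedMapError,
)


def _atom(serial, name, x, y, z, q, t):
    return (
        f"ATOM  {serial:>5} {name:<4} LIG A   1    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00    {q:6.3f} {t}"
    )


class TestPdbqt:
    def test_root_only_ligand_has_no_torsions(self):
        text = "\n".join(
            ["ROOT", _atom(1, "C1", 0, 0, 0, 0.1, "C"),
             _atom(2, "C2", 1.2, 0.7, 0, -0.1, "C"),
             _atom(3, "C3", 2.4, 0, 0, 0.1, "C"), "ENDROOT"]
        )
        lig = sd.read_pdbqt(io.StringIO(text))
        assert lig.n_torsions == 0
        assert lig.n_atoms == 3
        assert [a.name for a in lig.atoms] == ["C1", "C2", "C3"]
        assert lig.atoms[1].charge == pytest.approx(-0.1)

    def test_single_branch_moves_exactly_its_atom(self):
        text = "\n".join(
            ["ROOT", _atom(1, "C1", 0, 0, 0, 0.1, "C"),
             _atom(2, "C2", 1.2, 0.7, 0, -0.1, "C"), "ENDROOT",
             "BRANCH 2 3", _atom(3, "C3", 2.4, 0, 0, 0.1, "C"),
             "ENDBRANCH 2 3"]
        )
        lig = sd.read_pdbqt(io.StringIO(text))
        assert lig.n_torsions == 1
        assert lig.bonds[0].moved == frozenset({2})
        assert (lig.bonds[0].a, lig.bonds[0].b) == (1, 2)

    def test_nested_branches_trace_to_hand_enumerated_moved_sets(self):
        # 6 atoms: root {1,2,3}; branch 3-4 encloses atom 4 and an inner
        # branch 4-5 enclosing atoms 5,6.  Manual trace of the nesting:
        # outer bond moves {4,5,6} (0-based {3,4,5}), inner moves {4,5}.
        text = "\n".join(
            ["ROOT",
             _atom(1, "C1", 0, 0, 0, 0.1, "C"),
             _atom(2, "C2", 1.2, 0.7, 0, -0.1, "C"),
             _atom(3, "C3", 2.4, 0, 0, 0.1, "C"),
             "ENDROOT",
             "BRANCH 3 4",
             _atom(4, "C4", 3.6, 0.7, 0, -0.1, "C"),
             "BRANCH 4 5",
             _atom(5, "C5", 4.8, 0, 0, 0.1, "C"),
             _atom(6, "C6", 6.0, 0.7, 0, -0.1, "C"),
             "ENDBRANCH 4 5",
             "ENDBRANCH 3 4"]
        )
        lig = sd.read_pdbqt(io.StringIO(text))
        assert lig.n_torsions == 2
        outer, inner = lig.bonds
        assert outer.moved == frozenset({3, 4, 5})
        assert inner.moved == frozenset({4, 5})
        assert inner.parent_group == outer.group  # depth-2 nesting
        assert lig.groups[0] == [0, 1, 2]

    def test_unbalanced_branch_raises_structural_error_with_line(self):
        text = "\n".join(
            ["ROOT", _atom(1, "C1", 0, 0, 0, 0.1, "C"), "ENDROOT",
             "BRANCH 1 2", _atom(2, "C2", 1.2, 0.7, 0, -0.1, "C")]
        )
        with pytest.raises(StructuralParseError):
            sd.read_pdbqt(io.StringIO(text))

    def test_non_numeric_charge_raises_field_error(self):
        text = "\n".join(
            ["ROOT",
             "ATOM      1 C1   LIG A   1       0.000   0.000   0.000"
             "  1.00  0.00     abc C",
             "ENDROOT"]
        )
        with pytest.raises(FieldParseError, match="charge"):
            sd.read_pdbqt(io.StringIO(text))

    @pytest.mark.parametrize("n_atoms,n_torsions",
                             [(1, 0), (3, 0), (4, 1), (6, 2), (8, 6)])
    def test_torsion_count_equals_branch_count(self, n_atoms, n_torsions):
        text = sd.make_toy_ligand(
            sd.ToyLigandSpec(n_atoms=n_atoms, n_torsions=n_torsions)
        )
        assert text.count("BRANCH") - text.count("ENDBRANCH") == n_torsions
        lig = sd.read_pdbqt(io.StringIO(text))
        assert lig.n_torsions == n_torsions

    def test_read_write_read_is_stable(self):
        text = sd.make_toy_ligand(sd.ToyLigandSpec(n_atoms=6, n_torsions=3))
        lig = sd.read_pdbqt(io.StringIO(text))
        buf = io.StringIO()
        sd.write_pdbqt(lig, buf)
        assert buf.getvalue() == text


class TestParameters:
    def test_popsize_key_overrides_default(self):
        params = sd.parse_parameters(io.StringIO("ga_popsize 150"))
        assert params.ga_popsize == 150

    def test_empty_stream_yields_documented_defaults(self):
        params = sd.parse_parameters(io.StringIO(""))
        assert params.ga_runs == 20
        assert params.ga_popsize == 150
        assert params.ga_num_evals == 250000
        assert params.ga_num_generations == 27000

    def test_last_occurrence_wins(self):
        params = sd.parse_parameters(io.StringIO("ga_runs 1\nga_runs 5"))
        assert params.ga_runs == 5

    def test_non_integer_count_raises(self):
        with pytest.raises(FieldParseError):
            sd.parse_parameters(io.StringIO("ga_runs 2.5"))

    def test_negative_count_raises(self):
        with pytest.raises(RangeError):
            sd.parse_parameters(io.StringIO("ga_num_evals -1"))

    def test_unknown_keys_preserved_not_rejected(self):
        params = sd.parse_parameters(io.StringIO("outlev 1\nga_runs 3"))
        assert params.extras == {"outlev": "1"}
        assert params.ga_runs == 3

    @given(
        runs=st.integers(1, 500),
        pop=st.integers(1, 500),
        evals=st.integers(0, 10**7),
        gens=st.integers(0, 10**5),
        ls=st.floats(0, 1, allow_nan=False),
        policy=st.sampled_from(["reuse", "reload"]),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_serialize_parse_is_idempotent(self, runs, pop, evals, gens, ls,
                                           policy):
        p = sd.DockingParameters(
            ga_runs=runs, ga_popsize=pop, ga_num_evals=evals,
            ga_num_generations=gens, ls_frequency=ls, map_policy=policy,
            rng_base_seed=42,
        )
        q = sd.parse_parameters(io.StringIO(sd.serialize_parameters(p)))
        assert q == p
        assert sd.serialize_parameters(q) == sd.serialize_parameters(p)


class TestGridMapFormat:
    def test_standard_geometry_yields_226981_values(self):
        header = sd.GridHeader(0.375, 60, (0.0, 0.0, 0.0), "C")
        assert header.points_per_axis == 61
        assert header.n_values == 226981
        values = np.zeros((61, 61, 61))
        buf = io.StringIO()
        sd.write_map(header, values, buf)
        buf.seek(0)
        h2, v2 = sd.read_map(buf)
        assert v2.size == 226981
        assert h2 == header

    def test_value_ordering_is_x_fastest(self):
        # 27 values 0..26 in file order: line index = ix + 3*iy + 9*iz
        lines = ["SPACING 0.5", "NELEMENTS 2 2 2", "CENTER 0 0 0", "TYPE C"]
        lines += [str(v) for v in range(27)]
        _, values = sd.read_map(io.StringIO("\n".join(lines)))
        assert values[1, 0, 0] == 1
        assert values[0, 0, 1] == 9
        assert values[0, 1, 0] == 3
        assert values[2, 2, 2] == 26

    def test_wrong_value_count_reports_expected_vs_found(self):
        lines = ["SPACING 0.5", "NELEMENTS 2 2 2", "CENTER 0 0 0", "TYPE C"]
        lines += ["0.0"] * 26
        with pytest.raises(TruncatedMapError) as err:
            sd.read_map(io.StringIO("\n".join(lines)))
        assert err.value.expected == 27
        assert err.value.found == 26

    def test_odd_nelements_rejected(self):
        lines = ["SPACING 0.5", "NELEMENTS 3 3 3", "CENTER 0 0 0", "TYPE C"]
        lines += ["0.0"] * 64
        with pytest.raises(HeaderError):
            sd.read_map(io.StringIO("\n".join(lines)))

    def test_header_keywords_accepted_in_any_order(self):
        lines = ["TYPE e", "CENTER 1.0 2.0 3.0", "NELEMENTS 2 2 2",
                 "SPACING 0.25"] + ["1.5"] * 27
        header, values = sd.read_map(io.StringIO("\n".join(lines)))
        assert header.atom_type == "e"
        assert header.center == (1.0, 2.0, 3.0)
        assert np.all(values == 1.5)

    @given(
        npts=st.sampled_from([2, 4]),
        seed=st.integers(0, 2**31 - 1),
        spacing=st.floats(0.1, 2.0, allow_nan=False),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_round_trip_is_identity_on_numeric_text(self, npts, seed, spacing):
        rng = np.random.default_rng(seed)
        n = npts + 1
        header = sd.GridHeader(spacing, npts, (0.0, 0.0, 0.0), "C")
        values = rng.normal(scale=10.0, size=(n, n, n))
        first = io.StringIO()
        sd.write_map(header, values, first)
        first.seek(0)
        h2, v2 = sd.read_map(first)
        second = io.StringIO()
        sd.write_map(h2, v2, second)
        assert second.getvalue() == first.getvalue()
        assert np.array_equal(v2, values)


class TestDlg:
    @staticmethod
    def _docked(tmp_path, toy_complex, runs=4, threads=1):
        spec, index = toy_complex
        cache = sd.MapCache("reuse", sources=index)
        lig = sd.read_pdbqt(
            io.StringIO(sd.make_toy_ligand(sd.ToyLigandSpec(4, 1)))
        )
        params = sd.DockingParameters(
            ga_runs=runs, ga_popsize=10, ga_num_evals=200,
            ga_num_generations=10, rng_base_seed=99,
        )
        return sd.dock(lig, params, cache, concurrency=threads, job_id="jobA")

    def test_run_sections_ordered_and_contiguous(self, tmp_path, toy_complex):
        result = self._docked(tmp_path, toy_complex, runs=4)
        buf = io.StringIO()
        sd.write_dlg(result, buf)
        text = buf.getvalue()
        markers = [ln for ln in text.splitlines() if ln.startswith("Run ")]
        assert markers == ["Run 1", "Run 2", "Run 3", "Run 4"]
        for run in result.runs:
            assert run.log_buffer in text  # emitted en bloc, uninterleaved

    def test_single_run_clusters_to_one_singleton(self, tmp_path, toy_complex):
        result = self._docked(tmp_path, toy_complex, runs=1)
        buf = io.StringIO()
        sd.write_dlg(result, buf)
        assert "cluster 1 size 1" in buf.getvalue()
        assert result.clusters == [[1]]

    def test_missing_run_log_raises(self, tmp_path, toy_complex):
        result = self._docked(tmp_path, toy_complex, runs=2)
        result.runs.pop()
        with pytest.raises(sd.formats.IncompleteResultError):
            sd.write_dlg(result, io.StringIO())
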
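"""Screen driver: job lists, ordering, accounting logs, I/O counting, and
profiling."""

import time
from pathlib import Path

import pandas as pd
import pytest

import screendock as sd
from screendock.scheduler import (
    PROFILE_COLUMNS,
    ProfileRecord,
    order_jobs,
    profile_summary,
    write_profile,
)

FAST = dict(ga_runs=2, ga_popsize=8, ga_num_evals=120, ga_num_generations=6)


def _screen(tmp_path, n_jobs, mode="replicated", seed=0, fail_jobs=(),
            **params):
    return sd.make_screen(tmp_path / "screen", n_jobs, mode=mode, seed=seed,
                          params_overrides={**FAST, **params},
                          fail_jobs=fail_jobs)


class TestJoblist:
    def test_order_preserved(self, tmp_path):
        p = tmp_path / "jobs.txt"
        p.write_text("a/one\nb/two\nc/three\n")
        assert [str(j) for j in sd.read_joblist(p)] == \
            ["a/one", "b/two", "c/three"]

    def test_blank_lines_skipped(self, tmp_path):
        p = tmp_path / "jobs.txt"
        p.write_text("a/one\n\nb/two\nc/three\n\n")
        assert len(sd.read_joblist(p)) == 3

    def test_empty_list_yields_valid_empty_report(self, tmp_path):
        p = tmp_path / "jobs.txt"
        p.write_text("")
        report = sd.run_screen(sd.ScreenConfig(joblist_path=p,
                                               output_root=tmp_path))
        assert report.submitted == report.successful == []
        assert report.failed == []
        assert (tmp_path / "submitted.log").read_text() == ""


class TestOrderJobs:
    @staticmethod
    def _jobs_with_torsions(tmp_path, counts):
        jobs = []
        for i, t in enumerate(counts):
            d = tmp_path / f"j{i}"
            d.mkdir()
            (d / "ligand.pdbqt").write_text(
                sd.make_toy_ligand(sd.ToyLigandSpec(n_atoms=8, n_torsions=t))
            )
            jobs.append(d)
        return jobs

    def test_stable_descending_torsion_sort(self, tmp_path):
        jobs = self._jobs_with_torsions(tmp_path, [2, 5, 5, 0])
        ordered, failed = order_jobs(jobs, True)
        assert failed == []
        assert [j.name for j in ordered] == ["j1", "j2", "j0", "j3"]

    def test_flag_off_is_identity(self, tmp_path):
        jobs = self._jobs_with_torsions(tmp_path, [2, 5, 0])
        ordered, _ = order_jobs(jobs, False)
        assert ordered == jobs

    def test_equal_counts_keep_input_order(self, tmp_path):
        jobs = self._jobs_with_torsions(tmp_path, [3, 3, 3])
        ordered, _ = order_jobs(jobs, True)
        assert ordered == jobs

    def test_unparseable_ligand_routed_to_failures(self, tmp_path):
        jobs = self._jobs_with_torsions(tmp_path, [1])
        bad = tmp_path / "bad"
        bad.mkdir()
        (bad / "ligand.pdbqt").write_text("ROOT\nGARBAGE\n")
        ordered, failed = order_jobs(jobs + [bad], True)
        assert ordered == jobs
        assert len(failed) == 1 and failed[0][0] == bad


class TestRunScreen:
    def test_accounting_identity_all_successful(self, tmp_path):
        joblist = _screen(tmp_path, 6)
        out = tmp_path / "out"
        report = sd.run_screen(sd.ScreenConfig(
            joblist_path=joblist, worker_count=2, base_seed=3,
            output_root=out,
        ))
        assert len(report.submitted) == 6
        assert len(report.successful) == 6
        assert report.failed == []
        report.check_accounting()
        assert len((out / "submitted.log").read_text().splitlines()) == 6
        assert len((out / "successful.log").read_text().splitlines()) == 6
        assert (out / "failed.log").read_text() == ""
        for job in report.successful:
            assert (Path(job) / "dock.dlg").exists()

    def test_missing_map_job_lands_in_failed_log_with_reason(self, tmp_path):
        joblist = _screen(tmp_path, 3, fail_jobs=(1,))
        out = tmp_path / "out"
        report = sd.run_screen(sd.ScreenConfig(
            joblist_path=joblist, base_seed=3, output_root=out,
        ))
        assert len(report.successful) == 2
        assert len(report.failed) == 1
        job, reason = report.failed[0]
        assert job.endswith("job_001")
        assert "X" in reason
        failed_lines = (out / "failed.log").read_text().splitlines()
        assert len(failed_lines) == 1
        assert "\t" in failed_lines[0]

    def test_reuse_reads_strictly_fewer_than_reload_on_shared_types(
            self, tmp_path):
        joblist = _screen(tmp_path, 6, mode="varied")
        reads = {}
        for policy in ("reuse", "reload"):
            report = sd.run_screen(sd.ScreenConfig(
                joblist_path=joblist, map_policy=policy, base_seed=3,
                output_root=tmp_path / policy,
            ))
            assert report.failed == []
            reads[policy] = report.total_map_reads
        assert reads["reuse"] < reads["reload"]

    def test_per_worker_reads_match_set_union_oracle(self, tmp_path):
        joblist = _screen(tmp_path, 9, mode="varied")
        report = sd.run_screen(sd.ScreenConfig(
            joblist_path=joblist, worker_count=2, map_policy="reuse",
            base_seed=3, output_root=tmp_path / "out",
        ))
        # independent oracle: union of ligand type sets per worker, plus
        # the electrostatic and desolvation maps
        for wid, jobs in enumerate(report.worker_assignments):
            if not jobs:
                continue
            union = set()
            for job in jobs:
                lig = sd.read_pdbqt(Path(job) / "ligand.pdbqt")
                union |= lig.atom_types
            assert sum(report.map_reads_per_worker[wid].values()) == \
                len(union) + 2

    def test_reload_reads_equal_sum_over_jobs(self, tmp_path):
        joblist = _screen(tmp_path, 6, mode="varied")
        report = sd.run_screen(sd.ScreenConfig(
            joblist_path=joblist, worker_count=2, map_policy="reload",
            base_seed=3, output_root=tmp_path / "out",
        ))
        expected = 0
        for job in report.successful:
            lig = sd.read_pdbqt(Path(job) / "ligand.pdbqt")
            expected += len(lig.atom_types) + 2
        assert report.total_map_reads == expected

    def test_twenty_job_screen_completes_on_two_workers(self, tmp_path):
        joblist = _screen(tmp_path, 20, ga_runs=1, ga_num_evals=60)
        start = time.monotonic()
        report = sd.run_screen(sd.ScreenConfig(
            joblist_path=joblist, worker_count=2, threads_per_docking=2,
            base_seed=9, output_root=tmp_path / "out",
        ))
        assert len(report.successful) == 20
        assert time.monotonic() - start < 120

    def test_result_sets_identical_across_worker_configs(self, tmp_path):
        joblist = _screen(tmp_path, 4, mode="varied")
        dlgs = []
        for workers, threads in ((1, 1), (2, 2)):
            report = sd.run_screen(sd.ScreenConfig(
                joblist_path=joblist, worker_count=workers,
                threads_per_docking=threads, base_seed=11,
                output_root=tmp_path / f"out{workers}{threads}",
            ))
            assert report.failed == []
            dlgs.append({
                Path(j).name: (Path(j) / "dock.dlg").read_bytes()
                for j in report.successful
            })
        assert dlgs[0] == dlgs[1]


class TestProfiling:
    @staticmethod
    def _record(job_id="jobs/a"):
        t0 = 100.0
        rec = ProfileRecord(job_id=job_id, dispatch_ts=t0,
                            complete_ts=t0 + 5.0, status="success")
        for i, phase in enumerate(("fld", "map", "lig", "compute", "log")):
            rec.phases[phase] = (t0 + i, t0 + i + 0.5)
        return rec

    def test_line_field_count_matches_header(self, tmp_path):
        path = tmp_path / "profile.csv"
        write_profile(self._record(), path)
        header, line = path.read_text().splitlines()
        assert len(header.split(",")) == len(PROFILE_COLUMNS)
        assert len(line.split(",")) == len(PROFILE_COLUMNS)

    def test_two_records_one_header(self, tmp_path):
        path = tmp_path / "profile.csv"
        write_profile(self._record("a"), path)
        write_profile(self._record("b"), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 3
        assert lines[0].startswith("job_id")

    def test_durations_equal_stop_minus_start(self, tmp_path):
        path = tmp_path / "profile.csv"
        write_profile(self._record(), path)
        df = pd.read_csv(path)
        for phase in ("fld", "map", "lig", "compute", "log"):
            assert df[f"{phase}_dur"].iloc[0] == pytest.approx(
                df[f"{phase}_stop"].iloc[0] - df[f"{phase}_start"].iloc[0]
            )

    def test_screen_appends_one_line_per_finished_docking(self, tmp_path):
        joblist = _screen(tmp_path, 3)
        out = tmp_path / "out"
        report = sd.run_screen(sd.ScreenConfig(
            joblist_path=joblist, base_seed=3, profiling=True,
            output_root=out,
        ))
        df = pd.read_csv(out / "profile.csv")
        assert len(df) == 3
        assert set(df["status"]) == {"success"}
        assert (df["compute_dur"] >= 0).all()

    def test_summary_has_phase_statistics(self):
        records = [self._record(str(i)) for i in range(4)]
        summary = profile_summary(records)
        assert list(summary.columns) == ["ave", "rms", "med", "max"]
        assert summary.loc["compute", "ave"] == pytest.approx(0.5)
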
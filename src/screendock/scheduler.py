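"""The screen driver: master-worker job dispatch, per-worker map caches,
the three progress logs, and per-docking profiling.

A screen is a list of docking directories.  A coordinator hands jobs to
``worker_count`` workers dynamically (a worker receives its next job when
it finishes the previous one, which load-balances heterogeneous ligands);
each worker owns a private :class:`~screendock.gridmaps.MapCache` for its
lifetime, and each docking runs its GA executions at
``threads_per_docking``-way concurrency.  The coordinator maintains three
progress logs — ``submitted.log`` appended at dispatch, ``successful.log``
and ``failed.log`` appended on completion — whose id sets always satisfy
``submitted = successful ∪ failed`` with no duplicates, whatever fails.

The default transport is an in-process worker pool; the dispatch contract
(dispatch message → work → status message) is what the architecture
defines, not the wire.

When profiling is enabled each finished docking appends one CSV line
recording start/stop/duration for its grid-descriptor (FLD), map (MAP) and
ligand (LIG) loads, the docking compute, and the log write (LOG).
"""

from __future__ import annotations

import csv
import io
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import formats
from .docking import DockingResult, dock
from .errors import ScreendockError
from .formats import read_joblist
from .gridmaps import MapCache

__all__ = [
    "ScreenConfig",
    "ProfileRecord",
    "ScreenReport",
    "read_joblist",
    "order_jobs",
    "run_screen",
    "write_profile",
    "profile_summary",
    "PROFILE_COLUMNS",
]

_PHASES = ("fld", "map", "lig", "compute", "log")

PROFILE_COLUMNS = (
    ["job_id", "dispatch_ts", "complete_ts", "status"]
    + [f"{p}_{k}" for p in _PHASES for k in ("start", "stop", "dur")]
)


@dataclass
class ScreenConfig:
    """Screen-wide settings.

    ``worker_count`` × ``threads_per_docking`` is the dial between
    many-single-threaded-workers and fewer-multithreaded-workers;
    ``map_policy`` selects grid-map persistence per worker;
    ``sort_by_torsions`` pre-orders jobs by descending ligand complexity;
    ``base_seed`` overrides each job's configured seed when given
    (an integer, or ``"time"``/None to defer to the job files).
    """

    joblist_path: str | Path
    worker_count: int = 1
    threads_per_docking: int = 1
    map_policy: str = "reuse"
    sort_by_torsions: bool = False
    profiling: bool = False
    base_seed: int | str | None = None
    output_root: str | Path | None = None
    per_job_timeout: float | None = None

    def validate(self) -> None:
        if self.worker_count < 1 or self.threads_per_docking < 1:
            raise ValueError("worker_count and threads_per_docking must be >= 1")
        if self.map_policy not in ("reuse", "reload"):
            raise ValueError(f"unknown map policy {self.map_policy!r}")


@dataclass
class ProfileRecord:
    """Per-docking timing record: wall-clock start/stop pairs per phase."""

    job_id: str
    dispatch_ts: float
    complete_ts: float = 0.0
    status: str = ""
    phases: dict[str, tuple[float, float]] = field(default_factory=dict)

    def duration(self, phase: str) -> float:
        start, stop = self.phases.get(phase, (0.0, 0.0))
        return stop - start

    def as_row(self) -> list:
        row = [self.job_id, repr(self.dispatch_ts), repr(self.complete_ts),
               self.status]
        for p in _PHASES:
            start, stop = self.phases.get(p, (0.0, 0.0))
            row += [repr(start), repr(stop), repr(stop - start)]
        return row


@dataclass
class ScreenReport:
    """Dispatch accounting plus per-job results and cache introspection.

    Invariant: ``set(submitted) == set(successful) | {id for id, _ in
    failed}`` and no id is duplicated anywhere.
    """

    submitted: list[str] = field(default_factory=list)
    successful: list[str] = field(default_factory=list)
    failed: list[tuple[str, str]] = field(default_factory=list)
    profile: list[ProfileRecord] = field(default_factory=list)
    results: dict[str, DockingResult] = field(default_factory=dict)
    map_reads_per_worker: list[dict[str, int]] = field(default_factory=list)
    worker_assignments: list[list[str]] = field(default_factory=list)

    @property
    def total_map_reads(self) -> int:
        return sum(sum(c.values()) for c in self.map_reads_per_worker)

    def check_accounting(self) -> None:
        sub = set(self.submitted)
        ok = set(self.successful)
        bad = {j for j, _ in self.failed}
        if len(sub) != len(self.submitted) or len(ok) != len(self.successful) \
                or len(bad) != len(self.failed):
            raise AssertionError("duplicate job ids in screen logs")
        if ok & bad or sub != ok | bad:
            raise AssertionError("screen accounting identity violated")


def order_jobs(jobs: Sequence[Path], sort_by_torsions: bool
               ) -> tuple[list[Path], list[tuple[Path, str]]]:
    """Optionally pre-order jobs by descending ligand torsion count.

    Stable: ties keep input order.  With the flag off this is the identity.
    Jobs whose ligand cannot be parsed are returned separately so the
    screen can route them straight to the failed log.
    """
    if not sort_by_torsions:
        return list(jobs), []
    keyed: list[tuple[int, Path]] = []
    unparseable: list[tuple[Path, str]] = []
    for job in jobs:
        try:
            lig = formats.read_pdbqt(_ligand_file(Path(job)))
            keyed.append((lig.n_torsions, job))
        except (ScreendockError, OSError) as exc:
            unparseable.append((job, f"unparseable ligand: {exc}"))
    keyed.sort(key=lambda kv: -kv[0])  # stable descending
    return [job for _, job in keyed], unparseable


def _ligand_file(job_dir: Path) -> Path:
    cand = job_dir / "ligand.pdbqt"
    if cand.exists():
        return cand
    hits = sorted(job_dir.glob("*.pdbqt"))
    if not hits:
        raise ScreendockError(f"no ligand PDBQT in {job_dir}")
    return hits[0]


def _dpf_file(job_dir: Path) -> Path:
    cand = job_dir / "dock.dpf"
    if cand.exists():
        return cand
    hits = sorted(job_dir.glob("*.dpf"))
    if not hits:
        raise ScreendockError(f"no parameter file in {job_dir}")
    return hits[0]


def _fld_file(job_dir: Path) -> Path:
    cand = job_dir / "grid.fld"
    if cand.exists():
        return cand
    hits = sorted(job_dir.glob("*.fld"))
    if not hits:
        raise ScreendockError(f"no grid descriptor in {job_dir}")
    return hits[0]


class _ProgressLogs:
    """The coordinator's three append-only progress logs."""

    def __init__(self, out_dir: Path):
        out_dir.mkdir(parents=True, exist_ok=True)
        self._lock = threading.Lock()
        self._files = {
            name: open(out_dir / f"{name}.log", "w")
            for name in ("submitted", "successful", "failed")
        }

    def submitted(self, job_id: str) -> None:
        with self._lock:
            f = self._files["submitted"]
            f.write(job_id + "\n")
            f.flush()

    def successful(self, job_id: str) -> None:
        with self._lock:
            f = self._files["successful"]
            f.write(job_id + "\n")
            f.flush()

    def failed(self, job_id: str, reason: str) -> None:
        with self._lock:
            f = self._files["failed"]
            f.write(f"{job_id}\t{reason}\n")
            f.flush()

    def close(self) -> None:
        for f in self._files.values():
            f.close()


class _ProfileWriter:
    """Appends one CSV line per finished docking; header written once."""

    def __init__(self, path: Path):
        self._lock = threading.Lock()
        self._file = open(path, "w", newline="")
        self._writer = csv.writer(self._file)
        self._writer.writerow(PROFILE_COLUMNS)
        self._file.flush()

    def write(self, record: ProfileRecord) -> None:
        with self._lock:
            self._writer.writerow(record.as_row())
            self._file.flush()

    def close(self) -> None:
        self._file.close()


def write_profile(record: ProfileRecord, sink) -> None:
    """Write one profiling record as a single CSV line (plus a header when
    the sink is empty)."""
    own = not hasattr(sink, "write")
    f = open(sink, "a", newline="") if own else sink
    try:
        writer = csv.writer(f)
        if f.tell() == 0:
            writer.writerow(PROFILE_COLUMNS)
        writer.writerow(record.as_row())
    finally:
        if own:
            f.close()


def profile_summary(records: Sequence[ProfileRecord]) -> pd.DataFrame:
    """Per-phase ave/rms/med/max duration statistics (seconds)."""
    data = {p: [r.duration(p) for r in records] for p in _PHASES}
    df = pd.DataFrame(data)
    return pd.DataFrame(
        {
            "ave": df.mean(),
            "rms": (df.pow(2).mean()) ** 0.5,
            "med": df.median(),
            "max": df.max(),
        }
    )


def _process_job(job_dir: Path, config: ScreenConfig, cache: MapCache,
                 dispatch_ts: float) -> tuple[DockingResult, ProfileRecord]:
    record = ProfileRecord(job_id=str(job_dir), dispatch_ts=dispatch_ts)

    def phase(name):
        class _Phase:
            def __enter__(self_inner):
                self_inner.start = time.time()
                return self_inner

            def __exit__(self_inner, *exc):
                record.phases[name] = (self_inner.start, time.time())
                return False

        return _Phase()

    deadline = (
        time.monotonic() + config.per_job_timeout
        if config.per_job_timeout is not None else None
    )
    with phase("fld"):
        sources = formats.read_fld(_fld_file(job_dir))
        params = formats.parse_parameters(_dpf_file(job_dir))
    if config.base_seed is not None and config.base_seed != "time":
        params = params.copy(rng_base_seed=int(config.base_seed))
    with phase("lig"):
        ligand = formats.read_pdbqt(_ligand_file(job_dir),
                                    source_id=str(job_dir))
    with phase("map"):
        cache.begin_docking(ligand.atom_types, sources)
    with phase("compute"):
        result = dock(
            ligand, params, cache,
            concurrency=config.threads_per_docking,
            job_id=str(job_dir), deadline=deadline,
        )
    with phase("log"):
        if result.status == "success":
            formats.write_dlg(result, job_dir / "dock.dlg")
    record.complete_ts = time.time()
    record.status = result.status
    return result, record


def run_screen(config: ScreenConfig) -> ScreenReport:
    """Run a complete screen and return its accounting report.

    Jobs are dispatched dynamically to the worker pool; a failing job is
    recorded in the failed log with its reason and the screen continues.
    The per-job results are bit-identical for any ``worker_count`` and
    ``threads_per_docking`` given a fixed integer base seed.
    """
    config.validate()
    jobs = read_joblist(config.joblist_path)
    out_dir = Path(config.output_root) if config.output_root is not None \
        else Path(config.joblist_path).parent
    logs = _ProgressLogs(out_dir)
    profiler = (
        _ProfileWriter(out_dir / "profile.csv") if config.profiling else None
    )
    report = ScreenReport()
    try:
        ordered, prefailed = order_jobs(jobs, config.sort_by_torsions)
        for job, reason in prefailed:
            jid = str(job)
            logs.submitted(jid)
            logs.failed(jid, reason)
            report.submitted.append(jid)
            report.failed.append((jid, reason))
        if not ordered and not prefailed:
            return report

        queue: list[Path] = list(ordered)
        dispatch_lock = threading.Lock()
        report_lock = threading.Lock()
        caches = [MapCache(policy=config.map_policy)
                  for _ in range(config.worker_count)]
        assignments: list[list[str]] = [[] for _ in range(config.worker_count)]

        def worker(wid: int) -> None:
            cache = caches[wid]
            while True:
                with dispatch_lock:
                    if not queue:
                        return
                    job = queue.pop(0)
                    jid = str(job)
                    logs.submitted(jid)
                    with report_lock:
                        report.submitted.append(jid)
                    assignments[wid].append(jid)
                dispatch_ts = time.time()
                try:
                    result, record = _process_job(
                        job, config, cache, dispatch_ts
                    )
                except (ScreendockError, OSError) as exc:
                    result = None
                    record = ProfileRecord(job_id=jid,
                                           dispatch_ts=dispatch_ts,
                                           complete_ts=time.time(),
                                           status="failure")
                    reason = str(exc)
                else:
                    reason = result.failure_reason
                with report_lock:
                    if result is not None and result.status == "success":
                        logs.successful(jid)
                        report.successful.append(jid)
                        report.results[jid] = result
                    else:
                        logs.failed(jid, reason or "unknown failure")
                        report.failed.append((jid, reason or "unknown failure"))
                        if result is not None:
                            report.results[jid] = result
                    report.profile.append(record)
                if profiler is not None:
                    profiler.write(record)

        if config.worker_count == 1:
            worker(0)
        else:
            threads = [
                threading.Thread(target=worker, args=(w,), daemon=True)
                for w in range(config.worker_count)
            ]
            for t in threads:
                t.start()
            for t in threads:
                t.join()
        report.map_reads_per_worker = [dict(c.load_counter) for c in caches]
        report.worker_assignments = [list(a) for a in assignments]
        report.check_accounting()
        return report
    finally:
        logs.close()
        if profiler is not None:
            profiler.close()
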
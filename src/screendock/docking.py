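"""One docking: independent GA runs, executed serially or concurrently,
then clustered and ranked.

A docking launches ``ga_runs`` GA executions, each seeded
``base_seed + run_index``.  Runs may execute on any number of threads; the
results are collected and ordered by run index, so the docking result —
energies, poses, logs, clustering, ranking — is bit-identical whatever the
concurrency.  Best poses are grouped by greedy leader clustering on pose
RMSD and clusters are ranked by their lowest member energy.

:func:`compare_results` implements the standard procedure for comparing
two dockings of the same complex (e.g. one produced serially and one in
parallel): the RMSD between the overall lowest-energy poses and between
the lowest-energy members of the largest clusters, taking the lesser of
the two when a result's lowest-energy pose falls outside its largest
cluster.
"""

from __future__ import annotations

import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .conformation import apply_state, rmsd
from .energy import PoseEvaluator
from .errors import JobTimeoutError, ScreendockError
from .formats import DockingParameters, LigandStructure
from .gridmaps import MapCache
from .search import RunResult, make_seed, resolve_base_seed, run_lga

__all__ = ["DockingResult", "dock", "cluster_runs", "compare_results"]


@dataclass
class DockingResult:
    """Per-docking outcome: the ordered run results, greedy RMSD clusters
    (lists of 1-based run indices, members ordered by energy), the implied
    ranking (cluster order = ascending lowest-member energy), and the
    success/failure status with partial results retained on failure."""

    job_id: str
    ligand: LigandStructure
    params: DockingParameters
    runs: list[RunResult]
    clusters: list[list[int]] = field(default_factory=list)
    status: str = "success"
    failure_reason: str = ""
    base_seed: int | None = None

    @property
    def expected_runs(self) -> int:
        return self.params.ga_runs

    def run_by_index(self, run_index: int) -> RunResult:
        for r in self.runs:
            if r.run_index == run_index:
                return r
        raise KeyError(f"no run with index {run_index}")

    @property
    def ranking(self) -> list[list[int]]:
        """Clusters ordered by ascending lowest-member energy (identical to
        ``clusters`` by construction)."""
        return self.clusters

    def lowest_energy_run(self) -> RunResult:
        return min(self.runs, key=lambda r: (r.best_energy, r.run_index))

    def largest_cluster(self) -> list[int]:
        """Largest cluster; ties broken by better (lower-energy) rank."""
        if not self.clusters:
            raise ValueError("docking has no clusters")
        best = self.clusters[0]
        for c in self.clusters[1:]:
            if len(c) > len(best):
                best = c
        return best

    def best_pose(self) -> np.ndarray:
        return apply_state(self.ligand, self.lowest_energy_run().best_state)


def cluster_runs(runs: list[RunResult], tol: float,
                 ligand: LigandStructure) -> list[list[int]]:
    """Greedy leader clustering of the runs' best poses.

    Runs are visited by ascending energy (ties broken by run index); each
    unassigned pose within ``tol`` Å RMSD of the current leader joins its
    cluster.  Returns clusters as lists of run indices, members ordered by
    energy ascending; cluster order is ascending leader energy.
    """
    if tol <= 0:
        raise ValueError("cluster tolerance must be positive")
    if not runs:
        return []
    poses = {r.run_index: apply_state(ligand, r.best_state) for r in runs}
    order = sorted(runs, key=lambda r: (r.best_energy, r.run_index))
    unassigned = [r.run_index for r in order]
    clusters: list[list[int]] = []
    while unassigned:
        leader = unassigned.pop(0)
        members = [leader]
        rest = []
        for idx in unassigned:
            if rmsd(poses[idx], poses[leader]) <= tol:
                members.append(idx)
            else:
                rest.append(idx)
        unassigned = rest
        clusters.append(members)
    return clusters


def dock(ligand: LigandStructure, params: DockingParameters, cache: MapCache,
         concurrency: int = 1, job_id: str = "",
         deadline: float | None = None) -> DockingResult:
    """Run a complete docking at the requested run concurrency.

    All required maps are made resident first, so concurrent runs never
    touch the file system.  Any run's unrecoverable error marks the docking
    failed (with the reason recorded and completed runs retained).
    ``deadline`` is an absolute ``time.monotonic()`` cutoff checked between
    runs.
    """
    if concurrency < 1:
        raise ValueError("concurrency must be >= 1")
    params.validate()
    base_seed = resolve_base_seed(params.rng_base_seed)
    try:
        cache.begin_docking(ligand.atom_types)
        evaluator = PoseEvaluator(ligand, cache)
    except ScreendockError as exc:
        cache.end_docking()
        return DockingResult(
            job_id=job_id, ligand=ligand, params=params, runs=[],
            clusters=[], status="failure", failure_reason=str(exc),
            base_seed=base_seed,
        )

    def one_run(run_index: int) -> RunResult:
        if deadline is not None and time.monotonic() > deadline:
            raise JobTimeoutError(
                f"docking {job_id!r} exceeded its wall-clock budget"
            )
        return run_lga(
            ligand, params, cache, make_seed(base_seed, run_index),
            run_index=run_index, evaluator=evaluator,
        )

    indices = range(1, params.ga_runs + 1)
    runs: list[RunResult] = []
    status, reason = "success", ""
    try:
        if concurrency == 1:
            for i in indices:
                runs.append(one_run(i))
        else:
            with ThreadPoolExecutor(max_workers=concurrency) as pool:
                futures = [pool.submit(one_run, i) for i in indices]
                collected: list[RunResult | None] = [None] * params.ga_runs
                first_error: Exception | None = None
                for i, fut in enumerate(futures):
                    try:
                        collected[i] = fut.result()
                    except Exception as exc:  # retain partial results
                        if first_error is None:
                            first_error = exc
                runs = [r for r in collected if r is not None]
                if first_error is not None:
                    raise first_error
    except ScreendockError as exc:
        status, reason = "failure", str(exc)
    finally:
        cache.end_docking()

    clusters = (
        cluster_runs(runs, params.cluster_tolerance, ligand) if runs else []
    )
    return DockingResult(
        job_id=job_id, ligand=ligand, params=params, runs=runs,
        clusters=clusters, status=status if len(runs) == params.ga_runs else "failure",
        failure_reason=reason, base_seed=base_seed,
    )


def compare_results(a: DockingResult, b: DockingResult) -> float:
    """Pairwise RMSD between two dockings of the same complex.

    Computes the RMSD between the overall lowest-energy poses of ``a`` and
    ``b`` and between the lowest-energy members of their largest clusters.
    When both results' lowest-energy pose sits inside its largest cluster
    the two values coincide; otherwise the lesser of the two is returned.
    """
    if a.ligand.n_atoms != b.ligand.n_atoms or [
        at.atom_type for at in a.ligand.atoms
    ] != [at.atom_type for at in b.ligand.atoms]:
        raise ValueError("results describe incompatible ligands")
    low_a, low_b = a.lowest_energy_run(), b.lowest_energy_run()
    rmsd_lowest = rmsd(
        apply_state(a.ligand, low_a.best_state),
        apply_state(b.ligand, low_b.best_state),
    )
    rep_a = a.run_by_index(a.largest_cluster()[0])
    rep_b = b.run_by_index(b.largest_cluster()[0])
    rmsd_cluster = rmsd(
        apply_state(a.ligand, rep_a.best_state),
        apply_state(b.ligand, rep_b.best_state),
    )
    coincide = (
        low_a.run_index in a.largest_cluster()
        and low_b.run_index in b.largest_cluster()
    )
    if coincide:
        return rmsd_lowest
    return min(rmsd_lowest, rmsd_cluster)
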
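# Methods

## Scope and model

`screendock` implements the architecture of a multilevel-parallel virtual
screen — master–worker job dispatch, per-worker persistent grid-map
caches, and thread-parallel execution of the independent LGA runs inside
one docking — around a deliberately simplified docking engine. The package
is about the *parallel machinery and its correctness properties*
(serial ≡ parallel output, I/O reduction under map reuse, complete
dispatch accounting, contiguous logs), not about scoring fidelity: no
claim of chemical realism is made for the energy model, and acceptance of
the package rests on structural/policy properties, not on reproducing any
particular binding energy.

## Pose model and geometry

A pose is a genome `(t, q, θ_1..θ_T)`: the Cartesian position `t` of the
root rigid group's centroid (Å), a unit quaternion `q` (w, x, y, z) for
rigid-body orientation, and one torsion angle per rotatable bond, in
degrees in (−180, 180]. Torsion genes are *relative to the input
conformation*: the identity genome (input centroid, identity quaternion,
zero torsions) reproduces the input coordinates exactly. Torsions are
applied in tree order from the root outward, each rotating its moved-set
about the current proximal→distal bond axis by the right-hand rule; the
rigid-body rotation about the root centroid and the translation follow.
Every genetic operator renormalizes the quaternion; conversion between
genome vectors and states never renormalizes, so a stored genome re-scores
to exactly (bitwise) its recorded energy.

Pose RMSD is the plain per-atom root-mean-square deviation in the shared
receptor frame — no superposition (all poses of one complex live in one
grid frame) and no symmetry correction. Both are declared choices; a
symmetry-corrected RMSD would only lower reported values.

## Energy model

* **Intermolecular**: `Σ_i M_type(i)(x_i) + q_i·M_e(x_i) + |q_i|·M_d(x_i)`
  over ligand atoms, each map trilinearly interpolated on its cubic
  lattice (spacing default 0.375 Å). A pose atom outside the grid box
  contributes a fixed penalty of **+1e5 kcal/mol once** (rather than
  clamping to the boundary); this keeps the GA inside the box and is
  exposed as `OUT_OF_GRID_PENALTY`. Interpolation at a lattice point
  returns the stored value exactly, and trilinear interpolation reproduces
  affine fields exactly — both are test oracles.
* **Internal**: `Σ 4ε[(σ/r)¹² − (σ/r)⁶] + 332.0636·q_i q_j/(4r·r)` over
  *eligible* pairs — atoms ≥ 3 bonds apart **and** in different rigid
  groups — with distance-dependent dielectric ε(r) = 4r and a 0.01 Å
  distance floor. Defaults ε = 0.1 kcal/mol, σ = 3.4 Å for all type pairs,
  overridable per unordered type pair via an optional table. A rigid
  ligand therefore has internal energy exactly 0, and the term only shapes
  the torsional search. Bonds are inferred from the input geometry with a
  1.9 Å covalent cutoff plus the declared rotatable bonds (PDBQT carries
  no bond table).

One **energy evaluation** — the budget unit of `ga_num_evals` — is one
full-pose score (intermolecular + internal). Scoring is a pure function of
(genome, ligand, map contents): cache policy, thread count and call order
never change any returned value, which is what makes bitwise
serial/parallel equality a meaningful test surface.

## Search

Each docking runs `ga_runs` independent LGA executions. One run:

* population of `ga_popsize` genomes, initialized uniformly — translation
  in the grid box, orientation uniform on the quaternion sphere (normalized
  4-D Gaussian), torsions uniform in (−180, 180];
* per generation: rank-proportional selection (weight `N − rank + 1`),
  two-point crossover at gene boundaries (rate 0.8; the quaternion is one
  gene and is never split), per-gene Cauchy mutation (rate 0.02; scales
  2.0 Å translation, 0.2 rad quaternion via axis-angle composition, 30°
  torsion), elitism of one;
* Solis–Wets local search applied to each individual with probability
  `ls_frequency` (default 0.06), capped at 300 evaluations per invocation
  and at the remaining run budget, with the improved genome written back
  (Lamarckian inheritance). The walk lives in a local delta space
  (translation offset, rotation vector, torsion offsets; gene scales
  1.0 Å / 0.3 rad / 15°) around the current genome, proposes
  `x + bias + N(0, ρ·scale)`, accepts only improvements with bias update
  `b ← 0.2b + 0.4·step` (halved on failure), doubles ρ after 4 consecutive
  successes, halves it after 4 failures, and stops at ρ < 0.01 or budget
  exhaustion — single-sided (no reflected second candidate), a declared
  simplification;
* termination when `evals_used ≥ ga_num_evals` or
  `generations_done ≥ ga_num_generations`; the final generation may
  overshoot the evaluation budget by at most one population
  (`evals_used ≤ ga_num_evals + ga_popsize`), which is the documented
  slack. With `ga_num_generations = 0` the result is the best of the
  initial population.

Operator rates follow AutoDock 4.2's documented defaults; all rates and
scales are config-exposed (`GAConfig`, `DockingParameters`).

### Seeding and determinism

Each run draws from an independent PCG64 stream seeded
`base_seed + run_index` — injective in the run index, so concurrent runs
never share a stream. Seeding the *run* rather than the *thread* is the
package's one deliberate strengthening of the usual time+thread-ID scheme:
it preserves the uniqueness that scheme exists for, and additionally makes
every run a pure function of its inputs, so "parallel output is
substantially similar to serial" becomes exact byte equality, testable
with `==`. A `base_seed` of `"time"` samples the wall clock once per
docking and then behaves identically. All run log lines are accumulated in
memory and surrendered with the result (never emitted mid-run), so logs
from concurrent runs cannot interleave; the DLG writer emits sections in
run-index order.

## Clustering, ranking, comparison

Best poses are grouped by greedy leader clustering: visiting runs by
ascending energy (ties → lower run index), the lowest unassigned pose
seeds a cluster and absorbs every unassigned pose within
`cluster_tolerance` (default 2.0 Å, AutoDock's documented default).
Clusters are ordered (= ranked) by their lowest member energy. Two
dockings of the same complex are compared by the RMSD between their
overall-lowest-energy poses and between the lowest-energy members of their
largest clusters (size ties → better rank); when either result's lowest
pose is not in its largest cluster the lesser of the two values is used.

## Scheduler

The coordinator reads the job list, optionally pre-orders it by descending
ligand torsion count (stable sort; a load-balance heuristic for
heterogeneous libraries), and hands jobs to `worker_count` workers
dynamically — a worker takes its next job when it finishes the previous
one. The three progress logs are appended under a lock: `submitted` at
dispatch, `successful`/`failed` at completion, failed lines carrying a
tab-separated reason. Any package-level error in a job (missing map file,
malformed ligand, timeout) marks that job failed and the screen continues;
the accounting identity `submitted = successful ∪ failed` (disjoint, no
duplicates) is asserted on every report. The default transport is an
in-process thread pool; the dispatch contract (dispatch → work → status
message) is the module surface, and no message-passing transport is
bundled. Jobs always complete because run budgets are finite; the optional
per-job timeout is checked cooperatively between GA runs.

Profiling, when enabled, appends one CSV line per finished docking with
wall-clock start/stop/duration for five phases — grid-descriptor load
(FLD), map loads (MAP), ligand load (LIG), docking compute, and log write
(LOG) — plus dispatch/completion stamps. `profile_summary` computes
ave/rms/med/max per phase; these are hardware-dependent observables and
are never used as correctness criteria.

## Synthetic fixtures

The generator manufactures complete screens. Toy receptors are four point
atoms (charges ±0.3 e) placed at ±6 Å on the x and y axes — outside the
default 7.5 Å box, so their Lennard-Jones walls rise toward the ±x/±y box
faces. Affinity maps are the receptor LJ sum (clamped at ±1e3 kcal/mol to
keep the text finite) **plus a constructed Gaussian funnel** (depth
10 kcal/mol, width 3 Å) and harmonic confinement (0.1 kcal/mol/Å²) centred
on `well_center`; the electrostatic map uses the same ε(r) = 4r Coulomb
form and the desolvation map a smooth Gaussian occupancy. With
`well_center` on a lattice point, the lattice argmin of a single-atom
probe's energy is exactly that point, and — because a trilinear
interpolant attains its extrema over each cell at the cell's corners — the
interpolated landscape's global minimum is the same point. That gives the
search a known answer: single-well recovery is the synthetic analogue of
re-docking a known complex.

Toy ligands are zig-zag chains (bond ≈ 1.37 Å, second neighbours ≈ 2.3 Å,
so distance-based bond inference is unambiguous) with the requested number
of nested terminal torsions, alternating ±0.1 e charges, and types cycling
through a declared set. Varied-mode screens cycle type sets
{C} → {C,N} → {C,N,O} to exercise lazy map loading; replicated-mode
screens write the identical ligand into every job. Grids default to 20
intervals (21³ points) at 0.375 Å for speed; the standard 60-interval
geometry is exercised in the format tests (61³ = 226 981 values).

What the fixtures do **not** emulate: chemically meaningful geometry or
charges, receptor flexibility, the full AutoDock free-energy model
(desolvation volumes, directional hydrogen bonds, torsional entropy), or
realistic map roughness. Passing tests therefore demonstrate the
correctness of the parallel architecture, caching, formats, search
mechanics and reproducibility — not docking accuracy on real complexes.

## Numerical and implementation choices

* Grid values are stored `[ix, iy, iz]` with file order x-fastest
  (z-slowest), the AutoDock map convention; the canonical writer emits
  `repr()` of each float, so write→read→write is byte-stable.
* The map cache treats the electrostatic ("e") and desolvation ("d") maps
  exactly like affinity maps under the reserved labels; its lifetime is
  one worker, and `reload` empties it after every docking.
* Energy ties in selection, clustering and ranking are broken by lower run
  index; "largest cluster" ties by better rank — all orderings are total,
  so results are fully deterministic.
* The hot kernels (state application, trilinear interpolation, pair sums)
  are compiled with numba in nopython mode without fastmath, preserving
  IEEE semantics so results are bit-reproducible across thread counts;
  kernels release the GIL so concurrent runs overlap.
* Problem sizes in the test-suite and acceptance script (10-job screens,
  populations of 50, budgets of 10–25 k evaluations, 21³ grids) are the
  package's declared desk-scale study conditions: large enough for every
  architectural property to be exercised, small enough to run everywhere.

## Known limitations

* The DLG dialect is this package's own declared grammar (stable section
  markers, run order, clustering/ranking blocks) — not byte-compatible
  with AutoDock 4.2 logs.
* PDBQT writing emits the torsion tree depth-first; files whose root-group
  atoms interleave textually with branch blocks parse correctly but do not
  round-trip byte-identically.
* No simulated-annealing / pure-GA / pure-LS search modes; no
  symmetry-corrected RMSD; no checkpoint/restart of interrupted screens;
  failed jobs are recorded and not redispatched.
* Under CPython the in-process workers share the GIL; concurrency here
  buys architecture testing (and some overlap in the GIL-releasing
  kernels), not linear speedup.
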
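# screendock

Master–worker virtual screening at desk scale, built around a
self-contained grid-map docking engine.

## What this is

Virtual screening docks a library of small molecules against one receptor:
each *docking* runs a number of independent Lamarckian-genetic-algorithm
(LGA) searches over a ligand's pose — translation, rigid-body orientation
quaternion, and one angle per rotatable bond — scoring poses against
precomputed per-atom-type grid maps by trilinear interpolation, then
clusters and ranks the per-run best poses by RMSD. Screens of thousands of
ligands are embarrassingly parallel but have two classic systems problems:
grid-map loading dominates file I/O when every docking reloads the same
maps, and naively multithreading the LGA scrambles seeds and log files.

`screendock` implements the standard architecture for this workload so its
correctness properties can be tested end-to-end on synthetic fixtures:

* a **coordinator** dispatches docking directories from an ASCII job list
  to a pool of workers dynamically, maintaining three progress logs
  (`submitted.log`, `successful.log`, `failed.log`) whose id sets always
  satisfy `submitted = successful ∪ failed`;
* each worker owns a **persistent grid-map cache**: under the `reuse`
  policy a map is read once per worker lifetime and maps for previously
  unused atom types are loaded lazily, so a worker's total file reads
  equal `|union of its ligands' type sets| + 2` (electrostatic +
  desolvation) instead of `Σ(|types| + 2)` under `reload`;
* each docking runs its `ga_runs` LGA executions **concurrently**, with
  run seeds derived as `base_seed + run_index` and per-run buffered logs
  written en bloc — so the complete output (energies, poses, logs,
  clustering, ranking) is *bit-identical* for any worker/thread count;
* a **synthetic-fixture generator** manufactures toy receptors, analytic
  grid maps with a constructed global minimum, and PDBQT ligands with 0–6
  torsions, so nothing external is ever downloaded.

The scoring function is a declared simplification: grid intermolecular
term `Σ_i M_type(i)(x_i) + q_i·M_e(x_i) + |q_i|·M_d(x_i)` plus a 12-6
Lennard-Jones/Coulomb internal term over nonbonded pairs. See
`docs/methods.md` for the model, parameters and their defaults.

## Worked example

Generate a 6-job screen of varied toy ligands and run it on one worker
with two threads per docking:

```bash
screendock make-fixtures --out demo --jobs 6 --mode varied --seed 7
screendock screen --joblist demo/joblist.txt --workers 1 --threads 2 \
    --maps reuse --seed 7 --out demo/logs --profile
```

which prints

```
wrote 6 jobs; joblist at demo/joblist.txt
submitted 6  successful 6  failed 0  map reads 5
```

Six dockings were submitted and succeeded; the worker performed five
map-file reads in total — the three affinity types `{C, N, O}` introduced
across the varied ligands plus the shared electrostatic and desolvation
maps, rather than the 24 reads the same screen costs under `--maps
reload` (each docking re-reading its own types plus the two shared maps).
Each job directory now holds a `dock.dlg` log with one contiguous
section per GA run followed by the clustering and ranking; `demo/logs`
holds the three progress logs and `profile.csv` with per-phase (grid
descriptor, maps, ligand, compute, log-write) timings, one line per
docking. Re-running with `--workers 1 --threads 1` and the same seed
reproduces every `dock.dlg` byte for byte.

The same pipeline is available as a library:

```python
import screendock as sd

joblist = sd.make_screen("demo2", 6, mode="varied", seed=7)
report = sd.run_screen(sd.ScreenConfig(joblist_path=joblist,
                                       worker_count=1, base_seed=7))
print(len(report.successful), report.total_map_reads)   # 6 5
```

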
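"""The Lamarckian genetic algorithm and Solis-Wets local search.

One GA *run* is the unit of work that a docking parallelizes: an
independent population evolved under proportional selection, two-point
crossover at gene boundaries, per-gene Cauchy mutation, single-individual
elitism, and Solis-Wets local search applied with probability
``ls_frequency`` per individual per generation, with the locally improved
genome written back into the population (the "Lamarckian" inheritance).
A run terminates when it has spent its energy-evaluation budget
(``ga_num_evals``, with up to one population of final-generation slack) or
its generation budget (``ga_num_generations``), whichever comes first.

Every run draws from its own seeded 64-bit PCG64 stream, with the run seed
derived as ``base_seed + run_index``.  Per-run seeding (rather than
per-thread) makes each run a pure function of its inputs: results are
bit-identical whatever the thread or worker count, which upgrades
"parallel output is substantially similar to serial" into an exact-equality
test surface.

All log lines are accumulated in an in-memory buffer and surrendered with
the result, never emitted during execution, so concurrent runs can never
interleave their log text.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from ._kernels import apply_delta_kernel
from .conformation import (
    GenomeState,
    quat_from_axis_angle,
    quat_multiply,
    quat_normalize,
    random_unit_quaternion,
    wrap_angle,
)
from .energy import PoseEvaluator
from .errors import ParameterError
from .formats import DockingParameters, LigandStructure
from .gridmaps import MapCache

__all__ = [
    "RunResult",
    "RngStream",
    "make_seed",
    "resolve_base_seed",
    "solis_wets_vector",
    "solis_wets",
    "run_lga",
    "GAConfig",
]

# GA operator rates (AutoDock 4.2 defaults) and declared mutation /
# local-search step scales.  All overridable through GAConfig.
CROSSOVER_RATE = 0.8
MUTATION_RATE = 0.02
ELITISM = 1
CAUCHY_TRANSLATION_SCALE = 2.0  # Å
CAUCHY_QUATERNION_SCALE = 0.2  # radians, axis-angle perturbation
CAUCHY_TORSION_SCALE = 30.0  # degrees
SW_TRANSLATION_SCALE = 1.0  # Å, Solis-Wets gaussian step per rho unit
SW_ROTATION_SCALE = 0.3  # radians
SW_TORSION_SCALE = 15.0  # degrees
SW_RHO_START = 1.0
SW_RHO_MIN = 0.01
SW_STREAK = 4  # consecutive successes/failures before rho doubles/halves
SW_MAX_ITS = 300  # per-invocation evaluation cap


@dataclass
class GAConfig:
    """Operator rates and step scales; defaults mirror the module constants."""

    crossover_rate: float = CROSSOVER_RATE
    mutation_rate: float = MUTATION_RATE
    cauchy_translation: float = CAUCHY_TRANSLATION_SCALE
    cauchy_quaternion: float = CAUCHY_QUATERNION_SCALE
    cauchy_torsion: float = CAUCHY_TORSION_SCALE
    sw_max_its: int = SW_MAX_ITS


@dataclass
class RunResult:
    """Outcome of one GA run: the best pose found, its energy, the budgets
    actually spent, and the fully buffered per-generation log."""

    run_index: int
    seed: int
    best_state: GenomeState
    best_energy: float
    generations_done: int
    evals_used: int
    log_buffer: str


class RngStream:
    """An independent, portable 64-bit random stream (PCG64): identical
    seeds give identical draw sequences on every platform and under every
    thread count."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        self.generator = np.random.Generator(np.random.PCG64(self.seed))

    def __getattr__(self, name):
        return getattr(self.generator, name)


def make_seed(base_seed: int, run_index: int) -> int:
    """Seed for one GA run: ``base_seed + run_index`` — injective in the
    run index, so concurrent runs never share a stream."""
    if run_index < 1:
        raise ValueError("run_index is 1-based")
    return int(base_seed) + int(run_index)


def resolve_base_seed(configured: int | str | None) -> int:
    """Turn the configured base seed into a concrete integer, sampling the
    wall clock once when the configuration says ``"time"``."""
    if configured is None or configured == "time":
        return int(time.time() * 1000) & 0x7FFFFFFF
    return int(configured)


# ---------------------------------------------------------------------------
# Solis-Wets local search
# ---------------------------------------------------------------------------


def solis_wets_vector(x0, f, rng, budget: int, scales=None, f0=None,
                      rho: float = SW_RHO_START, rho_min: float = SW_RHO_MIN,
                      streak: int = SW_STREAK):
    """Adaptive random-walk minimization of ``f`` over a flat vector.

    Each step proposes ``x + bias + N(0, rho * scales)`` and accepts only
    improvements, updating the bias vector towards accepted moves.  The
    step size ``rho`` doubles after ``streak`` consecutive successes and
    halves after ``streak`` consecutive failures; the walk stops when
    ``rho`` falls below ``rho_min`` or the evaluation ``budget`` is spent.
    Returns ``(x_best, f_best, evals_used)`` with ``f_best <= f(x0)``.
    """
    x = np.asarray(x0, dtype=np.float64).copy()
    n = x.size
    scales = (np.ones(n) if scales is None
              else np.asarray(scales, dtype=np.float64))
    if f0 is None:
        if budget <= 0:
            return x, None, 0
        fx = f(x)
        evals = 1
    else:
        fx = f0
        evals = 0
    bias = np.zeros(n)
    successes = 0
    failures = 0
    while evals < budget and rho >= rho_min:
        dev = rng.normal(0.0, 1.0, n) * scales * rho
        cand = x + bias + dev
        fc = f(cand)
        evals += 1
        if fc < fx:
            step = cand - x
            x = cand
            fx = fc
            bias = 0.2 * bias + 0.4 * step
            successes += 1
            failures = 0
            if successes >= streak:
                rho *= 2.0
                successes = 0
        else:
            bias *= 0.5
            failures += 1
            successes = 0
            if failures >= streak:
                rho *= 0.5
                failures = 0
    return x, fx, evals


def _delta_scales(n_torsions: int) -> np.ndarray:
    return np.concatenate([
        np.full(3, SW_TRANSLATION_SCALE),
        np.full(3, SW_ROTATION_SCALE),
        np.full(n_torsions, SW_TORSION_SCALE),
    ])


def _apply_delta(vec: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Perturb a genome vector by a local-search delta
    ``[dt(3), rotation-vector(3), dtorsions(T)]``."""
    out = np.empty_like(vec)
    apply_delta_kernel(vec, np.ascontiguousarray(delta), out)
    return out


def solis_wets(state: GenomeState, score_fn, rng, budget: int,
               f0: float | None = None):
    """Solis-Wets over a genome: the walk lives in a local delta space
    (translation offset, rotation vector, torsion offsets) around the
    start state, so the quaternion stays exactly unit-norm.

    ``score_fn(state) -> energy``.  Returns ``(state, energy, evals)``
    with energy <= the start energy.
    """
    n_tor = len(state.torsions)
    vec = state.to_vector()

    def f(delta):
        return score_fn(GenomeState.from_vector(_apply_delta(vec, delta)))

    delta0 = np.zeros(6 + n_tor)
    best_delta, fx, evals = solis_wets_vector(
        delta0, f, rng, budget, scales=_delta_scales(n_tor), f0=f0
    )
    if fx is None:  # zero budget and unknown start energy
        return state, f0, 0
    return GenomeState.from_vector(_apply_delta(vec, best_delta)), fx, evals


# ---------------------------------------------------------------------------
# The Lamarckian GA
# ---------------------------------------------------------------------------


def _initial_population(rng, popsize: int, n_torsions: int,
                        box_low, box_high) -> np.ndarray:
    pop = np.empty((popsize, 7 + n_torsions))
    for i in range(popsize):
        pop[i, 0:3] = rng.uniform(box_low, box_high)
        pop[i, 3:7] = random_unit_quaternion(rng)
        if n_torsions:
            pop[i, 7:] = rng.uniform(-180.0, 180.0, n_torsions)
    if n_torsions:
        pop[:, 7:] = wrap_angle(pop[:, 7:])
    return pop


def _gene_boundaries(n_torsions: int) -> list[int]:
    # genes: tx | ty | tz | quaternion(4) | one per torsion
    bounds = [0, 1, 2, 3, 7]
    bounds += [8 + t for t in range(n_torsions)]
    return bounds


def _mutate(vec: np.ndarray, rng, cfg: GAConfig) -> None:
    n_genes = 4 + (vec.size - 7)
    for g in range(n_genes):
        if rng.random() >= cfg.mutation_rate:
            continue
        draw = rng.standard_cauchy()
        if g < 3:
            vec[g] += cfg.cauchy_translation * draw
        elif g == 3:
            axis = rng.normal(size=3)
            dq = quat_from_axis_angle(axis, cfg.cauchy_quaternion * draw)
            vec[3:7] = quat_normalize(quat_multiply(dq, vec[3:7]))
        else:
            t = 7 + (g - 4)
            vec[t] = wrap_angle(vec[t] + cfg.cauchy_torsion * draw)


def run_lga(ligand: LigandStructure, params: DockingParameters,
            cache: MapCache, seed: int, run_index: int = 1,
            evaluator: PoseEvaluator | None = None,
            ga_config: GAConfig | None = None) -> RunResult:
    """Execute one GA run and return its fully materialized result.

    The result is a pure function of (ligand, params, map contents, seed):
    repeated execution — under any concurrency — reproduces the identical
    best state, energy, and log buffer byte for byte.
    """
    params.validate()
    if params.ga_popsize < 1:
        raise ParameterError("population size must be >= 1")
    cfg = ga_config or GAConfig()
    ev = evaluator.sibling() if evaluator is not None else PoseEvaluator(ligand, cache)
    rng = RngStream(seed)
    popsize = params.ga_popsize
    n_tor = ligand.n_torsions
    evals_budget = params.ga_num_evals
    gens_budget = params.ga_num_generations
    n_genes_vec = 7 + n_tor
    bounds = _gene_boundaries(n_tor)
    n_genes = len(bounds) - 1

    log: list[str] = []
    pop = _initial_population(rng, popsize, n_tor, ev.box_low, ev.box_high)
    energies = ev.score_population(pop)
    gens = 0
    best_i = int(np.argmin(energies))
    log.append(
        f"gen 0 evals {ev.counter.count} best {energies[best_i]:.6f} "
        f"mean {float(np.mean(energies)):.6f}"
    )

    while ev.counter.count < evals_budget and gens < gens_budget:
        # elitism: the best individual survives unchanged
        order = np.argsort(energies, kind="stable")
        elite_vec = pop[order[0]].copy()
        elite_energy = energies[order[0]]
        # rank-proportional selection weights (best rank -> largest weight)
        probs = np.empty(popsize)
        for r, idx in enumerate(order):
            probs[idx] = popsize - r
        probs /= probs.sum()
        children = np.empty((popsize - ELITISM, n_genes_vec))
        k = 0
        while k < popsize - ELITISM:
            p1, p2 = rng.choice(popsize, size=2, p=probs)
            c1 = pop[p1].copy()
            c2 = pop[p2].copy()
            if rng.random() < cfg.crossover_rate:
                cut = np.sort(rng.integers(0, n_genes + 1, size=2))
                lo, hi = bounds[cut[0]], bounds[cut[1]]
                c1[lo:hi], c2[lo:hi] = c2[lo:hi].copy(), c1[lo:hi].copy()
            for child in (c1, c2):
                if k >= popsize - ELITISM:
                    break
                _mutate(child, rng, cfg)
                child[3:7] = quat_normalize(child[3:7])
                children[k] = child
                k += 1
        child_energies = ev.score_population(children)
        pop = np.vstack([elite_vec[None, :], children])
        energies = np.concatenate([[elite_energy], child_energies])
        # Lamarckian local search with write-back of improved genomes
        if params.ls_frequency > 0.0:
            for i in range(popsize):
                if rng.random() >= params.ls_frequency:
                    continue
                remaining = evals_budget - ev.counter.count
                if remaining <= 0:
                    break
                ls_budget = min(cfg.sw_max_its, remaining)
                delta0 = np.zeros(6 + n_tor)
                base_vec = pop[i].copy()

                def f(delta, _v=base_vec):
                    return ev.score_total(_apply_delta(_v, delta))

                best_delta, fx, _ = solis_wets_vector(
                    delta0, f, rng, ls_budget,
                    scales=_delta_scales(n_tor), f0=energies[i],
                )
                if fx < energies[i]:
                    pop[i] = _apply_delta(base_vec, best_delta)
                    energies[i] = fx
        gens += 1
        best_i = int(np.argmin(energies))
        log.append(
            f"gen {gens} evals {ev.counter.count} "
            f"best {energies[best_i]:.6f} "
            f"mean {float(np.mean(energies)):.6f}"
        )

    best_i = int(np.argmin(energies))
    best_state = GenomeState.from_vector(pop[best_i])
    return RunResult(
        run_index=run_index,
        seed=seed,
        best_state=best_state,
        best_energy=float(energies[best_i]),
        generations_done=gens,
        evals_used=ev.counter.count,
        log_buffer="\n".join(log) + "\n",
    )
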
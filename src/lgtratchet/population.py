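"""Generational life cycle of the haploid Wright-Fisher population with LGT.

Each generation applies, in the default ("methods") order:

1. **selection** — N offspring are sampled with replacement from the current
   generation, with probability proportional to fitness;
2. **mutation** — each offspring gains ``n ~ Poisson(U)`` new deleterious
   mutations at uniformly random loci (multi-hit loci allowed);
3. **lateral gene transfer** — each offspring independently, with probability
   ``lambda_lgt``, picks a random donor from the *previous* generation's
   end-of-life genomes (the environmental DNA pool, which persists exactly one
   generation) and copies the donor's alleles over ``L`` contiguous loci of
   the circular genome, starting at a uniformly random locus. An LGT event can
   raise or lower the recipient's mutation load.

The alternative ``"figure1"`` ordering runs LGT -> mutation -> selection
within each cycle. Under both orderings, per-generation statistics are taken
at the end of the cycle, after the new generation has completed recombination,
so that per-locus fixation is irreversible once observed (donors for the next
generation are drawn from the very genomes just measured).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ExtinctionError, ParameterError
from .fitness import FitnessModel, compute_fitness
from .params import SimulationParams
from .statistics import FixationTracker, GenerationStats, llc_size

__all__ = [
    "PopulationState", "init_population", "selection_step", "mutation_step",
    "lgt_step", "segment_loci", "advance_generation", "simulate", "SimulationResult",
]


@dataclass
class PopulationState:
    """Mutation counts of every individual plus the generation index.

    ``counts[j, i]`` is the number of deleterious mutations at locus ``i`` of
    individual ``j``; all entries are non-negative and the matrix shape never
    changes during a run.
    """

    counts: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ParameterError("counts: expected an N x g matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            raise ParameterError("counts: mutation counts must be integers")
        if counts.size and counts.min() < 0:
            raise ParameterError("counts: mutation counts must be non-negative")
        self.counts = counts

    @property
    def N(self) -> int:
        return self.counts.shape[0]

    @property
    def g(self) -> int:
        return self.counts.shape[1]

    def load(self) -> np.ndarray:
        """Total mutation count of each individual (row sums)."""
        return self.counts.sum(axis=1)

    def copy(self) -> "PopulationState":
        return PopulationState(self.counts.copy(), self.generation)


def init_population(params: SimulationParams) -> PopulationState:
    """All-zero population at generation 0 (started free of mutation)."""
    return PopulationState(np.zeros((params.N, params.g), dtype=np.int64), generation=0)


def selection_step(state: PopulationState, fitness: np.ndarray,
                   rng: np.random.Generator) -> PopulationState:
    """Fitness-proportional multinomial resampling of N offspring.

    Each offspring row is an independent copy of a parent row drawn with
    probability ``fitness_j / sum(fitness)``. The parent matrix is left
    unmodified (it becomes the eDNA donor pool). Raises
    :class:`ExtinctionError` if every fitness is zero.
    """
    fitness = np.asarray(fitness, dtype=float)
    if fitness.shape != (state.N,):
        raise ParameterError(
            f"fitness: expected shape ({state.N},), got {fitness.shape}")
    if np.any(fitness < 0):
        raise ParameterError("fitness: values must be non-negative")
    total = fitness.sum()
    if total <= 0.0:
        raise ExtinctionError(generation=state.generation)
    parents = rng.choice(state.N, size=state.N, p=fitness / total)
    return PopulationState(state.counts[parents].copy(), state.generation + 1)


def mutation_step(state: PopulationState, params: SimulationParams,
                  rng: np.random.Generator) -> PopulationState:
    """Poisson mutation: individual ``j`` gains ``n_j ~ Poisson(U)`` mutations
    at uniformly random loci (with replacement, so one locus may be hit more
    than once). No entry ever decreases."""
    counts = state.counts.copy()
    if params.U > 0:
        n_new = rng.poisson(params.U, size=state.N)
        total = int(n_new.sum())
        if total:
            rows = np.repeat(np.arange(state.N), n_new)
            cols = rng.integers(0, state.g, size=total)
            np.add.at(counts, (rows, cols), 1)
    return PopulationState(counts, state.generation)


def segment_loci(start: int, L: int, g: int) -> np.ndarray:
    """Locus indices of the length-``L`` segment starting at ``start`` on a
    circular genome of ``g`` loci (0-based, wrapping ``g-1 -> 0``)."""
    if not 1 <= L <= g:
        raise ParameterError(f"L: segment length {L} outside [1, g={g}]")
    return (start + np.arange(L)) % g


def lgt_step(state: PopulationState, donor_pool: PopulationState,
             params: SimulationParams, rng: np.random.Generator) -> PopulationState:
    """Segmental lateral gene transfer from the previous generation's genomes.

    Each recipient independently undergoes at most one event with probability
    ``lambda_lgt``; on an event a donor row is drawn uniformly from
    ``donor_pool``, a start locus uniformly from the circular genome, and the
    ``L`` contiguous loci from there are copied donor -> recipient at the same
    coordinates (homologous recombination, no translocation).
    """
    if donor_pool.g != state.g:
        raise ParameterError(
            f"donor_pool: genome size {donor_pool.g} does not match recipients ({state.g})")
    if donor_pool.N < 1:
        raise ParameterError("donor_pool: empty donor pool")
    if params.L > state.g:
        raise ParameterError(f"L: recombination length {params.L} exceeds g={state.g}")
    if params.lambda_lgt == 0.0:
        return PopulationState(state.counts.copy(), state.generation)
    counts = state.counts.copy()
    recipients = np.flatnonzero(rng.random(state.N) < params.lambda_lgt)
    k = recipients.size
    if k:
        donors = rng.integers(0, donor_pool.N, size=k)
        starts = rng.integers(0, state.g, size=k)
        # (k, L) column indices on the circular genome, one row per event
        cols = (starts[:, None] + np.arange(params.L)[None, :]) % state.g
        counts[recipients[:, None], cols] = donor_pool.counts[donors[:, None], cols]
    return PopulationState(counts, state.generation)


def advance_generation(state: PopulationState, params: SimulationParams,
                       fm: FitnessModel, rng: np.random.Generator
                       ) -> tuple[PopulationState, GenerationStats]:
    """One full life cycle in the default order: fitness-proportional
    selection, Poisson mutation, then LGT with the parent generation's
    end-of-life genomes as the eDNA pool. Statistics (least-loaded-class size,
    mean load, fixed total) are computed on the returned state, i.e. after
    recombination."""
    w = compute_fitness(state.counts, fm)
    offspring = selection_step(state, w, rng)
    offspring = mutation_step(offspring, params, rng)
    offspring = lgt_step(offspring, state, params, rng)
    return offspring, GenerationStats.measure(offspring)


@dataclass
class SimulationResult:
    """Outcome of one replicate: final state, fixation tracker, and the
    per-generation least-loaded-class size series."""

    final_state: PopulationState
    tracker: FixationTracker
    llc_series: np.ndarray
    mean_load_series: np.ndarray
    params: SimulationParams
    fitness_model: FitnessModel
    elapsed_generations: int
    extinct: bool = False


def simulate(params: SimulationParams, fm: FitnessModel,
             rng: np.random.Generator | None = None,
             stop_at_first_fixation: bool = False) -> SimulationResult:
    """Run one replicate for ``params.generations`` generations.

    ``stop_at_first_fixation`` ends the run as soon as any locus fixes (the
    least-loaded class is irreversibly lost), which is exact for extinction-
    time experiments and skips the post-click tail.

    With ``event_order="figure1"`` the cycle is LGT -> mutation -> selection;
    in the first generation there is no prior eDNA pool yet, so the (all-zero)
    initial population serves as its own donor pool.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if fm.g != params.g:
        raise ParameterError(f"fitness model g={fm.g} does not match params g={params.g}")
    state = init_population(params)
    # figure1 order: the newborn generation recombines before mutating; in the
    # first cycle the (all-zero) founding population serves as the eDNA pool.
    prev_end_of_life = state
    tracker = FixationTracker(params.g)
    llc = np.empty(params.generations, dtype=np.int64)
    mean_load = np.empty(params.generations, dtype=float)
    extinct = False
    t_done = 0
    for t in range(params.generations):
        try:
            if params.event_order == "methods":
                state, stats = advance_generation(state, params, fm, rng)
                measured = state
            else:
                mixed = lgt_step(state, prev_end_of_life, params, rng)
                measured = mixed  # after recombination, before new mutations
                mutated = mutation_step(mixed, params, rng)
                w = compute_fitness(mutated.counts, fm)
                state = selection_step(mutated, w, rng)
                prev_end_of_life = mutated
                stats = GenerationStats.measure(measured)
        except ExtinctionError as exc:
            exc.generation = state.generation
            extinct = True
            llc = llc[:t]
            mean_load = mean_load[:t]
            t_done = t
            break
        llc[t] = stats.llc_size
        mean_load[t] = stats.mean_load
        tracker.update(measured, generation=t + 1)
        t_done = t + 1
        if stop_at_first_fixation and tracker.text is not None:
            llc = llc[:t_done]
            mean_load = mean_load[:t_done]
            break
    return SimulationResult(
        final_state=state, tracker=tracker, llc_series=llc,
        mean_load_series=mean_load, params=params, fitness_model=fm,
        elapsed_generations=t_done, extinct=extinct)
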
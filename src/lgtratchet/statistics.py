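"""Ratchet severity measures: least-loaded class, fixations, and rates.

Two measures summarise the severity of Muller's ratchet in a run:

* ``Text`` — the generation at which a mutant first reaches fixation at any
  locus, irreversibly destroying the mutation-free (least-loaded) class. A
  mutant is fixed at locus ``i`` once every individual carries at least one
  mutation there, i.e. the column minimum is >= 1. Because back-mutation is
  neglected and eDNA donors are drawn from the previous generation, fixation
  observed after the LGT step is permanent.
* ``Delta m / Delta t`` — the genome-wide fixation rate: total fixed mutation
  levels (sum of per-locus column minima) at the end of the run divided by
  its duration. The per-locus rate is this divided by genome size ``g``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ParameterError

__all__ = [
    "GenerationStats", "FixationTracker", "RunSummary", "CompartmentSummary",
    "llc_size", "fixed_mutation_vector", "fixation_rates",
    "compartment_fixation_summary",
]


def llc_size(state) -> int:
    """Number of individuals in the least-loaded class (all-zero genomes)."""
    return int((state.counts.sum(axis=1) == 0).sum())


def fixed_mutation_vector(state) -> np.ndarray:
    """Per-locus column minima: ``min_j counts[j, i]`` for each locus ``i``.

    Locus ``i`` is fixed iff its minimum is >= 1; the value is the number of
    fixed mutation levels there. Any mutation-free individual forces the whole
    vector to zero.
    """
    return state.counts.min(axis=0)


@dataclass(frozen=True)
class GenerationStats:
    """Snapshot of one generation, taken after recombination."""

    generation: int
    llc_size: int
    mean_load: float
    fixed_total: int

    @classmethod
    def measure(cls, state) -> "GenerationStats":
        loads = state.counts.sum(axis=1)
        return cls(generation=state.generation,
                   llc_size=int((loads == 0).sum()),
                   mean_load=float(loads.mean()),
                   fixed_total=int(fixed_mutation_vector(state).sum()))


class FixationTracker:
    """Per-locus record of irreversible fixations across a run.

    ``first_fixation_generation[i]`` holds the generation at which locus ``i``
    first fixed (-1 while unfixed); ``fixed_mutation_count[i]`` holds the
    current number of fixed mutation levels (the column minimum at the last
    update). ``text`` is the generation of the first fixation anywhere in the
    genome, or None while the run is fixation-free (censored).
    """

    def __init__(self, g: int):
        self.g = g
        self.first_fixation_generation = np.full(g, -1, dtype=np.int64)
        self.fixed_mutation_count = np.zeros(g, dtype=np.int64)
        self.text: Optional[int] = None
        self.last_generation = -1

    def update(self, state, generation: int | None = None) -> "FixationTracker":
        """Record the state of one generation (call once per generation, after
        the LGT step, so that observed fixations are provably permanent)."""
        if generation is None:
            generation = state.generation
        if generation <= self.last_generation:
            raise ParameterError(
                f"generation: tracker updated with non-increasing index "
                f"{generation} after {self.last_generation}")
        minima = fixed_mutation_vector(state)
        newly_fixed = (minima >= 1) & (self.first_fixation_generation < 0)
        if newly_fixed.any():
            self.first_fixation_generation[newly_fixed] = generation
            if self.text is None:
                self.text = int(generation)
        self.fixed_mutation_count = np.asarray(minima, dtype=np.int64)
        self.last_generation = generation
        return self

    @property
    def fixed_total(self) -> int:
        """Total fixed mutation levels across the genome (Delta m)."""
        return int(self.fixed_mutation_count.sum())

    @property
    def fixed_locus_count(self) -> int:
        """Number of distinct loci that have fixed at least once."""
        return int((self.fixed_mutation_count >= 1).sum())


def fixation_rates(tracker: FixationTracker, elapsed_generations: int, g: int,
                   count_fixed_loci_only: bool = False) -> tuple[float, float]:
    """Genome-wide and per-locus fixation rates.

    ``Delta m`` counts fixed mutation *levels* by default (a locus that has
    fixed twice contributes 2); ``count_fixed_loci_only`` switches to counting
    distinct fixed loci instead. The per-locus rate is the genome-wide rate
    divided by ``g``, so ``per_locus * g == genome_wide`` exactly.
    """
    if elapsed_generations < 1:
        raise ParameterError(
            f"elapsed_generations: must be >= 1, got {elapsed_generations}")
    delta_m = tracker.fixed_locus_count if count_fixed_loci_only else tracker.fixed_total
    genome_wide = delta_m / elapsed_generations
    return genome_wide, genome_wide / g


@dataclass(frozen=True)
class CompartmentSummary:
    """Fixed-mutation counts and per-locus rates split core vs accessory.

    Rates are normalised by each compartment's own locus count (so core and
    accessory are comparable per locus) and by elapsed time; an empty
    compartment reports its rate as None rather than zero.
    ``normalise_by_total_g`` at construction divides both by total ``g``
    instead.
    """

    core_count: int
    accessory_count: int
    core_loci: int
    accessory_loci: int
    core_rate_per_locus: Optional[float]
    accessory_rate_per_locus: Optional[float]


def compartment_fixation_summary(tracker: FixationTracker, fm,
                                 elapsed_generations: int,
                                 normalise_by_total_g: bool = False
                                 ) -> CompartmentSummary:
    """Split the tracker's fixed counts by the fitness model's core mask."""
    if elapsed_generations < 1:
        raise ParameterError(
            f"elapsed_generations: must be >= 1, got {elapsed_generations}")
    mask = fm.core_mask
    core_count = int(tracker.fixed_mutation_count[mask].sum())
    acc_count = int(tracker.fixed_mutation_count[~mask].sum())
    core_loci = int(mask.sum())
    acc_loci = int((~mask).sum())
    g = core_loci + acc_loci

    def rate(count: int, loci: int) -> Optional[float]:
        denom = g if normalise_by_total_g else loci
        if denom == 0:
            return None
        return count / denom / elapsed_generations

    return CompartmentSummary(
        core_count=core_count, accessory_count=acc_count,
        core_loci=core_loci, accessory_loci=acc_loci,
        core_rate_per_locus=rate(core_count, core_loci),
        accessory_rate_per_locus=rate(acc_count, acc_loci))


@dataclass(frozen=True)
class RunSummary:
    """Per-replicate summary of a complete simulation run."""

    replicate: int
    seed: int
    N: int
    g: int
    mu: float
    U: float
    lambda_lgt: float
    L: int
    generations: int
    elapsed_generations: int
    text: int                 # first-fixation generation; run length if censored
    censored: bool            # True if no fixation occurred within the run
    fixed_total: int
    fixation_rate_genome: float
    fixation_rate_per_locus: float
    core_count: int = 0
    accessory_count: int = 0
    core_rate_per_locus: Optional[float] = None
    accessory_rate_per_locus: Optional[float] = None
    extinct: bool = False

    def __post_init__(self):
        # partition identity and rate identity, cheap self-checks
        assert self.core_count + self.accessory_count in (0, self.fixed_total)

    def as_dict(self) -> dict:
        return dict(self.__dict__)
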
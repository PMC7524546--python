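"""Seeded replicate runner and parameter sweeps.

Sweeps mirror the structure of the model's headline experiments:

* extinction time of the least-loaded class (``Text``) versus genome size for
  several recombination lengths and LGT rates, under a constant per-locus
  mutation rate;
* genome-wide and per-locus fixation rates versus genome size, under either a
  constant per-locus rate or a constant genome-wide rate ``U``;
* core/accessory selection regimes, splitting fixation by compartment.

Each replicate runs from its own RNG stream seeded as ``base_seed +
replicate_index``; the whole sweep is deterministic given its spec and base
seed. Results come back as tidy tables (one row per grid point per replicate)
plus mean/SD aggregates over replicates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ExtinctionError, ParameterError
from .fitness import LINEAR, FitnessModel
from .params import PER_LOCUS, SimulationParams, resolve_recombination_length
from .population import SimulationResult, simulate
from .statistics import RunSummary, compartment_fixation_summary, fixation_rates

__all__ = [
    "SelectionRegime", "SweepSpec", "SweepTable", "run_replicates",
    "sweep_genome_size", "core_accessory_experiment", "aggregate_sweep",
]


@dataclass(frozen=True)
class SelectionRegime:
    """How selection coefficients are assigned across the genome.

    ``uniform`` applies one coefficient ``s`` everywhere. ``core_accessory``
    draws ``g_core`` core loci uniformly at random (once per replicate, from
    the replicate's RNG stream) with coefficient ``s_core``; the remaining
    accessory loci get ``s_accessory``.
    """

    kind: str = "uniform"
    s: float = 1e-3
    g_core: int = 50
    s_core: float = 0.005
    s_accessory: float = 0.001
    form: str = LINEAR

    def __post_init__(self):
        if self.kind not in ("uniform", "core_accessory"):
            raise ParameterError(f"kind: unknown selection regime {self.kind!r}")

    def build(self, g: int, rng: np.random.Generator) -> FitnessModel:
        if self.kind == "uniform":
            return FitnessModel.uniform(g, self.s, form=self.form)
        if self.g_core > g:
            raise ParameterError(f"g_core: {self.g_core} exceeds genome size g={g}")
        return FitnessModel.core_accessory(
            g, self.g_core, rng, s_core=self.s_core,
            s_accessory=self.s_accessory, form=self.form)


@dataclass(frozen=True)
class SweepSpec:
    """Grid of simulation conditions plus replication settings.

    ``L_values`` entries may be integers or the fraction rule string
    ``"0.2g"`` (resolved per genome size as ``max(1, round(0.2 g))``).
    ``mutation_regime`` selects whether ``mu`` (per-locus) or ``U``
    (genome-wide) is held fixed as ``g`` varies.
    """

    g_values: Sequence[int]
    L_values: Sequence[Union[int, str]] = (1,)
    lambda_values: Sequence[float] = (0.0,)
    mutation_regime: str = PER_LOCUS
    mu: Optional[float] = None
    U: Optional[float] = None
    regime: SelectionRegime = field(default_factory=SelectionRegime)
    N: int = 500
    generations: int = 5000
    replicates: int = 10
    base_seed: int = 0
    event_order: str = "methods"
    stop_at_first_fixation: bool = False
    count_fixed_loci_only: bool = False

    def grid(self):
        """Yield (g, L_spec, lambda) tuples over the full grid."""
        return itertools.product(self.g_values, self.L_values, self.lambda_values)

    def params_for(self, g: int, L: Union[int, str], lam: float,
                   seed: int) -> SimulationParams:
        kwargs = dict(N=self.N, g=int(g), lambda_lgt=float(lam), L=L,
                      generations=self.generations, seed=seed,
                      mutation_regime=self.mutation_regime,
                      event_order=self.event_order)
        if self.mutation_regime == PER_LOCUS:
            if self.mu is None:
                raise ParameterError("mu: per_locus sweeps require mu")
            kwargs["mu"] = self.mu
        else:
            if self.U is None:
                raise ParameterError("U: genome_wide sweeps require U")
            kwargs["U"] = self.U
        return SimulationParams(**kwargs)


@dataclass
class SweepTable:
    """Tidy per-replicate rows plus mean/SD aggregates over replicates."""

    per_replicate: pd.DataFrame
    aggregated: pd.DataFrame
    locus_map: Optional[pd.DataFrame] = None


def _summarise(result: SimulationResult, replicate: int, seed: int,
               count_fixed_loci_only: bool = False) -> RunSummary:
    p = result.params
    elapsed = max(result.elapsed_generations, 1)
    genome_rate, locus_rate = fixation_rates(
        result.tracker, elapsed, p.g, count_fixed_loci_only=count_fixed_loci_only)
    comp = compartment_fixation_summary(result.tracker, result.fitness_model, elapsed)
    censored = result.tracker.text is None
    return RunSummary(
        replicate=replicate, seed=seed, N=p.N, g=p.g, mu=p.mu, U=p.U,
        lambda_lgt=p.lambda_lgt, L=p.L, generations=p.generations,
        elapsed_generations=result.elapsed_generations,
        text=p.generations if censored else result.tracker.text,
        censored=censored,
        fixed_total=result.tracker.fixed_total,
        fixation_rate_genome=genome_rate,
        fixation_rate_per_locus=locus_rate,
        core_count=comp.core_count, accessory_count=comp.accessory_count,
        core_rate_per_locus=comp.core_rate_per_locus,
        accessory_rate_per_locus=comp.accessory_rate_per_locus,
        extinct=result.extinct)


def run_replicates(params: SimulationParams, regime: SelectionRegime,
                   replicates: int, base_seed: int,
                   stop_at_first_fixation: bool = False,
                   count_fixed_loci_only: bool = False,
                   keep_results: bool = False
                   ) -> tuple[list[RunSummary], list[SimulationResult]]:
    """Run independent seeded replicates of one parameter set.

    Replicate ``i`` uses seed ``base_seed + i``; the core/accessory locus
    assignment (when applicable) is drawn once per replicate from that
    replicate's stream before the simulation starts. Returns the per-replicate
    summaries and, when ``keep_results``, the full simulation results.
    """
    if replicates < 1:
        raise ParameterError(f"replicates: must be >= 1, got {replicates}")
    summaries: list[RunSummary] = []
    results: list[SimulationResult] = []
    for i in range(replicates):
        seed = int(base_seed) + i
        rng = np.random.default_rng(seed)
        fm = regime.build(params.g, rng)
        try:
            res = simulate(params.with_seed(seed), fm, rng=rng,
                           stop_at_first_fixation=stop_at_first_fixation)
        except ExtinctionError as exc:
            exc.replicate = i
            raise
        summaries.append(_summarise(res, i, seed,
                                    count_fixed_loci_only=count_fixed_loci_only))
        if keep_results:
            results.append(res)
    return summaries, results


_AGG_COLS = ["text", "fixation_rate_genome", "fixation_rate_per_locus",
             "core_rate_per_locus", "accessory_rate_per_locus",
             "fixed_total", "core_count", "accessory_count"]


def aggregate_sweep(per_replicate: pd.DataFrame,
                    by: Sequence[str] = ("g", "L", "lambda_lgt")) -> pd.DataFrame:
    """Mean and SD over replicates for every grid point, plus the censoring
    fraction (share of replicates with no fixation within the run)."""
    by = [c for c in by if c in per_replicate.columns]
    cols = [c for c in _AGG_COLS if c in per_replicate.columns]
    grouped = per_replicate.groupby(by, dropna=False)
    agg = grouped[cols].agg(["mean", "std"])
    agg.columns = [f"{c}_{stat}" for c, stat in agg.columns]
    agg["replicates"] = grouped.size()
    agg["censored_fraction"] = grouped["censored"].mean()
    return agg.reset_index()


def _sweep(spec: SweepSpec) -> pd.DataFrame:
    rows = []
    for g, L_spec, lam in spec.grid():
        try:
            resolve_recombination_length(L_spec, int(g))
        except ParameterError as exc:
            warnings.warn(f"skipping infeasible grid point g={g}, L={L_spec}: {exc}")
            continue
        params = spec.params_for(g, L_spec, lam, seed=spec.base_seed)
        summaries, _ = run_replicates(
            params, spec.regime, spec.replicates, spec.base_seed,
            stop_at_first_fixation=spec.stop_at_first_fixation,
            count_fixed_loci_only=spec.count_fixed_loci_only)
        for s in summaries:
            row = s.as_dict()
            row["L_spec"] = str(L_spec)
            rows.append(row)
    return pd.DataFrame(rows)


def sweep_genome_size(spec: SweepSpec) -> SweepTable:
    """Run the (g, L, lambda) grid and aggregate Text and fixation rates.

    Infeasible grid points (resolved L > g) are skipped with a warning.
    Deterministic given the spec and its base seed.
    """
    per_rep = _sweep(spec)
    agg = aggregate_sweep(per_rep) if len(per_rep) else pd.DataFrame()
    return SweepTable(per_replicate=per_rep, aggregated=agg)


def core_accessory_experiment(spec: SweepSpec) -> SweepTable:
    """Core/accessory sweep with a per-locus fixed-mutation map.

    Requires ``spec.regime.kind == "core_accessory"``. The locus map holds,
    for every grid point and replicate, each locus's fixed-mutation count and
    core flag (the analogue of a per-locus fixation plot).
    """
    if spec.regime.kind != "core_accessory":
        raise ParameterError("regime: core_accessory_experiment requires a "
                             "core_accessory selection regime")
    rows = []
    map_rows = []
    for g, L_spec, lam in spec.grid():
        try:
            resolve_recombination_length(L_spec, int(g))
        except ParameterError as exc:
            warnings.warn(f"skipping infeasible grid point g={g}, L={L_spec}: {exc}")
            continue
        params = spec.params_for(g, L_spec, lam, seed=spec.base_seed)
        summaries, results = run_replicates(
            params, spec.regime, spec.replicates, spec.base_seed,
            count_fixed_loci_only=spec.count_fixed_loci_only, keep_results=True)
        for s, res in zip(summaries, results):
            row = s.as_dict()
            row["L_spec"] = str(L_spec)
            rows.append(row)
            fixed = res.tracker.fixed_mutation_count
            mask = res.fitness_model.core_mask
            map_rows.append(pd.DataFrame({
                "g": params.g, "L": params.L, "lambda_lgt": params.lambda_lgt,
                "replicate": s.replicate, "locus": np.arange(params.g),
                "is_core": mask, "fixed_count": fixed,
            }))
    per_rep = pd.DataFrame(rows)
    agg = aggregate_sweep(per_rep) if len(per_rep) else pd.DataFrame()
    locus_map = pd.concat(map_rows, ignore_index=True) if map_rows else None
    return SweepTable(per_replicate=per_rep, aggregated=agg, locus_map=locus_map)
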
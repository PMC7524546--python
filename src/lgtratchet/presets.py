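"""Named experiment presets.

``desk_preset`` returns scaled-down sweeps that preserve each experiment's
comparative structure while running in minutes on one CPU: population size,
run length and replicate count are reduced, and in the constant-per-locus-rate
experiments both the mutation rate and the selection coefficient are raised
tenfold (mu 1e-4 -> 1e-3, s 1e-3 -> 1e-2). Scaling mu and s together keeps
the deleterious mutation pressure per unit of selection (U/s, which sets the
equilibrium least-loaded-class size N*exp(-U/s)) at its published value while
running the ratchet on a ten-times-faster clock; raising mu alone would push
the population into a mutation-dominated regime with a qualitatively
different balance. The core/accessory preset keeps the published coefficients
(0.005 / 0.001), which already exceed the raised mutation rate.
``full_preset`` records the published-scale parameter sets (N = 5x10^3 or
10^4, mu = 1e-4, s = 1e-3, 50 replicates, 1e4-1e5 generations) for cluster
use; they are far too slow for interactive work.
"""

from __future__ import annotations

from .errors import ParameterError
from .experiments import SelectionRegime, SweepSpec
from .params import GENOME_WIDE, PER_LOCUS

PRESET_NAMES = ("fig2", "fig3", "fig4", "fig5-6")


def desk_preset(name: str, base_seed: int = 0) -> SweepSpec:
    """Desk-scale analogue of a named experiment.

    ``fig2``  — Text vs genome size for several L, with and without LGT
                (constant per-locus rate).
    ``fig3``  — fixation rate vs genome size for several L (constant
                per-locus rate).
    ``fig4``  — fixation rate vs genome size under a constant genome-wide
                rate U.
    ``fig5-6`` — core/accessory regime, per-locus fixation map and
                compartment rates.
    """
    if name == "fig2":
        return SweepSpec(
            g_values=(50, 100, 200), L_values=(1, 5, "0.2g"),
            lambda_values=(0.0, 0.1), mutation_regime=PER_LOCUS, mu=1e-3,
            regime=SelectionRegime(kind="uniform", s=1e-2),
            N=500, generations=20_000, replicates=10, base_seed=base_seed,
            stop_at_first_fixation=True)
    if name == "fig3":
        return SweepSpec(
            g_values=(50, 100, 200), L_values=(1, 5, "0.2g"),
            lambda_values=(0.0, 0.1), mutation_regime=PER_LOCUS, mu=1e-3,
            regime=SelectionRegime(kind="uniform", s=1e-2),
            N=500, generations=5000, replicates=10, base_seed=base_seed)
    if name == "fig4":
        return SweepSpec(
            g_values=(50, 100, 200), L_values=(1, 5, "0.2g"),
            lambda_values=(0.01, 0.1), mutation_regime=GENOME_WIDE, U=0.1,
            regime=SelectionRegime(kind="uniform", s=1e-3),
            N=500, generations=5000, replicates=10, base_seed=base_seed)
    if name == "fig5-6":
        return SweepSpec(
            g_values=(100, 200), L_values=(5, "0.2g"), lambda_values=(0.0, 0.1),
            mutation_regime=PER_LOCUS, mu=1e-3,
            regime=SelectionRegime(kind="core_accessory", g_core=50,
                                   s_core=0.005, s_accessory=0.001),
            N=500, generations=5000, replicates=10, base_seed=base_seed)
    raise ParameterError(f"preset: unknown preset {name!r}; choose from {PRESET_NAMES}")


def full_preset(name: str, base_seed: int = 0) -> SweepSpec:
    """Published-scale parameter sets (slow; intended for cluster runs)."""
    if name == "fig2":
        return SweepSpec(
            g_values=(50, 100, 250, 500, 1000, 2500),
            L_values=(1, 5, 25, "0.2g"), lambda_values=(0.01, 0.1),
            mutation_regime=PER_LOCUS, mu=1e-4,
            regime=SelectionRegime(kind="uniform", s=1e-3),
            N=5000, generations=10_000, replicates=50, base_seed=base_seed,
            stop_at_first_fixation=True)
    if name == "fig3":
        return SweepSpec(
            g_values=(50, 100, 250, 500, 1000, 2500),
            L_values=(1, 5, 25, "0.2g"), lambda_values=(0.01, 0.1),
            mutation_regime=PER_LOCUS, mu=1e-4,
            regime=SelectionRegime(kind="uniform", s=1e-3),
            N=10_000, generations=100_000, replicates=50, base_seed=base_seed)
    if name == "fig4":
        return SweepSpec(
            g_values=(50, 100, 250, 500, 1000, 2500),
            L_values=(1, 5, 25, "0.2g"), lambda_values=(0.01, 0.1),
            mutation_regime=GENOME_WIDE, U=0.1,
            regime=SelectionRegime(kind="uniform", s=1e-3),
            N=5000, generations=100_000, replicates=50, base_seed=base_seed)
    if name == "fig5-6":
        return SweepSpec(
            g_values=(100, 500), L_values=(5, "0.2g"), lambda_values=(0.0, 0.1),
            mutation_regime=PER_LOCUS, mu=1e-4,
            regime=SelectionRegime(kind="core_accessory", g_core=50,
                                   s_core=0.005, s_accessory=0.001),
            N=10_000, generations=100_000, replicates=50, base_seed=base_seed)
    raise ParameterError(f"preset: unknown preset {name!r}; choose from {PRESET_NAMES}")
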
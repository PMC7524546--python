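"""Analytic predictions used as oracles for the simulation.

At deterministic mutation-selection balance in a haploid population without
recombination, the expected size of the least-loaded (mutation-free) class is

    n0 = N * exp(-U / s)

(the classical Haigh equilibrium). Under a constant per-locus mutation rate,
U = mu * g, so n0 declines exponentially with genome size g — the severity of
Muller's ratchet (a smaller mutation-free class clicks sooner) grows
exponentially as the genome expands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = ["TheoryPrediction", "equilibrium_llc_size", "predicted_severity_curve"]


@dataclass(frozen=True)
class TheoryPrediction:
    """Expected equilibrium least-loaded-class size with its inputs."""

    N: int
    U: float
    s: float
    n0_expected: float


def equilibrium_llc_size(N: int, U: float, s: float) -> float:
    """Deterministic equilibrium size of the least-loaded class, N*exp(-U/s).

    Strictly decreasing in ``U``; equals ``N`` when ``U == 0``. Raises for
    ``s == 0`` (the equilibrium is undefined without selection).
    """
    if s <= 0:
        raise ParameterError(f"s: equilibrium undefined for s={s} (requires s > 0)")
    if U < 0:
        raise ParameterError(f"U: mutation rate must be >= 0, got {U}")
    if N < 1:
        raise ParameterError(f"N: population size must be >= 1, got {N}")
    return float(N * np.exp(-U / s))


def predicted_severity_curve(N: int, mu: float, s: float,
                             g_values) -> pd.DataFrame:
    """Tabulate the equilibrium least-loaded-class size against genome size.

    Applies :func:`equilibrium_llc_size` with ``U = mu * g`` for each ``g``;
    under a constant per-locus rate the output decreases exponentially in
    ``g`` (log n0 is linear in g with slope ``-mu/s``).
    """
    g_arr = np.asarray(list(g_values), dtype=int)
    if g_arr.size and g_arr.min() < 1:
        raise ParameterError("g_values: genome sizes must be positive integers")
    n0 = [equilibrium_llc_size(N, mu * g, s) for g in g_arr]
    return pd.DataFrame({"g": g_arr, "U": mu * g_arr, "n0_expected": n0})
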
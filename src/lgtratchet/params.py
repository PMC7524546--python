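"""Model parameters for the Wright-Fisher ratchet with lateral gene transfer.

The model tracks a haploid population of ``N`` individuals, each carrying a
circular genome of ``g`` loci. Deleterious mutations arrive at rate ``mu`` per
locus per generation (equivalently ``U = mu * g`` genome-wide), selection acts
with per-locus coefficients held by :class:`~lgtratchet.fitness.FitnessModel`,
and each individual undergoes at most one lateral gene transfer (LGT) event
per generation with probability ``lambda_lgt``, replacing ``L`` contiguous
loci with the homologous segment of a random donor from the previous
generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Union

from .errors import ParameterError

PER_LOCUS = "per_locus"
GENOME_WIDE = "genome_wide"
MUTATION_REGIMES = (PER_LOCUS, GENOME_WIDE)

EVENT_ORDERS = ("methods", "figure1")

#: Fraction of the genome replaced per LGT event under the whole-genome-scale
#: recombination rule discussed in the source model (L = 0.2 g).
L_FRACTION_RULE = 0.2


def resolve_recombination_length(L: Union[int, float, str], g: int) -> int:
    """Resolve a recombination length specification to an integer locus count.

    ``L`` may be an absolute integer, or the fraction rule ``"0.2g"`` (any
    string of the form ``"<fraction>g"``), resolved as
    ``max(1, round(fraction * g))``.

    >>> resolve_recombination_length("0.2g", 2500)
    500
    """
    if isinstance(L, str):
        text = L.strip().lower()
        if not text.endswith("g"):
            raise ParameterError(f"L: cannot parse recombination length {L!r}")
        try:
            frac = float(text[:-1] or L_FRACTION_RULE)
        except ValueError as exc:
            raise ParameterError(f"L: cannot parse recombination length {L!r}") from exc
        resolved = max(1, round(frac * g))
    elif isinstance(L, float) and not L.is_integer():
        raise ParameterError(f"L: recombination length must be an integer number of loci, got {L}")
    else:
        resolved = int(L)
    if not 1 <= resolved <= g:
        raise ParameterError(f"L: recombination length {resolved} outside [1, g={g}]")
    return resolved


@dataclass(frozen=True)
class SimulationParams:
    """All rates and sizes of one simulation run.

    Exactly one of ``mu`` (per-locus) and ``U`` (genome-wide) mutation rates
    must be supplied; the other is derived through ``U = mu * g``. If both are
    given they must satisfy that identity. ``mutation_regime`` records which
    rate is held fixed as genome size varies across a sweep.

    Parameters
    ----------
    N : population size (individuals), constant through a run.
    g : genome size (number of loci).
    mu : mutation rate per locus per generation.
    U : genome-wide mutation rate per generation.
    mutation_regime : ``"per_locus"`` or ``"genome_wide"``.
    lambda_lgt : probability per individual per generation of one LGT event.
    L : recombination length — contiguous loci replaced per LGT event; an
        integer, or the fraction rule string ``"0.2g"``.
    generations : run length.
    seed : base RNG seed for the run.
    event_order : ``"methods"`` (selection -> mutation -> LGT; default) or
        ``"figure1"`` (LGT -> mutation -> selection) life-cycle ordering.
    """

    N: int
    g: int
    mu: float | None = None
    U: float | None = None
    mutation_regime: str = PER_LOCUS
    lambda_lgt: float = 0.0
    L: Union[int, float, str] = 1
    generations: int = 10_000
    seed: int = 0
    event_order: str = "methods"

    def __post_init__(self) -> None:
        if not isinstance(self.N, int) or self.N < 1:
            raise ParameterError(f"N: population size must be an integer >= 1, got {self.N}")
        if not isinstance(self.g, int) or self.g < 1:
            raise ParameterError(f"g: genome size must be an integer >= 1, got {self.g}")
        if self.mutation_regime not in MUTATION_REGIMES:
            raise ParameterError(
                f"mutation_regime: expected one of {MUTATION_REGIMES}, got {self.mutation_regime!r}")
        if self.event_order not in EVENT_ORDERS:
            raise ParameterError(
                f"event_order: expected one of {EVENT_ORDERS}, got {self.event_order!r}")
        mu, U = self.mu, self.U
        if mu is None and U is None:
            raise ParameterError("mu/U: one of mu or U must be given")
        if mu is not None and U is not None:
            if not math.isclose(U, mu * self.g, rel_tol=1e-9, abs_tol=1e-15):
                raise ParameterError(
                    f"mu/U: inconsistent rates, U={U} but mu*g={mu * self.g}")
        elif mu is None:
            mu = U / self.g
        else:
            U = mu * self.g
        if mu < 0:
            raise ParameterError(f"mu: mutation rate must be >= 0, got {mu}")
        object.__setattr__(self, "mu", float(mu))
        object.__setattr__(self, "U", float(U))
        if not 0.0 <= self.lambda_lgt <= 1.0:
            raise ParameterError(
                f"lambda_lgt: LGT probability must lie in [0, 1], got {self.lambda_lgt}")
        object.__setattr__(self, "L", resolve_recombination_length(self.L, self.g))
        if not isinstance(self.generations, int) or self.generations < 1:
            raise ParameterError(
                f"generations: run length must be an integer >= 1, got {self.generations}")

    def with_seed(self, seed: int) -> "SimulationParams":
        """Copy of these parameters with a different RNG seed."""
        return replace(self, seed=int(seed))

    def as_dict(self) -> dict:
        """Flat dict of resolved parameter values (for metadata echo)."""
        return {
            "N": self.N, "g": self.g, "mu": self.mu, "U": self.U,
            "mutation_regime": self.mutation_regime,
            "lambda_lgt": self.lambda_lgt, "L": self.L,
            "generations": self.generations, "seed": self.seed,
            "event_order": self.event_order,
        }
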
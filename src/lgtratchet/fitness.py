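"""Fitness models: uniform selection, and core/accessory compartments.

Two functional forms are supported for the fitness of an individual carrying
``m_i`` mutations at locus ``i`` with selection coefficients ``s_i``:

``linear``
    ``w = max(0, 1 - sum_i s_i * m_i)`` — for uniform ``s`` this is the
    no-epistasis form ``w_m = 1 - s m``, clamped at zero.
``multiplicative``
    ``w = prod_i (1 - s_i)^{m_i}`` — each mutation multiplies fitness by
    ``(1 - s_i)``.

For the weak selection coefficients typical of this model (s <= 0.005) the two
agree to first order in ``s m``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

LINEAR = "linear"
MULTIPLICATIVE = "multiplicative"
FITNESS_FORMS = (LINEAR, MULTIPLICATIVE)


@dataclass(frozen=True)
class FitnessModel:
    """Per-locus selection coefficients plus core/accessory assignment.

    Attributes
    ----------
    form : ``"linear"`` or ``"multiplicative"``.
    s_per_locus : float array of shape ``(g,)``, entries in [0, 1].
    core_mask : boolean array of shape ``(g,)``; True marks core loci. The
        uniform model is the special case with an all-false mask.
    """

    form: str
    s_per_locus: np.ndarray
    core_mask: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s_per_locus, dtype=float)
        mask = np.asarray(self.core_mask, dtype=bool)
        if s.ndim != 1:
            raise ParameterError("s_per_locus: expected a 1-D vector")
        if mask.shape != s.shape:
            raise ParameterError(
                f"core_mask: shape {mask.shape} does not match s_per_locus {s.shape}")
        if np.any(s < 0) or np.any(s > 1):
            raise ParameterError("s_per_locus: selection coefficients must lie in [0, 1]")
        if self.form not in FITNESS_FORMS:
            raise ParameterError(f"form: expected one of {FITNESS_FORMS}, got {self.form!r}")
        object.__setattr__(self, "s_per_locus", s)
        object.__setattr__(self, "core_mask", mask)

    @property
    def g(self) -> int:
        return self.s_per_locus.shape[0]

    @property
    def g_core(self) -> int:
        """Number of core loci."""
        return int(self.core_mask.sum())

    @classmethod
    def uniform(cls, g: int, s: float, form: str = LINEAR) -> "FitnessModel":
        """Uniform selection coefficient ``s`` at every locus, no core set."""
        return cls(form=form,
                   s_per_locus=np.full(g, float(s)),
                   core_mask=np.zeros(g, dtype=bool))

    @classmethod
    def core_accessory(cls, g: int, g_core: int, rng: np.random.Generator,
                       s_core: float = 0.005, s_accessory: float = 0.001,
                       form: str = LINEAR) -> "FitnessModel":
        """Core/accessory regime: ``g_core`` loci drawn uniformly at random
        (without replacement) get coefficient ``s_core``; the rest get
        ``s_accessory``."""
        if not 0 <= g_core <= g:
            raise ParameterError(f"g_core: must lie in [0, g={g}], got {g_core}")
        mask = np.zeros(g, dtype=bool)
        mask[rng.choice(g, size=g_core, replace=False)] = True
        s = np.where(mask, float(s_core), float(s_accessory))
        return cls(form=form, s_per_locus=s, core_mask=mask)


def compute_fitness(counts: np.ndarray, fm: FitnessModel) -> np.ndarray:
    """Fitness of each individual given its per-locus mutation counts.

    Parameters
    ----------
    counts : integer array of shape ``(N, g)``; ``counts[j, i]`` is the number
        of mutations at locus ``i`` of individual ``j``.
    fm : the fitness model; ``fm.g`` must equal ``counts.shape[1]``.

    Returns
    -------
    float array of shape ``(N,)`` with values in [0, 1]; a mutation-free
    individual has fitness exactly 1.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] != fm.g:
        raise ParameterError(
            f"counts: shape {counts.shape} incompatible with g={fm.g} fitness model")
    if fm.form == LINEAR:
        return np.clip(1.0 - counts @ fm.s_per_locus, 0.0, None)
    # multiplicative: prod (1-s_i)^{m_i} = exp(sum m_i log(1-s_i));
    # loci with s_i == 1 zero out fitness for any mutation there.
    s = fm.s_per_locus
    lethal = s >= 1.0
    with np.errstate(divide="ignore"):
        log_terms = np.where(lethal, 0.0, np.log1p(-s))
    w = np.exp(counts @ log_terms)
    if lethal.any():
        w = np.where((counts[:, lethal] > 0).any(axis=1), 0.0, w)
    return w
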
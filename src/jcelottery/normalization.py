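"""Inter-model normalisations.

Comparing the four functional forms requires equalising predation pressure
across the two model axes:

1. **Distance normalisation** — equalise the total predation pressure a
   single tree spreads over space, ``2 pi g * int_0^inf x G(x) dx``.  With
   ``G(x) = e^(-x/v)`` (decay) this is ``2 pi g v^2``; with a step kernel of
   radius ``r`` it is ``pi g r^2``.  Setting them equal gives
   ``r = v * sqrt(2)`` and hence ``E_F = E_D``.
2. **Additivity normalisation** — equalise the *mean* predation pressure an
   offspring experiences on a random patch.  Additive accumulation raises
   mean pressure by ``a E / N`` in an N-species community, so the
   non-additive baseline is inflated to ``an = aA (1 + E / N)``.  Following
   the reference analysis, ``N`` is the equilibrium richness ``N_A``
   maintained by the additive distance-decay (AD) model at the same
   parameters.

The Moore-neighbourhood mapping for the fixed-distance spatial model uses
area equivalence: a ``k x k`` block of patches covers ``k^2 / g`` square
metres, matching a circle of radius ``r = k / sqrt(pi g)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import JCEForm, JCEParams
from .ode import ODEResult, run_ode

__all__ = [
    "radius_from_decay",
    "additivity_baseline",
    "moore_radius",
    "moore_k_from_radius",
    "NormalisedParameterSet",
    "normalized_parameter_set",
]


def radius_from_decay(v: float) -> float:
    """Fixed-distance radius with the same per-tree total pressure: ``v*sqrt(2)``."""
    if v <= 0:
        raise ValueError("v must be positive")
    return v * math.sqrt(2.0)


def additivity_baseline(aA: float, E: float, N: int) -> float:
    """Non-additive baseline matching additive mean pressure: ``aA (1 + E/N)``."""
    if aA < 0 or E < 0 or N < 1:
        raise ValueError("require aA >= 0, E >= 0, N >= 1")
    return aA * (1.0 + E / N)


def moore_radius(k: int, g: float) -> float:
    """Area-equivalent effect radius of a ``k x k`` Moore neighbourhood."""
    if k % 2 != 1 or k < 1:
        raise ValueError("k must be an odd integer >= 1")
    return k / math.sqrt(math.pi * g)


def moore_k_from_radius(r: float, g: float) -> int:
    """Nearest odd Moore side whose area matches a circle of radius ``r``."""
    k = r * math.sqrt(math.pi * g)
    k_odd = 2 * round((k - 1) / 2) + 1
    return max(1, int(k_odd))


@dataclass
class NormalisedParameterSet:
    """Per-form predation parameters sharing one ``(aA, v, g, D, sigma_Y)`` cell.

    ``an`` is the inflated non-additive baseline; ``N_A`` the equilibrium
    richness of the reference additive run used to compute it.
    """

    aA: float
    v: float
    r: float
    g: float
    D: float
    sigma_Y: float
    an: float
    N_A: int
    reference_form: JCEForm
    params: dict = field(default_factory=dict)
    reference_result: ODEResult | None = None

    def __getitem__(self, form) -> JCEParams:
        if not isinstance(form, JCEForm):
            form = JCEForm[str(form).upper()]
        return self.params[form]

    def to_config(self) -> dict:
        return {
            "aA": self.aA,
            "an": self.an,
            "v": self.v,
            "r": self.r,
            "g": self.g,
            "D": self.D,
            "sigma_Y": self.sigma_Y,
            "N_A": self.N_A,
            "reference_form": self.reference_form.name,
        }


_REFERENCE_CACHE: dict = {}


def normalized_parameter_set(
    aA: float,
    v: float,
    g: float,
    D: float,
    sigma_Y: float,
    seed: int,
    N0: int = 300,
    t_end: float = 10_000.0,
    ln_threshold: float = -11.0,
    reference_form: JCEForm = JCEForm.AD,
    Y: np.ndarray | None = None,
) -> NormalisedParameterSet:
    """Build the four normalised parameter sets for one parameter cell.

    Runs the reference additive model (AD by default) to equilibrium to
    obtain ``N_A``, then sets ``an = aA (1 + E / N_A)`` for NF and ND.  The
    reference run is cached per ``(aA, v, g, D, sigma_Y, seed, N0, t_end,
    ln_threshold, reference_form)``.
    """
    if not reference_form.additive:
        raise ValueError("the normalisation reference must be an additive form")
    r = radius_from_decay(v)
    if Y is None:
        from .core import sample_fitness

        Y = sample_fitness(N0, sigma_Y, seed)

    def jp(form, a):
        if form.distance_decay:
            return JCEParams(form, a=a, g=g, v=v)
        return JCEParams(form, a=a, g=g, r=r)

    key = (aA, v, g, D, sigma_Y, seed, N0, t_end, ln_threshold, reference_form)
    if key not in _REFERENCE_CACHE:
        _REFERENCE_CACHE[key] = run_ode(
            Y, jp(reference_form, aA), D, t_end=t_end, ln_threshold=ln_threshold
        )
    ref = _REFERENCE_CACHE[key]
    N_A = max(ref.richness, 1)
    E = jp(JCEForm.AD, aA).E_D  # = E_F under r = v*sqrt(2)
    an = additivity_baseline(aA, E, N_A)

    params = {
        JCEForm.AD: jp(JCEForm.AD, aA),
        JCEForm.AF: jp(JCEForm.AF, aA),
        JCEForm.ND: jp(JCEForm.ND, an),
        JCEForm.NF: jp(JCEForm.NF, an),
    }
    return NormalisedParameterSet(
        aA=aA,
        v=v,
        r=r,
        g=g,
        D=D,
        sigma_Y=sigma_Y,
        an=an,
        N_A=N_A,
        reference_form=reference_form,
        params=params,
        reference_result=ref,
    )
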
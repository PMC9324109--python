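"""Shared domain types and community-level summaries.

The models describe a community of ``N`` tree species competing for ``M``
patches, each patch holding exactly one adult.  Species differ only in
*intrinsic fitness* ``Y`` (a composite of fecundity and baseline offspring
survival); only relative values of ``Y`` matter in a lottery.  Janzen-Connell
effects (JCEs) — specialised predation of offspring near conspecific adults —
are parameterised by a baseline predation pressure ``a`` (``1 - e^-a`` is the
offspring death probability on a conspecific-occupied patch), an effect
radius ``r`` (fixed-distance forms) or decay length ``v`` (exponential
distance-decay forms), and the adult density ``g`` (adults per square metre).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "JCEForm",
    "CommunityParams",
    "JCEParams",
    "CommunityState",
    "sample_fitness",
    "shannon_diversity",
    "richness",
    "effect_areas",
    "DEFAULT_LN_EXTINCTION",
]

#: Default log-proportion extinction threshold: below this a species holds
#: less than one individual on the reference 50-ha forest plot.
DEFAULT_LN_EXTINCTION: float = -11.0

#: Simplex tolerance for proportion vectors.
_SIMPLEX_TOL = 1e-9


class JCEForm(enum.Enum):
    """The four Janzen-Connell predation functional forms.

    Forms vary on two axes: whether predation pressure accumulates
    *additively* with conspecific adult density, and whether it acts at a
    *fixed* rate within a radius or *decays* exponentially with distance.
    """

    NF = ("non-additive", "fixed")
    AF = ("additive", "fixed")
    ND = ("non-additive", "decay")
    AD = ("additive", "decay")

    def __init__(self, additivity: str, distance: str):
        self.additivity = additivity
        self.distance = distance

    @property
    def additive(self) -> bool:
        return self.additivity == "additive"

    @property
    def distance_decay(self) -> bool:
        return self.distance == "decay"

    @classmethod
    def from_axes(cls, additivity: str, distance: str) -> "JCEForm":
        for form in cls:
            if form.additivity == additivity and form.distance == distance:
                return form
        raise ValueError(f"no form with additivity={additivity!r}, distance={distance!r}")


def _as_form(form) -> JCEForm:
    if isinstance(form, JCEForm):
        return form
    return JCEForm[str(form).upper()]


@dataclass
class CommunityParams:
    """Community-level parameters shared by all four models.

    Parameters
    ----------
    N0
        Initial number of species.
    Y
        Intrinsic fitness vector, length ``N0``, all positive.
    sigma_Y
        Lognormal scale of ``ln Y`` (recorded for provenance).
    D
        Fraction of seeds dispersed uniformly over all patches; ``1 - D``
        is retained on the natal patch.
    delta
        Per-time-step adult death probability.
    g
        Adult density in adults per square metre; patch spacing is
        ``1/sqrt(g)`` metres.
    """

    N0: int
    Y: np.ndarray
    sigma_Y: float = 0.0
    D: float = 1.0
    delta: float = 0.1
    g: float = 0.172

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        if self.N0 < 1:
            raise ValueError("N0 must be >= 1")
        if self.Y.shape != (self.N0,):
            raise ValueError(f"Y must have length N0={self.N0}")
        if not np.all(self.Y > 0):
            raise ValueError("all intrinsic fitnesses must be positive")
        if not 0.0 <= self.D <= 1.0:
            raise ValueError("D must lie in [0, 1]")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.g <= 0:
            raise ValueError("g must be positive")


@dataclass
class JCEParams:
    """Predation parameters for one functional form.

    ``a`` is the baseline predation pressure (``aA`` for the additive forms,
    the normalised ``an`` for the non-additive forms).  ``r`` applies to the
    fixed-distance forms, ``v`` to the distance-decay forms.  The effect
    areas ``E_F = pi*g*r^2`` and ``E_D = 2*pi*g*v^2`` — the expected numbers
    of conspecific adults weighting mean-field predation — are always
    derived from ``(g, r, v)``, never set directly.
    """

    form: JCEForm
    a: float
    g: float = 0.172
    v: float | None = None
    r: float | None = None

    def __post_init__(self):
        self.form = _as_form(self.form)
        if self.a < 0:
            raise ValueError("baseline predation pressure a must be >= 0")
        if self.g <= 0:
            raise ValueError("g must be positive")
        if self.form.distance_decay:
            if self.v is None or self.v <= 0:
                raise ValueError("distance-decay forms require v > 0")
        else:
            if self.r is None or self.r <= 0:
                raise ValueError("fixed-distance forms require r > 0")

    @property
    def E_F(self) -> float:
        if self.r is None:
            raise ValueError("E_F requires an effect radius r")
        return math.pi * self.g * self.r**2

    @property
    def E_D(self) -> float:
        if self.v is None:
            raise ValueError("E_D requires a decay length v")
        return 2.0 * math.pi * self.g * self.v**2

    @property
    def E(self) -> float:
        """Effect area appropriate to the form (``E_F`` fixed, ``E_D`` decay)."""
        return self.E_D if self.form.distance_decay else self.E_F


@dataclass
class CommunityState:
    """Species proportions at a point in time."""

    p: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        _check_simplex(self.p)


def _check_simplex(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("proportion vector must be one-dimensional")
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) >= _SIMPLEX_TOL:
        raise ValueError(f"proportions must sum to 1 (got {p.sum()!r})")
    return p


def sample_fitness(N: int, sigma_Y: float, seed) -> np.ndarray:
    """Draw ``N`` intrinsic fitnesses with ``ln Y ~ Normal(0, sigma_Y^2)``.

    ``seed`` may be an integer or a :class:`numpy.random.Generator`.  The
    same seed always yields the same vector.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if sigma_Y < 0:
        raise ValueError("sigma_Y must be >= 0")
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(0.0, sigma_Y, size=N))


def shannon_diversity(p) -> float:
    """Shannon diversity ``H' = -sum p_i ln p_i`` over extant species."""
    p = _check_simplex(p)
    pos = p[p > 0]
    return float(-(pos * np.log(pos)).sum())


def richness(p, ln_threshold: float = DEFAULT_LN_EXTINCTION) -> int:
    """Count species with ``ln p_i >= ln_threshold`` (boundary is extant).

    The default threshold of -11 corresponds to less than one individual on
    the reference forest plot; for an ``M``-patch landscape pass
    ``ln(1/M)`` instead.
    """
    p = _check_simplex(p)
    with np.errstate(divide="ignore"):
        lnp = np.log(np.where(p > 0, p, np.nan))
    return int(np.sum(lnp >= ln_threshold))


def effect_areas(g: float, r: float | None = None, v: float | None = None):
    """Return ``(E_F, E_D) = (pi*g*r^2, 2*pi*g*v^2)``.

    Either may be ``None`` when the corresponding length is not supplied.
    Under the distance normalisation ``r = v*sqrt(2)`` the two are equal.
    """
    if g <= 0:
        raise ValueError("g must be positive")
    E_F = math.pi * g * r**2 if r is not None else None
    E_D = 2.0 * math.pi * g * v**2 if v is not None else None
    return E_F, E_D
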
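"""Per-patch Janzen-Connell survival probabilities and conspecific-context fields.

``patch_survival`` evaluates the probability ``J`` that an offspring survives
specialised predation on one patch, given the local conspecific context.  The
four functional forms are:

* **NF** — survival ``e^-a`` if any conspecific adult lies within ``r``
  metres (including the focal patch's occupant), else 1.
* **AF** — pressure adds linearly: ``exp(-a * n)`` with ``n`` the number of
  conspecific adults within the effect neighbourhood, the focal occupant
  counting once.
* **ND** — pressure decays exponentially with the distance to the *nearest*
  conspecific adult: ``exp(-a * e^(-d_min/v))``.
* **AD** — pressure adds over all conspecific adults with exponential
  distance weights: ``exp(-a * sum_m e^(-d_m/v))``.

In every form a conspecific occupant of the focal patch contributes weight 1
(distance zero); the context fields ``count_in_radius`` and
``weighted_density`` therefore *exclude* the focal occupant, which is
reported separately via ``occupant_conspecific``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import JCEForm

__all__ = ["ConspecificContext", "patch_survival", "conspecific_fields", "ConspecificFields"]

#: Relative truncation level for AD kernel tails: contributions with
#: ``e^(-d/v) < AD_TRUNCATION_EPS`` may be dropped (error in J below
#: ``a * eps`` per neighbour).  Exact mode keeps every term.
AD_TRUNCATION_EPS = 1e-8


@dataclass
class ConspecificContext:
    """Local conspecific-adult context of one patch for one species.

    ``min_dist`` is the distance (m) to the nearest conspecific adult other
    than the focal occupant (``inf`` if none); ``count_in_radius`` counts
    conspecific adults within the effect neighbourhood excluding the focal
    occupant; ``weighted_density`` is ``sum_m e^(-d_m/v)`` over conspecific
    adults excluding the focal occupant.
    """

    min_dist: float = math.inf
    count_in_radius: int = 0
    weighted_density: float = 0.0
    occupant_conspecific: bool = False

    def __post_init__(self):
        if self.min_dist <= 0:
            raise ValueError("min_dist must be positive (the focal occupant is excluded)")
        if self.count_in_radius < 0:
            raise ValueError("count_in_radius must be >= 0")
        if self.weighted_density < 0:
            raise ValueError("weighted_density must be >= 0")


def patch_survival(
    form: JCEForm,
    a: float,
    ctx: ConspecificContext,
    v: float | None = None,
    r: float | None = None,
) -> float:
    """Offspring survival probability ``J`` on one patch.

    Parameters mirror :class:`~jcelottery.core.JCEParams`: ``r`` is required
    for the fixed-distance forms, ``v`` for the distance-decay forms.
    """
    if a < 0:
        raise ValueError("a must be >= 0")
    occ = 1.0 if ctx.occupant_conspecific else 0.0
    if form is JCEForm.NF:
        if r is None:
            raise ValueError("NF requires an effect radius r")
        hit = ctx.occupant_conspecific or ctx.min_dist <= r
        return math.exp(-a) if hit else 1.0
    if form is JCEForm.AF:
        return math.exp(-a * (ctx.count_in_radius + occ))
    if form is JCEForm.ND:
        if v is None:
            raise ValueError("ND requires a decay length v")
        if ctx.occupant_conspecific:
            return math.exp(-a)
        return math.exp(-a * math.exp(-ctx.min_dist / v))
    if form is JCEForm.AD:
        return math.exp(-a * (ctx.weighted_density + occ))
    raise ValueError(f"unknown form {form!r}")


@dataclass
class ConspecificFields:
    """Per-patch conspecific context of one species over a landscape.

    Arrays are ``(L, L)``, aligned with ``Landscape.occupant``.
    """

    min_dist: np.ndarray
    count_in_radius: np.ndarray
    weighted_density: np.ndarray
    occupant_conspecific: np.ndarray

    def at(self, i: int, j: int) -> ConspecificContext:
        return ConspecificContext(
            min_dist=float(self.min_dist[i, j]),
            count_in_radius=int(self.count_in_radius[i, j]),
            weighted_density=float(self.weighted_density[i, j]),
            occupant_conspecific=bool(self.occupant_conspecific[i, j]),
        )


def torus_offsets(L: int) -> np.ndarray:
    """Signed minimum-image 1-D offsets: ``offsets[k]`` = wrapped distance ``k``."""
    k = np.arange(L)
    return np.minimum(k, L - k)


def conspecific_fields(
    landscape,
    species: int,
    form: JCEForm,
    v: float | None = None,
    moore_k: int | None = None,
    truncation_eps: float | None = AD_TRUNCATION_EPS,
) -> ConspecificFields:
    """Compute the conspecific context of ``species`` on every patch.

    Distances are minimum-image Euclidean between patch centres with spacing
    ``landscape.spacing`` metres (decay forms); ``count_in_radius`` uses the
    square ``moore_k x moore_k`` Moore neighbourhood (fixed forms).  The
    focal patch's occupant is excluded from all three fields and reported via
    ``occupant_conspecific``.

    ``truncation_eps=None`` computes the exponentially weighted density
    without tail truncation.
    """
    occ = landscape.occupant
    L = occ.shape[0]
    mask = occ == species
    occupant_conspecific = mask.copy()

    if not mask.any():
        inf = np.full((L, L), np.inf)
        zero_i = np.zeros((L, L), dtype=int)
        zero_f = np.zeros((L, L))
        return ConspecificFields(inf, zero_i, zero_f, occupant_conspecific)

    # Pairwise toroidal distances from every patch to every conspecific adult.
    off = torus_offsets(L)
    ii, jj = np.nonzero(mask)
    gi = np.arange(L)
    # (L, n_adults) wrapped axis distances in lattice units
    di = off[np.abs(gi[:, None] - ii[None, :]) % L]
    dj = off[np.abs(gi[:, None] - jj[None, :]) % L]
    d2 = di[:, None, :] ** 2 + dj[None, :, :] ** 2  # (L, L, n)
    dist = np.sqrt(d2, dtype=float) * landscape.spacing

    # exclude the focal occupant: on its own patch an adult sits at d = 0
    self_term = np.zeros((L, L))
    self_term[mask] = 1.0

    with np.errstate(over="ignore"):
        dmin = dist.min(axis=2)
    # where the focal patch holds the adult itself, d=0 is the self term;
    # recompute min over the others
    if mask.sum() == 1:
        dmin_excl = np.where(mask, np.inf, dmin)
    else:
        part = np.partition(dist, 1, axis=2)
        dmin_excl = np.where(mask, part[:, :, 1], dmin)

    if v is not None:
        w = np.exp(-dist / v)
        if truncation_eps is not None:
            w = np.where(w < truncation_eps, 0.0, w)
        weighted = w.sum(axis=2) - self_term
        weighted = np.maximum(weighted, 0.0)
    else:
        weighted = np.zeros((L, L))

    if moore_k is not None:
        if moore_k % 2 != 1 or moore_k < 1:
            raise ValueError("moore_k must be an odd integer >= 1")
        half = moore_k // 2
        cnt = np.zeros((L, L), dtype=int)
        for di_ in range(-half, half + 1):
            for dj_ in range(-half, half + 1):
                cnt += np.roll(mask, (di_, dj_), axis=(0, 1))
        count = cnt - mask.astype(int)
    else:
        count = np.zeros((L, L), dtype=int)

    return ConspecificFields(dmin_excl, count, weighted, occupant_conspecific)
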
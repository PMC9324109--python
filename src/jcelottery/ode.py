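"""Deterministic mean-field approximation of the spatial lottery.

Taking expectations of the per-patch offspring abundances over the spatial
configuration of adults yields, for each functional form, closed-form
expected abundances ``E[S_ii]`` (natal patch) and ``E[S_ik]`` (heterospecific
patch, independent of k's identity), and the community dynamics

    dp_i/dt = delta * [ (E[S_ii]/E[S_all,i]) p_i
                        + sum_{k != i} (E[S_ik]/E[S_all,k]) p_k  -  p_i ]

where ``E[S_all,k]`` sums expected abundances of all species on a patch of
species k.  The mean away-from-natal survival ``E[J_ik]`` per form:

* NF:  ``e^(-p E_F) + e^(-a) (1 - e^(-p E_F))`` — the chance no conspecific
  adult falls within the effect circle (Poisson count, mean ``p E_F``), else
  survival ``e^(-a)``.
* AF:  ``exp(-(1 - e^(-a)) p E_F)`` — the Poisson moment generating
  function of the conspecific count in the circle.
* AD:  ``exp(-a p E_D H(a))`` with ``H(a) = 3F3(1,1,1; 2,2,2; -a)`` — the
  Laplace functional of the exponentially weighted conspecific density.
* ND:  a second-order expansion of ``E[exp(-a e^(-X/v))]`` around the mean
  nearest-conspecific distance of a Poisson process (an approximation; an
  exact quadrature mode is selectable with ``nd_mode="quadrature"``).

``E_F = pi g r^2`` and ``E_D = 2 pi g v^2`` are the expected conspecific
adult counts weighting predation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .core import JCEForm, JCEParams, richness as _richness, shannon_diversity

__all__ = [
    "hyper_H",
    "ExpectedOffspring",
    "expected_offspring",
    "mean_away_survival",
    "ode_rhs",
    "run_ode",
    "ODEResult",
]

#: Hard floor (in ln p) below which a species is pruned from the active ODE
#: system; far below the -11 reporting threshold so pruning never affects
#: reported richness.
PRUNE_LN = -30.0


def hyper_H(a: float) -> float:
    """``H(a) = 3F3(1,1,1; 2,2,2; -a)``.

    Evaluated through the identity ``a H(a) = sum_{k>=1} (-1)^(k-1) a^k /
    (k! k^2)``; for large ``a`` (where the alternating series loses
    precision in double arithmetic) an arbitrary-precision evaluation is
    used instead.
    """
    if a < 0:
        raise ValueError("a must be >= 0")
    if a == 0.0:
        return 1.0
    if a > 15.0:
        import mpmath

        return float(mpmath.hyper([1, 1, 1], [2, 2, 2], -a))
    total = 0.0
    term = a  # k = 1 term of the a*H(a) series
    k = 1
    while abs(term) > 1e-17 * max(abs(total), 1e-300):
        total += term
        k += 1
        term *= -a / k * ((k - 1) / k) ** 2
        if k > 500:
            raise RuntimeError(f"H(a) series failed to converge at a={a}")
    return total / a


@dataclass
class ExpectedOffspring:
    """Expected per-patch offspring abundances of one species."""

    own: float
    away: float


def _nd_away_survival_closed(a: float, p, E_D: float):
    """Delta-method closed form for the ND mean away-survival."""
    p = np.asarray(p, dtype=float)
    pe = p * E_D
    pe_safe = np.where(pe > 0, pe, 1.0)
    q = np.sqrt(np.pi / (2.0 * pe_safe))
    w = a * np.exp(-q)
    out = np.exp(-w) * (1.0 + w * (w - 1.0) * (1.0 - np.pi / 4.0) / pe_safe)
    return np.where(pe > 0, out, 1.0)


def _nd_away_survival_quadrature(a: float, p: float, E_D: float) -> float:
    """Exact ND mean away-survival: expectation over the nearest-conspecific
    distance of a Poisson process, P(X > x) = exp(-pi g p x^2)."""
    if p == 0.0 or a == 0.0:
        return 1.0
    # in units u = x/v: density p*E_D*u*exp(-(p*E_D/2) u^2)
    lam = p * E_D

    def f(u):
        return math.exp(-a * math.exp(-u)) * lam * u * math.exp(-0.5 * lam * u * u)

    val, _ = integrate.quad(f, 0.0, np.inf, limit=200)
    return val


def mean_away_survival(form: JCEForm, p, params: JCEParams, nd_mode: str = "closed"):
    """Mean survival ``E[J_ik]`` of a species at proportion ``p`` on a random
    heterospecific patch (the negative-frequency-dependence curve)."""
    a = params.a
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("p must lie in [0, 1]")
    if form is JCEForm.NF:
        E_F = params.E_F
        out = np.exp(-p_arr * E_F) + math.exp(-a) * (1.0 - np.exp(-p_arr * E_F))
    elif form is JCEForm.AF:
        out = np.exp(-(1.0 - math.exp(-a)) * p_arr * params.E_F)
    elif form is JCEForm.AD:
        out = np.exp(-a * p_arr * params.E_D * hyper_H(a))
    elif form is JCEForm.ND:
        if nd_mode == "closed":
            out = _nd_away_survival_closed(a, p_arr, params.E_D)
        elif nd_mode == "quadrature":
            out = np.vectorize(_nd_away_survival_quadrature)(a, p_arr, params.E_D)
        else:
            raise ValueError(f"unknown nd_mode {nd_mode!r}")
    else:
        raise ValueError(f"unknown form {form!r}")
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(out)
    return out


def _own_extra_factor(form: JCEForm, p, params: JCEParams) -> np.ndarray:
    """Factor multiplying ``e^-a`` in E[J_ii] beyond the focal adult's own
    contribution: additive forms also feel the surrounding conspecifics."""
    p = np.asarray(p, dtype=float)
    if form is JCEForm.AF:
        return np.exp(-(1.0 - math.exp(-params.a)) * p * params.E_F)
    if form is JCEForm.AD:
        return np.exp(-params.a * p * params.E_D * hyper_H(params.a))
    return np.ones_like(p)


def expected_offspring(
    form: JCEForm,
    p_i: float,
    Y_i: float,
    params: JCEParams,
    D: float,
    nd_mode: str = "closed",
) -> ExpectedOffspring:
    """Expected offspring abundances of species i on natal (``own``) and
    heterospecific (``away``) patches."""
    if not 0.0 <= p_i <= 1.0:
        raise ValueError("p_i must lie in [0, 1]")
    a = params.a
    own = Y_i * (1.0 - D + p_i * D) * math.exp(-a) * float(_own_extra_factor(form, p_i, params))
    away = Y_i * p_i * D * float(mean_away_survival(form, p_i, params, nd_mode=nd_mode))
    return ExpectedOffspring(own=own, away=away)


def ode_rhs(
    p: np.ndarray,
    Y: np.ndarray,
    params: JCEParams,
    D: float,
    delta: float = 1.0,
    nd_mode: str = "closed",
) -> np.ndarray:
    """Right-hand side of the community dynamics, O(N) per call.

    With ``own_i = E[S_ii]``, ``away_i = E[S_ik]`` (k != i) and
    ``T = sum_n away_n``, the patch totals are ``A_k = own_k + T - away_k``
    and

        dp_i/dt = delta * [ p_i own_i / A_i + away_i sum_{k != i} p_k / A_k - p_i ].
    """
    # adaptive solvers probe slightly outside [0,1]; evaluate at the clipped state
    p = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
    a = params.a
    own = Y * (1.0 - D + p * D) * math.exp(-a) * _own_extra_factor(params.form, p, params)
    away = Y * p * D * np.asarray(mean_away_survival(params.form, p, params, nd_mode=nd_mode))
    T = away.sum()
    A = own + T - away
    ratio = p / A
    total_ratio = ratio.sum()
    return delta * (ratio * own + away * (total_ratio - ratio) - p)


@dataclass
class ODEResult:
    """Equilibrium summary of one mean-field run."""

    p: np.ndarray
    Y: np.ndarray
    t_end: float
    richness: int
    shannon: float
    ln_threshold: float
    pruned: list
    params: JCEParams
    D: float

    def state_frame(self):
        import pandas as pd

        with np.errstate(divide="ignore"):
            lnp = np.log(self.p)
        return pd.DataFrame(
            {
                "species": np.arange(len(self.p)),
                "ln_p": lnp,
                "Y": self.Y,
                "extant": lnp >= self.ln_threshold,
            }
        )


def run_ode(
    Y: np.ndarray,
    params: JCEParams,
    D: float,
    t_end: float = 10_000.0,
    ln_threshold: float = -11.0,
    delta: float = 1.0,
    nd_mode: str = "closed",
    rtol: float = 1e-8,
    atol: float = 1e-12,
    p0: np.ndarray | None = None,
    n_segments: int = 40,
) -> ODEResult:
    """Integrate the community from uniform proportions to ``t_end``.

    Integration proceeds in segments with a stiff-capable adaptive solver
    (LSODA); after each segment, species with ``ln p`` below the hard floor
    ``PRUNE_LN`` are removed from the active system (and recorded), keeping
    it well-conditioned.  Richness and Shannon diversity are evaluated at
    ``t_end`` with the inclusive ``ln_threshold``.
    """
    Y = np.asarray(Y, dtype=float)
    N = len(Y)
    if p0 is None:
        p0 = np.full(N, 1.0 / N)
    else:
        p0 = np.asarray(p0, dtype=float)

    active = np.arange(N)
    p = p0.copy()
    pruned: list = []
    t = 0.0
    seg = t_end / n_segments
    floor = math.exp(PRUNE_LN)

    while t < t_end - 1e-9:
        t_next = min(t + seg, t_end)
        sol = integrate.solve_ivp(
            lambda _t, q: ode_rhs(q, Y[active], params, D, delta=delta, nd_mode=nd_mode),
            (t, t_next),
            p[active],
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed at t={t}: {sol.message}")
        q = np.clip(sol.y[:, -1], 0.0, None)
        p[:] = 0.0
        p[active] = q
        t = t_next
        dead = active[q < floor]
        if len(dead):
            pruned.extend((t, int(i)) for i in dead)
            p[dead] = 0.0
            active = active[q >= floor]
            p[active] /= p[active].sum()

    p = p / p.sum()
    return ODEResult(
        p=p,
        Y=Y,
        t_end=t_end,
        richness=_richness(p, ln_threshold),
        shannon=shannon_diversity(p),
        ln_threshold=ln_threshold,
        pruned=pruned,
        params=params,
        D=D,
    )
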
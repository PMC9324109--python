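"""Approximate invasion criteria and their exact numerical counterpart.

For a rare invader facing ``N`` residents under global dispersal (D = 1),
each functional form admits an approximate invasion criterion

    Y_inv  >  Ybar * E[J_away](1/N)                      (mean-JCE-fitness term)
            + N Cov(p, Y) * d/dp[ p E[J_away](p) ]|_{p=1/N}   (covariance-JCE term)

whose right-hand side is the *minimum invader fitness*.  The mean term is
the mean JCE-scaled fitness of the resident community; the covariance term
quantifies extra competition from residents that are both fit and common
(``Cov(p, Y) > 0`` because fitter species equilibrate at higher
proportions), discounted by how strongly JCEs punish commonness.

The covariance coefficients for NF, AF and AD have closed forms; the ND
coefficient (a large expression) is evaluated numerically as the same
derivative ``d/dp[p E[J_away](p)]`` at ``p = 1/N`` by central differences —
the quantity the three analytic coefficients instantiate exactly.

``Cov(p, Y)`` is the population covariance (divisor ``N``): the only
convention under which the ``a = 0`` limit recovers the lottery threshold
``sum_i p_i Y_i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core import JCEForm, JCEParams
from .ode import hyper_H, mean_away_survival, ode_rhs

__all__ = [
    "InvasionBreakdown",
    "invasion_breakdown",
    "covariance_coefficient",
    "exact_invasion_threshold",
    "equilibrium_invasion_analysis",
]


@dataclass
class InvasionBreakdown:
    """Two-term decomposition of the minimum invader fitness."""

    form: JCEForm
    mean_jce_fitness_term: float
    covariance_jce_term: float
    Ybar: float
    cov_pY: float
    N: int
    gamma_star: float | None = None

    @property
    def min_invader_fitness(self) -> float:
        return self.mean_jce_fitness_term + self.covariance_jce_term


def _numeric_coefficient(form: JCEForm, params: JCEParams, N: int, nd_mode: str = "closed") -> float:
    p0 = 1.0 / N
    h = p0 * 1e-4
    f = lambda p: p * float(mean_away_survival(form, p, params, nd_mode=nd_mode))
    return (f(p0 + h) - f(p0 - h)) / (2.0 * h)


def covariance_coefficient(
    form: JCEForm, params: JCEParams, N: int, nd_mode: str = "closed"
) -> float:
    """Coefficient multiplying ``N Cov(p, Y)`` in the invasion criterion."""
    a = params.a
    if form is JCEForm.NF:
        E = params.E_F / N
        return math.exp(-E) * (1.0 - math.exp(-a)) * (1.0 - E) + math.exp(-a)
    if form is JCEForm.AF:
        c = (1.0 - math.exp(-a)) * params.E_F / N
        return (1.0 - c) * math.exp(-c)
    if form is JCEForm.AD:
        c = a * hyper_H(a) * params.E_D / N
        return (1.0 - c) * math.exp(-c)
    if form is JCEForm.ND:
        return _numeric_coefficient(form, params, N, nd_mode=nd_mode)
    raise ValueError(f"unknown form {form!r}")


def invasion_breakdown(
    form: JCEForm,
    p: np.ndarray,
    Y: np.ndarray,
    params: JCEParams,
    nd_mode: str = "closed",
) -> InvasionBreakdown:
    """Evaluate the Table-style decomposition at a resident community ``(p, Y)``."""
    p = np.asarray(p, dtype=float)
    Y = np.asarray(Y, dtype=float)
    N = len(p)
    if N < 2:
        raise ValueError("need at least two residents")
    Ybar = float(Y.mean())
    cov = float(np.mean(p * Y) - p.mean() * Y.mean())  # population covariance
    mean_term = Ybar * float(mean_away_survival(form, 1.0 / N, params, nd_mode=nd_mode))
    coeff = covariance_coefficient(form, params, N, nd_mode=nd_mode)
    return InvasionBreakdown(
        form=form,
        mean_jce_fitness_term=mean_term,
        covariance_jce_term=N * cov * coeff,
        Ybar=Ybar,
        cov_pY=cov,
        N=N,
        gamma_star=coeff if form is JCEForm.ND else None,
    )


def exact_invasion_threshold(
    form: JCEForm,
    p: np.ndarray,
    Y: np.ndarray,
    params: JCEParams,
    D: float = 1.0,
    p_invader: float = 1e-8,
    nd_mode: str = "closed",
    tol: float = 1e-6,
) -> float:
    """Smallest invader fitness with positive growth at proportion ``p_invader``.

    Appends the invader to the resident community (residents rescaled by
    ``1 - p_invader``) and bisects on the sign of the invader's growth rate
    under the mean-field dynamics.
    """
    p = np.asarray(p, dtype=float)
    Y = np.asarray(Y, dtype=float)
    p_full = np.append(p * (1.0 - p_invader), p_invader)

    def growth(Y_inv: float) -> float:
        Y_full = np.append(Y, Y_inv)
        return ode_rhs(p_full, Y_full, params, D, delta=1.0, nd_mode=nd_mode)[-1]

    lo, hi = 1e-12, max(float((p * Y).sum()), float(Y.max())) * 2.0
    tries = 0
    while growth(hi) <= 0:
        hi *= 4.0
        tries += 1
        if tries > 20:
            raise RuntimeError("failed to bracket the invasion threshold from above")
    if growth(lo) >= 0:
        return lo
    return float(optimize.brentq(growth, lo, hi, xtol=tol))


def equilibrium_invasion_analysis(
    aA_values,
    v: float,
    g: float,
    sigma_Y: float,
    seed: int,
    N0: int = 300,
    t_end: float = 10_000.0,
    ln_threshold: float = -11.0,
    nd_mode: str = "closed",
):
    """Per-form invasion breakdowns at ODE equilibria over an ``aA`` grid.

    Mirrors the simulation-then-decompose pipeline: for each ``aA``, the
    four normalised models are run to equilibrium under global dispersal
    (D = 1), residents are the species above the extinction threshold, and
    the breakdown is evaluated at their realised proportions and fitnesses.
    Returns a tidy :class:`pandas.DataFrame`.
    """
    import pandas as pd

    from .core import sample_fitness
    from .normalization import normalized_parameter_set
    from .ode import run_ode

    Y = sample_fitness(N0, sigma_Y, seed)
    rows = []
    for aA in aA_values:
        nps = normalized_parameter_set(
            aA, v, g, D=1.0, sigma_Y=sigma_Y, seed=seed, N0=N0, t_end=t_end,
            ln_threshold=ln_threshold, Y=Y,
        )
        for form in JCEForm:
            params = nps[form]
            res = run_ode(Y, params, D=1.0, t_end=t_end, ln_threshold=ln_threshold)
            with np.errstate(divide="ignore"):
                extant = np.log(res.p, where=res.p > 0, out=np.full_like(res.p, -np.inf)) >= ln_threshold
            p_res = res.p[extant] / res.p[extant].sum()
            bd = invasion_breakdown(form, p_res, Y[extant], params, nd_mode=nd_mode)
            rows.append(
                {
                    "form": form.name,
                    "aA": aA,
                    "a": params.a,
                    "N_residents": bd.N,
                    "mean_term": bd.mean_jce_fitness_term,
                    "cov_term": bd.covariance_jce_term,
                    "min_fitness": bd.min_invader_fitness,
                    "Ybar": bd.Ybar,
                    "cov_pY": bd.cov_pY,
                }
            )
    return pd.DataFrame(rows)
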
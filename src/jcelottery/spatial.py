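"""Discrete-time spatially explicit lottery simulation on a gridded torus.

Each of the ``M = L x L`` patches holds one adult.  Per time-step every
adult dies independently with probability ``delta``; a dying adult is
immediately replaced by an offspring drawn from the patch's offspring pool
(a lottery), where the pool reflects uniform dispersal of a fraction ``D``
of each tree's seeds, local retention of ``1 - D``, and Janzen-Connell
mortality from nearby conspecific adults.  Surviving adults' patches are
untouched (no seed bank).

Offspring abundances on a patch occupied by species ``k`` at location ``x``:

    S_ii(x) = Y_i (1 - D + p_i D) J_ii(x)          (natal patch, i = k)
    S_ik(x) = Y_i p_i D J_ik(x)                    (i != k)

with ``p_i`` the current global adult proportion and ``J`` the survival
kernel of the chosen functional form.  Because the focal occupant always
contributes predation weight 1 (distance zero), all four kernels unify to a
single expression per species that includes the focal adult in the
conspecific context; the step routine exploits this and evaluates ``S`` only
on dying patches (identical results to evaluating everywhere).

Distance-decay forms measure minimum-image Euclidean distance between patch
centres (spacing ``1/sqrt(g)`` m); fixed-distance forms use square Moore
neighbourhoods of side ``moore_k`` patches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np

from .core import CommunityParams, JCEForm, JCEParams
from .kernels import AD_TRUNCATION_EPS

__all__ = ["Landscape", "SpatialRun", "init_landscape", "patch_offspring", "step", "run_spatial"]

@numba.njit(cache=True)
def _decay_accumulate(occ_flat, rows, cols, K2, L, N, additive):
    """Per-species kernel aggregation at the queried patches.

    additive=True: sum of exp(-d/v) over conspecific adults (AD);
    additive=False: max of exp(-d/v), i.e. exp(-d_min/v) (ND).  The focal
    occupant is included (offset zero, weight 1).
    """
    m = rows.size
    M = occ_flat.size
    out = np.zeros((m, N))
    for t in range(m):
        r = rows[t]
        c = cols[t]
        for q in range(M):
            s = occ_flat[q]
            w = K2[q // L - r + L, q % L - c + L]
            if additive:
                out[t, s] += w
            elif w > out[t, s]:
                out[t, s] = w
    return out


@dataclass
class Landscape:
    """``L x L`` torus of adult occupants (species ids ``0..N-1``)."""

    occupant: np.ndarray
    spacing: float

    def __post_init__(self):
        self.occupant = np.asarray(self.occupant)
        if self.occupant.ndim != 2 or self.occupant.shape[0] != self.occupant.shape[1]:
            raise ValueError("occupant must be a square array")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def L(self) -> int:
        return self.occupant.shape[0]

    @property
    def M(self) -> int:
        return self.occupant.size

    def counts(self, N: int) -> np.ndarray:
        return np.bincount(self.occupant.ravel(), minlength=N)

    def proportions(self, N: int) -> np.ndarray:
        return self.counts(N) / self.M

    def copy(self) -> "Landscape":
        return Landscape(self.occupant.copy(), self.spacing)

    def to_csv(self, path) -> None:
        """Write the occupant matrix as comma-separated integers."""
        np.savetxt(path, self.occupant, fmt="%d", delimiter=",")

    @classmethod
    def from_csv(cls, path, g: float) -> "Landscape":
        occ = np.loadtxt(path, dtype=int, delimiter=",")
        return cls(occ, spacing=1.0 / np.sqrt(g))


@dataclass
class SpatialRun:
    """Outcome of one spatial simulation."""

    richness: np.ndarray
    shannon: np.ndarray
    landscape: Landscape
    seed: int
    generations: int
    converged: bool
    cparams: CommunityParams
    jparams: JCEParams

    @property
    def final_richness(self) -> int:
        return int(self.richness[-1])

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": np.arange(len(self.richness)),
                "richness": self.richness,
                "shannon": self.shannon,
            }
        )


def init_landscape(L: int, proportions, seed, g: float = 0.172) -> Landscape:
    """Populate an ``L x L`` torus with occupants drawn i.i.d. from ``proportions``."""
    if L < 2:
        raise ValueError("L must be >= 2")
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be a simplex vector")
    rng = np.random.default_rng(seed)
    occ = rng.choice(len(p), size=(L, L), p=p)
    return Landscape(occ, spacing=1.0 / np.sqrt(g))


# ---------------------------------------------------------------------------
# Survival kernels evaluated at a batch of patches (focal occupant included
# in the conspecific context; see module docstring).
# ---------------------------------------------------------------------------


def _moore_counts(occ: np.ndarray, rows: np.ndarray, cols: np.ndarray, k: int, N: int) -> np.ndarray:
    """Conspecific counts per species in the k x k Moore neighbourhood
    (focal patch included) around each queried patch.  Returns (m, N)."""
    L = occ.shape[0]
    half = k // 2
    offs = np.arange(-half, half + 1)
    di, dj = np.meshgrid(offs, offs, indexing="ij")
    di, dj = di.ravel(), dj.ravel()
    ids = occ[(rows[:, None] + di[None, :]) % L, (cols[:, None] + dj[None, :]) % L]
    m = len(rows)
    counts = np.zeros((m, N), dtype=np.int32)
    np.add.at(counts, (np.repeat(np.arange(m), k * k), ids.ravel()), 1)
    return counts


def _batch_survival(
    landscape: Landscape,
    rows: np.ndarray,
    cols: np.ndarray,
    jparams: JCEParams,
    N: int,
    moore_k: int | None,
    truncation_eps: float | None = AD_TRUNCATION_EPS,
) -> np.ndarray:
    """J_s(x) for every species s at each queried patch x.  Returns (m, N)."""
    form, a = jparams.form, jparams.a
    occ = landscape.occupant
    L = landscape.L
    m = len(rows)

    if not form.distance_decay:
        if moore_k is None:
            raise ValueError("fixed-distance forms require moore_k")
        counts = _moore_counts(occ, rows, cols, moore_k, N)
        if form is JCEForm.NF:
            return np.where(counts > 0, np.exp(-a), 1.0)
        return np.exp(-a * counts.astype(float))

    v = jparams.v
    occ_flat = np.ascontiguousarray(occ.ravel(), dtype=np.int64)

    # doubled lattice-offset kernel table, indexed by raw offset + L (no
    # modulo): K2[di + L, dj + L] = exp(-minimum-image distance / v)
    off = np.abs(np.arange(-L, L)) % L
    wrapped = np.minimum(off, L - off).astype(float)
    d = np.sqrt(wrapped[:, None] ** 2 + wrapped[None, :] ** 2) * landscape.spacing
    K2 = np.exp(-d / v)
    if truncation_eps is not None and form is JCEForm.AD:
        K2[K2 < truncation_eps] = 0.0

    agg = _decay_accumulate(
        occ_flat, rows.astype(np.int64), cols.astype(np.int64), K2, L, N,
        form is JCEForm.AD,
    )
    # AD: conspecific weighted density; ND: max weight = exp(-d_min/v)
    return np.exp(-a * agg)


def patch_offspring(
    landscape: Landscape,
    patch: tuple[int, int],
    cparams: CommunityParams,
    jparams: JCEParams,
    moore_k: int | None = None,
) -> np.ndarray:
    """Per-species offspring abundance ``S_.(x)`` on one patch.

    Reference (single-patch) entry point; the step routine evaluates the
    same quantity in batch on dying patches.
    """
    i, j = patch
    N = cparams.N0
    p = landscape.proportions(N)
    J = _batch_survival(landscape, np.array([i]), np.array([j]), jparams, N, moore_k)[0]
    S = cparams.Y * p * cparams.D * J
    k = landscape.occupant[i, j]
    S[k] += cparams.Y[k] * (1.0 - cparams.D) * J[k]
    return S


def step(
    landscape: Landscape,
    cparams: CommunityParams,
    jparams: JCEParams,
    rng: np.random.Generator,
    moore_k: int | None = None,
    inplace: bool = False,
) -> Landscape:
    """Advance the community one time-step (death + lottery replacement)."""
    out = landscape if inplace else landscape.copy()
    occ = out.occupant
    L = out.L
    N = cparams.N0

    dying = rng.random(out.M) < cparams.delta
    idx = np.nonzero(dying)[0]
    # successor draws consume one uniform per dying patch regardless of count
    u = rng.random(len(idx))
    if len(idx) == 0:
        return out

    rows, cols = idx // L, idx % L
    p = out.proportions(N)
    J = _batch_survival(out, rows, cols, jparams, N, moore_k)
    S = cparams.Y[None, :] * (p * cparams.D)[None, :] * J
    occ_dying = occ[rows, cols]
    ar = np.arange(len(idx))
    S[ar, occ_dying] += cparams.Y[occ_dying] * (1.0 - cparams.D) * J[ar, occ_dying]

    tot = S.sum(axis=1)
    ok = tot > 0
    succ = occ_dying.copy()  # patches with no offspring retain the previous occupant
    if ok.any():
        cum = np.cumsum(S[ok], axis=1)
        draw = u[ok] * cum[:, -1]
        succ[ok] = (draw[:, None] >= cum).sum(axis=1)
    occ[rows, cols] = succ
    return out


def run_spatial(
    cparams: CommunityParams,
    jparams: JCEParams,
    L: int,
    seed: int,
    max_generations: int = 10_000,
    stop_window: int = 500,
    moore_k: int | None = None,
    initial_proportions=None,
) -> SpatialRun:
    """Iterate the lottery until species richness stabilises.

    Stops when richness (number of species with at least one adult) has been
    constant over a trailing ``stop_window`` time-steps, or at
    ``max_generations``.  The trace is strictly non-increasing — there is no
    immigration.
    """
    N = cparams.N0
    if initial_proportions is None:
        initial_proportions = np.full(N, 1.0 / N)
    rng = np.random.default_rng(seed)
    land = init_landscape(L, initial_proportions, rng, g=cparams.g)

    def summaries(l):
        c = l.counts(N)
        pos = c[c > 0] / l.M
        return int(len(pos)), float(-(pos * np.log(pos)).sum())

    r0, h0 = summaries(land)
    richness = [r0]
    shannon = [h0]
    converged = False
    for _ in range(max_generations):
        step(land, cparams, jparams, rng, moore_k=moore_k, inplace=True)
        r, h = summaries(land)
        richness.append(r)
        shannon.append(h)
        if len(richness) > stop_window and richness[-1 - stop_window] == richness[-1]:
            converged = True
            break
    return SpatialRun(
        richness=np.asarray(richness),
        shannon=np.asarray(shannon),
        landscape=land,
        seed=seed,
        generations=len(richness) - 1,
        converged=converged,
        cparams=cparams,
        jparams=jparams,
    )
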
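import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from jcelottery.core import JCEForm
from jcelottery.kernels import ConspecificContext, conspecific_fields, patch_survival
from jcelottery.spatial import Landscape, init_landscape


def ctx(**kw):
    return ConspecificContext(**kw)


class TestPatchSurvival:
    @pytest.mark.parametrize(
        "form, a, kw, v, r, expected",
        [
            # conspecific occupant with 1-e^-a = 0.4 dies 40% of the time
            ("NF", -math.log(0.6), dict(occupant_conspecific=True), None, 5.0, 0.6),
            # heterospecific occupant, nearest conspecific beyond the radius
            ("NF", 1.0, dict(min_dist=7.0), None, 5.0, 1.0),
            ("NF", 1.0, dict(min_dist=4.0), None, 5.0, math.exp(-1.0)),
            # additive fixed: occupant + one neighbour => exponent 2a
            ("AF", 0.5, dict(count_in_radius=1, occupant_conspecific=True), None, 5.0, math.exp(-1.0)),
            # decay at one decay length
            ("ND", 0.7, dict(min_dist=4.0), 4.0, None, math.exp(-0.7 * math.exp(-1.0))),
            # occupant (weight 1) + adult at v*ln2 (weight 0.5)
            ("AD", 1.0, dict(weighted_density=0.5, occupant_conspecific=True), 4.0, None, math.exp(-1.5)),
        ],
    )
    def test_known_values(self, form, a, kw, v, r, expected):
        J = patch_survival(JCEForm[form], a, ctx(**kw), v=v, r=r)
        assert J == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("form", list(JCEForm))
    def test_zero_predation_means_full_survival(self, form):
        c = ctx(min_dist=1.0, count_in_radius=3, weighted_density=2.0, occupant_conspecific=True)
        assert patch_survival(form, 0.0, c, v=5.0, r=5.0) == 1.0

    def test_negative_pressure_rejected(self):
        with pytest.raises(ValueError):
            patch_survival(JCEForm.NF, -0.1, ctx(), r=5.0)

    def test_inconsistent_context_rejected(self):
        with pytest.raises(ValueError):
            ctx(min_dist=0.0)
        with pytest.raises(ValueError):
            ctx(count_in_radius=-1)
        with pytest.raises(ValueError):
            patch_survival(JCEForm.ND, 1.0, ctx(min_dist=3.0), v=None)

    @given(
        a=st.floats(0.0, 5.0),
        d=st.floats(0.5, 40.0),
        n=st.integers(0, 10),
        w=st.floats(0.0, 10.0),
    )
    def test_monotone_in_pressure_and_context(self, a, d, n, w):
        v, r = 5.0, 7.0
        base = {
            JCEForm.NF: patch_survival(JCEForm.NF, a, ctx(min_dist=d), r=r),
            JCEForm.AF: patch_survival(JCEForm.AF, a, ctx(count_in_radius=n), r=r),
            JCEForm.ND: patch_survival(JCEForm.ND, a, ctx(min_dist=d), v=v),
            JCEForm.AD: patch_survival(JCEForm.AD, a, ctx(weighted_density=w), v=v),
        }
        for form, J in base.items():
            assert 0.0 < J <= 1.0
            assert patch_survival(form, a + 0.5, ctx(min_dist=d, count_in_radius=n, weighted_density=w), v=v, r=r) <= J + 1e-15
        # more neighbours / tighter packing never helps survival
        assert patch_survival(JCEForm.AF, a, ctx(count_in_radius=n + 1), r=r) <= base[JCEForm.AF]
        assert patch_survival(JCEForm.AD, a, ctx(weighted_density=w + 0.5), v=v) <= base[JCEForm.AD]
        assert patch_survival(JCEForm.ND, a, ctx(min_dist=d + 1.0), v=v) >= base[JCEForm.ND]

    @given(a=st.floats(0.0, 5.0), d=st.floats(0.5, 40.0))
    def test_ad_equals_nd_for_single_source_tree(self, a, d):
        v = 6.0
        nd = patch_survival(JCEForm.ND, a, ctx(min_dist=d), v=v)
        ad = patch_survival(JCEForm.AD, a, ctx(weighted_density=math.exp(-d / v)), v=v)
        assert nd == pytest.approx(ad, rel=1e-12)


def brute_force_context(land: Landscape, species: int, i: int, j: int, v: float, k: int):
    """O(M) double-loop oracle for one patch's conspecific context."""
    L = land.L
    occ = land.occupant
    half = k // 2
    min_dist, weighted, count = math.inf, 0.0, 0
    for ii in range(L):
        for jj in range(L):
            if occ[ii, jj] != species or (ii == i and jj == j):
                continue
            di = min(abs(ii - i), L - abs(ii - i))
            dj = min(abs(jj - j), L - abs(jj - j))
            d = math.hypot(di, dj) * land.spacing
            min_dist = min(min_dist, d)
            weighted += math.exp(-d / v)
            if min(abs(ii - i), L - abs(ii - i)) <= half and min(abs(jj - j), L - abs(jj - j)) <= half:
                count += 1
    return min_dist, count, weighted, occ[i, j] == species


class TestConspecificFields:
    def test_absent_species_has_empty_context(self):
        land = Landscape(np.zeros((6, 6), dtype=int), spacing=1.0)
        f = conspecific_fields(land, species=3, form=JCEForm.AD, v=5.0)
        assert np.all(np.isinf(f.min_dist))
        assert not f.count_in_radius.any()
        assert not f.weighted_density.any()
        assert not f.occupant_conspecific.any()

    def test_single_adult_pythagorean_distance(self):
        occ = np.zeros((20, 20), dtype=int)
        occ[3, 4] = 1
        land = Landscape(occ, spacing=1.0)
        f = conspecific_fields(land, species=1, form=JCEForm.AD, v=5.0)
        # offset (3, 4) from the origin: a 3-4-5 triangle
        assert f.min_dist[0, 0] == pytest.approx(5.0)
        assert f.weighted_density[0, 0] == pytest.approx(math.exp(-1.0))
        assert np.isinf(f.min_dist[3, 4])  # the adult's own patch: no *other* conspecific

    def test_minimum_image_wraps_torus_edge(self):
        L = 10
        occ = np.zeros((L, L), dtype=int)
        occ[0, 0] = 1
        land = Landscape(occ, spacing=1.0)
        f = conspecific_fields(land, species=1, form=JCEForm.ND, v=5.0)
        assert f.min_dist[0, L - 1] == pytest.approx(1.0)
        assert f.min_dist[L - 1, L - 1] == pytest.approx(math.sqrt(2.0))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        land = init_landscape(20, np.full(5, 0.2), seed=rng, g=0.25)
        v, k = 4.0, 5
        for species in range(5):
            f = conspecific_fields(land, species, JCEForm.AD, v=v, moore_k=k, truncation_eps=None)
            for i, j in [(0, 0), (7, 13), (19, 19), (10, 2), (3, 18)]:
                md, cnt, wd, occ_c = brute_force_context(land, species, i, j, v, k)
                assert f.min_dist[i, j] == pytest.approx(md, rel=1e-10)
                assert f.count_in_radius[i, j] == cnt
                assert f.weighted_density[i, j] == pytest.approx(wd, rel=1e-10)
                assert f.occupant_conspecific[i, j] == occ_c

    @given(st.integers(0, 11), st.integers(0, 11))
    def test_translation_invariance_on_torus(self, si, sj):
        rng = np.random.default_rng(99)
        land = init_landscape(12, np.full(4, 0.25), seed=rng, g=0.25)
        shifted = Landscape(np.roll(land.occupant, (si, sj), axis=(0, 1)), land.spacing)
        f0 = conspecific_fields(land, 1, JCEForm.AD, v=3.0, moore_k=3)
        f1 = conspecific_fields(shifted, 1, JCEForm.AD, v=3.0, moore_k=3)
        assert np.allclose(np.roll(f0.weighted_density, (si, sj), axis=(0, 1)), f1.weighted_density)
        assert np.allclose(np.roll(f0.min_dist, (si, sj), axis=(0, 1)), f1.min_dist)
        assert np.array_equal(np.roll(f0.count_in_radius, (si, sj), axis=(0, 1)), f1.count_in_radius)
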
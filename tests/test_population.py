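"""Rate law identities, growth, death, division, shoving, trimming."""

import math

import numpy as np
import pytest

from plaquesim import population as pop
from plaquesim.biofilm import BiofilmState, RngStreams, init_biofilm, mass_to_radius
from plaquesim.fields import SoluteFields
from plaquesim.params import PTYPE_A, PTYPE_NA, TypeParams


@pytest.fixture()
def tp_a(params):
    return params.type_A


def _state_from_arrays(params, mass, pos, ptype=None, seed=7):
    n = len(mass)
    return BiofilmState(
        ids=np.arange(n, dtype=np.int64),
        ptype=np.zeros(n, dtype=np.int8) if ptype is None else np.asarray(ptype, np.int8),
        mass=np.asarray(mass, float),
        pos=np.asarray(pos, float),
        fields=SoluteFields.resting(params),
        t=0.0,
        rng=RngStreams(seed),
        next_id=n,
    )


class TestMetabolicRate:
    def test_half_saturation_and_preferred_acidity(self, tp_a):
        # both factors at their reference points: Monod = 1/2, pH factor = 1
        r = pop.metabolic_rate(10.0, tp_a.K_Gl, tp_a.K_acid, tp_a)
        assert r == pytest.approx(0.5 * 10.0 * tp_a.mu_max, rel=1e-12)

    def test_sugar_saturation_limit(self, tp_a):
        r = pop.metabolic_rate(3.0, 1e9 * tp_a.K_Gl, tp_a.K_acid, tp_a)
        assert r == pytest.approx(3.0 * tp_a.mu_max, rel=1e-6)

    def test_ninefold_acidity_gives_point_eighteen(self, tp_a):
        # pH factor 4*9/(10^2) = 0.36, Monod 1/2 -> r = 0.18 m mu_max
        r = pop.metabolic_rate(1.0, tp_a.K_Gl, 9.0 * tp_a.K_acid, tp_a)
        assert r == pytest.approx(0.18 * tp_a.mu_max, rel=1e-12)

    def test_ph_factor_peaks_exactly_at_preferred_acidity(self, tp_a):
        h = tp_a.K_acid * np.logspace(-2, 2, 201)
        r = pop.metabolic_rate(1.0, 1e9, h, tp_a)
        assert np.argmax(r) == 100
        assert r[100] == pytest.approx(tp_a.mu_max, rel=1e-9)

    def test_ph_factor_symmetric_in_ph_about_preferred(self, tp_a):
        # h -> K^2/h leaves the factor unchanged (symmetry in pH units)
        h = tp_a.K_acid * np.logspace(-3, 3, 61)
        r1 = pop.metabolic_rate(1.0, 1e9, h, tp_a)
        r2 = pop.metabolic_rate(1.0, 1e9, tp_a.K_acid**2 / h, tp_a)
        np.testing.assert_allclose(r1, r2, rtol=1e-12)

    def test_monotone_in_sugar_at_fixed_acidity(self, tp_a):
        gl = np.linspace(0, 10, 300)
        r = pop.metabolic_rate(1.0, gl, tp_a.K_acid, tp_a)
        assert np.all(np.diff(r) > 0)

    def test_rate_bounded_by_m_mu_max(self, tp_a, rng):
        gl = rng.random(1000) * 100
        h = 10 ** (-rng.random(1000) * 7)
        r = pop.metabolic_rate(2.0, gl, h, tp_a)
        assert np.all(r <= 2.0 * tp_a.mu_max * (1 + 1e-12))
        assert np.all(r >= 0)


class TestGrowth:
    def test_zero_rate_leaves_mass_unchanged(self, params):
        st = _state_from_arrays(params, [5.0], [[1, 1, 3]])
        pop.grow_particles(st, np.array([0.0]), params, 10.0)
        assert st.mass[0] == 5.0

    def test_yield_arithmetic(self, params):
        p = params.replace(Y=0.1)
        st = _state_from_arrays(p, [5.0], [[1, 1, 3]])
        pop.grow_particles(st, np.array([2.0]), p, 10.0)
        assert st.mass[0] == pytest.approx(5.0 + 0.1 * 2.0 * 10.0)

    def test_same_yield_for_both_types(self, params):
        # equal conversion rates give identical growth increments for A and NA
        st = _state_from_arrays(
            params, [5.0, 5.0], [[1, 1, 3], [4, 4, 3]], ptype=[PTYPE_A, PTYPE_NA]
        )
        pop.grow_particles(st, np.array([1.7, 1.7]), params, 30.0)
        assert st.mass[0] == st.mass[1]


class TestDeath:
    def test_zero_acidity_zero_rate(self, tp_a):
        assert pop.death_rate(tp_a, 0.0) == 0.0

    def test_na_dies_exactly_twice_as_fast(self, params):
        h = np.logspace(-7, -4, 10)
        ra = pop.death_rate(params.type_A, h, params.death_prefactor)
        rna = pop.death_rate(params.type_NA, h, params.death_prefactor)
        np.testing.assert_allclose(rna / ra, 2.0, rtol=1e-12)

    def test_rate_arithmetic(self):
        tp = TypeParams("A", 1e-3, 0.1, 1e-5, 1e-9)
        assert pop.death_rate(tp, 1e-5, 1e7) == pytest.approx(1e-7, rel=1e-12)

    def test_monte_carlo_matches_exponential_form(self, params):
        # rate * dt = ln 2 -> removal probability exactly 1/2
        n = 10_000
        dt = 30.0
        rate = math.log(2) / dt
        h = rate / (params.death_prefactor * params.type_NA.K_death)
        st = _state_from_arrays(
            params, np.ones(n), np.zeros((n, 3)) + [1, 1, 3],
            ptype=np.zeros(n), seed=42,
        )
        n_dead = pop.apply_deaths(st, np.full(n, h), params, dt)
        p_hat = n_dead / n
        sigma = math.sqrt(0.25 / n)
        assert abs(p_hat - 0.5) < 3 * sigma

    def test_all_zero_rates_no_removals(self, params):
        st = _state_from_arrays(params, [1.0, 2.0], [[1, 1, 3], [2, 2, 3]])
        assert pop.apply_deaths(st, np.array([1e-30, 1e-30]), params, 10.0) == 0
        assert st.n == 2

    def test_deaths_concentrate_where_acid_is_highest(self, params, rng):
        # acid gradient decreasing with height: removed particles must sit
        # lower, on average, than survivors
        n = 400
        z = rng.random(n) * params.B
        h = 1e-5 * np.exp(-z / 8.0)  # most acidic at the tooth surface
        dead_z, surv_z = [], []
        for seed in range(30):
            st = _state_from_arrays(
                params, np.ones(n), np.c_[rng.random(n) * 10, rng.random(n) * 10, z],
                seed=seed,
            )
            before = set(st.ids)
            pop.apply_deaths(st, h, params.replace(death_prefactor=1e7), 3000.0)
            after = set(st.ids)
            surv_z.extend(st.pos[:, 2])
            dead_z.extend(z[list(before - after)])
        assert np.mean(dead_z) < np.mean(surv_z)


class TestDivision:
    def test_supercritical_particle_splits_conserving_mass(self, params):
        m = 1.01 * params.m_crit
        st = _state_from_arrays(params, [m], [[10, 10, 10]])
        n_div = pop.divide_particles(st, params)
        assert n_div == 1 and st.n == 2
        assert st.mass.sum() == pytest.approx(m, rel=1e-15)
        assert st.mass[0] == st.mass[1]
        assert len(set(st.ids)) == 2

    def test_daughters_below_critical_no_cascade(self, params):
        st = _state_from_arrays(params, [1.3 * params.m_crit], [[10, 10, 10]])
        pop.divide_particles(st, params)
        d = 2 * mass_to_radius(st.mass, params.rho)
        assert np.all(d < params.d_crit)
        assert pop.divide_particles(st, params) == 0

    def test_subcritical_state_unchanged(self, params):
        st = _state_from_arrays(params, [0.9 * params.m_crit], [[10, 10, 10]])
        assert pop.divide_particles(st, params) == 0
        assert st.n == 1

    def test_daughters_never_penetrate_tooth(self, params):
        # parent resting on the tooth plane: both daughters keep z >= radius
        m = 1.05 * params.m_crit
        r_parent = mass_to_radius(m, params.rho)
        for seed in range(20):
            st = _state_from_arrays(params, [m], [[10, 10, r_parent]], seed=seed)
            pop.divide_particles(st, params)
            assert np.all(st.pos[:, 2] >= mass_to_radius(st.mass, params.rho) - 1e-12)

    def test_daughters_displaced_by_daughter_radius(self, params):
        st = _state_from_arrays(params, [1.05 * params.m_crit], [[10, 10, 10]])
        pop.divide_particles(st, params)
        r_d = mass_to_radius(st.mass[0], params.rho)
        gap = np.linalg.norm(st.pos[0] - st.pos[1])
        assert gap == pytest.approx(2 * r_d, rel=1e-9)


class TestShoving:
    def test_two_spheres_pushed_to_exact_tangency(self, params):
        m = params.m_crit / 2
        r = mass_to_radius(m, params.rho)
        st = _state_from_arrays(params, [m, m], [[10, 10, 10], [10 + 1.5 * r, 10, 10]])
        pop.relax_overlaps(st, params)
        d = np.linalg.norm(st.pos[0] - st.pos[1])
        assert d == pytest.approx(2 * r, rel=1e-12)
        # symmetric displacement: midpoint unchanged
        assert (st.pos[0, 0] + st.pos[1, 0]) / 2 == pytest.approx(10 + 0.75 * r)

    def test_sphere_below_tooth_plane_lifted(self, params):
        m = params.m_crit / 2
        r = mass_to_radius(m, params.rho)
        st = _state_from_arrays(params, [m], [[5, 5, 0.1 * r]])
        pop.relax_overlaps(st, params)
        assert st.pos[0, 2] == pytest.approx(r)

    def test_random_dense_configuration_resolves(self, params, rng):
        n = 120
        m = np.full(n, params.m_crit / 2)
        pos = np.c_[
            rng.random(n) * params.L,
            rng.random(n) * params.L,
            rng.random(n) * params.B * 0.5 + 1.0,
        ]
        st = _state_from_arrays(params, m, pos, seed=5)
        pop.relax_overlaps(st, params)
        # brute-force O(n^2) oracle on the relaxed state
        assert pop.max_relative_overlap(st, params) <= params.shove_tol + 1e-12
        r = st.radius(params)
        assert np.all(st.pos[:, 2] >= r - 1e-9)
        assert np.all((st.pos[:, 0] >= 0) & (st.pos[:, 0] < params.L))

    def test_coincident_centres_separated(self, params):
        m = params.m_crit / 2
        st = _state_from_arrays(params, [m, m], [[5, 5, 5], [5, 5, 5]])
        pop.relax_overlaps(st, params)
        assert np.linalg.norm(st.pos[0] - st.pos[1]) > 0


class TestTrim:
    def test_nothing_above_ceiling_unchanged(self, params):
        st = _state_from_arrays(params, [1.0, 1.0], [[1, 1, 3], [2, 2, params.B - 1]])
        assert pop.trim_thickness(st, params) == 0
        assert st.n == 2

    def test_counts_and_survivors(self, params, rng):
        n = 10
        z = np.array([3.0] * 7 + [params.B + 1] * 3)
        st = _state_from_arrays(params, np.ones(n), np.c_[np.ones(n), np.ones(n), z])
        assert pop.trim_thickness(st, params) == 3
        assert st.n == 7
        assert np.all(st.pos[:, 2] <= params.B)

    def test_composition_matches_independent_recount(self, params, rng):
        n = 60
        ptype = (rng.random(n) < 0.3).astype(np.int8)
        z = rng.random(n) * params.B * 1.3
        st = _state_from_arrays(
            params, np.ones(n), np.c_[rng.random(n), rng.random(n), z], ptype=ptype
        )
        keep = z <= params.B
        expected = ptype[keep].sum() / keep.sum()
        pop.trim_thickness(st, params)
        assert (st.ptype == PTYPE_A).sum() / st.n == pytest.approx(expected)
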
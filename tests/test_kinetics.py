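"""Kinetic primitives: Forster maps, rate matrices, occupancy-time law."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromofret import kinetics as kin


class TestEfficiencyDistanceMap:
    @pytest.mark.parametrize(
        "r, r0, expected",
        [
            (82.0, 82.0, 0.5),
            (164.0, 82.0, 1.0 / 65.0),
            (41.0, 82.0, 64.0 / 65.0),
        ],
    )
    def test_closed_form(self, r, r0, expected):
        pair = kin.DyePair(r0, 3.6)
        assert kin.efficiency_from_distance(r, pair) == pytest.approx(expected, rel=1e-12)

    def test_inverse_examples(self, pair568):
        assert kin.distance_from_efficiency(0.5, pair568) == pytest.approx(82.0)
        assert kin.distance_from_efficiency(1.0 / 65.0, pair568) == pytest.approx(164.0)

    @given(r=st.floats(min_value=30.0, max_value=150.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, r):
        pair = kin.DyePair(82.0, 3.6)
        e = kin.efficiency_from_distance(r, pair)
        assert kin.distance_from_efficiency(e, pair) == pytest.approx(r, rel=1e-9)

    def test_strictly_monotone(self, pair568):
        r = np.linspace(20, 180, 300)
        e = kin.efficiency_from_distance(r, pair568)
        assert np.all(np.diff(e) < 0)

    def test_domain_errors(self, pair568):
        with pytest.raises(kin.DomainError):
            kin.efficiency_from_distance(-1.0, pair568)
        for bad in (0.0, 1.0, -0.1, 1.3):
            with pytest.raises(kin.DomainError):
                kin.distance_from_efficiency(bad, pair568)

    def test_species_lifetime_relation(self, pair568):
        sp = kin.FRETSpecies("x", pair568, efficiency=0.3)
        assert sp.donor_lifetime == pytest.approx(pair568.donor_lifetime * 0.7)
        sp2 = kin.FRETSpecies("y", pair568, distance=82.0)
        assert sp2.efficiency == pytest.approx(0.5)


class TestRateMatrix:
    def test_relaxation_two_state_symmetric(self, species_pair):
        hi, lo = species_pair
        m = kin.KineticModel([hi, lo], np.array([[0.0, 135.0], [135.0, 0.0]]))
        assert kin.relaxation_times(m)[0] == pytest.approx(1.0 / 270.0)  # 3.7037 ms

    def test_relaxation_fast_pair(self, species_pair):
        hi, lo = species_pair
        m = kin.KineticModel([hi, lo], np.array([[0.0, 8333.3], [8333.3, 0.0]]))
        assert kin.relaxation_times(m)[0] == pytest.approx(60.0e-6, rel=1e-4)

    def test_relaxation_matches_eigendecomposition(self, pair568, rng):
        for n in (3, 4, 5):
            k = rng.uniform(10, 1e4, (n, n))
            np.fill_diagonal(k, 0.0)
            species = [kin.FRETSpecies(f"s{i}", pair568, efficiency=0.1 + 0.8 * i / n) for i in range(n)]
            m = kin.KineticModel(species, k)
            lam = np.linalg.eigvals(m.rate_matrix)
            lam = np.sort(np.real(lam))[: n - 1]
            expected = np.sort(-1.0 / lam)
            np.testing.assert_allclose(kin.relaxation_times(m), expected, rtol=1e-10)

    def test_stationary_examples(self, species_pair):
        hi, lo = species_pair
        sym = kin.KineticModel([hi, lo], np.array([[0.0, 500.0], [500.0, 0.0]]))
        np.testing.assert_allclose(kin.stationary_distribution(sym), [0.5, 0.5], atol=1e-12)
        asym = kin.KineticModel([hi, lo], np.array([[0.0, 100.0], [300.0, 0.0]]))
        np.testing.assert_allclose(kin.stationary_distribution(asym), [0.75, 0.25], atol=1e-12)

    def test_generator_invariants_random(self, pair568, rng):
        for _ in range(5):
            n = int(rng.integers(2, 6))
            k = rng.uniform(1, 1e3, (n, n))
            np.fill_diagonal(k, 0.0)
            species = [kin.FRETSpecies(f"s{i}", pair568, efficiency=0.5) for i in range(n)]
            m = kin.KineticModel(species, k)
            assert np.allclose(m.rate_matrix.sum(axis=1), 0.0, atol=1e-12 * k.max())
            pi = kin.stationary_distribution(m)
            assert pi.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(pi @ m.rate_matrix, 0.0, atol=1e-9 * k.max())
            assert np.all(pi > 0)

    def test_forbidden_transitions_enforced(self, species_pair, pair568):
        hi, lo = species_pair
        mask = np.array([[False, True], [True, False]])
        with pytest.raises(kin.ModelError):
            kin.KineticModel(
                [hi, lo], np.array([[0.0, 10.0], [5.0, 0.0]]),
                connectivity_mask=np.array([[False, False], [True, False]]),
            )
        # disconnected components are allowed, but global stationary law is not
        sp = [kin.FRETSpecies(f"s{i}", pair568, efficiency=0.2 * i + 0.1) for i in range(4)]
        k = np.zeros((4, 4))
        k[0, 1] = k[1, 0] = 100.0
        k[2, 3] = k[3, 2] = 500.0
        m = kin.KineticModel(sp, k, connectivity_mask=k > 0)
        assert len(kin.communicating_classes(m)) == 2
        with pytest.raises(kin.ModelError):
            kin.stationary_distribution(m)
        sub = kin.submodel(m, [2, 3])
        assert kin.relaxation_times(sub)[0] == pytest.approx(1e-3)

    def test_config_round_trip(self, two_state):
        cfg = kin.model_to_config(two_state)
        back = kin.model_from_config(cfg)
        np.testing.assert_array_equal(back.rate_matrix, two_state.rate_matrix)
        for a, b in zip(back.species, two_state.species):
            assert a.name == b.name
            assert a.distance == b.distance
            assert a.pair == b.pair
        assert back.static_fraction == two_state.static_fraction


class TestTrajectories:
    def test_one_state_constant(self, pair568):
        m = kin.KineticModel([kin.FRETSpecies("s", pair568, efficiency=0.4)], np.zeros((1, 1)))
        traj = kin.sample_trajectory(m, 1.0, rng=1)
        assert len(traj.states) == 1
        np.testing.assert_array_equal(traj.occupancy(1), [1.0])

    def test_occupancy_and_jump_statistics(self, species_pair):
        hi, lo = species_pair
        m = kin.KineticModel([hi, lo], np.array([[0.0, 1000.0], [1000.0, 0.0]]))
        rng = np.random.default_rng(7)
        occs, jumps = [], []
        for _ in range(200):
            traj = kin.sample_trajectory(m, 10.0, rng=rng)
            occs.append(traj.occupancy(2)[0])
            jumps.append(len(traj.states) - 1)
        # stationary occupancy 0.5; mean jump count = sum_i pi_i k_i T = 1e4
        se_occ = np.std(occs, ddof=1) / np.sqrt(len(occs))
        assert abs(np.mean(occs) - 0.5) < 3 * se_occ + 1e-3
        se_j = np.std(jumps, ddof=1) / np.sqrt(len(jumps))
        assert abs(np.mean(jumps) - 1e4) < 3 * se_j

    def test_vectorized_sampler_matches_stationary(self, two_state):
        occ = kin.sample_occupancies(two_state, 50e-3, 4000, rng=3)
        assert occ.shape == (4000, 2)
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-12)
        # long windows ergodically average to the stationary law
        np.testing.assert_allclose(occ.mean(axis=0), [0.4, 0.6], atol=0.01)


class TestOccupancyLaw:
    def test_point_masses_and_total_mass(self, species_pair):
        hi, lo = species_pair
        k01, k10, t = 700.0, 300.0, 2e-3
        m = kin.KineticModel([hi, lo], np.array([[0.0, k01], [k10, 0.0]]))
        dens = kin.occupancy_fraction_density(m, t)
        pi0, pi1 = 0.3, 0.7
        assert dens.mass_at_one == pytest.approx(pi0 * np.exp(-k01 * t))
        assert dens.mass_at_zero == pytest.approx(pi1 * np.exp(-k10 * t))
        assert dens.total_mass() == pytest.approx(1.0, abs=1e-9)

    def test_short_window_limit(self, species_pair):
        hi, lo = species_pair
        m = kin.KineticModel([hi, lo], np.array([[0.0, 100.0], [300.0, 0.0]]))
        dens = kin.occupancy_fraction_density(m, 1e-7)
        assert dens.mass_at_one == pytest.approx(0.75, abs=1e-4)
        assert dens.mass_at_zero == pytest.approx(0.25, abs=1e-4)

    def test_long_window_concentrates_at_stationary(self, species_pair):
        hi, lo = species_pair
        m = kin.KineticModel([hi, lo], np.array([[0.0, 1000.0], [1000.0, 0.0]]))
        dens = kin.occupancy_fraction_density(m, 1.0)  # T = 1000 x t_R
        x = np.linspace(0, 1, 20001)
        p = dens.pdf(x)
        p /= np.trapezoid(p, x)
        mean = np.trapezoid(p * x, x)
        var = np.trapezoid(p * (x - mean) ** 2, x)
        assert abs(mean - 0.5) < 1e-3
        assert var < 1e-3

    @pytest.mark.parametrize("ratio", [0.1, 1.0, 10.0])
    def test_matches_gillespie(self, species_pair, ratio):
        hi, lo = species_pair
        m = kin.KineticModel([hi, lo], np.array([[0.0, 600.0], [400.0, 0.0]]))
        t_r = 1e-3
        window = ratio * t_r
        dens = kin.occupancy_fraction_density(m, window)
        occ = kin.sample_occupancies(m, window, 100_000, rng=11)[:, 0]
        xs = np.linspace(0.0, 1.0, 401)
        emp = np.searchsorted(np.sort(occ), xs, side="right") / len(occ)
        assert np.max(np.abs(emp - dens.sample_cdf(xs))) < 0.02

    def test_requires_two_states(self, pair568):
        m = kin.KineticModel([kin.FRETSpecies("s", pair568, efficiency=0.4)], np.zeros((1, 1)))
        with pytest.raises(kin.ModelError):
            kin.occupancy_fraction_density(m, 1e-3)
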
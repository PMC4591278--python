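import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import diadrom as dd
from diadrom.demography import recruitment_capacity

TR = dd.ThermalResponse


class TestThermalDome:
    def test_unity_at_optimum_and_zero_at_bounds(self):
        resp = TR(3.0, 17.0, 26.0)
        assert dd.thermal_dome(17.0, resp) == pytest.approx(1.0)
        assert dd.thermal_dome(3.0, resp) == 0.0
        assert dd.thermal_dome(26.0, resp) == 0.0
        assert dd.thermal_dome(-5.0, resp) == 0.0
        assert dd.thermal_dome(40.0, resp) == 0.0

    def test_interior_value(self):
        # (t=10, 3, 17, 26): (7 * -16) / ((7 * -16) - 49) = 112/161
        assert dd.thermal_dome(10.0, TR(3.0, 17.0, 26.0)) == pytest.approx(112 / 161)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(0, 10), st.floats(11, 20), st.floats(21, 35),
        st.floats(-5, 40),
    )
    def test_bounded_unimodal(self, tmin, topt, tmax, t):
        v = dd.thermal_dome(t, TR(tmin, topt, tmax))
        assert 0.0 <= v <= 1.0 + 1e-12

    def test_invalid_triplet_rejected(self):
        with pytest.raises(ValueError):
            TR(20.0, 15.0, 26.0)


class TestAlleeEffect:
    def test_anchor_points(self):
        # eta=2.4, theta=2, wa=1000: S95=2400 -> 0.95, S50=1200 -> 0.5
        assert dd.allee_multiplier(2400.0, 1000.0, 2.4, 2.0) == pytest.approx(0.95)
        assert dd.allee_multiplier(1200.0, 1000.0, 2.4, 2.0) == pytest.approx(0.5)
        assert dd.effective_spawners(2400.0, 1000.0, 2.4, 2.0) == pytest.approx(2280.0)
        assert dd.effective_spawners(1200.0, 1000.0, 2.4, 2.0) == pytest.approx(600.0)

    def test_zero_spawners(self):
        # multiplier strictly positive, output 0
        m = dd.allee_multiplier(0.0, 1000.0, 2.4, 2.0)
        assert 0 < m < 0.5
        assert m == pytest.approx(1.0 / (1.0 + 19.0 ** (1200.0 / 1200.0)))
        assert dd.effective_spawners(0.0, 1000.0, 2.4, 2.0) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.5, 10), st.floats(1.2, 5), st.floats(10, 1e5))
    def test_strictly_increasing_with_anchors(self, eta, theta, wa):
        # between S50/2 and S95 the logistic is far from float saturation
        s = np.linspace(0.5 * eta * wa / theta, eta * wa, 200)
        m = dd.allee_multiplier(s, wa, eta, theta)
        assert (np.diff(m) > 0).all()
        assert ((0 < m) & (m < 1)).all()
        assert dd.allee_multiplier(eta * wa, wa, eta, theta) == pytest.approx(0.95)
        assert dd.allee_multiplier(eta * wa / theta, wa, eta, theta) == pytest.approx(0.5)


class TestRecruitment:
    def test_no_spawners_no_recruits(self, species):
        assert dd.recruitment(0.0, 1000.0, 20.0, species) == 0.0

    def test_zero_below_thermal_minimum(self, species):
        tmin = species.thermal_rep.t_min
        assert dd.recruitment(5000.0, 1000.0, tmin, species) == 0.0
        assert dd.recruitment(5000.0, 1000.0, tmin - 3.0, species) == 0.0

    def test_saturates_at_capacity(self, species):
        p = species.with_values(sigma_rep=0.0)
        cap = recruitment_capacity(p.lambda_rec, 1000.0)
        r = dd.recruitment_deterministic(1e12, 1000.0, p.thermal_rep.t_opt, p)
        assert r < cap
        assert r == pytest.approx(cap, rel=1e-3)

    def test_monotone_in_spawners(self, species):
        p = species.with_values(sigma_rep=0.0)
        s = np.linspace(0, 50000, 50)
        r = [dd.recruitment_deterministic(x, 1000.0, 20.0, p) for x in s]
        assert (np.diff(r) >= 0).all()

    def test_origin_slope_matches_fecundity_times_survival(self, species):
        """Low-density slope equals a * surv(t), checked by difference quotient
        against the Allee-free kernel (the depensation term is itself a
        density effect, so it is held at its zero-density value)."""
        p = species.with_values(sigma_rep=0.0)
        t = 18.0
        wa = 1000.0
        surv = p.surv_opt_rep * dd.thermal_dome(t, p.thermal_rep)
        m0 = dd.allee_multiplier(0.0, wa, p.eta, p.theta)
        eps = 1e-6
        slope = dd.recruitment_deterministic(eps, wa, t, p) / eps
        assert slope == pytest.approx(p.fecundity * surv * m0, rel=1e-3)

    def test_lognormal_noise_is_mean_corrected(self, species):
        p = species.with_values(sigma_rep=0.4)
        rng = np.random.default_rng(0)
        det = dd.recruitment_deterministic(5000.0, 1000.0, 20.0, p)
        draws = [dd.recruitment(5000.0, 1000.0, 20.0, p, rng) for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(det, rel=0.02)


class TestGrowth:
    def test_no_growth_outside_thermal_window(self, species):
        p = species.with_values(sigma_dl=0.0)
        assert dd.growth_increment(10.0, p.thermal_grow.t_min - 1, p) == 0.0
        assert dd.growth_increment(10.0, p.thermal_grow.t_max + 1, p) == 0.0

    def test_closed_form_increment(self):
        p = dd.SpeciesParameters(sigma_dl=0.0, k_opt_grow=0.3)
        dl = dd.growth_increment(2.0, p.thermal_grow.t_opt, p)
        assert dl == pytest.approx(58.0 * (1 - np.exp(-0.3)), rel=1e-9)

    def test_zero_at_asymptote(self, species):
        p = species.with_values(sigma_dl=0.0)
        assert dd.growth_increment(p.l_inf, p.thermal_grow.t_opt, p) == 0.0

    def test_monotone_convergence_to_l_inf(self, species):
        p = species.with_values(sigma_dl=0.0)
        ind = dd.SuperIndividual(1.0, 0.33, p.l_ini, "a", "sea:a")
        lengths = []
        for _ in range(200):
            lengths.append(dd.grow(ind, p.thermal_grow.t_opt, p))
        arr = np.array(lengths)
        assert (np.diff(arr) >= 0).all()
        assert arr[-1] <= p.l_inf
        assert arr[-1] == pytest.approx(p.l_inf, abs=1e-6)

    def test_noise_never_exceeds_asymptote(self, species):
        p = species.with_values(sigma_dl=0.5)
        rng = np.random.default_rng(1)
        for _ in range(200):
            assert dd.growth_increment(59.0, p.thermal_grow.t_opt, p, rng) <= 1.0 + 1e-12


class TestSurvival:
    @pytest.mark.parametrize("z, expected", [(0.0, 1.0), (0.4, np.exp(-0.1)), (0.6, np.exp(-0.15))])
    def test_sea_survival(self, z, expected):
        p = dd.SpeciesParameters(z_sea=z)
        assert dd.sea_survival_probability(p) == pytest.approx(expected)

    def test_river_survival_at_optimum(self):
        p = dd.SpeciesParameters(surv_opt_riv=1.0, h_riv=0.0)
        assert dd.river_survival_probability(p.thermal_surv_riv.t_opt, p) == pytest.approx(1.0)

    def test_river_survival_zero_outside_window(self, species):
        assert dd.river_survival_probability(species.thermal_surv_riv.t_min, species) == 0.0
        assert dd.river_survival_probability(species.thermal_surv_riv.t_max + 2, species) == 0.0

    def test_river_added_mortality(self):
        p = dd.SpeciesParameters(surv_opt_riv=1.0, h_riv=0.2)
        got = dd.river_survival_probability(p.thermal_surv_riv.t_opt, p)
        assert got == pytest.approx(np.exp(-0.05))

    def test_all_seasonal_survivals_are_probabilities(self, species):
        for t in np.linspace(-5, 40, 50):
            assert 0.0 <= dd.river_survival_probability(t, species) <= 1.0
        assert 0.0 <= dd.sea_survival_probability(species) <= 1.0


class TestSpawningAndMaturity:
    @pytest.mark.parametrize("sp_sp, expected", [(0.0, 0.0), (1.0, 1000.0), (0.1, 100.0)])
    def test_post_spawning_weight(self, sp_sp, expected):
        p = dd.SpeciesParameters(sp_sp=sp_sp)
        ind = dd.SuperIndividual(1000.0, 5.0, 45.0, "a", "a", mature=True)
        dd.post_spawning_survival(ind, p)
        assert ind.weight == pytest.approx(expected)
        assert ind.spawned_before

    def test_post_spawning_binomial_mode(self):
        p = dd.SpeciesParameters(sp_sp=0.1)
        rng = np.random.default_rng(0)
        survivors = []
        for _ in range(500):
            ind = dd.SuperIndividual(1000.0, 5.0, 45.0, "a", "a", mature=True)
            survivors.append(dd.post_spawning_survival(ind, p, rng, stochastic=True))
        assert np.mean(survivors) == pytest.approx(100.0, rel=0.05)
        assert all(s == int(s) for s in survivors)

    @pytest.mark.parametrize(
        "length, l_mat, expected",
        [(35.9, 36.0, False), (40.0, 40.0, True), (44.1, 44.0, True)],
    )
    def test_maturity_threshold(self, length, l_mat, expected):
        p = dd.SpeciesParameters(l_mat=l_mat)
        ind = dd.SuperIndividual(1.0, 4.0, length, "a", "sea:a")
        assert dd.is_mature(ind, p) is expected


class TestSpeciesParameters:
    def test_rejects_invalid_values(self):
        with pytest.raises(ValueError):
            dd.SpeciesParameters(theta=1.0)
        with pytest.raises(ValueError):
            dd.SpeciesParameters(p_hom=1.5)
        with pytest.raises(ValueError):
            dd.SpeciesParameters(l_inf=1.0)

    def test_nonzero_logit_terms_need_standardization(self):
        with pytest.raises(ValueError, match="tl_mean"):
            dd.SpeciesParameters(alpha_tl=1.0)
        with pytest.raises(ValueError, match="wa_mean"):
            dd.SpeciesParameters(alpha_wa=1.0)

    def test_with_values_updates_thermal_minima(self, species):
        p = species.with_values(tmin_rep=11.0, topt_grow=16.0, tmin_surv_riv=10.0)
        assert p.thermal_rep.t_min == 11.0
        assert p.thermal_grow.t_opt == 16.0
        assert p.thermal_surv_riv.t_min == 10.0

    def test_from_mapping_rejects_unknown_keys(self):
        with pytest.raises(KeyError, match="not_a_parameter"):
            dd.SpeciesParameters.from_mapping({"not_a_parameter": 1.0})

    def test_uncertain_ranges_cover_eleven_parameters(self):
        assert len(dd.UNCERTAIN_RANGES) == 11
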
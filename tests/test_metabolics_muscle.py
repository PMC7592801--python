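"""Muscle energetics: masses, recruitment, heat rates, work, limb profile."""

import numpy as np
import pytest

from gaitmet import metabolics_muscle as mm
from gaitmet import musclemodel, signals, stats, synthetic
from gaitmet.metabolics_muscle import (EnergeticsCoefficients, fiber_work_rate,
                                       heat_rates, limb_profile, muscle_mass,
                                       recruitment_fractions, total_muscle_rate)

COEFFS = EnergeticsCoefficients()


class TestMuscleMass:
    def test_soleus_hand_computation(self, model):
        # (6195 / 600000) * 0.04 * 1059.7
        m = muscle_mass(model["params"]["soleus"], COEFFS)
        assert abs(m - 0.4376) < 5e-4

    def test_linearity_in_fmax(self, model):
        from dataclasses import replace
        p = model["params"]["soleus"]
        assert muscle_mass(replace(p, f_max=2 * p.f_max), COEFFS) \
            == pytest.approx(2 * muscle_mass(p, COEFFS))

    def test_tibialis_lighter_than_soleus(self, model):
        assert muscle_mass(model["params"]["tibialis_anterior"], COEFFS) \
            < muscle_mass(model["params"]["soleus"], COEFFS)


class TestRecruitment:
    def test_limits(self):
        slow, fast = recruitment_fractions(0.0, 0.6)
        assert slow == 1.0 and fast == 0.0
        slow, fast = recruitment_fractions(1.0, 0.6)
        assert slow == pytest.approx(0.6) and fast == pytest.approx(0.4)

    def test_monotone_and_sums_to_one(self):
        grid = np.linspace(0, 1, 101)
        slow, fast = recruitment_fractions(grid, 0.55)
        assert np.all(np.diff(slow) <= 0)
        np.testing.assert_allclose(slow + fast, 1.0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            recruitment_fractions(0.5, 0.5, model="random")


class TestHeatRates:
    def test_no_drive_no_heat(self, model):
        p = model["params"]["soleus"]
        am, sl = heat_rates(0.0, 0.0, p.l_opt, 0.1, p, COEFFS)
        assert am == 0.0 and sl == 0.0

    def test_isometric_has_no_shortening_heat(self, model):
        p = model["params"]["soleus"]
        am, sl = heat_rates(0.5, 0.5, p.l_opt, 0.0, p, COEFFS)
        assert sl == 0.0 and am > 0.0

    def test_aerobic_factor_exact_scaling(self, model):
        from dataclasses import replace
        p = model["params"]["vastus_medialis"]
        rng = np.random.default_rng(0)
        a = rng.uniform(0.1, 0.9, 50)
        u = rng.uniform(0.1, 0.9, 50)
        lf = p.l_opt * rng.uniform(0.8, 1.2, 50)
        vf = rng.uniform(-0.3, 0.3, 50)
        am15, sl15 = heat_rates(a, u, lf, vf, p, COEFFS)
        base = replace(COEFFS, aerobic_factor=1.0)
        am1, sl1 = heat_rates(a, u, lf, vf, p, base)
        np.testing.assert_allclose(am15, 1.5 * am1, rtol=1e-12)
        np.testing.assert_allclose(sl15, 1.5 * sl1, rtol=1e-12)

    def test_rates_nonnegative(self, model):
        p = model["params"]["biceps_femoris"]
        rng = np.random.default_rng(1)
        am, sl = heat_rates(rng.uniform(0, 1, 100), rng.uniform(0, 1, 100),
                            p.l_opt * rng.uniform(0.5, 1.5, 100),
                            rng.uniform(-0.5, 0.5, 100), p, COEFFS)
        assert am.min() >= 0 and sl.min() >= 0

    def test_rejects_nonpositive_fiber_length(self, model):
        with pytest.raises(ValueError):
            heat_rates(0.5, 0.5, 0.0, 0.0, model["params"]["soleus"], COEFFS)


class TestFiberWork:
    def test_shortening_positive(self):
        assert fiber_work_rate(100.0, 0.1, 0.5) == pytest.approx(20.0)

    def test_lengthening_negative(self):
        assert fiber_work_rate(100.0, -0.1, 0.5) == pytest.approx(-20.0)

    def test_isometric_zero(self):
        assert fiber_work_rate(500.0, 0.0, 0.5) == 0.0

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            fiber_work_rate(1.0, 1.0, 0.0)


class TestTotalRate:
    def test_clamp_at_zero(self):
        out = total_muscle_rate(np.array([10.0]), np.array([5.0]),
                                np.array([-100.0]), 0.5, 80.0)
        assert out[0] == 0.0

    def test_clamp_identity_when_positive(self):
        out = total_muscle_rate(np.array([10.0]), np.array([5.0]),
                                np.array([2.0]), 0.5, 80.0)
        assert out[0] == pytest.approx(17.0 * 0.5 / 80.0)

    def test_clamped_integral_at_least_unclamped(self):
        rng = np.random.default_rng(2)
        am, sl = rng.uniform(0, 5, 200), rng.uniform(0, 5, 200)
        w = rng.normal(0, 20, 200)
        clamped = total_muscle_rate(am, sl, w, 0.4, 80.0)
        unclamped = (am + sl + w) * 0.4 / 80.0
        assert clamped.sum() >= unclamped.sum()
        assert clamped.min() >= 0.0


class TestLimbProfile:
    def test_single_muscle_identity(self):
        grid = np.linspace(0, 100, 11)
        rate = np.linspace(0, 1, 11)
        prof = limb_profile({"soleus": rate}, grid)
        np.testing.assert_array_equal(prof.total, rate)
        np.testing.assert_array_equal(prof.groups["plantarflexors"], rate)

    def test_group_shares_partition_the_total(self, model, level_trial):
        prof = mm.estimate_profile(level_trial, model["params"],
                                   model["geometry"], curves=model["curves"])
        shares = mm.group_shares(prof)
        assert abs(sum(shares.values()) - 100.0) < 1e-9

    def test_plantarflexor_group_mapping(self):
        assert set(mm.MUSCLE_GROUPS["plantarflexors"]) == {
            "soleus", "gastrocnemius_medialis", "gastrocnemius_lateralis"}
        assert mm.MUSCLE_GROUPS["dorsiflexors"] == ("tibialis_anterior",)
        assert mm.MUSCLE_GROUPS["hip_extensors"] == ("gluteus_maximus",)
        assert mm.MUSCLE_GROUPS["knee_flexors"] == ("biceps_femoris",)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            limb_profile({"soleus": np.zeros(5)}, np.linspace(0, 100, 11))


class TestEndToEnd:
    def test_component_decomposition_identity(self, model, simulated_states, level_trial):
        """Before clamping, total = AM + SL + W at every sample."""
        exc = {n: signals.normalize_emg(level_trial.emg_envelope[n],
                                        level_trial.participant.mvc[n])
               for n in model["params"]}
        totals, comps = mm.muscle_rate_components(
            simulated_states["states"], model["params"],
            level_trial.participant.body_mass, COEFFS, model["curves"], exc)
        for name in totals:
            unclamped = sum(comps[name].values())
            np.testing.assert_allclose(totals[name], np.clip(unclamped, 0, None),
                                       rtol=1e-9, atol=1e-12)
            assert totals[name].min() >= 0.0

    def test_scaling_fmax_scales_contribution(self, model):
        """Doubling f_max (hence mass) doubles the absolute rate contribution
        for identical normalized muscle states."""
        from dataclasses import replace
        p = model["params"]["tibialis_anterior"]
        p2 = replace(p, f_max=2 * p.f_max)
        rng = np.random.default_rng(3)
        a = rng.uniform(0.1, 0.8, 40)
        lf = p.l_opt * rng.uniform(0.8, 1.2, 40)
        vf = rng.uniform(-0.2, 0.2, 40)
        f_ce = 0.5 * p.f_max * a  # scales with f_max for identical states
        body = 80.0
        m1, m2 = muscle_mass(p, COEFFS), muscle_mass(p2, COEFFS)
        am1, sl1 = heat_rates(a, a, lf, vf, p, COEFFS)
        am2, sl2 = heat_rates(a, a, lf, vf, p2, COEFFS)
        np.testing.assert_allclose(am2, am1)  # per-kg heat independent of f_max
        r1 = total_muscle_rate(am1, sl1, fiber_work_rate(f_ce, -vf, m1), m1, body)
        r2 = total_muscle_rate(am2, sl2, fiber_work_rate(2 * f_ce, -vf, m2), m2, body)
        np.testing.assert_allclose(r2, 2 * r1, rtol=1e-12)

    def test_zero_activation_zero_profile(self, model, participant):
        trial = synthetic.generate_trial(participant, synthetic.ConditionSpec(),
                                         n_strides=3, noise_sd=0.0, seed=2,
                                         sampling_rate=200.0)
        for name in trial.emg_envelope:
            trial.emg_envelope[name] = np.zeros_like(trial.emg_envelope[name])
        prof = mm.estimate_profile(trial, model["params"], model["geometry"],
                                   curves=model["curves"], n_points=101)
        np.testing.assert_array_equal(prof.total, 0.0)
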
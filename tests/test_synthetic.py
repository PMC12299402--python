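"""Synthetic generators: determinism, noise statistics, round trips."""

import math

import numpy as np
import pytest

from tumorkin import (
    FlashParams,
    FractionSchedule,
    GompertzParams,
    NoiseModel,
    estimate_rt_series,
    gen_flash,
    gen_fractionated,
    gen_gl,
    gl_volume,
)
from tumorkin import fixtures
from tumorkin.fitting import FitConfig, TrajectoryModel, fit_model
from tumorkin.flash import flash_log_ratio


class TestNoiseModel:
    def test_zero_noise_is_exact(self, slow_gp):
        times = np.linspace(0, 60, 6)
        traj = gen_gl(slow_gp, times, NoiseModel(rel_sd=0.0))
        assert np.allclose(traj.values, gl_volume(slow_gp, times), rtol=0)

    def test_fixed_seed_reproduces_series(self, slow_gp):
        times = np.linspace(0, 60, 6)
        a = gen_gl(slow_gp, times, NoiseModel(rel_sd=0.025, seed=123))
        b = gen_gl(slow_gp, times, NoiseModel(rel_sd=0.025, seed=123))
        c = gen_gl(slow_gp, times, NoiseModel(rel_sd=0.025, seed=124))
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_sample_mean_matches_model_value(self, slow_gp):
        # CLT check: mean of 1e4 multiplicative draws around one model
        # value stays within 3 standard errors of it
        t = 30.0
        v = float(gl_volume(slow_gp, t))
        noise = NoiseModel(rel_sd=0.025, seed=42)
        draws = noise.apply(np.full(10_000, v))
        se = 0.025 * v / math.sqrt(10_000)
        # -3 SD truncation biases the mean upward by ~phi(3)*sd, well
        # below the 3-SE band
        assert abs(draws.mean() - v) < 3 * se

    def test_truncation_keeps_volumes_positive(self):
        gp = GompertzParams(V0=1e-6, V_inf=1e-5, k=0.05)
        noise = NoiseModel(rel_sd=0.3, seed=5)
        traj = gen_gl(gp, np.linspace(0, 50, 40), noise)
        assert np.all(traj.values > 0)

    def test_negative_rel_sd_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(rel_sd=-0.01)


class TestGenFlash:
    def test_therapy_off_equals_untreated_generator(self, slow_gp):
        times = np.linspace(0, 40, 5)
        fp = FlashParams(c0=0.0, c1=0.0, c2=0.1, cf=0.0)
        a = gen_flash(slow_gp, fp, times, NoiseModel(rel_sd=0.025, seed=9))
        b = gen_gl(GompertzParams(1.0, slow_gp.V_inf / slow_gp.V0, slow_gp.k),
                   times, NoiseModel(rel_sd=0.025, seed=9))
        assert np.allclose(a.values, b.values, rtol=1e-12)

    def test_negative_cf_drives_late_decrease(self, slow_gp):
        # cf < 0 (above-critical dose): the mean curve keeps shrinking
        fp = fixtures.flash_params("25_gy_flash")
        late = np.array([100.0, 150.0, 200.0, 300.0])
        traj = gen_flash(slow_gp, fp, late, NoiseModel(rel_sd=0.0))
        assert np.all(np.diff(traj.values) < 0)

    def test_noiseless_refit_recovers_parameters(self):
        # round trip through the generic chi-square engine with the flash
        # family itself (growth parameters held fixed)
        gp = GompertzParams(V0=1.0, V_inf=5.0, k=0.1)
        fp = FlashParams(c0=0.08, c1=0.3, c2=1.0, cf=0.0004)
        # dense early sampling pins the fast transient (c1, c2); the grid
        # starts at 0 to match the fitter's relative-time convention
        times = np.concatenate([np.linspace(0.0, 5.0, 11),
                                np.linspace(10.0, 120.0, 12)])
        traj = gen_flash(gp, fp, times, NoiseModel(rel_sd=0.0))

        def curve(p, t):
            trial = FlashParams(c0=p["c0"], c1=p["c1"], c2=p["c2"], cf=p["cf"])
            return np.exp(flash_log_ratio(gp, trial, t))

        model = TrajectoryModel(
            "flash_ratio", ("c0", "c1", "c2", "cf"), curve,
            starts=[{"c0": 0.05, "c1": 0.1, "c2": 0.5, "cf": 0.0}],
            default_bounds={"c2": (0.0, 10.0)},
        )
        fit = fit_model(traj, model, FitConfig(normalize=False))
        for name, truth in [("c0", 0.08), ("c1", 0.3), ("c2", 1.0),
                            ("cf", 0.0004)]:
            assert fit.params[name] == pytest.approx(truth, abs=1e-4)


class TestGenFractionated:
    def _schedule(self):
        return FractionSchedule(dose_times=np.arange(0.0, 29.0, 7.0))

    def test_zero_effects_follow_untreated_law(self, slow_gp):
        sched = self._schedule()
        traj, rt = gen_fractionated(slow_gp, sched, rt_true=[0.0] * 4)
        assert np.allclose(traj.values, gl_volume(slow_gp, sched.dose_times))
        assert np.allclose(rt, 0.0)

    def test_planted_effects_recovered_exactly(self, slow_gp):
        sched = self._schedule()
        rt_true = [0.2, 0.35, 0.1, 0.25]
        traj, rt = gen_fractionated(slow_gp, sched, rt_true=rt_true)
        est = estimate_rt_series(traj.values, slow_gp, 7.0)
        assert np.allclose(est, rt_true, atol=1e-12)

    def test_constant_kill_ground_truth_matches_closed_form(self, slow_gp):
        sched = self._schedule()
        F0 = 0.08
        traj, rt_implied = gen_fractionated(slow_gp, sched, F=lambda _: F0)
        expected = (F0 / slow_gp.k) * (1 - math.exp(-slow_gp.k * 7.0))
        assert np.allclose(rt_implied, expected, rtol=1e-8)
        # trajectory inversion agrees with the quadrature ground truth
        est = estimate_rt_series(traj.values, slow_gp, 7.0)
        assert np.allclose(est, rt_implied, atol=1e-8)

    def test_requires_exactly_one_effect_source(self, slow_gp):
        sched = self._schedule()
        with pytest.raises(ValueError, match="exactly one"):
            gen_fractionated(slow_gp, sched)
        with pytest.raises(ValueError, match="exactly one"):
            gen_fractionated(slow_gp, sched, rt_true=[0.1] * 4, F=lambda _: 0.1)


class TestFixtures:
    def test_packaged_constants_unchanged(self):
        # byte-level checksum of the packaged reference-constant file
        assert fixtures.data_sha256() == (
            "da8cd0c07ac05964f1a398724390dff456ae9812a1d648b040961089668b861c"
        )

    def test_flash_fixture_labels_complete(self):
        assert set(fixtures.flash_fit_labels()) == {
            "15_gy_flash", "19.5_gy_conv", "20_gy_flash", "25_gy_flash"
        }

    def test_dose_law_fixture_matches_constants(self):
        law = fixtures.flash_dose_law()
        assert (law.a, law.b, law.d_ref, law.p) == (
            0.000515, 2.17e-7, 15.0, 3.64
        )

    def test_fixed_k_value(self):
        assert fixtures.k_in_vivo() == 0.0342
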
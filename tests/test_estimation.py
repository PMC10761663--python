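import itertools

import numpy as np
import pytest

from petkin.aif import FENG_POPULATION_MEAN, FengParams, sample_aif
from petkin.estimation import (
    AIFFitter,
    ParamBounds,
    TwoTCMFitter,
    fit_2tcm,
    fit_aif,
    fit_patlak,
    simulation_2tcm_bounds,
    simulation_aif_bounds,
)
from petkin.kinetics import TwoTCMParams, net_influx_rate, tac_2tcm
from petkin.noise import NoiseConfig, add_frame_noise
from petkin.protocol import select_window

CENTER = TwoTCMParams(0.075, 0.15, 0.03, 0.03)


@pytest.fixture(scope="module")
def cardiac_samples(protocol):
    schedule, injections, windows = protocol
    frames = schedule.subset(select_window(schedule, windows["cardiac"]))
    return sample_aif(FENG_POPULATION_MEAN, injections, frames), injections


class TestFitAif:
    def test_noiseless_recovery_is_exact(self, cardiac_samples):
        samples, injections = cardiac_samples
        result = fit_aif(samples, injections)
        assert result.converged
        rel = result.estimate.as_array() / FENG_POPULATION_MEAN.as_array() - 1
        assert np.max(np.abs(rel)) < 1e-6

    def test_estimate_respects_bounds(self, cardiac_samples):
        samples, injections = cardiac_samples
        rng = np.random.default_rng(3)
        bounds = simulation_aif_bounds()
        noisy = add_frame_noise(samples, NoiseConfig(0.6), rng=rng)
        result = fit_aif(noisy, injections)
        est = result.estimate.as_array()
        assert np.all(est >= bounds.lower) and np.all(est <= bounds.upper)

    def test_grid_search_never_beats_nls(self, cardiac_samples):
        """Brute-force 11-points-per-axis search within the bounds."""
        samples, injections = cardiac_samples
        fitter = AIFFitter(samples.schedule, injections)
        bounds = fitter.bounds
        axes = [np.linspace(lo, hi, 11) for lo, hi in zip(bounds.lower, bounds.upper)]
        grid = np.array(list(itertools.product(*axes)))
        rng = np.random.default_rng(11)
        for _ in range(5):
            noisy = add_frame_noise(samples, NoiseConfig(0.3), rng=rng)
            result = fitter.fit(noisy.activity)
            best_grid = min(
                float(np.sum((fitter.model_frames(x) - noisy.activity) ** 2))
                for x in grid
            )
            assert best_grid >= result.residual_ss - 1e-9

    def test_descent_from_initialization(self, cardiac_samples):
        samples, injections = cardiac_samples
        fitter = AIFFitter(samples.schedule, injections)
        rng = np.random.default_rng(5)
        noisy = add_frame_noise(samples, NoiseConfig(0.6), rng=rng)
        init_ss = float(
            np.sum((fitter.model_frames(fitter.bounds.midpoint) - noisy.activity) ** 2)
        )
        result = fitter.fit(noisy.activity)
        assert result.residual_ss <= init_ss + 1e-12

    def test_too_few_frames_rejected(self, cardiac_samples):
        samples, injections = cardiac_samples
        with pytest.raises(ValueError):
            fit_aif(samples.subset(np.arange(3)), injections)


class TestFit2TCM:
    def test_noiseless_recovery(self, short_window_frames, mean_triple_aif):
        tac = tac_2tcm(CENTER, mean_triple_aif, short_window_frames)
        result = fit_2tcm(tac, mean_triple_aif)
        assert result.converged
        est = result.estimate
        rel = est.as_array() / CENTER.as_array() - 1
        assert np.max(np.abs(rel)) < 1e-4
        assert result.ki == pytest.approx(net_influx_rate(CENTER), rel=1e-4)

    @pytest.mark.parametrize("k1,k2,k3", [(0.05, 0.25, 0.02), (0.1, 0.05, 0.04)])
    def test_noiseless_recovery_at_grid_corners(
        self, short_window_frames, mean_triple_aif, k1, k2, k3
    ):
        truth = TwoTCMParams(k1, k2, k3, 0.03)
        tac = tac_2tcm(truth, mean_triple_aif, short_window_frames)
        result = fit_2tcm(tac, mean_triple_aif)
        assert np.max(np.abs(result.estimate.as_array() / truth.as_array() - 1)) < 1e-4

    def test_grid_search_never_beats_nls(self, short_window_frames, mean_triple_aif):
        fitter = TwoTCMFitter(short_window_frames, mean_triple_aif)
        bounds = fitter.bounds
        axes = [np.linspace(lo, hi, 11) for lo, hi in zip(bounds.lower, bounds.upper)]
        grid = np.array(list(itertools.product(*axes)))
        tac = tac_2tcm(CENTER, mean_triple_aif, short_window_frames)
        rng = np.random.default_rng(13)
        for _ in range(5):
            noisy = add_frame_noise(tac, NoiseConfig(0.4), rng=rng)
            result = fitter.fit(noisy.activity)
            best_grid = min(
                float(np.sum((fitter.model_frames(x) - noisy.activity) ** 2))
                for x in grid
            )
            assert best_grid >= result.residual_ss - 1e-9

    def test_vb_is_held_fixed(self, short_window_frames, mean_triple_aif):
        tac = tac_2tcm(CENTER, mean_triple_aif, short_window_frames)
        result = fit_2tcm(tac, mean_triple_aif, vb=0.03)
        assert result.estimate.vb == 0.03

    def test_too_few_frames_rejected(self, short_window_frames, mean_triple_aif):
        tac = tac_2tcm(CENTER, mean_triple_aif, short_window_frames)
        with pytest.raises(ValueError):
            fit_2tcm(tac.subset(np.arange(2)), mean_triple_aif)


class TestFitPatlak:
    def test_exactly_linear_points_recovered(self, protocol):
        from scipy.integrate import cumulative_trapezoid

        schedule, injections, _ = protocol
        plasma = sample_aif(FENG_POPULATION_MEAN, injections, schedule)
        mid = schedule.midtimes
        integral = cumulative_trapezoid(
            np.concatenate(([0.0], plasma.activity)), np.concatenate(([0.0], mid))
        )
        tissue = plasma.with_activity(0.02 * integral + 0.5 * plasma.activity)
        ki, intercept = fit_patlak(tissue, plasma, t_start=5.0)
        assert ki == pytest.approx(0.02, rel=1e-9)
        assert intercept == pytest.approx(0.5, rel=1e-9)

    def test_constant_curves_give_zero_slope(self):
        import numpy as np

        from petkin.aif import TimeActivityCurve
        from petkin.protocol import FrameSchedule

        sched = FrameSchedule(np.arange(10.0), np.ones(10))
        flat = TimeActivityCurve(sched, np.full(10, 4.0))
        ki, _ = fit_patlak(flat, flat, t_start=0.0)
        assert ki == pytest.approx(0.0, abs=1e-12)

    def test_single_injection_slope_near_net_influx_rate(self, protocol):
        from petkin.aif import multi_injection_aif
        from petkin.protocol import InjectionSchedule

        schedule, _, windows = protocol
        single = InjectionSchedule(np.array([0.0]), np.array([1.0]))

        def aif(t):
            return multi_injection_aif(FENG_POPULATION_MEAN, single, t)

        idx = select_window(schedule, windows["validation"])
        frames = schedule.subset(idx)
        plasma = sample_aif(FENG_POPULATION_MEAN, single, frames, step=1 / 150)
        tissue = tac_2tcm(CENTER, aif, frames)
        ki, _ = fit_patlak(tissue, plasma, t_start=15.0)
        assert ki == pytest.approx(0.0125, rel=0.10)

    def test_insufficient_late_points_rejected(self, protocol):
        schedule, injections, _ = protocol
        plasma = sample_aif(FENG_POPULATION_MEAN, injections, schedule)
        with pytest.raises(ValueError):
            fit_patlak(plasma, plasma, t_start=59.9)


class TestParamBounds:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParamBounds(np.array([1.0, 0.0]), np.array([1.0, 2.0]))

    def test_simulation_bound_conventions(self):
        aif_b = simulation_aif_bounds()
        assert aif_b.lower[0] == pytest.approx(0.5 * (263 - 120))
        assert aif_b.upper[0] == pytest.approx(2 * (263 + 120))
        tcm_b = simulation_2tcm_bounds()
        assert tcm_b.lower == pytest.approx([0.025, 0.025, 0.01])
        assert tcm_b.upper == pytest.approx([0.2, 0.5, 0.08])
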
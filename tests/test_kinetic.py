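"""Compartment-model forward simulation, fitting, coupling and AIC."""

import numpy as np
import pytest

from petkin.errors import DomainError, InsufficientDataError
from petkin.kinetic import (
    CompartmentParams,
    FrameSchedule,
    TimeActivityCurve,
    compute_aic,
    derive_fnd,
    fit_coupled,
    fit_region,
    frame_weights,
    simulate_tissue,
)
from petkin.synthetic import two_hour_frames

from conftest import ode_tissue_oracle


class TestSimulateTissue:
    def test_matches_independent_ode_integration(self, input_function, reference_2t_params):
        """Analytic convolution vs stiff-ODE oracle: <= 0.1% at every frame."""
        frames = two_hour_frames()
        sim = simulate_tissue(reference_2t_params, input_function, frames)
        oracle = ode_tissue_oracle(reference_2t_params, input_function, frames)
        np.testing.assert_allclose(sim.values, oracle, atol=1e-3 * np.max(oracle))

    def test_random_parameter_sets_agree_with_ode(self, input_function):
        frames = two_hour_frames()
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = CompartmentParams(
                K1=rng.uniform(0.05, 1.0),
                k2=rng.uniform(0.01, 0.3),
                k3=rng.uniform(0.0, 0.15),
                k4=rng.uniform(0.005, 0.15),
            )
            sim = simulate_tissue(p, input_function, frames)
            oracle = ode_tissue_oracle(p, input_function, frames)
            scale = np.max(oracle)
            np.testing.assert_allclose(sim.values, oracle, atol=1e-3 * scale, rtol=1e-3)

    def test_k3_zero_reduces_to_one_tissue(self, input_function):
        frames = two_hour_frames()
        two = simulate_tissue(
            CompartmentParams(K1=0.37, k2=0.047, k3=0.0, k4=0.05), input_function, frames
        )
        one = simulate_tissue(
            CompartmentParams(K1=0.37, k2=0.047), input_function, frames
        )
        np.testing.assert_allclose(two.values, one.values, rtol=1e-12)

    def test_zero_influx_gives_zero_tac(self, input_function):
        sim = simulate_tissue(
            CompartmentParams(K1=0.0, k2=0.05), input_function, two_hour_frames()
        )
        assert np.all(sim.values == 0.0)

    def test_input_not_covering_frames_raises(self, input_function):
        frames = FrameSchedule.from_durations([60.0] * 5)  # extends to 300 min
        with pytest.raises(DomainError):
            simulate_tissue(CompartmentParams(K1=0.3, k2=0.05), input_function, frames)


class TestFitRegion:
    def test_noiseless_recovery_within_one_percent(self, input_function, reference_2t_params):
        tac = simulate_tissue(reference_2t_params, input_function, two_hour_frames())
        fit = fit_region("2T", tac, input_function, n_starts=5)
        assert fit.converged and not fit.irreversible_limit
        for name in ("K1", "k2", "k3", "k4"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(reference_2t_params, name), rel=0.01
            )
        assert fit.VT == pytest.approx(reference_2t_params.VT, rel=0.005)
        assert fit.reliable  # noiseless => tiny %SE

    def test_irreversible_truth_pins_k4_at_bound(self, input_function):
        truth = CompartmentParams(K1=0.37, k2=0.047, k3=0.03, k4=0.0)
        tac = simulate_tissue(truth, input_function, two_hour_frames())
        fit = fit_region("2T", tac, input_function, n_starts=5)
        assert fit.converged
        assert fit.irreversible_limit
        assert fit.params.k4 <= 1e-6
        assert fit.BPND is None and fit.VT is None

    def test_one_tissue_fit_recovers_one_tissue_truth(self, input_function):
        truth = CompartmentParams(K1=0.47, k2=0.047)
        tac = simulate_tissue(truth, input_function, two_hour_frames())
        fit = fit_region("1T", tac, input_function, n_starts=5)
        assert fit.params.K1 == pytest.approx(0.47, rel=0.01)
        assert fit.VT == pytest.approx(10.0, rel=0.005)

    def test_aic_prefers_two_tissue_on_two_tissue_data(
        self, input_function, reference_2t_params
    ):
        """Model selection on clean biphasic kinetics favors 2T over 1T."""
        tac = simulate_tissue(reference_2t_params, input_function, two_hour_frames())
        fit1 = fit_region("1T", tac, input_function, n_starts=4)
        fit2 = fit_region("2T", tac, input_function, n_starts=4)
        assert fit2.aic < fit1.aic

    def test_aic_selects_generating_model_under_noise(
        self, input_function, reference_2t_params
    ):
        """Monte-Carlo: with moderate noise 2T wins the AIC vote on 2T data."""
        frames = two_hour_frames()
        clean = simulate_tissue(reference_2t_params, input_function, frames)
        rng = np.random.default_rng(3)
        sd = 0.5 * np.sqrt(np.maximum(clean.values, 0) / frames.durations)
        wins = 0
        n_rep = 20
        for _ in range(n_rep):
            noisy = TimeActivityCurve(
                "mc", frames, clean.values + rng.normal(size=len(sd)) * sd
            )
            f1 = fit_region("1T", noisy, input_function, n_starts=3)
            f2 = fit_region("2T", noisy, input_function, n_starts=3)
            wins += f2.aic < f1.aic
        assert wins > n_rep / 2


class TestCoupledFit:
    def test_noiseless_regions_recover_shared_vnd(self, input_function):
        vnd = 7.89
        bps = [0.95, 1.07, 1.19]
        tacs = []
        for i, bp in enumerate(bps):
            p = CompartmentParams(K1=0.37, k2=0.37 / vnd, k3=bp * 0.028, k4=0.028)
            sim = simulate_tissue(p, input_function, two_hour_frames())
            tacs.append(TimeActivityCurve(f"r{i}", sim.frames, sim.values))
        res = fit_coupled(tacs, input_function, n_starts=3)
        assert res.converged
        assert res.shared_VND == pytest.approx(vnd, rel=0.01)
        assert res.mean_bpnd == pytest.approx(np.mean(bps), rel=0.02)
        for fr in res.per_region.values():
            assert fr.params.K1 / fr.params.k2 == pytest.approx(res.shared_VND, rel=1e-9)

    def test_identical_regions_match_unconstrained_fit(self, input_function):
        p = CompartmentParams(K1=0.37, k2=0.047, k3=0.03, k4=0.028)
        sim = simulate_tissue(p, input_function, two_hour_frames())
        tacs = [TimeActivityCurve(f"r{i}", sim.frames, sim.values) for i in range(2)]
        coupled = fit_coupled(tacs, input_function, n_starts=3)
        single = fit_region("2T", tacs[0], input_function, n_starts=3)
        assert coupled.shared_VND == pytest.approx(single.VND, rel=0.01)
        for fr in coupled.per_region.values():
            assert fr.VT == pytest.approx(single.VT, rel=0.01)

    def test_mismatched_truth_inflates_coupled_residual(self, input_function):
        """Regions with different true V_ND: constraint is active, residual grows."""
        frames = two_hour_frames()
        tacs = []
        for i, vnd in enumerate([6.0, 10.0]):
            p = CompartmentParams(K1=0.37, k2=0.37 / vnd, k3=0.03, k4=0.028)
            sim = simulate_tissue(p, input_function, frames)
            tacs.append(TimeActivityCurve(f"r{i}", frames, sim.values))
        coupled = fit_coupled(tacs, input_function, n_starts=4)
        free_rss = sum(
            fit_region("2T", tac, input_function, n_starts=4).rss for tac in tacs
        )
        assert coupled.rss > free_rss
        assert coupled.rss > 1e-6  # strictly positive lack of fit

    def test_requires_two_regions(self, input_function):
        p = CompartmentParams(K1=0.37, k2=0.047, k3=0.03, k4=0.028)
        sim = simulate_tissue(p, input_function, two_hour_frames())
        with pytest.raises(InsufficientDataError):
            fit_coupled([sim], input_function)


class TestAicAndMacro:
    def test_aic_formula(self):
        assert compute_aic(10.0, 33, 4) - compute_aic(10.0, 33, 2) == pytest.approx(4.0)
        assert compute_aic(5.0, 33, 4) == pytest.approx(
            compute_aic(10.0, 33, 4) - 33 * np.log(2)
        )
        with pytest.raises(DomainError):
            compute_aic(-1.0, 33, 4)
        with pytest.raises(DomainError):
            compute_aic(1.0, 4, 4)

    def test_aic_comparison_invariant_to_activity_rescaling(
        self, input_function, reference_2t_params
    ):
        """Rescaling activities (with weights following) shifts both AICs equally."""
        frames = two_hour_frames()
        tac = simulate_tissue(reference_2t_params, input_function, frames)
        w = frame_weights(tac)
        rss1, rss2 = 4.0, 2.5  # any two weighted RSS values on the original scale
        c = 7.3
        # weights ∝ duration/value scale by 1/c, so weighted RSS scales by c
        d_orig = compute_aic(rss1, len(tac.values), 2) - compute_aic(rss2, len(tac.values), 4)
        d_scaled = compute_aic(c * rss1, len(tac.values), 2) - compute_aic(
            c * rss2, len(tac.values), 4
        )
        assert d_orig == pytest.approx(d_scaled)
        scaled = TimeActivityCurve(tac.region, frames, c * tac.values)
        np.testing.assert_allclose(frame_weights(scaled), w / c, rtol=1e-12)

    def test_vt_identity_holds(self, input_function, reference_2t_params):
        tac = simulate_tissue(reference_2t_params, input_function, two_hour_frames())
        fit = fit_region("2T", tac, input_function, n_starts=3)
        assert fit.VT == pytest.approx(fit.VND * (1 + fit.BPND), abs=1e-10)

    def test_free_tissue_fraction(self):
        assert derive_fnd(1.0, 1.0) == pytest.approx(1.0)
        assert derive_fnd(0.426, 7.89) == pytest.approx(0.054, abs=5e-4)
        assert derive_fnd(0.5, 10.0) == pytest.approx(0.05)
        with pytest.raises(DomainError):
            derive_fnd(0.4, 0.0)
        with pytest.raises(DomainError):
            derive_fnd(1.5, 5.0)


class TestFrameSchedule:
    def test_invalid_frames_rejected(self):
        with pytest.raises(DomainError):
            FrameSchedule([0.0, 1.0], [2.0, 3.0])  # overlapping
        with pytest.raises(DomainError):
            FrameSchedule([0.0], [0.0])  # zero duration

    def test_durations_and_midtimes(self):
        fs = FrameSchedule.from_durations([1.0, 2.0, 3.0])
        np.testing.assert_allclose(fs.mid_times, [0.5, 2.0, 4.5])
        np.testing.assert_allclose(fs.durations, [1.0, 2.0, 3.0])
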
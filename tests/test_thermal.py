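"""Melting-temperature estimators (midpoint, two-state fit, DSC peak) and
decay half-life fitting: parameter recovery, estimator concordance, limits."""

import math

import numpy as np
import pytest

from stabkit import synthetic, thermal
from stabkit.thermal import (
    DecayCurve,
    MeltingCurve,
    NoTransitionError,
    delta_tm,
    fit_decay,
    fit_two_state,
    normalize_transition,
    tm_dsc_peak,
    tm_midpoint,
)


def _melt(tm, dh=80.0, noise=0.0, seed=0, modality="fluorescence", **kw):
    curve, _ = synthetic.gen_melting_curve(
        tm=tm, dh_vh=dh, noise_sd=noise, seed=seed, modality=modality, **kw
    )
    return curve


class TestNormalizeTransition:
    def test_midpoint_is_half_unfolded(self):
        norm = normalize_transition(_melt(60.0))
        i = int(np.argmin(np.abs(norm.temperature_c - 60.0)))
        assert norm.fraction_unfolded[i] == pytest.approx(0.5, abs=0.01)

    def test_flat_curve_has_no_transition(self):
        t = np.linspace(25, 90, 131)
        rng = np.random.default_rng(0)
        curve = MeltingCurve(t, 1.0 + rng.normal(0, 0.01, t.size))
        with pytest.raises(NoTransitionError):
            normalize_transition(curve)

    def test_sloping_baselines_round_trip(self):
        """Normalized curve matches the generator's fraction unfolded."""
        curve = _melt(62.0, baselines=((-0.004, 1.2), (0.003, 2.4)))
        norm = normalize_transition(curve)
        truth = synthetic.two_state_fraction_unfolded(norm.temperature_c, 62.0, 80.0)
        assert np.max(np.abs(norm.fraction_unfolded - truth)) < 0.01

    def test_bounded_and_monotone_after_smoothing(self):
        norm = normalize_transition(_melt(60.0))
        f = norm.fraction_unfolded
        assert f.min() >= 0.0 and f.max() <= 1.0


class TestTmMidpoint:
    def test_noiseless_within_half_step(self):
        norm = normalize_transition(_melt(60.0, step=0.5))
        assert tm_midpoint(norm) == pytest.approx(60.0, abs=0.25)

    def test_noisy_recovery(self):
        errs = []
        for seed in range(30):
            curve = _melt(63.0, noise=0.01, seed=seed)
            errs.append(abs(tm_midpoint(normalize_transition(curve)) - 63.0))
        assert np.median(errs) < 0.2

    def test_multiple_noisy_crossings_resolve_deterministically(self):
        # plant a spike that crosses 0.5 twice around the true midpoint
        curve = _melt(60.0)
        i = int(np.argmin(np.abs(curve.temperature_c - 59.0)))
        curve.signal[i] += 0.4
        a = tm_midpoint(normalize_transition(curve))
        b = tm_midpoint(normalize_transition(curve))
        assert a == b
        assert abs(a - 60.0) < 1.5

    def test_no_crossing_errors(self):
        norm = normalize_transition(_melt(60.0))
        norm.fraction_unfolded = norm.fraction_unfolded * 0.3  # never reaches 0.5
        with pytest.raises(NoTransitionError):
            tm_midpoint(norm)


class TestFitTwoState:
    def test_recovers_parameters_to_three_sig_figs(self):
        fit = fit_two_state(_melt(65.0, dh=80.0))
        assert fit.success
        assert fit.tm == pytest.approx(65.0, rel=1e-3)
        assert fit.dh_vh == pytest.approx(80.0, rel=1e-3)

    def test_large_enthalpy_sharpens_but_keeps_midpoint(self):
        soft = fit_two_state(_melt(65.0, dh=60.0))
        sharp = fit_two_state(_melt(65.0, dh=400.0))
        assert sharp.tm == pytest.approx(soft.tm, abs=0.1)
        # sharper transition: fraction changes faster around Tm
        t = np.array([63.0, 67.0])
        assert np.diff(sharp.fraction_unfolded(t)) > np.diff(soft.fraction_unfolded(t))

    def test_planted_stability_gain_recovered(self):
        """Wildtype-like vs stabilized-variant melts: fitted dTm equals the
        planted +19 degC offset."""
        wt = fit_two_state(_melt(60.7, seed=1, noise=0.005))
        stab = fit_two_state(_melt(79.7, seed=2, noise=0.005))
        assert delta_tm(stab, wt) == pytest.approx(19.0, abs=0.3)

    def test_agrees_with_midpoint_on_clean_data(self):
        curve = _melt(58.0)
        fit = fit_two_state(curve)
        mid = tm_midpoint(normalize_transition(curve))
        assert abs(fit.tm - mid) < 0.5


class TestTmDscPeak:
    def test_noiseless_peak_at_tm(self):
        curve = _melt(60.0, modality="dsc")
        peak = tm_dsc_peak(curve)
        assert peak.tm == pytest.approx(60.0, abs=0.15)
        assert not peak.on_boundary

    def test_two_peaks_returns_taller_reports_both(self):
        a, _ = synthetic.gen_melting_curve(tm=55.0, dh_vh=90.0, modality="dsc",
                                           baselines=((0, 0), (0, 0)))
        b, _ = synthetic.gen_melting_curve(tm=75.0, dh_vh=90.0, modality="dsc",
                                           baselines=((0, 0), (0, 0)))
        curve = MeltingCurve(a.temperature_c, a.signal + 0.6 * b.signal, modality="dsc")
        peak = tm_dsc_peak(curve)
        assert peak.tm == pytest.approx(55.0, abs=0.3)
        assert len(peak.peaks) >= 2
        assert any(abs(t - 75.0) < 1.0 for t, _h in peak.peaks)

    def test_noisy_recovery(self):
        errs = []
        for seed in range(30):
            curve = _melt(62.0, modality="dsc", noise=0.07, seed=seed)  # ~1% of peak
            errs.append(abs(tm_dsc_peak(curve, smoothing_window=5).tm - 62.0))
        assert np.median(errs) < 0.3

    def test_boundary_peak_flagged(self):
        # heat absorption still rising at the end of the scan
        t = np.linspace(25, 90, 131)
        curve = MeltingCurve(t, np.exp((t - 90.0) / 5.0), modality="dsc")
        assert tm_dsc_peak(curve).on_boundary

    def test_wrong_modality_rejected(self):
        with pytest.raises(ValueError):
            tm_dsc_peak(_melt(60.0))


class TestEstimatorConcordance:
    @pytest.mark.parametrize("tm", [50.0, 60.0, 75.0])
    def test_three_estimators_agree_on_noiseless_curves(self, tm):
        sig = _melt(tm)
        dsc = _melt(tm, modality="dsc")
        t_mid = tm_midpoint(normalize_transition(sig))
        t_fit = fit_two_state(sig).tm
        t_dsc = tm_dsc_peak(dsc).tm
        assert max(t_mid, t_fit, t_dsc) - min(t_mid, t_fit, t_dsc) < 0.5

    def test_rank_preserved_over_tm_grid(self):
        grid = [48.0, 55.0, 62.0, 69.0, 76.0]
        mids, fits, peaks = [], [], []
        for tm in grid:
            mids.append(tm_midpoint(normalize_transition(_melt(tm))))
            fits.append(fit_two_state(_melt(tm)).tm)
            peaks.append(tm_dsc_peak(_melt(tm, modality="dsc")).tm)
        for est in (mids, fits, peaks):
            assert all(a < b for a, b in zip(est, est[1:]))


class TestFitDecay:
    def test_exact_recovery_noiseless(self):
        curve, _ = synthetic.gen_decay_curve(t_half=8.0, noise_sd=0.0)
        fit = fit_decay(curve)
        assert fit.t_half_h == pytest.approx(8.0, rel=1e-3)
        assert not fit.stable

    def test_half_life_identity_exact(self):
        curve, _ = synthetic.gen_decay_curve(t_half=5.0, noise_sd=0.02, seed=3)
        fit = fit_decay(curve)
        assert fit.t_half_h == fit.tau_h * math.log(2)  # exact, not approx

    def test_lambda_half_life_correspondence(self):
        curve, _ = synthetic.gen_decay_curve(t_half=8.0)
        fit = fit_decay(curve)
        assert fit.lambda_per_h == pytest.approx(0.0866, abs=0.0005)

    def test_constant_curve_flagged_stable(self):
        curve, _ = synthetic.gen_decay_curve(t_half=math.inf, noise_sd=0.0)
        fit = fit_decay(curve)
        assert fit.stable and math.isinf(fit.t_half_h)

    def test_slow_decay_within_window_flagged_stable(self):
        # half-life 10x the 24 h window: "stable for at least 24 h"
        curve, _ = synthetic.gen_decay_curve(t_half=240.0, noise_sd=0.0)
        assert fit_decay(curve).stable

    def test_noisy_recovery(self):
        errs = []
        for seed in range(30):
            curve, _ = synthetic.gen_decay_curve(t_half=8.0, noise_sd=0.05, seed=seed)
            errs.append(abs(fit_decay(curve).t_half_h - 8.0) / 8.0)
        assert np.median(errs) < 0.05


class TestDeltaTm:
    def test_subtraction(self):
        assert delta_tm(79.7, 60.7) == pytest.approx(19.0)

    def test_identical_fits_zero(self):
        fit = fit_two_state(_melt(60.0))
        assert delta_tm(fit, fit) == 0.0

    def test_batch_matches_elementwise(self):
        wt = fit_two_state(_melt(58.0))
        tms = [60.0, 64.0, 71.0]
        fits = [fit_two_state(_melt(t)) for t in tms]
        batch = [delta_tm(f, wt) for f in fits]
        assert batch == pytest.approx([f.tm - wt.tm for f in fits])

    def test_failed_fit_rejected(self):
        with pytest.raises(ValueError):
            delta_tm(float("nan"), 60.0)


class TestFitDecaySeries:
    def test_shared_plateau_recovers_individual_rates(self):
        from stabkit.thermal import fit_decay_series

        curves = [
            synthetic.gen_decay_curve(t_half=th, plateau=0.3, noise_sd=0.02, seed=s)[0]
            for th, s in [(4.0, 1), (8.0, 2), (16.0, 3)]
        ]
        fits = fit_decay_series(curves, share_plateau=True)
        assert len({f.plateau for f in fits}) == 1  # one shared plateau
        for fit, th in zip(fits, (4.0, 8.0, 16.0)):
            assert fit.t_half_h == pytest.approx(th, rel=0.05)

    def test_unshared_mode_matches_per_curve_fit(self):
        from stabkit.thermal import fit_decay_series

        curve, _ = synthetic.gen_decay_curve(t_half=6.0, noise_sd=0.01, seed=4)
        joint = fit_decay_series([curve], share_plateau=False)[0]
        single = fit_decay(curve)
        assert joint.t_half_h == single.t_half_h
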
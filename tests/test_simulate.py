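"""Phantom geometry, parameter sampling, rendering, and recovery metrics."""

import numpy as np
import pytest

from pulsewave import (
    SimulationConfig,
    WaveletAngiogram,
    make_phantom_layout,
    render_synthetic_angiogram,
    sample_bolus_params,
    seed_rois,
    validate_recovery,
)
from pulsewave.io import resample_trace_to_frames
from pulsewave.simulate import (
    CompartmentSpec,
    _unit_peak_envelope,
    control_config,
)
from pulsewave.stats import wrap_angle
from pulsewave.wavelet import cardiac_reference, crosscorrelate


class TestPhantomLayout:
    def test_deterministic_given_seed(self):
        a = make_phantom_layout(128, 128, seed=4)
        b = make_phantom_layout(128, 128, seed=4)
        np.testing.assert_array_equal(a.arterial_mask, b.arterial_mask)
        np.testing.assert_array_equal(a.venous_mask, b.venous_mask)
        assert a.arterial_anchor == b.arterial_anchor

    def test_trees_disjoint_inside_cranium(self):
        lay = make_phantom_layout(128, 128, seed=0)
        assert not (lay.arterial_mask & lay.venous_mask).any()
        for m in (lay.arterial_mask, lay.venous_mask, lay.parenchymal_mask):
            assert not (m & ~lay.intracranial_mask).any()

    @pytest.mark.parametrize("seed", range(3))
    def test_vessel_trees_are_substantial(self, seed):
        lay = make_phantom_layout(128, 128, seed=seed)
        assert lay.arterial_mask.sum() >= 300
        assert lay.venous_mask.sum() >= 300

    def test_too_small_frame_rejected(self):
        with pytest.raises(ValueError, match="64"):
            make_phantom_layout(32, 32, seed=0)

    def test_seed_rois_live_on_their_vessels(self):
        lay = make_phantom_layout(128, 128, seed=1)
        art, ven = seed_rois(lay)
        assert art.label == "artery" and ven.label == "vein"
        assert lay.arterial_mask[art.pixels[:, 0], art.pixels[:, 1]].all()
        assert lay.venous_mask[ven.pixels[:, 0], ven.pixels[:, 1]].all()


class TestSampleBolusParams:
    def test_arterial_delay_precedes_venous(self, rng):
        cfg = SimulationConfig()
        art = sample_bolus_params("arterial", cfg, rng, size=10_000)
        ven = sample_bolus_params("venous", cfg, rng, size=10_000)
        assert art["delay"].mean() < ven["delay"].mean()
        assert art["cardiac_amp"].mean() > ven["cardiac_amp"].mean()

    def test_draws_stay_in_support(self, rng):
        cfg = SimulationConfig()
        for role in ("arterial", "venous", "parenchymal"):
            d = sample_bolus_params(role, cfg, rng, size=5000)
            assert (d["k"] > 1.0).all() and (d["theta"] > 0).all()
            assert (d["amp"] > 0).all() and (d["cardiac_amp"] >= 0).all()
            assert (d["delay"] >= 0).all()
            assert (d["phase"] > -np.pi).all() and (d["phase"] <= np.pi).all()

    def test_negative_spread_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            CompartmentSpec(
                k=(2, -0.1), theta=(2, 0.1), delay=(3, 0.1), amp=(1, 0.1),
                cardiac_amp=(0.5, 0.05), phase=(0, 0.3),
            )

    def test_single_draw_returns_params_object(self, rng):
        p = sample_bolus_params("arterial", SimulationConfig(), rng)
        assert p.k > 1.0 and p.amp > 0

    def test_control_mix_makes_phases_exchangeable(self):
        # permutation test on the difference of compartment trig resultants
        rng = np.random.default_rng(8)
        cfg = control_config(SimulationConfig())
        art = sample_bolus_params("arterial", cfg, rng, size=10_000)["phase"]
        ven = sample_bolus_params("venous", cfg, rng, size=10_000)["phase"]

        def stat(a, b):
            return abs(np.exp(1j * a).mean() - np.exp(1j * b).mean())

        observed = stat(art, ven)
        pooled = np.concatenate([art, ven])
        perm_rng = np.random.default_rng(99)
        exceed = 0
        n_perm = 200
        for _ in range(n_perm):
            perm = perm_rng.permutation(pooled)
            if stat(perm[: art.size], perm[art.size:]) >= observed:
                exceed += 1
        assert (exceed + 1) / (n_perm + 1) > 0.01  # cannot reject exchangeability

    def test_without_mix_venous_center_is_reciprocal(self, rng):
        cfg = SimulationConfig()
        art = sample_bolus_params("arterial", cfg, rng, size=5000)["phase"]
        ven = sample_bolus_params("venous", cfg, rng, size=5000)["phase"]
        mu_a = np.angle(np.exp(1j * art).mean())
        mu_v = np.angle(np.exp(1j * ven).mean())
        assert abs(abs(wrap_angle(mu_a - mu_v)) - np.pi) < 0.05


class TestRenderSyntheticAngiogram:
    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="sampling theorem"):
            SimulationConfig(frame_rate=6.0, cardiac_rate=3.2)

    def test_deterministic_given_seed(self):
        lay = make_phantom_layout(96, 96, seed=2)
        d1 = render_synthetic_angiogram(lay, SimulationConfig(seed=3))
        d2 = render_synthetic_angiogram(lay, SimulationConfig(seed=3))
        np.testing.assert_array_equal(d1.angio.frames, d2.angio.frames)
        np.testing.assert_array_equal(d1.trace.samples, d2.trace.samples)

    def test_zero_noise_zero_cardiac_gives_pure_envelope(self):
        lay = make_phantom_layout(96, 96, seed=2)
        cfg = SimulationConfig(seed=3, noise_sigma=0.0)
        for role in ("arterial", "venous", "parenchymal"):
            spec = cfg.compartments[role]
            cfg.compartments[role] = CompartmentSpec(
                k=spec.k, theta=spec.theta, delay=spec.delay, amp=spec.amp,
                cardiac_amp=(0.0, 0.0), phase=spec.phase,
            )
        ds = render_synthetic_angiogram(lay, cfg)
        t = ds.angio.times
        r, c = np.argwhere(lay.arterial_mask)[0]
        pm = ds.truth.param_maps
        env = _unit_peak_envelope(
            t, np.array([pm["k"][r, c]]), np.array([pm["theta"][r, c]]),
            np.array([pm["delay"][r, c]]), np.array([pm["amp"][r, c]]),
        )[:, 0]
        np.testing.assert_allclose(
            ds.angio.frames[:, r, c], env + cfg.baseline, rtol=1e-12, atol=1e-12
        )

    def test_residual_spectrum_peaks_at_cardiac_rate(self):
        lay = make_phantom_layout(96, 96, seed=2)
        cfg = SimulationConfig(seed=3, noise_sigma=0.0)
        ds = render_synthetic_angiogram(lay, cfg)
        t = ds.angio.times
        r, c = ds.truth.layout.arterial_anchor
        pm = ds.truth.param_maps
        env = _unit_peak_envelope(
            t, np.array([pm["k"][r, c]]), np.array([pm["theta"][r, c]]),
            np.array([pm["delay"][r, c]]), np.array([pm["amp"][r, c]]),
        )[:, 0]
        resid = ds.angio.frames[:, r, c] - cfg.baseline - env
        freqs = np.fft.rfftfreq(t.size, 1.0 / cfg.frame_rate)
        spec = np.abs(np.fft.rfft(resid))
        spec[freqs < 0.5] = 0  # ignore the slow bolus-envelope leakage
        assert freqs[int(np.argmax(spec))] == pytest.approx(cfg.cardiac_rate, abs=0.05)

    def test_trace_and_pixels_share_phase_end_to_end(self, noiseless_result):
        # the wavelet restoration inverts the simulation: a zero-noise pixel's
        # recovered argument equals its assigned phase wherever the envelope
        # carries signal
        res = noiseless_result
        wav, truth = res.wav, res.dataset.truth
        mask = truth.layout.arterial_mask | truth.layout.venous_mask
        coeffs = wav.coeffs[:, mask]
        mags = np.abs(coeffs)
        # >= 20% of each pixel's peak magnitude: below that the bolus-onset
        # ramp dominates and instantaneous phase is transiently biased
        strong = mags > 0.2 * mags.max(axis=0, keepdims=True)
        strong &= wav.valid[:, None]
        assigned = truth.phase_map[mask]
        errs = wrap_angle(np.angle(coeffs) - assigned[None, :])[strong]
        assert np.sqrt(np.mean(errs**2)) < 0.05

    def test_background_is_noise_only(self):
        lay = make_phantom_layout(96, 96, seed=2)
        cfg = SimulationConfig(seed=3, noise_sigma=0.0)
        ds = render_synthetic_angiogram(lay, cfg)
        bg = ~lay.intracranial_mask
        np.testing.assert_allclose(ds.angio.frames[:, bg], cfg.baseline)


class TestValidateRecovery:
    def _wav_from_truth(self, truth):
        phase = truth.phase_map
        z = np.where(np.isnan(phase), 0, np.exp(1j * np.nan_to_num(phase)))
        T = 12
        coeffs = np.broadcast_to(z, (T,) + z.shape).copy()
        return WaveletAngiogram(
            coeffs=coeffs, scale_star=0.8, freq_star=1.2, frame_rate=6.0,
            valid=np.ones(T, bool),
        )

    def test_truth_against_itself_is_perfect(self):
        lay = make_phantom_layout(96, 96, seed=2)
        ds = render_synthetic_angiogram(lay, SimulationConfig(seed=3))
        wav = self._wav_from_truth(ds.truth)
        masks = {
            "arterial": lay.arterial_mask,
            "venous": lay.venous_mask,
            "parenchymal": lay.parenchymal_mask,
        }
        rep = validate_recovery(ds.truth, wav, masks)
        assert rep.phase_circ_rmse == pytest.approx(0.0, abs=1e-9)
        assert rep.jaccard_arterial == 1.0 and rep.jaccard_venous == 1.0
        assert rep.phase_separation == pytest.approx(np.pi, abs=0.1)

    def test_noiseless_run_recovers_everything(self, noiseless_result):
        rep = noiseless_result.report
        assert rep.phase_circ_rmse < 0.05
        assert rep.jaccard_arterial > 0.9 and rep.jaccard_venous > 0.9

    def test_noise_monotonically_degrades_phase_recovery(self):
        # average circular correlation over seeds must not improve as the
        # noise doubles
        levels = [1.0 / 6.0, 1.0 / 3.0, 2.0 / 3.0]
        mean_corr = []
        for sigma in levels:
            corrs = []
            for seed in range(20):
                lay = make_phantom_layout(96, 96, seed=seed)
                cfg = SimulationConfig(seed=seed, noise_sigma=sigma)
                ds = render_synthetic_angiogram(lay, cfg)
                at_frames = resample_trace_to_frames(ds.trace, ds.angio)
                ref = cardiac_reference(at_frames, ds.angio.frame_rate)
                wav = crosscorrelate(ds.angio, ref)
                corrs.append(validate_recovery(ds.truth, wav).phase_circ_corr)
            mean_corr.append(np.mean(corrs))
        assert mean_corr[0] >= mean_corr[1] >= mean_corr[2]

    def test_control_run_shows_no_arteriovenous_difference(self, control_result):
        rep = control_result.report
        assert rep.separation_resultant < 0.3
        assert not rep.separation_significant
        assert abs(rep.mask_discrimination) < 0.15
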
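"""HRF convolution, regressor correlation, orthogonalization, GLM recovery."""

import numpy as np
import pytest

from memcrit.regressors import (
    DesignTiming,
    EventSeries,
    coding_correlation,
    convolve_hrf,
    double_gamma_hrf,
    orthogonalize,
    session_events,
    toy_glm_recovery,
)


class TestHRF:
    def test_shape_matches_external_double_gamma_oracle(self):
        """Same canonical double-gamma family as the neuroimaging stack."""
        from nilearn.glm.first_level.hemodynamic_models import spm_hrf

        ours = double_gamma_hrf(dt=0.1)
        ref = spm_hrf(0.1, oversampling=1)
        n = min(ours.size, ref.size)
        r = np.corrcoef(ours[:n], ref[:n])[0, 1]
        assert r > 0.999

    def test_single_event_peaks_about_five_seconds_after_onset(self):
        ev = EventSeries(onsets=[10.0], amplitudes=[1.0], run_length_s=60.0)
        reg = convolve_hrf(ev, mean_center=False)
        peak_s = np.argmax(reg) * ev.tr_s
        assert 14.0 <= peak_s <= 16.0  # onset 10 s + ~5 s to peak

    def test_empty_event_list_gives_zero_regressor(self):
        ev = EventSeries(onsets=[], amplitudes=[], run_length_s=40.0)
        assert not convolve_hrf(ev).any()

    def test_convolution_is_linear_in_amplitude(self):
        e1 = EventSeries(onsets=[4.0, 20.0], amplitudes=[1.0, -0.5], run_length_s=60.0)
        e2 = EventSeries(onsets=[4.0, 20.0], amplitudes=[2.0, -1.0], run_length_s=60.0)
        np.testing.assert_allclose(2 * convolve_hrf(e1), convolve_hrf(e2), atol=1e-12)

    def test_events_beyond_run_end_rejected(self):
        with pytest.raises(ValueError):
            EventSeries(onsets=[10.0, 70.0], amplitudes=[1.0, 1.0], run_length_s=60.0)

    def test_non_increasing_onsets_rejected(self):
        with pytest.raises(ValueError):
            EventSeries(onsets=[5.0, 5.0], amplitudes=[1.0, 1.0], run_length_s=60.0)


class TestTiming:
    def test_intervals_fall_inside_stated_ranges(self, rng):
        timing = DesignTiming()
        iti = timing.draw_iti(rng, 3000)
        isi = timing.draw_isi(rng, 3000)
        assert iti.min() >= 1.0 and iti.max() <= 11.0
        assert isi.min() >= 1.0 and isi.max() <= 6.0
        assert iti.mean() == pytest.approx(2.0, abs=0.15)
        assert isi.mean() == pytest.approx(2.85, abs=0.2)

    def test_session_layout_orders_trial_then_feedback(self, coded_fmri_sessions):
        timed = session_events(coded_fmri_sessions[0], seed=0)
        assert (timed.feedback_onset_s > timed.onset_s).all()
        assert timed.onset_s.is_monotonic_increasing


class TestCodingCorrelation:
    def test_coding_correlated_with_itself_is_unity(self, coded_fmri_sessions):
        out = coding_correlation(coded_fmri_sessions[:2], "ms_pe", "ms_pe")
        assert out["r_squared"] == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_in_the_two_codings(self, coded_fmri_sessions):
        a = coding_correlation(coded_fmri_sessions, "ms_pe", "ero_pe", seed=5)
        b = coding_correlation(coded_fmri_sessions, "ero_pe", "ms_pe", seed=5)
        assert a["r"] == pytest.approx(b["r"], abs=1e-12)

    def test_invariant_to_affine_rescaling_of_amplitudes(self, coded_fmri_sessions):
        base = coding_correlation(coded_fmri_sessions[:2], "ms_pe", "ero_pe", seed=5)
        rescaled = [s.assign(ms_pe=3.0 * s.ms_pe + 0.7) for s in coded_fmri_sessions[:2]]
        out = coding_correlation(rescaled, "ms_pe", "ero_pe", seed=5)
        assert out["r"] == pytest.approx(base["r"], abs=1e-9)

    def test_pe_codings_share_substantial_but_partial_variance(self, coded_fmri_sessions):
        pe = coding_correlation(coded_fmri_sessions, "ms_pe", "ero_pe", seed=7)
        ev = coding_correlation(coded_fmri_sessions, "ms_ev", "ero_ev", seed=7)
        assert 0.2 < pe["r_squared"] < 0.9
        assert ev["r_squared"] < pe["r_squared"]  # EV codings diverge more

    def test_constant_regressor_reported_missing(self, coded_fmri_sessions):
        flat = [coded_fmri_sessions[0].assign(ms_pe=0.5)]
        out = coding_correlation(flat, "ms_pe", "ero_pe")
        assert out["n"] == 0 and np.isnan(out["r"])


class TestOrthogonalize:
    def test_self_orthogonalization_vanishes(self, rng):
        x = rng.normal(size=200)
        np.testing.assert_allclose(orthogonalize(x, x), 0.0, atol=1e-10)

    def test_residual_uncorrelated_with_first_regressor(self, rng):
        x = rng.normal(size=500)
        y = 0.6 * x + rng.normal(size=500)
        res = orthogonalize(x, y)
        assert abs(np.corrcoef(x, res)[0, 1]) < 1e-10

    def test_already_orthogonal_input_only_mean_centred(self, rng):
        x = np.tile([1.0, -1.0], 100)
        y = rng.normal(size=200)
        y -= np.polyfit(x, y, 1)[0] * x  # remove any x component
        np.testing.assert_allclose(orthogonalize(x, y), y - y.mean(), atol=1e-8)

    def test_zero_variance_first_regressor_degrades_to_centring(self, rng):
        y = rng.normal(size=50)
        np.testing.assert_allclose(orthogonalize(np.ones(50), y), y - y.mean())


class TestToyGLM:
    def test_noiseless_signal_attributed_exactly_to_generating_coding(
        self, coded_fmri_sessions
    ):
        out = toy_glm_recovery(coded_fmri_sessions[0], "ms_pe", beta=2.0,
                               noise_sd=0.0, seed=0)
        assert out["coef_ms"] == pytest.approx(2.0, abs=1e-8)
        assert out["coef_ero"] == pytest.approx(0.0, abs=1e-8)

    def test_symmetric_recovery_for_ero_generated_signal(self, coded_fmri_sessions):
        out = toy_glm_recovery(coded_fmri_sessions[0], "ero_pe", beta=1.5,
                               noise_sd=0.0, seed=0)
        assert out["coef_ero"] == pytest.approx(1.5, abs=1e-8)
        assert out["winner"] == "ero_pe"

    def test_recovery_power_grows_with_design_size(self, coded_fmri_sessions):
        """Longer sessions give larger t for the generating coding."""
        session = coded_fmri_sessions[0]
        ts = []
        for n in (120, 240, 480):
            sub = session.iloc[:n].reset_index(drop=True)
            out = toy_glm_recovery(sub, "ms_pe", beta=1.0, noise_sd=1.0, seed=3)
            ts.append(abs(out["t_ms"]))
        assert ts[0] < ts[1] < ts[2]
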
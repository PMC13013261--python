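"""Transfer function analysis: spectra, coherence gating, band rules."""

import numpy as np
import pytest

from cerauto.signals import InsufficientDataError, UniformSignal
from cerauto.synth import SynthConfig, apply_transfer, generate_recording
from cerauto.tfa import (
    VLF_BAND,
    EmptyBandError,
    FrequencyBand,
    TransferFunctionAnalysis,
    band_metrics,
    bf_band,
    coherence_critical,
    cross_spectra,
)


class TestCrossSpectra:
    def test_identity_system(self, white_signal):
        spec = cross_spectra(white_signal, UniformSignal(white_signal.values.copy(), 4.0))
        power = (spec.freqs > 0.01) & (spec.freqs < 1.9)
        np.testing.assert_allclose(spec.msc[power], 1.0, atol=1e-9)
        np.testing.assert_allclose(spec.phase_deg[power], 0.0, atol=1e-6)
        np.testing.assert_allclose(spec.gain[power], 1.0, atol=1e-6)

    def test_scalar_gain(self, white_signal):
        spec = cross_spectra(white_signal, UniformSignal(2.0 * white_signal.values, 4.0))
        power = (spec.freqs > 0.01) & (spec.freqs < 1.9)
        np.testing.assert_allclose(spec.gain[power], 2.0, atol=1e-6)
        np.testing.assert_allclose(spec.msc[power], 1.0, atol=1e-9)

    def test_imposed_phase_recovered(self, white_signal):
        """A 36-deg lead imposed through the synthesis transfer shows up at 0.1 Hz."""
        y = apply_transfer(white_signal, lambda f: np.ones_like(f),
                           lambda f: np.full_like(f, 36.0))
        spec = cross_spectra(white_signal, y)
        i = np.argmin(np.abs(spec.freqs - 0.1))
        assert spec.phase_deg[i] == pytest.approx(36.0, abs=3.0)

    def test_phase_antisymmetry(self, white_signal):
        rng = np.random.default_rng(8)
        y = UniformSignal(
            np.roll(white_signal.values, 2) + 0.3 * rng.standard_normal(white_signal.n), 4.0
        )
        fwd = cross_spectra(white_signal, y)
        rev = cross_spectra(y, white_signal)
        power = (fwd.freqs > 0.02) & (fwd.freqs < 1.5)
        np.testing.assert_allclose(fwd.phase_deg[power], -rev.phase_deg[power], atol=1e-6)

    def test_msc_scale_invariant_gain_linear(self, white_signal):
        rng = np.random.default_rng(9)
        y = UniformSignal(white_signal.values + rng.standard_normal(white_signal.n), 4.0)
        base = cross_spectra(white_signal, y)
        scaled = cross_spectra(white_signal, UniformSignal(5.0 * y.values, 4.0))
        np.testing.assert_allclose(scaled.msc, base.msc, atol=1e-9)
        np.testing.assert_allclose(scaled.gain, 5.0 * base.gain, rtol=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            x = UniformSignal(np.zeros(400), 4.0)
            cross_spectra(x, x)

    def test_wrong_rate_rejected(self):
        x = UniformSignal(np.zeros(1000), 5.0)
        with pytest.raises(ValueError, match="4.0 Hz"):
            cross_spectra(x, x)


class TestCoherenceCritical:
    def test_formula_endpoint(self):
        assert coherence_critical(2) == pytest.approx(0.95)

    def test_closed_form_values(self):
        assert coherence_critical(5) == pytest.approx(0.5271, abs=1e-4)
        assert coherence_critical(100) == pytest.approx(0.0298, abs=1e-4)

    def test_monotone_decreasing(self):
        vals = [coherence_critical(L) for L in range(2, 30)]
        assert np.all(np.diff(vals) < 0)

    def test_requires_two_windows(self):
        with pytest.raises(ValueError):
            coherence_critical(1)


class TestBandMetrics:
    def test_identity_vlf(self, white_signal):
        spec = cross_spectra(white_signal, UniformSignal(white_signal.values.copy(), 4.0))
        m = band_metrics(spec, VLF_BAND)
        in_band = (spec.freqs >= 0.02) & (spec.freqs <= 0.07)
        assert m.n_bins_used == int(in_band.sum())
        assert m.coherence == pytest.approx(1.0, abs=1e-9)
        assert m.ps_deg == pytest.approx(0.0, abs=1e-6)
        assert m.gain == pytest.approx(1.0, abs=1e-6)

    def test_all_gated_band_flagged_undefined(self, white_signal):
        rng = np.random.default_rng(10)
        indep = UniformSignal(rng.standard_normal(white_signal.n), 4.0)
        spec = cross_spectra(white_signal, indep)
        # force every VLF bin below threshold
        spec.msc[:] = 0.0
        m = band_metrics(spec, VLF_BAND)
        assert m.n_bins_used == 0
        assert not m.defined
        assert np.isnan(m.ps_deg)

    def test_highpass_phase_matches_analytic_average(self, white_signal):
        """First-order high-pass with 0.07 Hz corner: VLF band-average phase
        tracks the analytic filter phase averaged over retained bins."""
        from cerauto.synth import highpass_gain, highpass_phase_deg

        y = apply_transfer(white_signal, highpass_gain, highpass_phase_deg)
        spec = cross_spectra(white_signal, y)
        m = band_metrics(spec, VLF_BAND)
        kept = (spec.freqs >= 0.02) & (spec.freqs <= 0.07)
        analytic = highpass_phase_deg(spec.freqs[kept]).mean()
        assert m.ps_deg == pytest.approx(analytic, abs=5.0)

    def test_empty_band_raises(self, white_signal):
        spec = cross_spectra(white_signal, UniformSignal(white_signal.values.copy(), 4.0))
        with pytest.raises(EmptyBandError):
            band_metrics(spec, FrequencyBand(0.0301, 0.0304))


class TestBFBand:
    @pytest.mark.parametrize(
        "bpm,lo,hi", [(6, 0.08, 0.12), (10, 0.15, 0.19), (15, 0.23, 0.27)]
    )
    def test_paced_bands(self, bpm, lo, hi):
        band = bf_band(resp_bpm=bpm)
        assert band.f_lo == pytest.approx(lo)
        assert band.f_hi == pytest.approx(hi)

    def test_unsupported_rate_rejected(self):
        with pytest.raises(ValueError):
            bf_band(resp_bpm=8)

    def test_spontaneous_band(self):
        band = bf_band(spontaneous_stats=(12.0, 3.0))
        assert band.f_lo == pytest.approx(9.0 / 60.0)
        assert band.f_hi == pytest.approx(15.0 / 60.0)

    def test_degenerate_sd_widened(self):
        band = bf_band(spontaneous_stats=(15.0, 0.0))
        assert band.f_hi - band.f_lo == pytest.approx(0.04)
        assert 0.5 * (band.f_lo + band.f_hi) == pytest.approx(0.25)


def test_full_pipeline_phase_and_gain_recovery():
    """Waveforms -> beats -> 4 Hz -> band metrics recovers an imposed
    20-deg lead within 5 deg and unit gain within 10% at the 6/min band."""
    cfg = SynthConfig(
        duration_s=360, resp_bpm=6, seed=3,
        ca_gain=lambda f: np.ones_like(np.asarray(f, float)),
        ca_phase_deg=lambda f: np.full_like(np.asarray(f, float), 20.0),
    )
    rec, _ = generate_recording(cfg)
    res = TransferFunctionAnalysis.from_waveforms(rec["abp"], rec["cbv"]).fit(
        bands=[bf_band(resp_bpm=6)]
    )
    m = res.band(bf_band(resp_bpm=6))
    assert m.coherence > 0.8
    assert m.ps_deg == pytest.approx(20.0, abs=5.0)
    assert m.gain == pytest.approx(1.0, rel=0.10)
    table = res.summary()
    assert {"coherence", "ps_deg", "gain_cm_s_mmHg"} <= set(table.columns)
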
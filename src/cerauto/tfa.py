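"""Transfer function analysis (TFA) of the pressure-flow relationship.

Cerebral autoregulation is quantified as a linear transfer function between
beat-averaged arterial pressure (input) and cerebral blood velocity (output),
both resampled to 4 Hz: Welch cross-spectra with Hanning-windowed 102.5-s
segments at 50% overlap yield magnitude-squared coherence, phase shift
(degrees, positive = CBv leads ABP) and gain (cm s^-1 mmHg^-1) per frequency.
Band averages are reported in the very-low-frequency range (0.02-0.07 Hz,
where autoregulation acts) and in a breathing-frequency band centred on the
paced rate, after two gates: bins with coherence below the 95% confidence
limit for the number of windows are excluded, and negative-phase bins below
0.1 Hz are removed to avoid phase wrapping.

Model-style entry point: ``TransferFunctionAnalysis(abp4, cbv4).fit()`` or
``TransferFunctionAnalysis.from_waveforms(abp, cbv).fit()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import preprocess
from .signals import InsufficientDataError, UniformSignal

__all__ = [
    "SpectralEstimate",
    "FrequencyBand",
    "BandMetrics",
    "VLF_BAND",
    "cross_spectra",
    "coherence_critical",
    "band_metrics",
    "bf_band",
    "TransferFunctionAnalysis",
    "TFAResults",
]

#: Working sampling rate of the beat-averaged series, Hz.
TARGET_FS = 4.0
#: Welch segment length in samples at 4 Hz. The nominal 102.4-s window is
#: 409.6 samples; the nearest integer (410 samples, 102.5 s) is used.
SEGMENT_SAMPLES = 410
#: Frequency below which negative phase is treated as wrapping and removed.
ANTIWRAP_HZ = 0.1


class EmptyBandError(ValueError):
    """Raised when a frequency band contains no spectral bins."""


@dataclass
class FrequencyBand:
    f_lo: float
    f_hi: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi <= TARGET_FS / 2):
            raise ValueError(f"invalid band [{self.f_lo}, {self.f_hi}] Hz")


VLF_BAND = FrequencyBand(0.02, 0.07, "VLF")

#: Paced-protocol breathing rates (breaths/min) -> band centre (Hz).
BF_CENTERS = {6: 0.10, 10: 0.17, 15: 0.25}
BF_HALF_WIDTH = 0.02
MIN_SPONTANEOUS_WIDTH = 0.04


@dataclass
class SpectralEstimate:
    """Cross-spectral TFA estimate per frequency bin."""

    freqs: np.ndarray
    msc: np.ndarray
    phase_deg: np.ndarray
    gain: np.ndarray
    n_windows: int


@dataclass
class BandMetrics:
    """Band-averaged coherence / phase shift / gain after coherence gating."""

    coherence: float
    ps_deg: float
    gain: float
    n_bins_used: int
    band: FrequencyBand

    @property
    def defined(self) -> bool:
        return self.n_bins_used > 0


def cross_spectra(abp4: UniformSignal, cbv4: UniformSignal) -> SpectralEstimate:
    """Welch auto-/cross-spectra of the 4 Hz pressure and velocity series.

    Means are subtracted (no detrending); 410-sample Hanning segments with 50%
    overlap are averaged. Phase is the argument of ``S_xy`` in degrees with
    positive values meaning CBv leads ABP; gain is ``|S_xy| / S_xx``.
    """
    for name, sig in (("abp", abp4), ("cbv", cbv4)):
        if abs(sig.fs - TARGET_FS) > 1e-9:
            raise ValueError(f"{name} must be sampled at {TARGET_FS} Hz, got {sig.fs}")
    if abp4.n != cbv4.n:
        raise ValueError("abp and cbv must have equal length")
    n = abp4.n
    if n < SEGMENT_SAMPLES:
        raise InsufficientDataError(
            f"need >= {SEGMENT_SAMPLES} samples ({SEGMENT_SAMPLES / TARGET_FS:.1f} s), got {n}"
        )
    x = abp4.values - abp4.values.mean()
    y = cbv4.values - cbv4.values.mean()
    win = sps.get_window("hann", SEGMENT_SAMPLES)
    step = SEGMENT_SAMPLES // 2
    starts = range(0, n - SEGMENT_SAMPLES + 1, step)
    sxx = syy = sxy = 0.0
    for s in starts:
        fx = np.fft.rfft(win * x[s : s + SEGMENT_SAMPLES])
        fy = np.fft.rfft(win * y[s : s + SEGMENT_SAMPLES])
        sxx = sxx + (fx * np.conj(fx)).real
        syy = syy + (fy * np.conj(fy)).real
        sxy = sxy + np.conj(fx) * fy
    n_windows = len(list(starts))
    freqs = np.fft.rfftfreq(SEGMENT_SAMPLES, 1.0 / TARGET_FS)
    with np.errstate(invalid="ignore", divide="ignore"):
        msc = np.abs(sxy) ** 2 / (sxx * syy)
        gain = np.abs(sxy) / sxx
    msc = np.clip(np.nan_to_num(msc), 0.0, 1.0)
    gain = np.nan_to_num(gain)
    phase = np.degrees(np.angle(sxy))
    return SpectralEstimate(
        freqs=freqs, msc=msc, phase_deg=phase, gain=gain, n_windows=n_windows
    )


def coherence_critical(n_windows: int, alpha: float = 0.05) -> float:
    """95% confidence limit for magnitude-squared coherence under independence.

    For ``L`` averaged windows the null distribution of coherence satisfies
    ``P(msc > c) = (1 - c)^(L-1)``, so the critical value at level ``alpha`` is
    ``1 - alpha^(1/(L-1))``; monotonically decreasing in ``L``.
    """
    if n_windows < 2:
        raise ValueError("coherence threshold requires >= 2 windows")
    return 1.0 - alpha ** (1.0 / (n_windows - 1))


def band_metrics(spec: SpectralEstimate, band: FrequencyBand) -> BandMetrics:
    """Average coherence / phase / gain over a band with coherence gating.

    Bins with centres inside the closed band are kept, then bins with
    coherence below :func:`coherence_critical` are excluded, and negative-phase
    bins below 0.1 Hz are removed (anti-wrap). If every bin is excluded the
    metrics are NaN and flagged undefined via ``n_bins_used = 0``.
    """
    sel = (spec.freqs >= band.f_lo) & (spec.freqs <= band.f_hi)
    if not np.any(sel):
        raise EmptyBandError(f"no spectral bins inside [{band.f_lo}, {band.f_hi}] Hz")
    thr = coherence_critical(spec.n_windows) if spec.n_windows >= 2 else 0.0
    keep = sel & (spec.msc >= thr)
    # tolerance keeps numerically-zero phases (identity system) in the average
    keep &= ~((spec.freqs < ANTIWRAP_HZ) & (spec.phase_deg < -1e-9))
    n_used = int(keep.sum())
    if n_used == 0:
        return BandMetrics(np.nan, np.nan, np.nan, 0, band)
    return BandMetrics(
        coherence=float(spec.msc[keep].mean()),
        ps_deg=float(spec.phase_deg[keep].mean()),
        gain=float(spec.gain[keep].mean()),
        n_bins_used=n_used,
        band=band,
    )


def bf_band(
    resp_bpm: Optional[float] = None,
    spontaneous_stats: Optional[tuple] = None,
) -> FrequencyBand:
    """Breathing-frequency band for a paced rate or spontaneous breathing.

    Paced rates 6/10/15 breaths/min map to bands centred at 0.10/0.17/0.25 Hz
    (+/- 0.02 Hz). For spontaneous breathing the band is the individual's mean
    respiratory rate +/- SD (in Hz), widened to at least 0.04 Hz.
    """
    if (resp_bpm is None) == (spontaneous_stats is None):
        raise ValueError("give exactly one of resp_bpm or spontaneous_stats")
    if resp_bpm is not None:
        key = int(round(resp_bpm))
        if key not in BF_CENTERS or abs(resp_bpm - key) > 1e-9:
            raise ValueError(f"paced rate must be one of {sorted(BF_CENTERS)}, got {resp_bpm}")
        c = BF_CENTERS[key]
        return FrequencyBand(c - BF_HALF_WIDTH, c + BF_HALF_WIDTH, f"BF{key}")
    mean_bpm, sd_bpm = spontaneous_stats
    if mean_bpm <= 0 or sd_bpm < 0:
        raise ValueError("spontaneous stats require mean > 0 and sd >= 0")
    lo, hi = (mean_bpm - sd_bpm) / 60.0, (mean_bpm + sd_bpm) / 60.0
    if hi - lo < MIN_SPONTANEOUS_WIDTH:
        c = mean_bpm / 60.0
        lo, hi = c - MIN_SPONTANEOUS_WIDTH / 2, c + MIN_SPONTANEOUS_WIDTH / 2
    return FrequencyBand(max(lo, 1e-6), hi, "BFspont")


class TransferFunctionAnalysis:
    """Pressure-to-flow transfer function model on 4 Hz beat-averaged series.

    Parameters
    ----------
    abp4, cbv4 : UniformSignal
        Beat-averaged, 4 Hz resampled pressure (mmHg) and velocity (cm/s).
    """

    def __init__(self, abp4: UniformSignal, cbv4: UniformSignal):
        self.abp4 = abp4
        self.cbv4 = cbv4

    @classmethod
    def from_waveforms(cls, abp: UniformSignal, cbv: UniformSignal):
        """Build the model from raw waveforms: artifact repair, systolic-peak
        detection on ABP, beat averaging of both channels, 4 Hz resampling."""
        abp_clean, _ = preprocess.remove_artifacts(abp)
        cbv_clean, _ = preprocess.remove_artifacts(cbv)
        beats = preprocess.detect_systolic_peaks(abp_clean)
        abp4 = preprocess.beat_average_resample(abp_clean, beats, TARGET_FS)
        cbv4 = preprocess.beat_average_resample(cbv_clean, beats, TARGET_FS)
        n = min(abp4.n, cbv4.n)
        abp4.values, cbv4.values = abp4.values[:n], cbv4.values[:n]
        return cls(abp4, cbv4)

    def fit(self, bands: Sequence[FrequencyBand] = (VLF_BAND,)) -> "TFAResults":
        spec = cross_spectra(self.abp4, self.cbv4)
        return TFAResults(spec, list(bands))


class TFAResults:
    """Fitted TFA: per-bin spectra plus band-averaged metrics."""

    def __init__(self, spectral: SpectralEstimate, bands: Sequence[FrequencyBand]):
        self.spectral = spectral
        self.bands = list(bands)

    def band(self, band: FrequencyBand) -> BandMetrics:
        return band_metrics(self.spectral, band)

    def summary(self) -> pd.DataFrame:
        rows = []
        for b in self.bands:
            m = self.band(b)
            rows.append(
                {
                    "band": b.label or f"[{b.f_lo}, {b.f_hi}]",
                    "f_lo_hz": b.f_lo,
                    "f_hi_hz": b.f_hi,
                    "coherence": m.coherence,
                    "ps_deg": m.ps_deg,
                    "gain_cm_s_mmHg": m.gain,
                    "n_bins_used": m.n_bins_used,
                    "n_windows": self.spectral.n_windows,
                }
            )
        return pd.DataFrame(rows)
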
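"""Waveform cleaning, beat detection, and beat-to-beat resampling.

Front end of every analysis stage: artifact repair on the raw waveforms,
systolic-peak detection on arterial pressure, R-peak detection on the ECG,
beat-interval averaging with spline resampling to a uniform 4 Hz grid, and
whole-epoch heart-rate / respiratory-rate estimates.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .signals import (
    BeatSeries,
    InsufficientBeatsError,
    InsufficientDataError,
    NoBeatsError,
    UniformSignal,
)

__all__ = [
    "remove_artifacts",
    "detect_systolic_peaks",
    "detect_r_peaks",
    "pulse_intervals",
    "beat_average_resample",
    "resample_beat_values",
    "estimate_hr_fft",
    "estimate_resp_rate",
    "HREstimate",
    "RespRateEstimate",
]

#: Minimum spacing between detected beats (supports heart rates up to 240 bpm).
REFRACTORY_S = 0.25
#: Sliding evaluation window for artifact detection, seconds.
ARTIFACT_WINDOW_S = 10.0


def remove_artifacts(x: UniformSignal, window_s: float = ARTIFACT_WINDOW_S):
    """Repair spike artifacts by derivative thresholding + linear interpolation.

    The first difference is computed; within each evaluation window, samples
    whose absolute first difference exceeds twice the window's difference SD
    are replaced by linear interpolation between the nearest clean neighbours.

    Returns ``(cleaned, artifact_count)``. A clean or constant input is
    returned unchanged with count 0.
    """
    v = x.values
    if v.size < 3:
        return x, 0
    d = np.diff(v)
    bad = np.zeros(v.size, dtype=bool)
    win = max(int(round(window_s * x.fs)), 4)
    hop = max(win // 2, 1)
    for start in range(0, d.size, hop):
        seg = d[start : start + win]
        sd = seg.std()
        if sd == 0:
            continue
        exceeded = np.flatnonzero(np.abs(seg) > 2.0 * sd)
        # a large jump implicates the sample after the step
        bad[start + exceeded + 1] = True
    count = int(bad.sum())
    if count == 0:
        return x, 0
    good = ~bad
    if good.sum() < 2:
        return x, 0
    idx = np.arange(v.size)
    repaired = v.copy()
    repaired[bad] = np.interp(idx[bad], idx[good], v[good])
    return (
        UniformSignal(repaired, x.fs, t0=x.t0, label=x.label, units=x.units),
        count,
    )


def _find_beat_peaks(v: np.ndarray, fs: float) -> np.ndarray:
    """Prominence-gated peak picking with the refractory period enforced."""
    span = np.ptp(v)
    if span <= 0 or not np.all(np.isfinite(v)):
        raise NoBeatsError("signal has no pulsatile content")
    distance = max(int(round(REFRACTORY_S * fs)), 1)
    peaks, _ = sps.find_peaks(v, distance=distance, prominence=0.25 * span)
    if peaks.size == 0:
        raise NoBeatsError("no beats detected")
    return peaks


def detect_systolic_peaks(abp: UniformSignal) -> BeatSeries:
    """Detect systolic peaks of the ABP waveform.

    One peak per cardiac cycle; the SAP value is the waveform maximum of the
    cycle. Raises :class:`NoBeatsError` for pulseless input.
    """
    peaks = _find_beat_peaks(abp.values, abp.fs)
    times = abp.t0 + peaks / abp.fs
    return BeatSeries(times, abp.values[peaks], label="SAP", units="mmHg")


def detect_r_peaks(ecg: UniformSignal) -> BeatSeries:
    """Detect R peaks and return the RR-interval series (ms).

    The ECG is band-passed 8-20 Hz with a second-order Butterworth applied
    forward-backward (zero-phase; effective order four), then peaks are picked
    with a 0.25 s refractory period and an adaptive height gate. RR values are
    successive R-R differences in ms anchored at the later R time.
    """
    if np.ptp(ecg.values) == 0:
        raise NoBeatsError("flat ECG trace")
    sos = sps.butter(2, [8.0, 20.0], btype="bandpass", fs=ecg.fs, output="sos")
    filt = sps.sosfiltfilt(sos, ecg.values)
    distance = max(int(round(REFRACTORY_S * ecg.fs)), 1)
    cand, props = sps.find_peaks(filt, distance=distance, height=0.0)
    if cand.size == 0:
        raise NoBeatsError("no R peaks detected")
    # adaptive threshold from the upper envelope of candidate heights
    ref = np.percentile(props["peak_heights"], 90)
    peaks = cand[props["peak_heights"] > 0.4 * ref]
    if peaks.size < 2:
        raise NoBeatsError("fewer than two R peaks detected")
    r_times = ecg.t0 + peaks / ecg.fs
    rr = np.diff(r_times) * 1000.0
    return BeatSeries(r_times[1:], rr, label="RR", units="ms")


def pulse_intervals(sap: BeatSeries, anchor: str = "end") -> BeatSeries:
    """Beat-to-beat pulse intervals (ms) from detected systolic-peak times.

    ``anchor="end"`` places each interval at the beat that closes it (the ECG
    convention); ``anchor="start"`` at the beat that opens it (matches the
    generator's baroreflex alignment).
    """
    if sap.n < 2:
        raise InsufficientBeatsError("need >= 2 beats for pulse intervals")
    rr = np.diff(sap.times) * 1000.0
    times = sap.times[1:] if anchor == "end" else sap.times[:-1]
    return BeatSeries(times, rr, label="PI", units="ms")


def beat_average_resample(
    x: UniformSignal, beats: BeatSeries, target_fs: float = 4.0
) -> UniformSignal:
    """Average a waveform over beat intervals and spline-resample uniformly.

    Per-beat means are computed on half-open intervals ``[beat_i, beat_{i+1})``
    and anchored at the interval midpoint, then cubic-spline interpolated onto
    a uniform ``target_fs`` grid spanning the anchored range. Used to turn raw
    ABP/CBv into the 4 Hz beat-averaged series transfer-function analysis
    consumes.
    """
    if beats.n < 4:
        raise InsufficientBeatsError(f"need >= 4 beats, got {beats.n}")
    edges = np.searchsorted(x.times, beats.times)
    means, anchors = [], []
    for i in range(beats.n - 1):
        lo, hi = edges[i], edges[i + 1]
        if hi <= lo:
            continue
        means.append(x.values[lo:hi].mean())
        anchors.append(0.5 * (beats.times[i] + beats.times[i + 1]))
    if len(means) < 4:
        raise InsufficientBeatsError("fewer than 4 beat intervals inside the signal")
    anchors = np.asarray(anchors)
    means = np.asarray(means)
    spline = CubicSpline(anchors, means)
    step = 1.0 / target_fs
    grid = anchors[0] + step * np.arange(int((anchors[-1] - anchors[0]) / step) + 1)
    return UniformSignal(
        spline(grid), fs=target_fs, t0=anchors[0], label=x.label, units=x.units
    )


def resample_beat_values(beats: BeatSeries, target_fs: float = 4.0) -> UniformSignal:
    """Cubic-spline a beat-value series (e.g. RR in ms) onto a uniform grid."""
    if beats.n < 4:
        raise InsufficientBeatsError(f"need >= 4 beats, got {beats.n}")
    spline = CubicSpline(beats.times, beats.values)
    step = 1.0 / target_fs
    grid = beats.times[0] + step * np.arange(
        int((beats.times[-1] - beats.times[0]) / step) + 1
    )
    return UniformSignal(spline(grid), fs=target_fs, t0=beats.times[0], label=beats.label)


class HREstimate(NamedTuple):
    bpm: float
    band_edge: bool


def estimate_hr_fft(abp: UniformSignal) -> HREstimate:
    """Heart rate from the first harmonic of the ABP spectrum, 40-140 bpm band.

    Returns the frequency (as bpm) of the amplitude-spectrum maximum within
    0.67-2.33 Hz; ``band_edge`` flags a maximum at the band boundary.
    """
    if abp.duration < 60.0:
        raise InsufficientDataError("need >= 60 s of signal for HR estimation")
    v = abp.values - abp.values.mean()
    nfft = int(2 ** np.ceil(np.log2(4 * v.size)))
    amp = np.abs(np.fft.rfft(v, nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / abp.fs)
    band = (freqs >= 40.0 / 60.0) & (freqs <= 140.0 / 60.0)
    idx_band = np.flatnonzero(band)
    k = idx_band[np.argmax(amp[idx_band])]
    # a maximum hugging the band boundary (within 2% of the band width)
    # suggests the true fundamental lies outside 40-140 bpm
    f_lo, f_hi = freqs[idx_band[0]], freqs[idx_band[-1]]
    margin = 0.02 * (f_hi - f_lo)
    at_edge = freqs[k] <= f_lo + margin or freqs[k] >= f_hi - margin
    return HREstimate(bpm=60.0 * freqs[k], band_edge=bool(at_edge))


class RespRateEstimate(NamedTuple):
    bpm: float
    compliant: Optional[bool]


class NoBreathsError(NoBeatsError):
    """Raised when no breath cycles are detected in the capnogram."""


def estimate_resp_rate(
    etco2: UniformSignal, target_bpm: Optional[float] = None
) -> RespRateEstimate:
    """Respiratory rate from capnogram plateau cycles, with compliance gate.

    Breaths are detected as plateau-wave cycles; the rate is
    ``60 * (n_breaths - 1) / span``. When ``target_bpm`` is given, the paced
    protocol's +/-1 bpm tolerance decides the ``compliant`` flag.
    """
    if etco2.duration < 60.0:
        raise InsufficientDataError("need >= 60 s of capnogram")
    v = etco2.values
    if np.ptp(v) <= 0:
        raise NoBreathsError("flat capnogram")
    # light smoothing so plateau ripple does not split breaths
    win = max(int(round(0.5 * etco2.fs)), 1)
    smooth = np.convolve(v, np.ones(win) / win, mode="same")
    distance = max(int(round(1.5 * etco2.fs)), 1)  # supports rates up to 40 bpm
    peaks, _ = sps.find_peaks(smooth, distance=distance, prominence=0.3 * np.ptp(smooth))
    if peaks.size < 2:
        raise NoBreathsError("fewer than two breaths detected")
    span = (peaks[-1] - peaks[0]) / etco2.fs
    rate = 60.0 * (peaks.size - 1) / span
    compliant = None if target_bpm is None else bool(abs(rate - target_bpm) <= 1.0)
    return RespRateEstimate(bpm=rate, compliant=compliant)


def end_tidal_values(etco2: UniformSignal) -> BeatSeries:
    """Per-breath end-tidal values (maxima of each breath cycle), capnography style."""
    if np.ptp(etco2.values) <= 0:
        raise NoBreathsError("flat capnogram")
    win = max(int(round(0.5 * etco2.fs)), 1)
    smooth = np.convolve(etco2.values, np.ones(win) / win, mode="same")
    distance = max(int(round(1.5 * etco2.fs)), 1)
    peaks, _ = sps.find_peaks(
        smooth, distance=distance, prominence=0.3 * np.ptp(smooth)
    )
    if peaks.size == 0:
        raise NoBreathsError("no breaths detected")
    # refine to raw-trace maxima near each smoothed peak
    vals = []
    half = max(int(round(0.75 * etco2.fs)), 1)
    for p in peaks:
        lo, hi = max(0, p - half), min(etco2.n, p + half + 1)
        vals.append(etco2.values[lo:hi].max())
    return BeatSeries(etco2.t0 + peaks / etco2.fs, vals, label="EtCO2", units="mmHg")
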
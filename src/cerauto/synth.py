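"""Synthetic cardio-cerebral signal generator with known ground truth.

Emulates the signal ensemble of a paced-breathing physiology session:

* a pulsatile arterial pressure (ABP) waveform whose systolic values carry
  Mayer-wave (0.1 Hz) and respiratory oscillations,
* an RR-interval series coupled to systolic pressure through a baroreflex
  slope acting after a configurable latency (beat-domain lag),
* cerebral blood velocity (CBv) produced from the ABP fluctuation through a
  linear transfer function with frequency-dependent gain and phase lead
  (cerebral autoregulation behaves as a high-pass filter: slow pressure
  oscillations are buffered and phase-advanced, fast ones pass through),
* an ECG R-wave train consistent with the beat times,
* a breath-synchronous end-tidal CO2 trace whose plateau level falls as the
  breathing rate rises (hyperventilation washout).

Because every coupling parameter is configured explicitly, downstream
estimators (transfer-function analysis, xBRS, joint symbolic dynamics, HRV)
can be validated by parameter recovery instead of against irreproducible
human recordings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .signals import BeatSeries, Recording, UniformSignal

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_recording",
    "generate_beat_pair",
    "apply_transfer",
    "highpass_gain",
    "highpass_phase_deg",
]

#: Corner frequency (Hz) of the default first-order high-pass autoregulation model.
DEFAULT_CA_CORNER_HZ = 0.07


def highpass_gain(f, corner_hz: float = DEFAULT_CA_CORNER_HZ, g_inf: float = 1.0):
    """|H(f)| of a first-order high-pass: ``g_inf * (f/fc) / sqrt(1 + (f/fc)^2)``."""
    f = np.asarray(f, dtype=float)
    ratio = f / corner_hz
    return g_inf * ratio / np.sqrt(1.0 + ratio**2)


def highpass_phase_deg(f, corner_hz: float = DEFAULT_CA_CORNER_HZ):
    """Phase lead (degrees) of a first-order high-pass: 90 deg at DC, 0 at infinity."""
    f = np.asarray(f, dtype=float)
    return 90.0 - np.degrees(np.arctan(f / corner_hz))


@dataclass
class SynthConfig:
    """Generator configuration. Defaults describe a typical healthy adult at rest.

    Heart rate, pressure and EtCO2 levels follow cohort medians for young
    volunteers (HR ~70 bpm, SAP ~120 mmHg, EtCO2 ~36.5 mmHg); the baroreflex
    slope (10 ms/mmHg) and 2-s latency sit in the reported healthy range, and
    the default autoregulation transfer function is a first-order high-pass
    with a 0.07 Hz corner (gain ~0.8 and phase lead ~35 deg at 0.1 Hz).
    """

    duration_s: float = 300.0
    fs: float = 200.0
    hr_bpm: float = 70.0
    resp_bpm: float = 15.0
    rsa_amp_ms: float = 40.0
    mayer_amp_mmHg: float = 3.0
    resp_abp_amp_mmHg: float = 2.0
    brs_slope_ms_per_mmHg: float = 10.0
    brs_delay_s: float = 2.0
    ca_gain: Callable = highpass_gain
    ca_phase_deg: Callable = highpass_phase_deg
    etco2_base_mmHg: float = 36.5
    etco2_slope_mmHg_per_bpm: float = 0.45
    etco2_reference_bpm: float = 6.0
    sap_base_mmHg: float = 120.0
    pulse_pressure_mmHg: float = 40.0
    cbv_base_cm_s: float = 57.0
    noise_sd: dict = field(
        default_factory=lambda: {
            "abp": 0.3,
            "cbv": 0.3,
            "ecg": 0.01,
            "etco2": 0.2,
            "rr_ms": 3.0,
            "sap_mmHg": 0.5,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        scalars = {
            "duration_s": (0.0, np.inf),
            "fs": (np.nextafter(0, 1), np.inf),
            "hr_bpm": (40.0, 140.0),
            "resp_bpm": (np.nextafter(0, 1), np.inf),
            "rsa_amp_ms": (0.0, np.inf),
            "mayer_amp_mmHg": (0.0, np.inf),
            "resp_abp_amp_mmHg": (0.0, np.inf),
            "brs_delay_s": (0.0, np.inf),
            "etco2_base_mmHg": (0.0, np.inf),
            "sap_base_mmHg": (0.0, np.inf),
            "pulse_pressure_mmHg": (0.0, np.inf),
            "cbv_base_cm_s": (0.0, np.inf),
        }
        for name, (lo, hi) in scalars.items():
            val = getattr(self, name)
            if not np.isfinite(val) or not (lo <= val <= hi):
                raise ValueError(f"SynthConfig.{name} out of range: {val!r}")
        if not np.isfinite(self.brs_slope_ms_per_mmHg):
            raise ValueError("SynthConfig.brs_slope_ms_per_mmHg must be finite")
        for key, sd in self.noise_sd.items():
            if not np.isfinite(sd) or sd < 0:
                raise ValueError(f"SynthConfig.noise_sd[{key!r}] out of range: {sd!r}")

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Known generative parameters and event series for parameter-recovery tests."""

    beat_times: np.ndarray
    rr_ms: np.ndarray
    sap_mmHg: np.ndarray
    brs_slope_ms_per_mmHg: float
    brs_delay_s: float
    brs_delay_beats: int
    etco2_epoch_mean_mmHg: float
    ca_probe_freqs_hz: np.ndarray
    ca_gain: np.ndarray
    ca_phase_deg: np.ndarray
    rr_anchor: str = "interval_start"

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        return out


# systolic upstroke duration as a fraction of the shortest plausible beat
_UPSTROKE_S = 0.12
_DECAY_TAU_FRAC = 0.35  # diastolic decay time constant as a fraction of the beat


def _beat_dynamics(config: SynthConfig, rng: np.random.Generator):
    """Simulate beat onsets, per-beat SAP and baroreflex-coupled RR intervals.

    Beat-domain recursion: ``RR_n = RR0 + slope * (SAP_{n-k} - SAP_base)
    + RSA(t_n) + noise`` with ``k = round(delay_s * hr / 60)`` beats.
    RR_n is the interval started by beat n, so at zero delay RR_n is an exact
    affine function of SAP_n.
    """
    rr0 = 60000.0 / config.hr_bpm
    f_resp = config.resp_bpm / 60.0
    k = int(round(config.brs_delay_s * config.hr_bpm / 60.0))
    sd_sap = config.noise_sd.get("sap_mmHg", 0.0)
    sd_rr = config.noise_sd.get("rr_ms", 0.0)

    onsets, saps, rrs = [], [], []
    t = 0.0
    while t < config.duration_s:
        sap = (
            config.sap_base_mmHg
            + config.mayer_amp_mmHg * np.sin(2 * np.pi * 0.1 * t)
            + config.resp_abp_amp_mmHg * np.sin(2 * np.pi * f_resp * t)
            + (sd_sap * rng.standard_normal() if sd_sap > 0 else 0.0)
        )
        onsets.append(t)
        saps.append(sap)
        n = len(saps) - 1
        sap_driver = saps[n - k] if n - k >= 0 else config.sap_base_mmHg
        rr = (
            rr0
            + config.brs_slope_ms_per_mmHg * (sap_driver - config.sap_base_mmHg)
            + config.rsa_amp_ms * np.sin(2 * np.pi * f_resp * t)
            + (sd_rr * rng.standard_normal() if sd_rr > 0 else 0.0)
        )
        rr = max(rr, 250.0)  # physiological floor
        rrs.append(rr)
        t += rr / 1000.0
    # the last onset starts an interval ending beyond duration_s; keep it as the
    # closing beat time so diff(beat_times) reproduces rr_ms exactly
    onsets.append(t)
    return np.asarray(onsets), np.asarray(saps), np.asarray(rrs), k


def generate_beat_pair(config: SynthConfig):
    """Generate coupled (RR, SAP) beat series plus their ground truth.

    Returns
    -------
    rr : BeatSeries
        RR intervals in ms, anchored at the beat that starts each interval.
    sap : BeatSeries
        Systolic pressure per beat, mmHg, same anchors as ``rr``.
    truth : GroundTruth
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    onsets, saps, rrs, k = _beat_dynamics(config, rng)
    if len(rrs) < 10:
        raise ValueError(
            f"duration_s={config.duration_s} yields only {len(rrs)} beats (need >= 10)"
        )
    truth = _ground_truth(config, onsets, saps, rrs, k)
    rr = BeatSeries(onsets[:-1], rrs, label="RR", units="ms")
    sap = BeatSeries(onsets[:-1], saps, label="SAP", units="mmHg")
    return rr, sap, truth


def _ground_truth(config, beat_times, saps, rrs, k) -> GroundTruth:
    probe = np.array([0.02, 0.05, 0.07, 0.10, 0.17, 0.25])
    return GroundTruth(
        beat_times=beat_times,
        rr_ms=rrs,
        sap_mmHg=saps,
        brs_slope_ms_per_mmHg=config.brs_slope_ms_per_mmHg,
        brs_delay_s=config.brs_delay_s,
        brs_delay_beats=k,
        etco2_epoch_mean_mmHg=_etco2_level(config),
        ca_probe_freqs_hz=probe,
        ca_gain=np.asarray(config.ca_gain(probe), dtype=float),
        ca_phase_deg=np.asarray(config.ca_phase_deg(probe), dtype=float),
    )


def _etco2_level(config: SynthConfig) -> float:
    return config.etco2_base_mmHg - config.etco2_slope_mmHg_per_bpm * (
        config.resp_bpm - config.etco2_reference_bpm
    )


def apply_transfer(x: UniformSignal, gain, phase_deg) -> UniformSignal:
    """Apply a linear transfer function (gain and phase lead per frequency).

    ``gain(f)`` and ``phase_deg(f)`` are callables on [0, fs/2]. Positive phase
    means the output *leads* the input: a 36 deg lead at 0.1 Hz advances a
    0.1 Hz sine by one second. Identity transfer returns the input to round-off.
    """
    n = x.n
    freqs = np.fft.rfftfreq(n, 1.0 / x.fs)
    g = np.asarray(gain(freqs), dtype=float)
    ph = np.asarray(phase_deg(freqs), dtype=float)
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(ph))):
        raise ValueError("transfer gain/phase must be finite on [0, fs/2]")
    h = g * np.exp(1j * np.deg2rad(ph))
    h[0] = g[0]  # DC carries no phase
    if n % 2 == 0:
        h[-1] = h[-1].real  # Nyquist bin must be real
    y = np.fft.irfft(np.fft.rfft(x.values) * h, n)
    return UniformSignal(y, fs=x.fs, t0=x.t0, label=x.label, units=x.units)


def _abp_waveform(t, onsets, saps, rrs, pulse_pressure):
    """Per-beat raised-cosine systolic upstroke + exponential diastolic decay."""
    abp = np.empty_like(t)
    idx = np.searchsorted(onsets, t, side="right") - 1
    idx = np.clip(idx, 0, len(rrs) - 1)
    tau_in_beat = t - onsets[idx]
    rr_s = rrs[idx] / 1000.0
    sap = saps[idx]
    dia = sap - pulse_pressure
    up = np.minimum(tau_in_beat / _UPSTROKE_S, 1.0)
    rising = 0.5 * (1.0 - np.cos(np.pi * up))  # 0 -> 1 raised cosine
    decay = np.exp(-(tau_in_beat - _UPSTROKE_S) / (_DECAY_TAU_FRAC * rr_s))
    shape = np.where(tau_in_beat < _UPSTROKE_S, rising, decay)
    abp = dia + pulse_pressure * shape
    return abp


def _ecg_waveform(t, r_times, width_s=0.012, amp_mv=1.0):
    """Gaussian R spikes plus a low broad T wave at each beat."""
    ecg = np.zeros_like(t)
    fs = 1.0 / (t[1] - t[0])
    half = int(round(5 * width_s * fs))
    for rt in r_times:
        i = int(round((rt - t[0]) * fs))
        lo, hi = max(0, i - half), min(len(t), i + half + 1)
        if lo >= hi:
            continue
        ecg[lo:hi] += amp_mv * np.exp(-0.5 * ((t[lo:hi] - rt) / width_s) ** 2)
        # T wave ~0.25 s after R, broad and low
        j0 = int(round((rt + 0.25 - t[0]) * fs))
        tlo, thi = max(0, j0 - int(0.1 * fs)), min(len(t), j0 + int(0.1 * fs))
        if tlo < thi:
            ecg[tlo:thi] += 0.15 * amp_mv * np.exp(
                -0.5 * ((t[tlo:thi] - rt - 0.25) / 0.05) ** 2
            )
    return ecg


def _etco2_waveform(t, config: SynthConfig):
    """Breath-synchronous plateau wave; the end-tidal value is the per-breath max."""
    level = _etco2_level(config)
    f_resp = config.resp_bpm / 60.0
    phase = (t * f_resp) % 1.0
    # inspiration (fresh gas, ~35% of cycle): CO2 falls to near zero;
    # expiration: rapid rise then an alveolar plateau at the end-tidal level
    insp = 0.35
    rise = 0.15
    wave = np.where(
        phase < insp,
        level * 0.05 * (1.0 - phase / insp),
        np.where(
            phase < insp + rise,
            level * (0.05 + 0.95 * (phase - insp) / rise),
            level * (1.0 + 0.02 * np.sin(2 * np.pi * (phase - insp - rise))),
        ),
    )
    return np.minimum(wave, level), level


def generate_recording(config: SynthConfig):
    """Generate a five-channel 200 Hz recording plus its ground truth.

    Channels: ``abp`` (mmHg), ``cbv`` (cm/s), ``ecg`` (mV), ``etco2`` (mmHg).
    CBv is the ABP fluctuation passed through the configured transfer function,
    riding on a constant baseline; ECG R waves sit at the beat times; the
    ground-truth ``beat_times`` are the systolic-peak times of the ABP waveform.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    onsets, saps, rrs, k = _beat_dynamics(config, rng)
    if len(rrs) < 2:
        raise ValueError("duration too short to form beats")

    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    abp = _abp_waveform(t, onsets, saps, rrs, config.pulse_pressure_mmHg)
    ecg = _ecg_waveform(t, onsets[:-1])
    etco2, _ = _etco2_waveform(t, config)

    cbv_fluct = apply_transfer(
        UniformSignal(abp - abp.mean(), config.fs), config.ca_gain, config.ca_phase_deg
    ).values
    cbv = config.cbv_base_cm_s + cbv_fluct

    for name, arr in (("abp", abp), ("cbv", cbv), ("ecg", ecg), ("etco2", etco2)):
        sd = config.noise_sd.get(name, 0.0)
        if sd > 0:
            arr += sd * rng.standard_normal(n)

    channels = {
        "abp": UniformSignal(abp, config.fs, label="abp", units="mmHg"),
        "cbv": UniformSignal(cbv, config.fs, label="cbv", units="cm/s"),
        "ecg": UniformSignal(ecg, config.fs, label="ecg", units="mV"),
        "etco2": UniformSignal(etco2, config.fs, label="etco2", units="mmHg"),
    }
    # ground-truth beat times = systolic peak times (onset + upstroke duration)
    peak_times = onsets + _UPSTROKE_S
    truth = _ground_truth(config, peak_times, saps, rrs, k)
    return Recording(channels=channels, fs=config.fs), truth
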
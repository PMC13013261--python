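"""Heart rate variability metrics: time domain, frequency domain, entropy.

Time domain follows the Task Force definitions (SDNN, RMSSD, meanNN, pNN20,
pNN50). Frequency-domain powers come from a Welch periodogram of the RR
series spline-resampled to 4 Hz, integrated over LF (0.04-0.15 Hz) and HF
(0.15-0.40 Hz); normalized components divide by total power over
0.04-0.40 Hz, so LFn + HFn = 1. Entropy metrics (ApEn, SampEn, FuzzyEn,
MSEn) use m = 2 and r = 0.2 * SD (see :mod:`cerauto.entropy`).

Model-style entry point: ``HRV(rr).fit()`` -> :class:`HRVResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import entropy
from .preprocess import resample_beat_values
from .signals import BeatSeries, InsufficientBeatsError, InsufficientDataError

__all__ = ["HRVMetrics", "hrv_time", "hrv_freq", "hrv_entropy", "HRV", "HRVResults"]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
#: Welch segment length for the RR spectrum, seconds (50% overlap).
SPECTRAL_SEGMENT_S = 120.0


@dataclass
class HRVMetrics:
    meannn_ms: float = np.nan
    sdnn_ms: float = np.nan
    rmssd_ms: float = np.nan
    pnn20_pct: float = np.nan
    pnn50_pct: float = np.nan
    lf_ms2: float = np.nan
    hf_ms2: float = np.nan
    lfn: float = np.nan
    hfn: float = np.nan
    lf_hf: float = np.nan
    apen: float = np.nan
    sampen: float = np.nan
    fuzzyen: float = np.nan
    msen: float = np.nan

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def hrv_time(rr: BeatSeries) -> HRVMetrics:
    """Time-domain metrics from an RR series in ms (needs >= 10 intervals)."""
    v = rr.values
    if v.size < 10:
        raise InsufficientBeatsError(f"need >= 10 RR intervals, got {v.size}")
    diff = np.diff(v)
    return HRVMetrics(
        meannn_ms=float(v.mean()),
        sdnn_ms=float(v.std(ddof=1)),
        rmssd_ms=float(np.sqrt(np.mean(diff**2))),
        pnn20_pct=100.0 * float(np.mean(np.abs(diff) > 20.0)),
        pnn50_pct=100.0 * float(np.mean(np.abs(diff) > 50.0)),
    )


def hrv_freq(rr: BeatSeries, fs: float = 4.0) -> HRVMetrics:
    """Spectral LF/HF powers and normalized components of the RR series.

    The beat series is cubic-spline resampled to ``fs`` and analysed with a
    Welch periodogram (120-s Hanning segments, 50% overlap, constant detrend).
    ``lf_hf`` is NaN when the HF power is zero.
    """
    if rr.duration < 120.0:
        raise InsufficientDataError("need >= 120 s of RR data for spectral HRV")
    uni = resample_beat_values(rr, fs)
    nperseg = min(int(SPECTRAL_SEGMENT_S * fs), uni.n)
    freqs, psd = sps.welch(
        uni.values, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant",
    )
    df = freqs[1] - freqs[0]
    lf = float(psd[(freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])].sum() * df)
    hf = float(psd[(freqs >= HF_BAND[0]) & (freqs <= HF_BAND[1])].sum() * df)
    tp = lf + hf
    return HRVMetrics(
        lf_ms2=lf,
        hf_ms2=hf,
        lfn=lf / tp if tp > 0 else np.nan,
        hfn=hf / tp if tp > 0 else np.nan,
        lf_hf=lf / hf if hf > 0 else np.nan,
    )


def hrv_entropy(
    rr: BeatSeries,
    m: int = 2,
    r: Optional[float] = None,
    scales=(1, 2, 3),
) -> HRVMetrics:
    """Entropy metrics of the RR series (needs >= 100 intervals for scale 1).

    MSEn is NaN (flagged) when the series cannot support the largest scale.
    """
    v = rr.values
    if v.size < 100:
        raise InsufficientBeatsError(f"need >= 100 RR intervals, got {v.size}")
    return HRVMetrics(
        apen=entropy.apen(v, m=m, r=r),
        sampen=entropy.sampen(v, m=m, r=r),
        fuzzyen=entropy.fuzzyen(v, m=m, r=r),
        msen=entropy.msen(v, m=m, r=r, scales=scales),
    )


class HRV:
    """Heart rate variability model over one RR-interval series (ms)."""

    def __init__(self, rr: BeatSeries):
        self.rr = rr

    def fit(self, m: int = 2, r: Optional[float] = None, scales=(1, 2, 3)) -> "HRVResults":
        metrics = hrv_time(self.rr).to_dict()
        metrics.update(
            {k: v for k, v in hrv_freq(self.rr).to_dict().items() if not np.isnan(v)}
        )
        if self.rr.n >= 100:
            ent = hrv_entropy(self.rr, m=m, r=r, scales=scales).to_dict()
            for k in ("apen", "sampen", "fuzzyen", "msen"):
                metrics[k] = ent[k]
        return HRVResults(HRVMetrics(**{k: metrics.get(k, np.nan) for k in metrics}))


class HRVResults:
    def __init__(self, metrics: HRVMetrics):
        self.metrics = metrics

    def summary(self) -> pd.DataFrame:
        d = self.metrics.to_dict()
        return pd.DataFrame({"metric": list(d), "value": list(d.values())})
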
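"""Cross-correlation baroreflex sensitivity (xBRS).

The spontaneous-baroreflex estimator of Westerhof: systolic pressure and
beat-to-beat pulse interval are interpolated onto a common 1 Hz grid; in each
10-s window sliding by 1 s the interval series is regressed on pressure at
candidate delays of 0-3 s, the delay with the best *positive* correlation is
selected, and the window contributes its regression slope (ms/mmHg) when the
correlation p-value is below 0.05 and no ectopic beat falls inside the
window. The per-epoch xBRS is the median accepted slope; the dominant delay
is the mode of the selected delays.

Model-style entry point: ``BaroreflexSensitivity(rr, sap).fit()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .signals import BeatSeries, InsufficientDataError

__all__ = ["XBRSResult", "compute_xbrs", "flag_ectopic_beats", "BaroreflexSensitivity"]

WINDOW_S = 10
DELAYS_S = (0, 1, 2, 3)
P_THRESHOLD = 0.05
#: Relative deviation from the local-median interval that flags an ectopic beat.
ECTOPIC_REL_DEV = 0.25
ECTOPIC_NEIGHBORS = 10


@dataclass
class XBRSResult:
    """Per-epoch xBRS summary; ``defined`` is False when no window passed."""

    xbrs_ms_per_mmHg: float
    delay_mode_s: float
    n_windows_used: int
    n_windows_total: int
    window_values: np.ndarray = field(default_factory=lambda: np.array([]))
    window_delays: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def defined(self) -> bool:
        return self.n_windows_used > 0


def flag_ectopic_beats(rr: BeatSeries) -> np.ndarray:
    """Flag intervals deviating > 25% from the median of their 10 neighbours."""
    v = rr.values
    flags = np.zeros(v.size, dtype=bool)
    half = ECTOPIC_NEIGHBORS // 2
    for i in range(v.size):
        lo, hi = max(0, i - half), min(v.size, i + half + 1)
        neigh = np.concatenate([v[lo:i], v[i + 1 : hi]])
        if neigh.size == 0:
            continue
        med = np.median(neigh)
        if med > 0 and abs(v[i] - med) > ECTOPIC_REL_DEV * med:
            flags[i] = True
    return flags


def compute_xbrs(rr: BeatSeries, sap: BeatSeries) -> XBRSResult:
    """Estimate xBRS from coupled pulse-interval (ms) and SAP (mmHg) series."""
    t0 = max(rr.times[0], sap.times[0])
    t1 = min(rr.times[-1], sap.times[-1])
    if t1 - t0 < 30.0:
        raise InsufficientDataError("need >= 30 s of overlapping RR and SAP data")
    grid = np.arange(np.ceil(t0), np.floor(t1) + 1e-9, 1.0)
    # sample-and-hold of beat values: each grid second carries the most recent
    # beat's value (keeps grid samples equal to actual beat values and limits
    # interpolation-induced serial correlation in the windowed regressions)
    rr_g = rr.values[np.clip(np.searchsorted(rr.times, grid, side="right") - 1, 0, None)]
    sap_g = sap.values[np.clip(np.searchsorted(sap.times, grid, side="right") - 1, 0, None)]
    ect_flags = flag_ectopic_beats(rr)
    ect_times = rr.times[ect_flags]

    max_delay = max(DELAYS_S)
    slopes, delays = [], []
    n_total = 0
    for s in range(0, grid.size - WINDOW_S - max_delay + 1):
        n_total += 1
        sap_w = sap_g[s : s + WINDOW_S]
        if sap_w.std() == 0:
            continue
        best = None
        for d in DELAYS_S:
            rr_w = rr_g[s + d : s + d + WINDOW_S]
            if rr_w.std() == 0:
                continue
            r = float(np.corrcoef(sap_w, rr_w)[0, 1])
            if r > 0 and (best is None or r > best[0]):
                best = (r, d, rr_w)
        if best is None:
            continue
        r, d, rr_w = best
        # two-sided p-value of the Pearson correlation (t distribution, n-2 df)
        n = WINDOW_S
        r_clip = min(r, 1.0 - 1e-15)
        tstat = r_clip * np.sqrt((n - 2) / (1.0 - r_clip**2))
        p = 2.0 * stats.t.sf(tstat, n - 2)
        if p >= P_THRESHOLD:
            continue
        w_start, w_end = grid[s], grid[s] + WINDOW_S + d
        if ect_times.size and np.any((ect_times >= w_start) & (ect_times <= w_end)):
            continue
        slope = r * rr_w.std() / sap_w.std()
        slopes.append(slope)
        delays.append(d)

    if not slopes:
        return XBRSResult(np.nan, np.nan, 0, n_total)
    slopes = np.asarray(slopes)
    delays = np.asarray(delays, dtype=float)
    vals, counts = np.unique(delays, return_counts=True)
    return XBRSResult(
        xbrs_ms_per_mmHg=float(np.median(slopes)),
        delay_mode_s=float(vals[np.argmax(counts)]),
        n_windows_used=len(slopes),
        n_windows_total=n_total,
        window_values=slopes,
        window_delays=delays,
    )


class BaroreflexSensitivity:
    """xBRS model over coupled pulse-interval and systolic-pressure series."""

    def __init__(self, rr: BeatSeries, sap: BeatSeries):
        self.rr = rr
        self.sap = sap

    def fit(self) -> "BaroreflexResults":
        return BaroreflexResults(compute_xbrs(self.rr, self.sap))


class BaroreflexResults:
    def __init__(self, result: XBRSResult):
        self.result = result

    @property
    def xbrs_ms_per_mmHg(self) -> float:
        return self.result.xbrs_ms_per_mmHg

    def summary(self) -> pd.DataFrame:
        r = self.result
        return pd.DataFrame(
            [
                {
                    "xbrs_ms_per_mmHg": r.xbrs_ms_per_mmHg,
                    "delay_mode_s": r.delay_mode_s,
                    "n_windows_used": r.n_windows_used,
                    "n_windows_total": r.n_windows_total,
                    "acceptance_rate": (
                        r.n_windows_used / r.n_windows_total if r.n_windows_total else np.nan
                    ),
                }
            ]
        )

    def windows(self) -> pd.DataFrame:
        """Per-window diagnostics (slope in ms/mmHg, selected delay in s)."""
        return pd.DataFrame(
            {"slope_ms_per_mmHg": self.result.window_values, "delay_s": self.result.window_delays}
        )
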
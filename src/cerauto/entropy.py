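"""Regularity / complexity statistics for beat-to-beat interval series.

Standard template-matching entropies with the literature-convention
parameters m = 2 and tolerance r = 0.2 * SD of the (original-scale) series:

* ApEn(m, r)  = Phi^m(r) - Phi^(m+1)(r), self-matches included;
* SampEn(m,r) = -ln(A / B), self-matches excluded, N - m templates at both
  lengths;
* FuzzyEn     — exponential membership exp(-(d/r)^2) of mean-removed
  templates (Chebyshev distance), order 2;
* MSEn        — mean SampEn over coarse-grained scales 1..3 with r fixed from
  the scale-1 SD.

Undefined results (no template matches) are returned as NaN rather than a
substituted infinity.
"""

from __future__ import annotations

import numpy as np

__all__ = ["apen", "sampen", "fuzzyen", "msen"]


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("entropy input must be finite")
    return x


def _default_r(x: np.ndarray, r) -> float:
    return 0.2 * x.std() if r is None else float(r)


def _templates(x: np.ndarray, m: int) -> np.ndarray:
    n = x.size - m + 1
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n]


def _cheb(a: np.ndarray) -> np.ndarray:
    """Pairwise Chebyshev distances between template rows."""
    return np.max(np.abs(a[:, None, :] - a[None, :, :]), axis=-1)


def apen(x, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy; 0 for constant series, larger = more irregular."""
    x = _as_series(x)
    r = _default_r(x, r)
    if x.size < m + 2:
        raise ValueError("series too short for ApEn")

    def phi(mm: int) -> float:
        t = _templates(x, mm)
        c = (_cheb(t) <= r).mean(axis=1)  # self-match included
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sampen(x, m: int = 2, r: float | None = None) -> float:
    """Sample entropy; NaN when no length-(m+1) matches exist."""
    x = _as_series(x)
    r = _default_r(x, r)
    if x.size < m + 2:
        raise ValueError("series too short for SampEn")
    n_t = x.size - m  # same template count at both lengths
    tm = _templates(x, m)[:n_t]
    tm1 = _templates(x, m + 1)
    iu = np.triu_indices(n_t, k=1)
    b = int((_cheb(tm)[iu] <= r).sum())
    a = int((_cheb(tm1)[iu] <= r).sum())
    if a == 0 or b == 0:
        return np.nan
    return -np.log(a / b)


def fuzzyen(x, m: int = 2, r: float | None = None, order: int = 2) -> float:
    """Fuzzy entropy with exponential membership on mean-removed templates."""
    x = _as_series(x)
    r = _default_r(x, r)
    if x.size < m + 2:
        raise ValueError("series too short for FuzzyEn")
    if r == 0:
        return 0.0  # constant series: all templates identical

    def phi(mm: int) -> float:
        t = _templates(x, mm)[: x.size - m]
        t = t - t.mean(axis=1, keepdims=True)
        d = _cheb(t)
        iu = np.triu_indices(t.shape[0], k=1)
        return float(np.mean(np.exp(-((d[iu] / r) ** order))))

    p_m, p_m1 = phi(m), phi(m + 1)
    if p_m1 == 0 or p_m == 0:
        return np.nan
    return np.log(p_m / p_m1)


def _coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    n = x.size // scale
    return x[: n * scale].reshape(n, scale).mean(axis=1)


def msen(x, m: int = 2, r: float | None = None, scales=(1, 2, 3)) -> float:
    """Multiscale entropy: mean SampEn over coarse-grained scales.

    The tolerance is fixed from the scale-1 series SD (Costa convention).
    Returns NaN if the series is too short for the largest scale
    (< 100 * max(scale) samples) or any scale's SampEn is undefined.
    """
    x = _as_series(x)
    r = _default_r(x, r)
    if x.size < 100 * max(scales):
        return np.nan
    vals = [sampen(_coarse_grain(x, s), m=m, r=r) for s in scales]
    if any(np.isnan(v) for v in vals):
        return np.nan
    return float(np.mean(vals))
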
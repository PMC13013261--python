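"""Joint symbolic dynamics (JSD) of pulse-interval and systolic-pressure series.

Beat-to-beat changes of RR interval and SAP are reduced to binary symbols
(1 = increase, 0 = decrease or tie; threshold l = 0), overlapping 3-symbol
words are formed on each series, and the joint distribution of the 64
possible (RR word, SAP word) pairs is compiled into the 8x8 relative-
frequency matrix W. Baroreflex-like (concordant) behaviour concentrates mass
on the main diagonal, summarized as JSD_sym; patterns opposing baroreflex
behaviour sit on the antidiagonal, summarized as JSD_diam. Symbols depend
only on difference signs, so the whole pipeline is invariant under positive
affine transforms of the underlying series.

Model-style entry point: ``JointSymbolicDynamics(rr, sap).fit()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import BeatSeries, InsufficientDataError

__all__ = [
    "SymbolSequence",
    "WordMatrix",
    "JSDIndices",
    "symbolize",
    "build_word_matrix",
    "jsd_indices",
    "JointSymbolicDynamics",
    "JSDResults",
]

WORD_LEN = 3
N_WORDS = 2**WORD_LEN  # 8 per series -> 64 joint word types


@dataclass
class SymbolSequence:
    symbols: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=int)
        if self.symbols.size and not np.isin(self.symbols, (0, 1)).all():
            raise ValueError("symbols must be binary")

    @property
    def n(self) -> int:
        return self.symbols.size


@dataclass
class WordMatrix:
    """8x8 relative-frequency matrix; rows = RR words, cols = SAP words.

    Word index encodes the three symbols MSB-first in time (earliest symbol is
    the most significant bit), so index 7 = three consecutive increases.
    """

    w: np.ndarray
    n_words: int

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (N_WORDS, N_WORDS):
            raise ValueError(f"word matrix must be {N_WORDS}x{N_WORDS}")
        if self.n_words > 0 and abs(self.w.sum() - 1.0) > 1e-9:
            raise ValueError("relative frequencies must sum to 1")

    def to_long(self) -> pd.DataFrame:
        rr_idx, sap_idx = np.meshgrid(np.arange(N_WORDS), np.arange(N_WORDS), indexing="ij")
        return pd.DataFrame(
            {
                "rr_word": rr_idx.ravel(),
                "sap_word": sap_idx.ravel(),
                "freq": self.w.ravel(),
            }
        )


@dataclass
class JSDIndices:
    jsd_sym: float
    jsd_diam: float


def symbolize(x: BeatSeries | np.ndarray, l: float = 0.0) -> SymbolSequence:
    """Binary symbolization of successive changes: 1 iff ``x_n - x_{n+1} < l``.

    With the default threshold l = 0 a symbol is 1 on a strict increase and 0
    on a decrease or tie. The output has length n - 1.
    """
    v = x.values if isinstance(x, BeatSeries) else np.asarray(x, dtype=float)
    label = x.label if isinstance(x, BeatSeries) else ""
    if v.size < 2:
        raise InsufficientDataError("need >= 2 values to symbolize")
    if not np.all(np.isfinite(v)):
        raise ValueError("symbolize requires finite values")
    return SymbolSequence((v[:-1] - v[1:] < l).astype(int), source_label=label)


def _words(s: np.ndarray, word_len: int) -> np.ndarray:
    """Overlapping MSB-first word codes (stride 1)."""
    weights = 2 ** np.arange(word_len - 1, -1, -1)
    win = np.lib.stride_tricks.sliding_window_view(s, word_len)
    return win @ weights


def build_word_matrix(
    s_rr: SymbolSequence,
    s_sap: SymbolSequence,
    word_len: int = WORD_LEN,
    lag: int = 0,
) -> WordMatrix:
    """Compile the joint word distribution of two symbol sequences.

    Overlapping words of ``word_len`` symbols are formed on each series; the
    RR word starting at symbol ``n`` is paired with the SAP word starting at
    ``n + lag`` (default lag 0; with RR intervals anchored at the beat ending
    them this realizes "a pressure change drives the subsequent interval").
    Counts are normalized to relative frequencies.
    """
    a, b = s_rr.symbols, s_sap.symbols
    if a.size != b.size:
        raise ValueError("symbol sequences must have equal length")
    if a.size < word_len + abs(lag):
        raise InsufficientDataError(
            f"need >= {word_len + abs(lag)} symbols, got {a.size}"
        )
    rr_words = _words(a, word_len)
    sap_words = _words(b, word_len)
    if lag > 0:
        rr_words, sap_words = rr_words[:-lag], sap_words[lag:]
    elif lag < 0:
        rr_words, sap_words = rr_words[-lag:], sap_words[:lag]
    n_side = 2**word_len
    counts = np.zeros((n_side, n_side))
    np.add.at(counts, (rr_words, sap_words), 1)
    n_words = rr_words.size
    return WordMatrix(counts / n_words, n_words=int(n_words))


def jsd_indices(w: WordMatrix) -> JSDIndices:
    """Diagonal (baroreflex-like) and antidiagonal (opposed) word frequencies."""
    return JSDIndices(
        jsd_sym=float(np.trace(w.w)),
        jsd_diam=float(np.trace(np.fliplr(w.w))),
    )


class JointSymbolicDynamics:
    """JSD coupling model over paired pulse-interval and SAP beat series."""

    def __init__(self, rr: BeatSeries, sap: BeatSeries, lag: int = 0):
        if rr.n != sap.n:
            raise ValueError("rr and sap must have the same number of beats")
        self.rr = rr
        self.sap = sap
        self.lag = lag

    def fit(self) -> "JSDResults":
        s_rr = symbolize(self.rr)
        s_sap = symbolize(self.sap)
        w = build_word_matrix(s_rr, s_sap, lag=self.lag)
        return JSDResults(w, jsd_indices(w))


class JSDResults:
    def __init__(self, word_matrix: WordMatrix, indices: JSDIndices):
        self.word_matrix = word_matrix
        self.indices = indices

    @property
    def jsd_sym(self) -> float:
        return self.indices.jsd_sym

    @property
    def jsd_diam(self) -> float:
        return self.indices.jsd_diam

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "jsd_sym": self.jsd_sym,
                    "jsd_diam": self.jsd_diam,
                    "n_words": self.word_matrix.n_words,
                }
            ]
        )

    def plot(self, ax=None):
        """Heatmap of the word matrix, diagonal/antidiagonal highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(self.word_matrix.w, cmap="viridis", origin="lower")
        ax.set_xlabel("SAP word")
        ax.set_ylabel("R-R word")
        ax.figure.colorbar(im, ax=ax, label="relative frequency")
        return ax
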
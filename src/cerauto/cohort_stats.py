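"""Cohort-level statistics for repeated paced-breathing conditions.

Nonparametric repeated-measures layer: Friedman ANOVA with Kendall's W
effect size, Bonferroni-corrected Wilcoxon signed-rank post-hocs, Spearman
correlation matrices between autonomic and autoregulation metrics, and a
linear mixed-effects interface (random participant intercept; respiratory
rate, EtCO2 and one autonomic metric at a time as fixed effects, estimated
by statsmodels' restricted-likelihood machinery).

Repeated tables are pandas DataFrames with participants as rows and
conditions (e.g. 6/10/15 breaths/min) as columns; participants missing any
condition are dropped listwise for the rank tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

__all__ = [
    "friedman_test",
    "kendalls_w",
    "wilcoxon_posthoc",
    "spearman_matrix",
    "LMMSpec",
    "fit_lmm",
]


class FriedmanResult(NamedTuple):
    chi2: float
    p: float
    n: int
    k: int


def _complete_cases(table: pd.DataFrame) -> np.ndarray:
    data = np.asarray(table, dtype=float)
    return data[np.all(np.isfinite(data), axis=1)]


def friedman_test(table: pd.DataFrame) -> FriedmanResult:
    """Friedman rank ANOVA with average-rank tie handling.

    All-tied data yield ``chi2 = 0, p = 1`` instead of a degenerate division.
    """
    data = _complete_cases(table)
    n, k = data.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 complete participants and >= 2 conditions, got {n}x{k}")
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # tie correction: C = 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_term = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        tie_term += np.sum(counts**3 - counts)
    c = 1.0 - tie_term / (n * k * (k**2 - 1))
    if c <= 0:
        return FriedmanResult(0.0, 1.0, n, k)
    chi2 /= c
    return FriedmanResult(float(chi2), float(stats.chi2.sf(chi2, k - 1)), n, k)


def kendalls_w(table: pd.DataFrame) -> float:
    """Kendall's W concordance effect size: ``chi2 / (n * (k - 1))``, in [0, 1]."""
    res = friedman_test(table)
    return float(np.clip(res.chi2 / (res.n * (res.k - 1)), 0.0, 1.0))


def wilcoxon_posthoc(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank tests with a Bonferroni threshold.

    All ``m`` condition pairs are tested; significance is declared at
    ``p < alpha / m`` (for the three paced rates, 0.05 / 3 < 0.017). Zero
    differences are dropped (Wilcoxon convention); the exact null distribution
    is used for up to 25 non-zero pairs, the continuity-corrected normal
    approximation above.
    """
    cols = list(table.columns)
    pairs = list(combinations(cols, 2))
    threshold = alpha / len(pairs)
    rows = []
    for a, b in pairs:
        sub = table[[a, b]].dropna()
        diff = sub[a].to_numpy(dtype=float) - sub[b].to_numpy(dtype=float)
        nz = diff[diff != 0]
        if nz.size == 0:
            p = 1.0
        else:
            method = "exact" if nz.size <= 25 else "approx"
            p = float(
                stats.wilcoxon(
                    nz, zero_method="wilcox", correction=True, method=method
                ).pvalue
            )
        rows.append(
            {
                "pair": f"{a} vs {b}",
                "n_pairs": int(sub.shape[0]),
                "n_nonzero": int(nz.size),
                "p": p,
                "threshold": threshold,
                "significant": p < threshold,
            }
        )
    return pd.DataFrame(rows)


def spearman_matrix(ans: pd.DataFrame, ca: pd.DataFrame):
    """Spearman rank correlations between autonomic and autoregulation metrics.

    Pairwise-complete handling per cell; a constant column yields NaN.
    Returns ``(r, p)`` DataFrames shaped (ANS metrics x CA metrics).
    """
    r = pd.DataFrame(index=ans.columns, columns=ca.columns, dtype=float)
    p = pd.DataFrame(index=ans.columns, columns=ca.columns, dtype=float)
    for ac in ans.columns:
        for cc in ca.columns:
            sub = pd.concat([ans[ac], ca[cc]], axis=1).dropna()
            if sub.shape[0] < 10:
                r.loc[ac, cc] = np.nan
                p.loc[ac, cc] = np.nan
                continue
            x, y = sub.iloc[:, 0], sub.iloc[:, 1]
            if x.nunique() < 2 or y.nunique() < 2:
                r.loc[ac, cc] = np.nan
                p.loc[ac, cc] = np.nan
                continue
            res = stats.spearmanr(x, y)
            r.loc[ac, cc] = res.statistic
            p.loc[ac, cc] = res.pvalue
    return r, p


@dataclass
class LMMSpec:
    """One mixed-model fit: a CA response, one ANS metric, respiratory covariates."""

    response: str
    ans_metric: str
    covariates: Sequence[str] = ("resp_rate", "etco2")
    group: str = "participant"


def fit_lmm(data: pd.DataFrame, spec: LMMSpec) -> pd.DataFrame:
    """Random-intercept mixed model for one CA metric and one ANS metric.

    ``response ~ ans_metric + covariates`` with a participant random
    intercept, fitted by REML via statsmodels MixedLM. Per fixed effect a Wald
    F (the squared z statistic, 1 numerator df) and its p-value are reported;
    a singular/non-converged fit is flagged but still returned.
    """
    fixed = [spec.ans_metric, *spec.covariates]
    cols = [spec.response, *fixed, spec.group]
    sub = data[cols].dropna()
    counts = sub.groupby(spec.group).size()
    if (counts < 2).any() or counts.size < 2:
        raise ValueError("need >= 2 observations per participant and >= 2 participants")
    formula = f"{spec.response} ~ " + " + ".join(fixed)
    flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, sub, groups=sub[spec.group])
        fit = model.fit(reml=True)
        flagged = any("converge" in str(w.message).lower() or "singular" in str(w.message).lower()
                      for w in caught)
    rows = []
    for term in fixed:
        coef = fit.params[term]
        se = fit.bse[term]
        if se > 0 and np.isfinite(se):
            z = coef / se
            f_stat = z**2
            p = float(stats.chi2.sf(f_stat, 1))
        else:
            f_stat, p = np.nan, np.nan
            flagged = True
        rows.append(
            {
                "term": term,
                "estimate": float(coef),
                "se": float(se),
                "F": float(f_stat),
                "p": p,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)
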
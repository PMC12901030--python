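"""Shared inferential utilities: FDR control and paired t tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    p: float
    df: int
    corrected_p: np.ndarray | None = None
    mask: np.ndarray | None = None


def fdr_correct(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR correction.

    Returns (adjusted p-values, rejection mask at level ``q``); empty
    input yields empty output.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    shape = p.shape
    reject, p_adj, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return p_adj.reshape(shape), reject.reshape(shape)


def paired_t(a, b, alternative: str = "two-sided") -> TestResult:
    """Classical paired t test of ``a - b`` against zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("a and b must have equal length >= 2")
    d = a - b
    if np.all(d == 0):
        # identical inputs: no evidence either way
        p = 1.0 if alternative == "two-sided" else 0.5
        return TestResult(statistic=0.0, p=p, df=int(a.size - 1))
    if d.std(ddof=1) == 0.0:
        raise ValueError("zero variance of paired differences")
    res = sps.ttest_rel(a, b, alternative=alternative)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      df=int(a.size - 1))
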
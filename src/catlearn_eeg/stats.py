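"""Small statistical helpers shared by the behavioral, ERP, and decoding stages.

These wrap the classical closed forms with explicit handling of the
degenerate zero-variance cases, which scipy reports as NaN: a zero-variance
paired difference with nonzero mean is reported as an infinite t (p = 0) with
a warning, and identical samples give t = 0, p = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    n: int


def _t_from_diffs(diffs: np.ndarray) -> TTestResult:
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    if n < 2:
        raise ValueError("t-test requires at least 2 observations")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0, mean_diff=0.0, n=n)
        warnings.warn("zero-variance differences with nonzero mean: reporting "
                      "infinite t", RuntimeWarning, stacklevel=3)
        return TTestResult(t=float(np.sign(mean)) * np.inf, df=df, p=0.0,
                           mean_diff=mean, n=n)
    t = mean / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p=p, mean_diff=mean, n=n)


def paired_t(x, y) -> TTestResult:
    """Two-sided paired-samples t-test of ``x − y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired_t requires equal-length samples")
    return _t_from_diffs(x - y)


def one_sample_t(x, popmean: float) -> TTestResult:
    """Two-sided one-sample t-test of ``x`` against ``popmean``."""
    return _t_from_diffs(np.asarray(x, dtype=float) - popmean)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p.

    Returns ``(nan, nan)`` when either input has zero variance (the
    correlation is undefined, not zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson_r requires two equal-length 1-D samples")
    if len(x) < 3 or x.std() == 0.0 or y.std() == 0.0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def binomial_test(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value for ``k`` successes out of ``n``."""
    return float(sps.binomtest(k, n, p0).pvalue)
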
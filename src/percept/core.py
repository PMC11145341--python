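"""The PERCEPT transform.

PERCEPT (P-value Enhanced Rescaling for Comprehensive Exploration and
Preservation of Trends) replaces binary p-value thresholding with a
continuous shrinkage of each measured effect toward a hypothetical mean.
Given a replicate mean ``m1``, a hypothetical mean ``m0``, a p-value ``p``
from a test of the replicates against ``m0`` and a penalty factor ``F``,
the scaled value is

    V = m0 + (m1 - m0) * F**(-p)

A confident measurement (p near 0) is preserved almost exactly; a noisy,
low-confidence one (p near 1) is pulled toward ``m0`` by a factor of up
to ``1/F``.  ``F = 10 * n`` (n = replicate count) is the recommended
starting point for tuning.

All functions in this module are pure and perform no I/O.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PerceptOutcome",
    "ScalingConfig",
    "percept_scale",
    "scaling_factor",
    "one_sample_t_pvalue",
    "percept_from_replicates",
    "default_penalty",
]

_ALTERNATIVES = ("two-sided", "less", "greater")


@dataclass(frozen=True)
class ScalingConfig:
    """Parameters of the transform.

    Parameters
    ----------
    m0
        Hypothetical mean the replicates are tested against, in the same
        units as the measurements (0 for log2 ratios, 1 for raw ratios).
    F
        Penalty factor (> 0).  Values <= 1 invert the intent of the
        method (the scaling factor becomes >= 1) and trigger a warning.
    alternative
        Sidedness of the t-test: "two-sided" (default), "less", "greater".
    """

    m0: float = 0.0
    F: float = 20.0
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if not np.isfinite(self.m0):
            raise ValueError("m0 must be finite")
        _check_penalty(self.F)
        if self.alternative not in _ALTERNATIVES:
            raise ValueError(f"alternative must be one of {_ALTERNATIVES}")


@dataclass(frozen=True)
class PerceptOutcome:
    """Per-feature result: replicate count and mean, p-value, scaling
    factor ``s = F**(-p)`` and scaled value ``V``."""

    feature_id: str
    n: int
    m1: float
    p: float
    s: float
    V: float


def _check_penalty(F: float) -> None:
    F = float(F)
    if not np.isfinite(F) or F <= 0:
        raise ValueError(f"penalty factor F must be positive and finite, got {F}")
    if F <= 1:
        warnings.warn(
            f"F = {F} <= 1 gives a scaling factor >= 1, amplifying rather "
            "than suppressing low-confidence effects",
            UserWarning,
            stacklevel=3,
        )


def _check_p(p):
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def scaling_factor(p, F: float):
    """Scaling factor ``F**(-p)``, in (0, 1] for F >= 1.

    Strictly decreasing in p for F > 1 and in F for p > 0.  Evaluated as
    exp(-p * ln F) for stability at large F.  Accepts scalar or array p.
    """
    _check_penalty(F)
    p = _check_p(p)
    s = np.exp(-p * np.log(float(F)))
    return float(s) if s.ndim == 0 else s


def percept_scale(m1, m0, p, F: float):
    """Scale a measured mean toward the hypothetical mean.

    Returns ``V = m0 + (m1 - m0) * F**(-p)``.  At p = 0 the measurement
    is preserved exactly (V = m1); at p = 1 it is maximally suppressed
    (V = m0 + (m1 - m0)/F).  Accepts scalars or broadcastable arrays.
    """
    m1 = np.asarray(m1, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if np.any(~np.isfinite(m1)) or np.any(~np.isfinite(m0)):
        raise ValueError("m1 and m0 must be finite")
    s = scaling_factor(p, F)
    V = m0 + (m1 - m0) * s
    # p = 0 preserves the measurement exactly; the algebraic form can lose
    # the tail of m1 to cancellation when |m0| dwarfs |m1|
    V = np.where(np.asarray(s) == 1.0, m1, V)
    return float(V) if np.ndim(V) == 0 else V


def one_sample_t_pvalue(values, m0: float, alternative: str = "two-sided") -> float:
    """p-value of a one-sample t-test of ``values`` against ``m0``.

    Missing values are dropped first; at least two finite values are
    required.  The sample standard deviation uses the n-1 denominator.
    Degenerate (zero-variance) samples follow a continuity convention:
    p = 0 when the common value differs from m0 (an infinitely confident
    deviation, scaling factor 1) and p = 1 when it equals m0.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    n = v.size
    if n < 2:
        raise ValueError(f"need at least 2 finite replicate values, got {n}")
    if not np.isfinite(m0):
        raise ValueError("m0 must be finite")
    mean = v.mean()
    sd = v.std(ddof=1)
    if sd == 0.0:
        if alternative == "two-sided":
            return 0.0 if mean != m0 else 1.0
        # one-sided: deviation in the tested direction -> 0, else 1
        if mean == m0:
            return 1.0
        hit = mean < m0 if alternative == "less" else mean > m0
        return 0.0 if hit else 1.0
    res = stats.ttest_1samp(v, popmean=m0, alternative=alternative)
    return float(res.pvalue)


def percept_from_replicates(
    values, config: ScalingConfig, feature_id: str = ""
) -> PerceptOutcome:
    """Apply the full transform to one replicate vector.

    Composes :func:`one_sample_t_pvalue` against ``config.m0`` with
    :func:`percept_scale` and records all intermediate quantities.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    p = one_sample_t_pvalue(v, config.m0, config.alternative)
    m1 = float(v.mean())
    s = scaling_factor(p, config.F)
    V = percept_scale(m1, config.m0, p, config.F)
    return PerceptOutcome(feature_id=feature_id, n=int(v.size), m1=m1, p=p, s=s, V=V)


def default_penalty(n: int) -> float:
    """Recommended starting penalty, ``F = 10 * n``.

    A suggestion only; any F > 0 may be supplied instead.
    """
    n = int(n)
    if n < 2:
        raise ValueError("n must be at least 2")
    return 10.0 * n


def t_statistics_matrix(matrix, m0, alternative: str = "two-sided"):
    """Row-wise one-sample t-test for a features x replicates matrix.

    NaN-aware workhorse shared by the cohort and imaging layers.  ``m0``
    may be a scalar or a per-row array.  Returns ``(n, mean, p)`` arrays;
    rows with fewer than two finite values get NaN mean and p (flagged
    null, never an exception), and zero-variance rows follow the same
    degenerate convention as :func:`one_sample_t_pvalue`.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (features x replicates)")
    m0 = np.broadcast_to(np.asarray(m0, dtype=float), (x.shape[0],))
    finite = np.isfinite(x)
    n = finite.sum(axis=1)
    ok = n >= 2

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # rows with <2 finite values are flagged NaN below, not warned about
        warnings.simplefilter("ignore", RuntimeWarning)
        masked = np.where(finite, x, np.nan)
        mean = np.where(ok, np.nanmean(masked, axis=1), np.nan)
        sd = np.where(ok, np.nanstd(masked, axis=1, ddof=1), np.nan)
        t = (mean - m0) / (sd / np.sqrt(n))

    p = np.full(x.shape[0], np.nan)
    df = n - 1.0
    regular = ok & (sd > 0)
    if alternative == "two-sided":
        p[regular] = 2.0 * stats.t.sf(np.abs(t[regular]), df[regular])
    elif alternative == "greater":
        p[regular] = stats.t.sf(t[regular], df[regular])
    else:
        p[regular] = stats.t.cdf(t[regular], df[regular])

    degen = ok & (sd == 0)
    if np.any(degen):
        same = mean == m0
        if alternative == "two-sided":
            p[degen] = np.where(same[degen], 1.0, 0.0)
        else:
            hit = mean < m0 if alternative == "less" else mean > m0
            p[degen] = np.where(same[degen], 1.0, np.where(hit[degen], 0.0, 1.0))
    np.clip(p, 0.0, 1.0, out=p)
    return n.astype(int), mean, p
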
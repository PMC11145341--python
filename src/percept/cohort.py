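"""Cohort-level operations on feature x donor abundance tables.

The workflow mirrors a case/control omics study: raw per-donor intensities
are converted to log2 abundance ratios against the control-cohort mean,
data-driven effect-size thresholds are derived from a pseudo-control
distribution, features are placed into volcano-plot categories, and the
PERCEPT transform is applied per feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import core

__all__ = [
    "FeatureTable",
    "EffectThresholds",
    "CATEGORIES",
    "abundance_ratios",
    "pseudo_control_thresholds",
    "categorize",
    "scale_table",
    "normalize_symmetric",
]

VALUE_SPACES = ("intensity", "ratio", "log2_ratio")
CONTROL, CASE = "control", "case"
CATEGORIES = ("S/A", "NS/A", "NS/NA", "S/NA")


@dataclass
class FeatureTable:
    """Features x samples matrix with cohort labels.

    ``data`` is a pandas DataFrame indexed by unique feature identifiers
    with one column per sample.  ``groups`` labels each sample "control"
    or "case"; it may be omitted for tables that are already case-only
    ratios.  ``value_space`` declares what the numbers are: raw positive
    "intensity", linear "ratio", or "log2_ratio".
    """

    data: pd.DataFrame
    groups: pd.Series | None = None
    value_space: str = "intensity"

    def __post_init__(self) -> None:
        if self.data.empty:
            raise ValueError("feature table is empty")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if self.value_space not in VALUE_SPACES:
            raise ValueError(f"value_space must be one of {VALUE_SPACES}")
        self.data = self.data.astype(float)
        if self.groups is not None:
            if isinstance(self.groups, Mapping):
                self.groups = pd.Series(self.groups)
            missing = self.data.columns.difference(self.groups.index)
            if len(missing):
                raise ValueError(f"samples without group label: {list(missing)[:5]}")
            self.groups = self.groups.reindex(self.data.columns)
            bad = set(self.groups.unique()) - {CONTROL, CASE}
            if bad:
                raise ValueError(f"group labels must be 'control'/'case', got {bad}")
        if self.value_space == "intensity":
            vals = self.data.to_numpy()
            if np.any(vals[np.isfinite(vals)] <= 0):
                raise ValueError("intensity-space values must be strictly positive")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def samples_in(self, group: str) -> list[str]:
        if self.groups is None:
            raise ValueError("table has no group labels")
        return list(self.groups.index[self.groups == group])

    def subset_samples(self, samples: Iterable[str]) -> "FeatureTable":
        samples = list(samples)
        groups = self.groups.loc[samples] if self.groups is not None else None
        return replace(self, data=self.data[samples], groups=groups)


@dataclass(frozen=True)
class EffectThresholds:
    """Lower/upper log2 effect bounds plus a significance level.

    Together these define volcano-plot quadrants: a feature is "affected"
    when its effect falls strictly outside (lower, upper) and
    "significant" when p < alpha.
    """

    lower: float
    upper: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("thresholds must be finite")
        if self.lower > self.upper:
            raise ValueError("lower threshold must not exceed upper")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def abundance_ratios(table: FeatureTable) -> FeatureTable:
    """Per-donor log2 abundance ratios against the control-cohort mean.

    For each feature and case donor the ratio is the donor's intensity
    divided by the mean intensity of that feature across control donors,
    returned in log2 space for the case samples only.  Features whose
    control mean is unusable (all missing or non-positive) come back as
    all-NaN rows rather than raising, so whole-table runs never abort.
    """
    if table.value_space != "intensity":
        raise ValueError("abundance_ratios expects an intensity-space table")
    controls = table.samples_in(CONTROL)
    cases = table.samples_in(CASE)
    if not controls or not cases:
        raise ValueError("need at least one control and one case sample")
    ctrl_mean = table.data[controls].mean(axis=1, skipna=True)
    ctrl_mean = ctrl_mean.where(ctrl_mean > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.log2(table.data[cases].div(ctrl_mean, axis=0))
    groups = pd.Series(CASE, index=ratios.columns)
    return FeatureTable(data=ratios, groups=groups, value_space="log2_ratio")


def pseudo_control_ratios(control_table: FeatureTable, seed: int) -> np.ndarray:
    """Pooled pseudo-control log2 ratios from a control-only cohort.

    The control cohort is compared against a label-randomized version of
    itself: per feature, donor labels are permuted (seeded) and each
    donor's value is divided by the mean of the permuted cohort for that
    feature.  The pooled log2 ratios capture the cohort's inherent
    experimental variability under the null of no effect.
    """
    if control_table.groups is not None:
        cols = control_table.samples_in(CONTROL)
        if len(cols) < 2:
            raise ValueError("need at least 2 control samples")
        data = control_table.data[cols]
    else:
        data = control_table.data
    if data.shape[1] < 2:
        raise ValueError("need at least 2 control samples")
    if control_table.value_space != "intensity":
        raise ValueError("pseudo-control ratios require an intensity-space table")

    rng = np.random.default_rng(seed)
    x = data.to_numpy()
    permuted = np.empty_like(x)
    for i in range(x.shape[0]):  # independent donor-label permutation per feature
        permuted[i] = x[i, rng.permutation(x.shape[1])]
    with np.errstate(invalid="ignore", divide="ignore"):
        perm_mean = np.nanmean(permuted, axis=1)
        perm_mean = np.where(perm_mean > 0, perm_mean, np.nan)
        ratios = np.log2(x / perm_mean[:, None])
    return ratios[np.isfinite(ratios)]


def pseudo_control_thresholds(
    control_table: FeatureTable,
    coverage: float = 0.90,
    seed: int = 0,
    alpha: float = 0.05,
) -> EffectThresholds:
    """Data-driven effect thresholds bracketing the pseudo-control bulk.

    Returns the (1-coverage)/2 and 1-(1-coverage)/2 quantiles (5th/95th
    percentiles at the default 90% coverage) of the pooled pseudo-control
    log2-ratio distribution, computed with linear interpolation between
    order statistics.  The bounds are not forced to be symmetric.
    """
    if not 0 < coverage < 1:
        raise ValueError("coverage must lie in (0, 1)")
    pooled = pseudo_control_ratios(control_table, seed=seed)
    if pooled.size == 0:
        raise ValueError("no finite pseudo-control ratios")
    tail = (1.0 - coverage) / 2.0
    lower, upper = np.quantile(pooled, [tail, 1.0 - tail])
    return EffectThresholds(lower=float(lower), upper=float(upper), alpha=alpha)


def categorize(effect: float, p: float, thresholds: EffectThresholds) -> str:
    """Volcano category of one feature.

    "Affected" means the effect lies strictly outside (lower, upper);
    "significant" means p < alpha (i.e. -log10 p > 1.3 at alpha = 0.05).
    The four crosses S/A, NS/A, S/NA, NS/NA partition the plane; features
    with an undefined effect or p-value return "NA".
    """
    if not np.isfinite(effect) or not np.isfinite(p):
        return "NA"
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    affected = effect > thresholds.upper or effect < thresholds.lower
    significant = p < thresholds.alpha
    return ("S" if significant else "NS") + "/" + ("A" if affected else "NA")


def scale_table(
    table: FeatureTable,
    m0: float = 0.0,
    F: float | None = 20.0,
    alternative: str = "two-sided",
    thresholds: EffectThresholds | None = None,
) -> pd.DataFrame:
    """Apply PERCEPT feature-wise to a log2-ratio table.

    Per feature: drop missing donors, one-sample t-test of the remaining
    replicates against ``m0``, then scale the replicate mean by F**(-p).
    ``F=None`` resolves the recommended 10*n penalty per feature.  Rows
    left with fewer than two donors yield NaN outcomes (flagged nulls).

    Returns a DataFrame indexed by feature id with columns
    ``n, m1, p, s, V`` (plus ``category`` when thresholds are given),
    in the input feature order.
    """
    if table.value_space != "log2_ratio":
        raise ValueError("scale_table expects a log2_ratio table")
    x = table.data.to_numpy()
    n, m1, p = core.t_statistics_matrix(x, m0, alternative=alternative)
    if F is None:
        fvals = 10.0 * np.maximum(n, 2)  # per-feature 10*n default
        with np.errstate(invalid="ignore"):
            s = np.exp(-p * np.log(fvals))
    else:
        valid = ~np.isnan(p)
        s = np.full_like(p, np.nan)
        s[valid] = core.scaling_factor(p[valid], F)
    V = m0 + (m1 - m0) * s
    out = pd.DataFrame(
        {"n": n, "m1": m1, "p": p, "s": s, "V": V}, index=table.feature_ids
    )
    out.index.name = "feature_id"
    if thresholds is not None:
        out["category"] = [
            categorize(e, pv, thresholds) if np.isfinite(e) and np.isfinite(pv) else "NA"
            for e, pv in zip(out["m1"], out["p"])
        ]
    return out


def normalize_symmetric(table: FeatureTable) -> FeatureTable:
    """Divide every value by the table-wide maximum absolute value.

    Rescales a log2-ratio table symmetrically into [-1, 1] without moving
    the center of 0, so differently-scaled studies can be compiled.
    """
    if table.value_space != "log2_ratio":
        raise ValueError("normalize_symmetric expects a log2_ratio table")
    vals = table.data.to_numpy()
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("table has no finite values")
    max_abs = np.abs(finite).max()
    if max_abs == 0:
        return replace(table, data=table.data.copy())
    return replace(table, data=table.data / max_abs)
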
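"""Seeded generators for synthetic cohorts and ground-truth images.

These produce every input the rest of the package needs with known ground
truth, so the full pipeline — ratios, thresholds, scaling, subsampling
evaluation, image demonstration — runs end-to-end with no downloads.

The cohort generator emulates a case/control proteomics study: per-feature
log-normal baseline intensities spanning a realistic dynamic range,
per-donor multiplicative (log2-normal) measurement noise, and a minority
of truly affected features carrying a fixed-magnitude log2 effect with
random sign in the case cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CASE, CONTROL, FeatureTable

__all__ = ["CohortSpec", "generate_cohort", "generate_ground_truth_image"]

PATTERNS = ("blocks", "stripes", "checker")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic case/control cohort.

    Defaults describe a mid-sized study: 500 features across 20 control
    and 40 case donors, 30% of features truly affected with a |log2
    fold-change| of 0.5 (random sign), per-donor log2 noise of sd 0.6,
    and log-normal baselines spanning several orders of magnitude as in
    label-free proteomics intensity data.
    """

    n_features: int = 500
    n_control: int = 20
    n_case: int = 40
    affected_fraction: float = 0.3
    effect_log2: float = 0.5
    noise_sd_log2: float = 0.6
    baseline_log_mean: float = 14.0  # natural-log scale, exp(14) ~ 1.2e6
    baseline_log_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("need at least 2 donors per cohort")
        if not 0 <= self.affected_fraction <= 1:
            raise ValueError("affected_fraction must lie in [0, 1]")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be non-negative")


def generate_cohort(
    spec: CohortSpec, effects: np.ndarray | None = None
) -> tuple[FeatureTable, pd.DataFrame]:
    """Synthetic intensity table plus its ground-truth sidecar.

    Intensities are ``baseline * 2**(effect * case_indicator + noise)``
    with ``baseline ~ LogNormal`` and ``noise ~ N(0, noise_sd_log2)``,
    fully determined by the spec's seed.  The truth table lists each
    feature's affected flag and true (signed) log2 effect.

    ``effects`` optionally fixes the per-feature true log2 effects (e.g.
    to simulate two studies sharing one ground truth with independent
    noise); by default they are drawn from the spec.
    """
    rng = np.random.default_rng(spec.seed)
    nf, nc, nd = spec.n_features, spec.n_control, spec.n_case

    baseline = np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, nf))
    n_affected = int(round(spec.affected_fraction * nf))
    affected_idx = rng.choice(nf, size=n_affected, replace=False)
    signs = rng.choice([-1.0, 1.0], size=nf)
    if effects is None:
        affected = np.zeros(nf, dtype=bool)
        affected[affected_idx] = True
        effects = np.where(affected, signs * spec.effect_log2, 0.0)
    else:
        effects = np.asarray(effects, dtype=float)
        if effects.shape != (nf,):
            raise ValueError("effects must have one entry per feature")
        affected = effects != 0.0

    case_ind = np.concatenate([np.zeros(nc), np.ones(nd)])
    noise = rng.normal(0.0, 1.0, size=(nf, nc + nd)) * spec.noise_sd_log2
    log2_values = (
        np.log2(baseline)[:, None] + effects[:, None] * case_ind[None, :] + noise
    )
    values = np.exp2(log2_values)

    feature_ids = [f"F{i + 1:04d}" for i in range(nf)]
    sample_ids = [f"ctrl_{i + 1:02d}" for i in range(nc)] + [
        f"case_{i + 1:02d}" for i in range(nd)
    ]
    groups = pd.Series([CONTROL] * nc + [CASE] * nd, index=sample_ids)
    table = FeatureTable(
        data=pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                          columns=sample_ids),
        groups=groups,
        value_space="intensity",
    )
    truth = pd.DataFrame(
        {"affected": affected, "true_log2_effect": effects},
        index=table.feature_ids,
    )
    return table, truth


def generate_ground_truth_image(
    height: int,
    width: int,
    pattern: str = "blocks",
    seed: int = 0,
    block_size: int | None = None,
    period: int = 4,
) -> np.ndarray:
    """Binary (0/1) reference image.

    Patterns: "checker" (alternating cells of ``block_size``, default 1,
    a per-pixel checkerboard), "stripes" (vertical bands of ``period``
    columns), and "blocks" (random binary tiles of ``block_size``,
    default 8, seeded).
    """
    if height < 1 or width < 1:
        raise ValueError("image dimensions must be positive")
    if pattern not in PATTERNS:
        raise ValueError(f"pattern must be one of {PATTERNS}")
    if block_size is None:
        block_size = 1 if pattern == "checker" else 8
    if block_size < 1 or period < 1:
        raise ValueError("block_size and period must be positive")
    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]
    if pattern == "checker":
        img = (rows // block_size + cols // block_size) % 2
    elif pattern == "stripes":
        img = np.broadcast_to((cols // period) % 2, (height, width)).copy()
    else:
        rng = np.random.default_rng(seed)
        tiles = rng.integers(
            0, 2, size=(-(-height // block_size), -(-width // block_size))
        )
        img = np.kron(tiles, np.ones((block_size, block_size), dtype=int))
        img = img[:height, :width]
    return img.astype(float)
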
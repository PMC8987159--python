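"""Group-level inference on encoding-performance maps.

Per-sample PCC maps are z-scored across voxels, aggregated, and tested
voxel-wise with a one-sample t-test against zero (one-sided: encoding
accuracy above chance). t-values are converted to standard-normal Z by
probability matching, Z = Phi^{-1}(t CDF), the usual neuroimaging
convention, and thresholded conjunctively at p < 0.01 and Z >= 2.3.
Paired comparisons (unsupervised vs supervised features) apply the same
machinery to per-voxel map differences. No multiple-comparison
correction is applied; surviving-voxel counts make that explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Z ceiling for infinite / overflowing t-values (zero-variance voxels).
Z_CEILING = 37.0

DEFAULT_Z_MIN = 2.3
DEFAULT_P_MAX = 0.01


@dataclass
class GroupZMap:
    """Voxel-wise group statistics for one feature layer."""

    t: np.ndarray
    p: np.ndarray  # one-sided, H1: mean > 0
    z: np.ndarray
    df: int
    capped: np.ndarray  # voxels whose Z hit the ceiling (degenerate variance)
    z_min: float = DEFAULT_Z_MIN
    p_max: float = DEFAULT_P_MAX

    @property
    def mask(self) -> np.ndarray:
        """Suprathreshold voxels at the stored conjunctive criterion."""
        return threshold_map(self, self.z_min, self.p_max)[0]


def normalize_map(values: np.ndarray) -> np.ndarray:
    """Z-score one performance map across its non-missing (non-NaN) voxels."""
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing voxels to normalize a map")
    mu = values[ok].mean()
    sd = values[ok].std()
    if sd == 0:
        raise ValueError("constant performance map cannot be normalized")
    out = np.full_like(values, np.nan)
    out[ok] = (values[ok] - mu) / sd
    return out


def _t_to_z(t: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-sided p and probability-matched Z, with a documented ceiling."""
    p = stats.t.sf(t, df)
    with np.errstate(over="ignore"):
        z = stats.norm.isf(p)
    capped = ~np.isfinite(z) | (np.abs(z) > Z_CEILING)
    z = np.clip(np.where(np.isfinite(z), z, np.sign(t) * Z_CEILING), -Z_CEILING, Z_CEILING)
    return p, z, capped


def one_sample_ttest(
    maps: np.ndarray, z_min: float = DEFAULT_Z_MIN, p_max: float = DEFAULT_P_MAX
) -> GroupZMap:
    """Voxel-wise one-sample t-test across maps (rows = samples).

    Missing (NaN) entries are excluded pairwise per voxel; voxels with
    fewer than 2 observations or zero variance get an infinite-t path:
    t = +/-inf by mean sign (0 if the mean is 0) and Z at the ceiling,
    flagged in ``capped``.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 maps")
    n = (~np.isnan(maps)).sum(axis=0)
    if np.any(n < 2):
        raise ValueError("every voxel needs >= 2 non-missing observations")
    mean = np.nanmean(maps, axis=0)
    sd = np.nanstd(maps, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = sd == 0
    t[degenerate & (mean > 0)] = np.inf
    t[degenerate & (mean < 0)] = -np.inf
    t[degenerate & (mean == 0)] = 0.0
    df = int(maps.shape[0] - 1)
    p, z, capped = _t_to_z(np.nan_to_num(t, posinf=1e308, neginf=-1e308), df)
    p[degenerate & (mean > 0)] = 0.0
    p[degenerate & (mean == 0)] = 0.5
    return GroupZMap(
        t=t, p=p, z=z, df=df, capped=capped | degenerate & (mean != 0),
        z_min=z_min, p_max=p_max,
    )


def paired_ttest(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    ids_a=None,
    ids_b=None,
    z_min: float = DEFAULT_Z_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> GroupZMap:
    """Paired comparison a vs b: one-sample t-test on per-voxel differences.

    If sample identifiers are given they must match elementwise, keeping
    the pairing honest.
    """
    maps_a = np.atleast_2d(np.asarray(maps_a, dtype=float))
    maps_b = np.atleast_2d(np.asarray(maps_b, dtype=float))
    if maps_a.shape != maps_b.shape:
        raise ValueError("paired map stacks must have identical shape")
    if ids_a is not None or ids_b is not None:
        if list(ids_a) != list(ids_b):
            raise ValueError("sample identifiers of the two conditions do not match")
    return one_sample_ttest(maps_a - maps_b, z_min=z_min, p_max=p_max)


def threshold_map(
    zmap: GroupZMap, z_min: float = DEFAULT_Z_MIN, p_max: float = DEFAULT_P_MAX
) -> tuple[np.ndarray, int]:
    """Conjunctive threshold: Z >= z_min AND p < p_max.

    Returns (boolean mask, surviving voxel count).
    """
    mask = (zmap.z >= z_min) & (zmap.p < p_max)
    return mask, int(mask.sum())


def enrichment_odds_ratio(
    mask: np.ndarray, positives: np.ndarray, negatives: np.ndarray
) -> float:
    """Haldane-corrected odds ratio of mask membership, positives vs negatives.

    Used to check that voxels simulated as responsive to a layer are
    enriched in that layer's suprathreshold mask relative to null voxels.
    """
    mask = np.asarray(mask, dtype=bool)
    a = mask[positives].sum() + 0.5
    b = (~mask[positives]).sum() + 0.5
    c = mask[negatives].sum() + 0.5
    d = (~mask[negatives]).sum() + 0.5
    return float((a / b) / (c / d))
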
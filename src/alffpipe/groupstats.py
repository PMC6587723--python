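"""Group-level statistics on voxelwise fluctuation maps.

The central statistic is the voxelwise one-sample t value — the group
mean divided by the standard error — interpreted as intersubject
consistency of the (nonnegative) fluctuation measure: a preprocessing
step that reduces variability across subjects relative to the mean
amplitude raises this statistic.  Pipelines are compared through percent
changes of t values relative to the pipeline without nuisance
regression, summarised as means over a grey-matter mask, and through the
within-subject variance of repeated sessions (test–retest variance).

Voxels where a statistic is undefined (zero variance, zero baseline) are
flagged as missing (NaN) rather than infinite; summaries skip them and
report the number of contributing voxels.  Variances use the unbiased
(n-1) estimator throughout.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .spectral import FluctuationMap

logger = logging.getLogger(__name__)

__all__ = [
    "StatMap",
    "one_sample_t",
    "paired_t",
    "percent_change",
    "masked_mean",
    "test_retest_variance",
    "bonferroni_threshold",
]

STATISTICS = ("t_one_sample", "t_paired", "percent_change", "variance")


@dataclasses.dataclass
class StatMap:
    """A voxelwise group statistic; NaN marks missing voxels."""

    values: np.ndarray
    statistic: str
    n_subjects: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("StatMap values must be a 3-D volume")
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")


def _stack(maps: list[FluctuationMap] | list[np.ndarray]) -> np.ndarray:
    arrays = [m.values if isinstance(m, FluctuationMap) else np.asarray(m) for m in maps]
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise ValueError(f"misaligned grids: {a.shape} vs {shape}")
    return np.stack(arrays, axis=0)


def one_sample_t(maps: list[FluctuationMap] | list[np.ndarray]) -> StatMap:
    """Voxelwise group mean divided by the standard error.

    ``t = mean / (sd / sqrt(n))`` with the unbiased sd.  Voxels whose
    across-subject sd is zero (or that are NaN in any subject) are
    flagged missing.
    """
    data = _stack(maps)
    n = data.shape[0]
    if n < 2:
        raise ValueError("one-sample t needs at least 2 subjects")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
    t[~np.isfinite(mean)] = np.nan
    return StatMap(t, "t_one_sample", n)


def paired_t(
    maps_a: list[FluctuationMap] | list[np.ndarray],
    maps_b: list[FluctuationMap] | list[np.ndarray],
) -> StatMap:
    """One-sample t of the per-subject differences ``a - b``."""
    a = _stack(maps_a)
    b = _stack(maps_b)
    if a.shape != b.shape:
        raise ValueError(
            f"conditions have different subject sets or grids: {a.shape} vs {b.shape}"
        )
    out = one_sample_t(list(a - b))
    return StatMap(out.values, "t_paired", out.n_subjects)


def percent_change(t_with: StatMap, t_without: StatMap) -> StatMap:
    """Voxelwise ``100 * (with - without) / without``.

    Voxels with a zero or missing baseline are flagged missing.
    """
    a, b = t_with.values, t_without.values
    if a.shape != b.shape:
        raise ValueError("StatMaps are on different grids")
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(b != 0, 100.0 * (a - b) / np.where(b != 0, b, 1.0), np.nan)
    pct[~np.isfinite(a) | ~np.isfinite(b)] = np.nan
    return StatMap(pct, "percent_change", t_with.n_subjects)


def masked_mean(stat_map: StatMap | np.ndarray, mask: np.ndarray) -> tuple[float, int]:
    """Mean of in-mask, non-missing voxels and the contributing count."""
    values = stat_map.values if isinstance(stat_map, StatMap) else np.asarray(stat_map)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("mask shape does not match map shape")
    if not mask.any():
        raise ValueError("mask is empty")
    inside = values[mask]
    good = np.isfinite(inside)
    if not good.any():
        raise ValueError("no non-missing voxels inside the mask")
    return float(inside[good].mean()), int(good.sum())


def test_retest_variance(
    session_maps: dict[int, list[FluctuationMap] | list[np.ndarray]],
) -> StatMap:
    """Within-subject variance across sessions, averaged over subjects.

    ``session_maps`` maps a subject identifier to that subject's
    per-session fluctuation maps.  Subjects with fewer than two sessions
    are excluded with a logged warning.  Per voxel, the unbiased variance
    across each subject's sessions is computed and then averaged across
    subjects; a lower value indicates better test–retest reliability.
    """
    per_subject = []
    for subject, maps in session_maps.items():
        if len(maps) < 2:
            logger.warning(
                "subject %r has only %d session(s); excluded from "
                "test-retest variance",
                subject,
                len(maps),
            )
            continue
        data = _stack(maps)
        per_subject.append(data.var(axis=0, ddof=1))
    if not per_subject:
        raise ValueError("no subject has at least two sessions")
    avg = np.mean(np.stack(per_subject, axis=0), axis=0)
    return StatMap(avg, "variance", len(per_subject))


def bonferroni_threshold(
    n_voxels: int, alpha: float = 0.05, df: int | None = None
) -> float:
    """Bonferroni-corrected t threshold over ``n_voxels`` tests.

    Simple multiple-comparison plumbing over in-mask voxels.  This is a
    conservative alternative to random-field-theory family-wise error
    thresholds and not equivalent to them.
    """
    from scipy import stats

    if n_voxels < 1:
        raise ValueError("n_voxels must be positive")
    p = alpha / n_voxels
    if df is None:
        return float(stats.norm.isf(p))
    return float(stats.t.isf(p, df))
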
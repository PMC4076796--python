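"""Random-effects group inference and its behavior under heterogeneity.

Group-level fMRI inference usually reduces each subject to a per-voxel
summary value and tests those across subjects with a one-sample t-test
("random effects").  Three demonstrations live here:

* :func:`heterogeneity_grid` — a single-location simulation of a 20-subject
  group that mixes *responders* (values from a shifted normal) with
  *non-responders* (null normal), sweeping group composition and effect
  size.  High significance can be reached when only half the group carries
  the effect.
* :func:`overlap_map` / :func:`subject_count_map` — the conjunction view:
  group maps converge on the voxels active in *all* subjects, so the
  effective overlap erodes as subjects are added, while the per-voxel
  subject count reports how frequently an effect is actually found in
  individual brains.
* :func:`map_similarity` — Pearson cross-correlation of unthresholded maps,
  the standard yardstick for within- vs between-subject map reliability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import VoxelGrid

__all__ = [
    "SubjectMap",
    "GridResult",
    "one_sample_t",
    "heterogeneity_grid",
    "significance_category",
    "overlap_map",
    "subject_count_map",
    "map_similarity",
    "DEFAULT_EFFECT_OFFSETS",
]

#: Default effect offsets (in units of the per-subject noise sd) swept by the
#: heterogeneity simulation.
DEFAULT_EFFECT_OFFSETS: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


@dataclass
class SubjectMap:
    """One subject's effect map plus its (true or thresholded) activation mask."""

    subject_id: str
    effect: VoxelGrid
    activation_mask: np.ndarray
    is_responder: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        self.activation_mask = np.asarray(self.activation_mask, dtype=bool)
        if self.activation_mask.shape != self.effect.shape:
            raise ValueError("effect map and activation mask must be congruent")


def one_sample_t(values, two_sided: bool = False) -> tuple[float, float]:
    """One-sample t-test of per-subject values against zero.

    One-sided by default (testing activation > 0), df = n - 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 subjects")
    if values.std(ddof=1) == 0:
        raise ValueError("zero variance across subjects: t is undefined")
    res = stats.ttest_1samp(values, 0.0, alternative="two-sided" if two_sided else "greater")
    return float(res.statistic), float(res.pvalue)


def significance_category(p: float) -> str:
    """Bin a p-value: high (<0.001), moderate (<0.01), mild (<0.05), else n.s."""
    if p < 0.001:
        return "high"
    if p < 0.01:
        return "moderate"
    if p < 0.05:
        return "mild"
    return "n.s."


@dataclass
class GridResult:
    """Composition x effect-size significance surface of the group simulation.

    ``table`` has one row per (responder count r, effect offset delta) cell
    with the mean and median one-sided p over repetitions, the rejection
    rates at 0.05 and 0.001, and the significance category of the median p.
    """

    n_subjects: int
    effect_offsets: tuple[float, ...]
    n_reps: int
    seed: int
    table: pd.DataFrame


def heterogeneity_grid(
    n_subjects: int = 20,
    effect_offsets=DEFAULT_EFFECT_OFFSETS,
    n_reps: int = 1000,
    seed: int = 0,
) -> GridResult:
    """Simulate group t-tests over responder/non-responder compositions.

    For every responder count r in 0..n_subjects and every effect offset
    delta: draw r values from N(delta, 1) and n - r from N(0, 1), run the
    one-sided one-sample t-test, and repeat ``n_reps`` times.  The r = 0
    rows are the null calibration check (5% rejections at alpha = 0.05).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = n_subjects
    tcrit = {}
    rows = []
    for delta in effect_offsets:
        for r in range(0, n + 1):
            draws = rng.standard_normal((n_reps, n))
            draws[:, :r] += delta
            mean = draws.mean(axis=1)
            sd = draws.std(axis=1, ddof=1)
            t = mean / (sd / np.sqrt(n))
            p = stats.t.sf(t, n - 1)
            rows.append(
                {
                    "responders": r,
                    "delta": float(delta),
                    "mean_p": float(p.mean()),
                    "median_p": float(np.median(p)),
                    "reject_rate_05": float((p < 0.05).mean()),
                    "reject_rate_001": float((p < 0.001).mean()),
                    "category": significance_category(float(np.median(p))),
                }
            )
    table = pd.DataFrame(rows)
    return GridResult(
        n_subjects=n,
        effect_offsets=tuple(float(d) for d in effect_offsets),
        n_reps=n_reps,
        seed=seed,
        table=table,
    )


def overlap_map(subject_masks) -> tuple[np.ndarray, list[float]]:
    """Voxelwise conjunction of subject activation masks.

    Returns the AND of all masks plus each subject's *retention*: the share
    of their own activation surviving into the overlap (0 for an empty
    mask).  Adding subjects can only shrink the overlap.
    """
    masks = [np.asarray(m, dtype=bool) for m in subject_masks]
    if len(masks) < 2:
        raise ValueError("need at least 2 subject masks")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("subject masks must be congruent")
    overlap = np.logical_and.reduce(masks)
    n_overlap = int(overlap.sum())
    retention = [(n_overlap / int(m.sum()) if m.any() else 0.0) for m in masks]
    return overlap, retention


def subject_count_map(subject_maps, threshold: float) -> np.ndarray:
    """Per voxel, the number of subjects whose effect exceeds the threshold.

    The honest group summary: instead of a single group statistic it reports
    how frequently the effect is found in the individual brains.  Counts
    strictly between 0 and n mark voxels a conjunction would discard and a
    group mean would silently average over.
    """
    effects = [
        (m.effect.values if isinstance(m, SubjectMap) else np.asarray(m, dtype=float))
        for m in subject_maps
    ]
    shape = effects[0].shape
    if any(e.shape != shape for e in effects):
        raise ValueError("subject maps must be congruent")
    counts = np.zeros(shape, dtype=int)
    for e in effects:
        counts += e > threshold
    return counts


def map_similarity(map_a: VoxelGrid | np.ndarray, map_b: VoxelGrid | np.ndarray) -> float:
    """Pearson correlation between two unthresholded maps over all voxels."""
    a = (map_a.values if isinstance(map_a, VoxelGrid) else np.asarray(map_a, dtype=float)).ravel()
    b = (map_b.values if isinstance(map_b, VoxelGrid) else np.asarray(map_b, dtype=float)).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must be congruent")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance map: correlation is undefined")
    return float(np.corrcoef(a, b)[0, 1])
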
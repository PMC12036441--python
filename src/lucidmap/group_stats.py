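"""Voxelwise one-sample group analysis.

Produces the group mean effect map and the two-sided t statistic map
(df = n - 1) that drive thresholding, rendering, and the jackknife
stability analysis.  Only the one-sample design is implemented; the group
analyses this package reproduces are all one-group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes import EffectVolume, MaskVolume, StatVolume, require_aligned


@dataclass
class GroupDataset:
    """Aligned per-subject effect volumes with an analysis mask."""

    subjects: list[EffectVolume]
    subject_ids: list[str]
    mask: MaskVolume
    #: ground-truth effect template, attached by the synthetic generator
    truth_template: EffectVolume | None = field(default=None, repr=False)
    truth_meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.subjects) < 2:
            raise ValueError("a group needs at least 2 subjects")
        if len(self.subject_ids) != len(self.subjects):
            raise ValueError("one id per subject required")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject ids must be unique")
        require_aligned(self.mask, *self.subjects, what="group volumes")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def stacked(self) -> np.ndarray:
        """(n, X, Y, Z) array of subject effect data."""
        return np.stack([s.vol.data for s in self.subjects], axis=0)

    def drop(self, ids: list[str]) -> "GroupDataset":
        """Subgroup with the listed subjects removed (order preserved)."""
        missing = set(ids) - set(self.subject_ids)
        if missing:
            raise ValueError(f"unknown subject ids: {sorted(missing)}")
        keep = [i for i, sid in enumerate(self.subject_ids) if sid not in set(ids)]
        return GroupDataset(subjects=[self.subjects[i] for i in keep],
                            subject_ids=[self.subject_ids[i] for i in keep],
                            mask=self.mask,
                            truth_template=self.truth_template,
                            truth_meta=self.truth_meta)


def one_sample_ttest(group: GroupDataset) -> tuple[EffectVolume, StatVolume, int]:
    """Voxelwise one-sample t-test against zero.

    Per voxel: mean m = sum(x)/n, sd s with the n-1 denominator, and
    t = m / (s / sqrt(n)) with df = n - 1.  Zero-variance voxels inside the
    mask are statistically undefined; they are set to t = 0 (hence treated
    as subthreshold downstream) and counted in the returned
    ``undefined_count`` for quality control.
    """
    # sort per voxel so reductions are bit-identical under subject permutation
    x = np.sort(group.stacked(), axis=0)
    n = group.n_subjects
    inside = group.mask.bool_data
    m = x.mean(axis=0)
    s = x.std(axis=0, ddof=1)
    # tolerance for "identical values": rounding debris scales with |m|
    undefined = inside & (s <= 1e-12 + 1e-9 * np.abs(m))
    t = np.zeros_like(m)
    ok = inside & ~undefined
    t[ok] = m[ok] / (s[ok] / np.sqrt(n))
    m = np.where(inside, m, 0.0)

    base = group.subjects[0].vol
    mean_vol = EffectVolume(base.like(m), units=group.subjects[0].units)
    t_vol = StatVolume(base.like(t), stat_type="t", df=n - 1)
    return mean_vol, t_vol, int(undefined.sum())
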
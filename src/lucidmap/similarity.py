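"""Cross-map agreement: Dice overlap of binarized maps vs Pearson correlation.

These are the two meta-analytic lenses the package contrasts: overlap of
thresholded (binarized) cluster maps is hypersensitive to statistic
magnitude, while correlation of the continuous maps captures agreement of
spatial pattern regardless of amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .thresholding import ThresholdSpec, extract_clusters
from .volumes import MaskVolume, StatVolume, require_aligned

log = logging.getLogger(__name__)

METRICS = ("dice", "pearson")


def dice_coefficient(a: MaskVolume, b: MaskVolume) -> float:
    """Dice overlap D = 2|A ∩ B| / (|A| + |B|).

    Both masks empty is defined as perfect agreement (1.0, logged): two null
    results agree.  Exactly one empty gives 0.0.
    """
    require_aligned(a, b, what="masks")
    na, nb = a.n_foreground, b.n_foreground
    if na == 0 and nb == 0:
        log.info("dice_coefficient: both masks empty; defining D = 1.0")
        return 1.0
    inter = int(np.logical_and(a.bool_data, b.bool_data).sum())
    return 2.0 * inter / (na + nb)


def pearson_within_mask(a: StatVolume, b: StatVolume,
                        mask: MaskVolume) -> float:
    """Sample Pearson correlation over in-mask voxels.

    Returns NaN (an explicit "undefined" marker, never a fabricated number)
    when either map is constant within the mask.
    """
    require_aligned(a, b, mask, what="maps and mask")
    if mask.n_foreground == 0:
        raise ValueError("mask is empty")
    inside = mask.bool_data
    x = a.vol.data[inside]
    y = b.vol.data[inside]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity across labeled maps."""

    labels: list[str]
    values: np.ndarray
    metric: str
    undefined_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match labels")

    def mean_offdiagonal(self) -> float:
        n = len(self.labels)
        off = ~np.eye(n, dtype=bool)
        vals = self.values[off]
        return float(np.nanmean(vals))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.6g")

    def heatmap(self, path, dpi: int = 150) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        vmin, vmax = (0.0, 1.0) if self.metric == "dice" else (-1.0, 1.0)
        fig, ax = plt.subplots(figsize=(4.5, 4.0))
        im = ax.imshow(self.values, vmin=vmin, vmax=vmax, cmap="viridis")
        ax.set_xticks(range(len(self.labels)), self.labels, rotation=90, fontsize=7)
        ax.set_yticks(range(len(self.labels)), self.labels, fontsize=7)
        ax.set_title(f"{self.metric} similarity")
        fig.colorbar(im, ax=ax, shrink=0.85)
        fig.tight_layout()
        fig.savefig(path, dpi=dpi)
        plt.close(fig)


def binarize_map(stat: StatVolume, tspec: ThresholdSpec,
                 mask: MaskVolume | None = None) -> MaskVolume:
    """Suprathreshold-cluster mask for Dice comparisons.

    Sign-agnostic: voxels with |v| >= theta belonging to components that
    survive the extent filter, regardless of sign.
    """
    clusters = extract_clusters(stat, tspec, mask)
    return clusters.mask_volume()


def build_similarity_matrix_from_pairs(masks: list[MaskVolume] | None = None,
                                       stat_maps: list[StatVolume] | None = None,
                                       mask: MaskVolume | None = None,
                                       labels: list[str] | None = None
                                       ) -> SimilarityMatrix:
    """Similarity matrix from already-prepared inputs.

    Give ``masks`` for a Dice matrix, or ``stat_maps`` plus an analysis
    ``mask`` for a Pearson matrix.  Used where binarization has already
    happened upstream (e.g. the jackknife keeps per-stage cluster masks).
    """
    if (masks is None) == (stat_maps is None):
        raise ValueError("give exactly one of masks or stat_maps")
    items = masks if masks is not None else stat_maps
    if labels is None:
        labels = [f"map{i:02d}" for i in range(len(items))]
    n = len(items)
    values = np.eye(n)
    undefined: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if masks is not None:
                v = dice_coefficient(masks[i], masks[j])
            else:
                if mask is None:
                    raise ValueError("pearson requires an analysis mask")
                v = pearson_within_mask(stat_maps[i], stat_maps[j], mask)
                if np.isnan(v):
                    undefined.append((i, j))
            values[i, j] = values[j, i] = v
    metric = "dice" if masks is not None else "pearson"
    return SimilarityMatrix(labels=list(labels), values=values, metric=metric,
                            undefined_pairs=undefined)


def build_similarity_matrix(maps: list[StatVolume], metric: str,
                            tspec: ThresholdSpec | None = None,
                            mask: MaskVolume | None = None,
                            labels: list[str] | None = None) -> SimilarityMatrix:
    """Pairwise similarity matrix across statistic maps.

    ``dice`` binarizes each map through cluster extraction under ``tspec``
    (required) then compares surviving-voxel masks; ``pearson`` compares the
    unthresholded values within ``mask`` (required).  The result is symmetric
    with unit diagonal; undefined Pearson pairs (a constant map) are NaN and
    listed in ``undefined_pairs``.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    require_aligned(*maps, what="statistic maps")
    if labels is None:
        labels = [f"map{i:02d}" for i in range(len(maps))]
    n = len(maps)
    values = np.eye(n)
    undefined: list[tuple[int, int]] = []

    if metric == "dice":
        if tspec is None:
            raise ValueError("dice requires a ThresholdSpec")
        bin_masks = [binarize_map(m, tspec, mask) for m in maps]
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = dice_coefficient(bin_masks[i],
                                                               bin_masks[j])
    else:
        if mask is None:
            raise ValueError("pearson requires an analysis mask")
        for i in range(n):
            for j in range(i + 1, n):
                r = pearson_within_mask(maps[i], maps[j], mask)
                if np.isnan(r):
                    undefined.append((i, j))
                values[i, j] = values[j, i] = r

    return SimilarityMatrix(labels=list(labels), values=values, metric=metric,
                            undefined_pairs=undefined)
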
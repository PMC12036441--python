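"""Voxelwise thresholds, cluster extraction, and multiplicity adjustment.

Two complementary adjustments for the massive-univariate setting are
provided:

* cluster-extent thresholding at a family-wise error (FWE) rate calibrated
  by Monte-Carlo simulation on smooth Gaussian null fields
  (:func:`estimate_cluster_extent_fwe`), and
* Benjamini-Hochberg false discovery rate control on per-voxel p-values
  (:func:`bh_fdr_threshold`).

All thresholding is two-sided on the statistic magnitude.  Clustering is
sign-split: positive and negative suprathreshold voxels never join the same
connected component, matching the separate treatment of task-positive and
task-negative effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats
from statsmodels.stats.multitest import multipletests

from .smoothing import smooth_unit_variance
from .volumes import MaskVolume, StatVolume, Volume3D, require_aligned

CONNECTIVITIES = (6, 18, 26)

#: scipy rank of the binary structure for each face/edge/corner neighbourhood
_CONN_RANK = {6: 1, 18: 2, 26: 3}


def connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity not in CONNECTIVITIES:
        raise ValueError(f"connectivity must be one of {CONNECTIVITIES}")
    return ndimage.generate_binary_structure(3, _CONN_RANK[connectivity])


@dataclass
class ThresholdSpec:
    """Voxelwise threshold (as a p-value or a statistic value) plus extent.

    Exactly one of ``voxel_p`` / ``stat_threshold`` must be given.  The
    statistic threshold derived from ``voxel_p`` depends on the map's
    reference distribution (Z, or t with its df), so it is resolved per map
    via :func:`resolve_threshold`.
    """

    voxel_p: float | None = None
    stat_threshold: float | None = None
    connectivity: int = 6
    min_cluster_size: int = 0

    def __post_init__(self) -> None:
        if (self.voxel_p is None) == (self.stat_threshold is None):
            raise ValueError("give exactly one of voxel_p or stat_threshold")
        if self.voxel_p is not None and not (0.0 < self.voxel_p <= 1.0):
            raise ValueError("voxel_p must be in (0, 1]")
        if self.stat_threshold is not None and self.stat_threshold <= 0:
            raise ValueError("stat_threshold must be positive")
        if self.connectivity not in CONNECTIVITIES:
            raise ValueError(f"connectivity must be one of {CONNECTIVITIES}")
        if self.min_cluster_size < 0:
            raise ValueError("min_cluster_size must be >= 0")


def p_to_stat_threshold(p: float, stat_type: str, df: int | None = None) -> float:
    """Two-sided statistic threshold for a voxelwise p-value.

    Returns the (1 - p/2) quantile of the reference distribution, e.g.
    p = 0.05 on a Z map gives 1.96 (the conventional "Z ~= 2").
    """
    if not (0.0 < p <= 1.0):
        raise ValueError("p must be in (0, 1]")
    if stat_type == "Z":
        return float(stats.norm.isf(p / 2.0))
    if stat_type == "t":
        if df is None:
            raise ValueError("df required for t maps")
        return float(stats.t.isf(p / 2.0, df))
    raise ValueError(f"unknown stat_type {stat_type!r}")


def resolve_threshold(spec: ThresholdSpec, stat_type: str = "Z",
                      df: int | None = None) -> float:
    if spec.stat_threshold is not None:
        return float(spec.stat_threshold)
    return p_to_stat_threshold(spec.voxel_p, stat_type, df)


def t_to_z(stat: StatVolume) -> StatVolume:
    """Convert a t map to the Z map with identical per-voxel tail probability.

    Sign-preserving and monotone: Z = Phi^{-1}(F_t(t; df)).  Computed in
    log-probability space so extreme |t| values do not saturate.
    """
    if stat.stat_type != "t":
        raise ValueError("t_to_z expects a t statistic map")
    t = stat.vol.data
    logsf = stats.t.logsf(np.abs(t), stat.df)
    z = -special.ndtri_exp(logsf) * np.sign(t)
    return StatVolume(stat.vol.like(z), stat_type="Z")


@dataclass
class ClusterTable:
    """Suprathreshold connected components, with a dense label volume.

    ``table`` columns: label, size_vox, peak_value, peak_{x,y,z}_mm,
    com_{x,y,z}_mm, sign.  Labels are contiguous from 1, ordered by
    (size descending, then minimal flat voxel index) for determinism.
    """

    table: pd.DataFrame
    label_volume: np.ndarray
    affine: np.ndarray
    threshold: float
    connectivity: int

    @property
    def n_clusters(self) -> int:
        return len(self.table)

    def cluster_mask(self) -> np.ndarray:
        return self.label_volume > 0

    def mask_volume(self) -> MaskVolume:
        return MaskVolume.from_data(self.cluster_mask(), self.affine)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


_TABLE_COLUMNS = ["label", "size_vox", "peak_value", "peak_x_mm", "peak_y_mm",
                  "peak_z_mm", "com_x_mm", "com_y_mm", "com_z_mm", "sign"]


def extract_clusters(stat: StatVolume, spec: ThresholdSpec,
                     mask: MaskVolume | None = None) -> ClusterTable:
    """Label sign-split suprathreshold components and filter by extent.

    Components of {v >= theta} and {v <= -theta} are labeled separately
    under ``spec.connectivity`` and those smaller than
    ``spec.min_cluster_size`` voxels are dropped.
    """
    theta = resolve_threshold(spec, stat.stat_type, stat.df)
    data = stat.vol.data
    if mask is not None:
        require_aligned(stat, mask, what="stat map and mask")
        if mask.n_foreground == 0:
            raise ValueError("analysis mask is empty")
        data = np.where(mask.bool_data, data, 0.0)

    structure = connectivity_structure(spec.connectivity)
    shape = data.shape
    components: list[tuple[int, int, np.ndarray, int]] = []  # size, minidx, voxidx, sign
    for sign, supra in ((1, data >= theta), (-1, data <= -theta)):
        labeled, n = ndimage.label(supra, structure=structure)
        if n == 0:
            continue
        flat = labeled.ravel()
        order = np.argsort(flat, kind="stable")
        sorted_labels = flat[order]
        bounds = np.searchsorted(sorted_labels, np.arange(1, n + 2))
        for lab in range(1, n + 1):
            vox = order[bounds[lab - 1]:bounds[lab]]
            if len(vox) >= spec.min_cluster_size:
                components.append((len(vox), int(vox.min()), vox, sign))

    components.sort(key=lambda c: (-c[0], c[1]))

    label_vol = np.zeros(shape, dtype=np.int32)
    vol = stat.vol
    rows = []
    for new_label, (size, _minidx, vox, sign) in enumerate(components, start=1):
        ijk = np.column_stack(np.unravel_index(vox, shape))
        label_vol.reshape(-1)[vox] = new_label
        vals = data.reshape(-1)[vox]
        peak_local = int(np.argmax(np.abs(vals)))
        peak_xyz = np.atleast_1d(vol.voxel_to_mm(ijk[peak_local]))
        com_xyz = np.atleast_1d(vol.voxel_to_mm(ijk.mean(axis=0)))
        rows.append({
            "label": new_label, "size_vox": size,
            "peak_value": float(vals[peak_local]),
            "peak_x_mm": peak_xyz[0], "peak_y_mm": peak_xyz[1],
            "peak_z_mm": peak_xyz[2],
            "com_x_mm": com_xyz[0], "com_y_mm": com_xyz[1],
            "com_z_mm": com_xyz[2],
            "sign": "+" if sign > 0 else "-",
        })
    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    return ClusterTable(table=table, label_volume=label_vol,
                        affine=vol.affine.copy(), threshold=theta,
                        connectivity=spec.connectivity)


@dataclass
class NullSimConfig:
    """Monte-Carlo null configuration for cluster-extent FWE calibration."""

    shape: tuple[int, int, int]
    mask: MaskVolume | None = None
    fwhm_vox: float = 0.0
    n_iter: int = 1000
    seed: int = 0
    voxel_p: float = 0.001
    fwe_rate: float = 0.05
    connectivity: int = 6

    def __post_init__(self) -> None:
        if self.n_iter < 100:
            raise ValueError("n_iter must be >= 100 for calibration use")
        if not (0.0 < self.fwe_rate <= 1.0):
            raise ValueError("fwe_rate must be in (0, 1]")
        if self.fwhm_vox < 0:
            raise ValueError("fwhm_vox must be >= 0")
        if self.connectivity not in CONNECTIVITIES:
            raise ValueError(f"connectivity must be one of {CONNECTIVITIES}")
        if self.mask is not None and self.mask.n_foreground == 0:
            raise ValueError("mask is empty")


@dataclass
class FweCalibration:
    """Result of a Monte-Carlo cluster-extent calibration."""

    k_min: int
    max_sizes: np.ndarray
    theta: float
    config: NullSimConfig = field(repr=False)

    def exceedance(self, k: int) -> float:
        """Fraction of null fields whose largest cluster has >= k voxels."""
        return float(np.mean(self.max_sizes >= k))

    def null_distribution_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"iteration": np.arange(len(self.max_sizes)),
                             "max_cluster_size": self.max_sizes})


def k_min_from_max_sizes(max_sizes: np.ndarray, fwe_rate: float) -> int:
    """Smallest extent k with P(max null cluster >= k) <= fwe_rate."""
    max_sizes = np.asarray(max_sizes)
    for k in range(1, int(max_sizes.max(initial=0)) + 2):
        if np.mean(max_sizes >= k) <= fwe_rate:
            return k
    return 1  # unreachable; k = max+1 always satisfies the bound


def simulate_null_max_sizes(cfg: NullSimConfig,
                            stat_threshold: float | None = None) -> tuple[np.ndarray, float]:
    """Max suprathreshold cluster size per synthetic null field.

    Each iteration draws white Gaussian noise, smooths it to ``cfg.fwhm_vox``
    with mask-edge variance renormalization, standardizes to zero mean / unit
    variance within the mask, thresholds two-sided at theta, and records the
    largest sign-split component (0 if none survive the voxel threshold).
    """
    theta = (float(stat_threshold) if stat_threshold is not None
             else p_to_stat_threshold(cfg.voxel_p, "Z"))
    mask = None if cfg.mask is None else cfg.mask.bool_data
    inside = np.ones(cfg.shape, dtype=bool) if mask is None else mask
    structure = connectivity_structure(cfg.connectivity)
    rng = np.random.default_rng(cfg.seed)
    max_sizes = np.zeros(cfg.n_iter, dtype=np.int64)
    for i in range(cfg.n_iter):
        noise = rng.standard_normal(cfg.shape)
        field_ = smooth_unit_variance(noise, cfg.fwhm_vox, inside)
        vals = field_[inside]
        field_[inside] = (vals - vals.mean()) / vals.std()
        best = 0
        for supra in (field_ >= theta, field_ <= -theta):
            labeled, n = ndimage.label(supra & inside, structure=structure)
            if n:
                best = max(best, int(np.bincount(labeled.ravel())[1:].max()))
        max_sizes[i] = best
    return max_sizes, theta


def estimate_cluster_extent_fwe(cfg: NullSimConfig,
                                stat_threshold: float | None = None) -> FweCalibration:
    """Calibrate the minimum cluster extent for the target FWE rate.

    Returns the smallest integer k such that the fraction of null fields
    containing any component of >= k voxels is <= ``cfg.fwe_rate``, along
    with the simulated null max-cluster-size distribution.  Deterministic
    given ``cfg.seed``.
    """
    max_sizes, theta = simulate_null_max_sizes(cfg, stat_threshold)
    return FweCalibration(k_min=k_min_from_max_sizes(max_sizes, cfg.fwe_rate),
                          max_sizes=max_sizes, theta=theta, config=cfg)


def voxelwise_p(stat: StatVolume) -> np.ndarray:
    """Two-sided per-voxel p-values for a Z or t map."""
    a = np.abs(stat.vol.data)
    if stat.stat_type == "Z":
        return 2.0 * stats.norm.sf(a)
    return 2.0 * stats.t.sf(a, stat.df)


def bh_fdr_threshold(stat: StatVolume, q: float,
                     mask: MaskVolume) -> tuple[float, MaskVolume]:
    """Benjamini-Hochberg step-up FDR control within a mask.

    Returns the adaptive p-value threshold p(i*) (0.0 when nothing survives)
    and the survivor mask.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    require_aligned(stat, mask, what="stat map and mask")
    if mask.n_foreground == 0:
        raise ValueError("mask is empty")
    inside = mask.bool_data
    p = voxelwise_p(stat)[inside]
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    p_threshold = float(p[reject].max()) if reject.any() else 0.0
    surv = np.zeros(stat.vol.shape, dtype=bool)
    surv[inside] = reject
    return p_threshold, MaskVolume.from_data(surv, stat.vol.affine,
                                             stat.vol.space_label)
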
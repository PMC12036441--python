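"""Transparent-thresholding slice rendering.

The display style implemented here keeps suprathreshold voxels fully opaque
and outlined, while subthreshold voxels fade with the statistic magnitude:

    alpha = floor + (1 - floor) * (|v| / theta) ** exponent   (clamped to 1)

with exponent 2 by default, so opacity falls off quadratically below the
threshold and near-threshold structure remains visible.  Overlay *colors*
may come from either the statistic itself or from an effect-estimate map in
physical units; thresholding and fading are always driven by the statistic.
Compositing is per-pixel convex blending over a grayscale underlay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib import colormaps
from scipy import ndimage

from .thresholding import ClusterTable, ThresholdSpec, extract_clusters, resolve_threshold
from .volumes import (EffectVolume, MaskVolume, StatVolume, Volume3D,
                      require_aligned)

PLANES = ("axial", "sagittal", "coronal")
_PLANE_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class AlphaSpec:
    """Opacity law: strict ('opaque') or graded ('transparent')."""

    mode: str = "transparent"
    exponent: float = 2.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("opaque", "transparent"):
            raise ValueError("mode must be 'opaque' or 'transparent'")
        if self.exponent <= 0:
            raise ValueError("exponent must be > 0")
        if not (0.0 <= self.floor < 1.0):
            raise ValueError("floor must be in [0, 1)")


@dataclass
class RenderSpec:
    """Display choices for slice montages."""

    overlay_source: str = "statistic"
    colormap: str = "RdBu_r"
    color_range: float | None = None  # symmetric (-V, +V); None = data max
    underlay_range: tuple[float, float] = (2.0, 98.0)
    plane: str = "axial"
    slice_coords_mm: list[float] | None = None
    left_convention: str = "neurological"
    outline: bool = True
    outline_color: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_fov: str = "full_fov"
    dpi: int = 150

    def __post_init__(self) -> None:
        if self.overlay_source not in ("statistic", "effect"):
            raise ValueError("overlay_source must be 'statistic' or 'effect'")
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}")
        if self.left_convention not in ("neurological", "radiological"):
            raise ValueError("left_convention must be neurological|radiological")
        if self.background_fov not in ("mask_only", "full_fov"):
            raise ValueError("background_fov must be mask_only|full_fov")
        if self.color_range is not None and self.color_range <= 0:
            raise ValueError("color_range must be positive")


def compute_alpha(stat, theta: float, spec: AlphaSpec) -> np.ndarray:
    """Per-voxel opacity in [0, 1] from the statistic magnitude.

    Transparent mode: ``clamp(floor + (1-floor)(|v|/theta)^exponent, 0, 1)``
    so alpha = 1 wherever |v| >= theta.  Opaque mode: 1 above threshold,
    0 below.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    values = stat.vol.data if isinstance(stat, StatVolume) else np.asarray(stat)
    a = np.abs(values)
    if spec.mode == "opaque":
        return (a >= theta).astype(np.float64)
    alpha = spec.floor + (1.0 - spec.floor) * (a / theta) ** spec.exponent
    return np.clip(alpha, 0.0, 1.0)


def outline_boundary(cluster_mask_2d: np.ndarray) -> np.ndarray:
    """One-pixel inner boundary of a binary in-plane mask.

    boundary = mask AND NOT erode(mask) with 4-neighbor erosion; always a
    subset of the mask, so removing it strictly shrinks any nonempty mask.
    """
    m = np.asarray(cluster_mask_2d).astype(bool)
    if not m.any():
        return np.zeros_like(m)
    cross = ndimage.generate_binary_structure(2, 1)
    eroded = ndimage.binary_erosion(m, structure=cross, border_value=0)
    return m & ~eroded


def slice_index_for_mm(vol: Volume3D, plane: str, coord_mm: float) -> int:
    """Voxel index along the plane's axis for a world coordinate in mm."""
    axis = _PLANE_AXIS[plane]
    probe = np.zeros(3)
    probe[axis] = coord_mm
    # remaining coordinates: grid centre, irrelevant for an axis-aligned grid
    centre_vox = (np.asarray(vol.shape) - 1) / 2.0
    centre_mm = vol.voxel_to_mm(centre_vox)
    for a in range(3):
        if a != axis:
            probe[a] = centre_mm[a]
    idx = int(round(float(np.atleast_1d(vol.mm_to_voxel(probe))[axis])))
    if not (0 <= idx < vol.shape[axis]):
        raise ValueError(f"{plane} coordinate {coord_mm} mm is out of bounds")
    return idx


def orient_slice(data: np.ndarray, plane: str, index: int,
                 left_convention: str = "neurological") -> np.ndarray:
    """Extract and orient a display slice from an RAS+ volume.

    Rows run top-to-bottom as anterior-to-posterior (axial) or
    superior-to-inferior (sagittal/coronal).  For axial and coronal planes,
    neurological convention puts the subject's left on the image left;
    radiological flips horizontally.
    """
    axis = _PLANE_AXIS[plane]
    sl = np.take(data, index, axis=axis)
    img = sl.T[::-1, :]  # rows: last remaining axis descending
    if plane in ("axial", "coronal") and left_convention == "radiological":
        img = img[:, ::-1]
    return img


def _gray_underlay(under: Volume3D, pct: tuple[float, float]) -> np.ndarray:
    lo, hi = np.percentile(under.data, pct)
    if hi <= lo:
        return np.zeros(under.shape)
    return np.clip((under.data - lo) / (hi - lo), 0.0, 1.0)


def _overlay_rgb(values: np.ndarray, cmap_name: str, vmax: float) -> np.ndarray:
    cmap = colormaps[cmap_name]
    normed = np.clip((values + vmax) / (2.0 * vmax), 0.0, 1.0)
    return np.asarray(cmap(normed))[..., :3]


def composite_slice(underlay: Volume3D, overlay_values: Volume3D,
                    alpha: np.ndarray, clusters: ClusterTable | None,
                    spec: RenderSpec, plane: str, coord_mm: float,
                    mask: MaskVolume | None = None) -> np.ndarray:
    """Alpha-blend one slice: ``out = a*cmap(overlay) + (1-a)*gray(under)``.

    Outline pixels (per-cluster 1-pixel boundaries) are overwritten with the
    outline color.  With ``background_fov='mask_only'`` the overlay is
    confined to the mask.  Returns a float RGB array in [0, 1]; the image is
    fully opaque.
    """
    require_aligned(underlay, overlay_values, what="underlay and overlay")
    if alpha.shape != underlay.shape:
        raise ValueError("alpha grid does not match the volume grid")
    if mask is not None:
        require_aligned(underlay, mask, what="volumes and mask")

    alpha = alpha.copy()
    if spec.background_fov == "mask_only" and mask is not None:
        alpha[~mask.bool_data] = 0.0

    idx = slice_index_for_mm(underlay, plane, coord_mm)
    conv = spec.left_convention
    gray2d = orient_slice(_gray_underlay(underlay, spec.underlay_range),
                          plane, idx, conv)
    over2d = orient_slice(overlay_values.data, plane, idx, conv)
    a2d = orient_slice(alpha, plane, idx, conv)[..., None]

    vmax = spec.color_range
    if vmax is None:
        vmax = float(np.abs(overlay_values.data).max()) or 1.0
    rgb_over = _overlay_rgb(over2d, spec.colormap, vmax)
    rgb_under = np.repeat(gray2d[..., None], 3, axis=-1)
    out = a2d * rgb_over + (1.0 - a2d) * rgb_under

    if spec.outline and clusters is not None and clusters.n_clusters > 0:
        lab2d = orient_slice(clusters.label_volume.astype(float), plane,
                             idx, conv).astype(int)
        boundary = np.zeros(lab2d.shape, dtype=bool)
        for lab in np.unique(lab2d):
            if lab > 0:
                boundary |= outline_boundary(lab2d == lab)
        out[boundary] = np.asarray(spec.outline_color, dtype=float)
    return np.clip(out, 0.0, 1.0)


def to_uint8(rgb: np.ndarray) -> np.ndarray:
    return np.round(np.clip(rgb, 0.0, 1.0) * 255.0).astype(np.uint8)


def colorbar_rgb(vmax: float, theta: float, aspec: AlphaSpec,
                 rspec: RenderSpec, height: int = 256, width: int = 20,
                 bg_gray: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Colorbar strip with the fade law applied below the threshold.

    Returns ``(values, rgb)`` where ``values`` runs from +vmax (top row) to
    -vmax (bottom row) and each row is blended against a mid-gray background
    with the same alpha the volume renderer would use, so the bar depicts
    exactly how subthreshold values appear.
    """
    values = np.linspace(vmax, -vmax, height)
    alpha = compute_alpha(values, theta, aspec)[:, None, None]
    rgb_over = _overlay_rgb(values[:, None], rspec.colormap, vmax)[:, 0, :]
    strip = alpha * rgb_over[:, None, :] + (1 - alpha) * bg_gray
    return values, np.broadcast_to(strip, (height, width, 3)).copy()


def render_panel(stat: StatVolume, effect: EffectVolume | None,
                 underlay: Volume3D, tspec: ThresholdSpec, aspec: AlphaSpec,
                 rspec: RenderSpec, out_prefix,
                 mask: MaskVolume | None = None) -> dict[str, Path]:
    """Write a slice montage plus a fade-annotated colorbar as PNG files.

    Thresholding and fading always come from the statistic; overlay colors
    come from the statistic or, with ``overlay_source='effect'``, from the
    effect-estimate map.  Output is deterministic for fixed inputs (no
    timestamps embedded).
    """
    if rspec.overlay_source == "effect" and effect is None:
        raise ValueError("overlay_source='effect' requires an effect volume")
    require_aligned(stat, underlay, what="stat map and underlay")
    theta = resolve_threshold(tspec, stat.stat_type, stat.df)
    clusters = extract_clusters(stat, tspec, mask)
    overlay_vol = effect.vol if rspec.overlay_source == "effect" else stat.vol
    alpha = compute_alpha(stat, theta, aspec)

    coords = rspec.slice_coords_mm
    if coords is None:
        axis = _PLANE_AXIS[rspec.plane]
        centre = underlay.voxel_to_mm((np.asarray(underlay.shape) - 1) / 2.0)
        coords = [float(np.atleast_1d(centre)[axis])]

    vmax = rspec.color_range
    if vmax is None:
        vmax = float(np.abs(overlay_vol.data).max()) or 1.0

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    fig, axes = plt.subplots(1, len(coords),
                             figsize=(3.0 * len(coords), 3.2), squeeze=False)
    for ax, coord in zip(axes[0], coords):
        img = composite_slice(underlay, overlay_vol, alpha, clusters, rspec,
                              rspec.plane, coord, mask)
        ax.imshow(img, interpolation="nearest")
        ax.set_title(f"{rspec.plane[0]} = {coord:g} mm", fontsize=9)
        ax.axis("off")
    fig.tight_layout()
    montage_path = out_prefix.with_name(out_prefix.name + "_montage.png")
    fig.savefig(montage_path, dpi=rspec.dpi)
    plt.close(fig)

    values, strip = colorbar_rgb(vmax, theta, aspec, rspec)
    fig, ax = plt.subplots(figsize=(1.8, 4.0))
    ax.imshow(strip, extent=(0, 1, -vmax, vmax), aspect="auto",
              interpolation="nearest")
    for level in (theta, -theta):
        if abs(level) <= vmax:
            ax.axhline(level, color="k", lw=1.0)
    ax.set_xticks([])
    ax.set_ylabel("overlay value")
    fig.tight_layout()
    colorbar_path = out_prefix.with_name(out_prefix.name + "_colorbar.png")
    fig.savefig(colorbar_path, dpi=rspec.dpi)
    plt.close(fig)

    return {"montage": montage_path, "colorbar": colorbar_path}


def render_adjustment_pair(stat: StatVolume, effect: EffectVolume | None,
                           underlay: Volume3D, pre_tspec: ThresholdSpec,
                           post_tspec: ThresholdSpec, aspec: AlphaSpec,
                           rspec: RenderSpec, out_prefix,
                           mask: MaskVolume | None = None) -> list[Path]:
    """Before/after multiple-comparisons-adjustment montage pair.

    'Before' renders with the plain voxelwise threshold; 'after' applies the
    adjusted spec (e.g. the calibrated cluster extent).  Returns the two
    montage paths.
    """
    out_prefix = Path(out_prefix)
    before = render_panel(stat, effect, underlay, pre_tspec, aspec, rspec,
                          out_prefix.with_name(out_prefix.name + "_before"),
                          mask)
    after = render_panel(stat, effect, underlay, post_tspec, aspec, rspec,
                         out_prefix.with_name(out_prefix.name + "_after"),
                         mask)
    return [before["montage"], after["montage"]]
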
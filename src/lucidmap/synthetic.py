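"""Synthetic volumetric data: smooth null fields, blob-activation groups,
the four-map subthreshold-degeneracy set, and a small-FOV noise phantom.

Every generator is a pure function of its configuration and seed, so all
outputs are bit-reproducible.  Effects are smooth Gaussian bumps rather than
hard spheres, reflecting the gradual spatial drop-off of real hemodynamic
responses; between-subject variability enters as a scalar amplitude
multiplier on the effect template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .group_stats import GroupDataset
from .smoothing import smooth_periodic
from .volumes import (EffectVolume, MaskVolume, StatVolume, Volume3D,
                      default_affine)

EFFECT_UNITS = "BOLD % signal change"


class Blob(NamedTuple):
    """A Gaussian activation bump in voxel coordinates."""

    center_vox: tuple[float, float, float]
    width_vox: float
    amplitude: float


def _bump(shape, center, width) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.exp(-0.5 * d2 / width ** 2)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic group generator.

    Defaults emulate a modest single-site task study: a 20-subject group on
    a 24^3 grid (2 mm voxels), subject noise fields smoothed to FWHM 2
    voxels, a strong right-hemisphere bump of 1.0 effect units plus a weaker
    mirrored bump of 0.6, 20% between-subject amplitude scatter, and
    unit-variance measurement noise.  With these values the strong bump sits
    deliberately near the usual p = 0.001 cluster threshold, which is the
    regime where thresholded results are least stable.
    """

    shape: tuple[int, int, int] = (24, 24, 24)
    fwhm_vox: float = 2.0
    n_subj: int = 20
    blobs: list[Blob] = field(default_factory=lambda: [
        Blob(center_vox=(17.0, 12.0, 12.0), width_vox=2.5, amplitude=1.0),
        Blob(center_vox=(6.0, 12.0, 12.0), width_vox=2.5, amplitude=0.6),
    ])
    between_subject_sd: float = 0.2
    noise_sd: float = 1.0
    seed: int = 0
    voxel_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.n_subj < 2:
            raise ValueError("n_subj must be >= 2")
        if self.fwhm_vox < 0 or self.noise_sd < 0 or self.between_subject_sd < 0:
            raise ValueError("widths and noise levels must be nonnegative")
        for b in self.blobs:
            if b.width_vox <= 0:
                raise ValueError("blob widths must be > 0")
            if not np.isfinite(b.amplitude):
                raise ValueError("blob amplitudes must be finite")

    def template(self) -> np.ndarray:
        out = np.zeros(self.shape)
        for b in self.blobs:
            out += b.amplitude * _bump(self.shape, b.center_vox, b.width_vox)
        return out


def smooth_gaussian_field(shape, fwhm_vox: float,
                          seed: int | np.random.Generator = 0) -> Volume3D:
    """Standardized smooth Gaussian random field (zero mean, unit variance).

    White Gaussian noise convolved with a Gaussian kernel
    (sigma = fwhm / 2.3548) under periodic boundaries, then standardized
    over the grid.  Periodic boundaries keep the field stationary, so its
    autocorrelation matches the kernel-implied prediction everywhere.
    """
    if min(shape) < 1:
        raise ValueError(f"nonpositive shape {shape}")
    if fwhm_vox < 0:
        raise ValueError("fwhm_vox must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    field_ = smooth_periodic(rng.standard_normal(shape), fwhm_vox)
    field_ = (field_ - field_.mean()) / field_.std()
    return Volume3D(field_, default_affine(shape))


def simulate_group(cfg: SynthConfig) -> GroupDataset:
    """Synthetic group dataset with the ground-truth template attached.

    Subject i's effect volume is
    ``(1 + between_subject_sd * g_i) * template + noise_sd * field_i``
    with g_i a standard normal scalar and field_i an independent smooth
    unit-variance noise field.
    """
    rng = np.random.default_rng(cfg.seed)
    affine = default_affine(cfg.shape, cfg.voxel_mm)
    template = cfg.template()
    amp_scatter = rng.standard_normal(cfg.n_subj)
    subjects = []
    for i in range(cfg.n_subj):
        noise = smooth_gaussian_field(cfg.shape, cfg.fwhm_vox, rng).data
        data = (1.0 + cfg.between_subject_sd * amp_scatter[i]) * template \
            + cfg.noise_sd * noise
        subjects.append(EffectVolume(Volume3D(data, affine), units=EFFECT_UNITS))
    mask = MaskVolume.from_data(np.ones(cfg.shape), affine)
    truth = EffectVolume(Volume3D(template, affine), units=EFFECT_UNITS)
    ids = [f"sub-{i+1:03d}" for i in range(cfg.n_subj)]
    meta = {"seed": cfg.seed, "fwhm_vox": cfg.fwhm_vox,
            "between_subject_sd": cfg.between_subject_sd,
            "noise_sd": cfg.noise_sd,
            "blobs": [b._asdict() for b in cfg.blobs]}
    return GroupDataset(subjects=subjects, subject_ids=ids, mask=mask,
                        truth_template=truth, truth_meta=meta)


def make_quartet(theta: float, shape=(32, 32, 16),
                 seed: int = 0) -> list[StatVolume]:
    """Four Z maps that are bitwise identical above |theta| yet tell four
    different scientific stories below it.

    All four share one right-hemisphere suprathreshold cluster.  Their
    subthreshold content realizes: (1) a same-sign mirrored pattern (nearly
    symmetric activation), (2) the mirrored-and-negated version of (1)
    (anti-symmetric activation), (3) near-zero background (truly lateralized
    response), and (4) spatially incoherent noise scaled strictly below
    theta (an artifact-like result).  Under opaque thresholding the four
    reduce to the same image.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    shape = tuple(shape)
    nx = shape[0]
    affine = default_affine(shape)

    # supra bump on the subject's right (high x in RAS+)
    center = (0.72 * (nx - 1), (shape[1] - 1) / 2.0, (shape[2] - 1) / 2.0)
    width = 2.5
    b_right = 1.6 * theta * _bump(shape, center, width)
    supra = b_right >= theta  # the shared cluster C

    def mirror(a: np.ndarray) -> np.ndarray:
        return a[::-1, :, :]

    b_left_unit = mirror(b_right) / (1.6 * theta)
    clip = 0.95 * theta

    def assemble(sub_pattern: np.ndarray) -> StatVolume:
        sub = np.clip(sub_pattern, -clip, clip)
        data = np.where(supra, b_right, sub)
        return StatVolume(Volume3D(data, affine), stat_type="Z")

    pattern1 = b_right + 0.9 * theta * b_left_unit
    pattern2 = -mirror(pattern1)
    pattern3 = 0.05 * theta * b_left_unit
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    pattern4 = noise * (0.9 * theta / np.abs(noise).max())

    return [assemble(p) for p in (pattern1, pattern2, pattern3, pattern4)]


def make_phantom_fov(fov_shape=(24, 24, 12),
                     anatomy_center=(11.5, 11.5, 5.5),
                     anatomy_semiaxes=(7.0, 5.0, 3.5),
                     noise_sd: float = 0.4,
                     fwhm_vox: float = 1.5,
                     seed: int = 0,
                     injected_cluster: tuple | None = None
                     ) -> tuple[EffectVolume, StatVolume, MaskVolume]:
    """Small field-of-view noise phantom with an anatomy mask.

    Emulates scanning an inert object: noise fills the entire FOV (so the
    background "noise floor" is visible), an ellipsoid marks the subject's
    anatomy, and an optional small suprathreshold cluster with a low effect
    amplitude can be injected inside the anatomy to emulate a false positive
    that survives voxelwise thresholding.  ``injected_cluster`` is
    (center_vox, width_vox, peak_z).  The effect map is ``noise_sd`` times
    the Z map, so high statistics still carry small physical effects.
    """
    fov_shape = tuple(fov_shape)
    grids = np.ogrid[tuple(slice(0, s) for s in fov_shape)]
    ell = sum(((g - c) / a) ** 2
              for g, c, a in zip(grids, anatomy_center, anatomy_semiaxes))
    anatomy = ell <= 1.0
    lo = np.array(anatomy_center) - np.array(anatomy_semiaxes)
    hi = np.array(anatomy_center) + np.array(anatomy_semiaxes)
    if (lo < 0).any() or (hi > np.array(fov_shape) - 1).any():
        raise ValueError("anatomy ellipsoid extends outside the FOV")

    z = smooth_gaussian_field(fov_shape, fwhm_vox, seed).data
    if injected_cluster is not None:
        center, width, peak_z = injected_cluster
        z = z + peak_z * _bump(fov_shape, center, width)

    affine = default_affine(fov_shape)
    effect = EffectVolume(Volume3D(noise_sd * z, affine), units=EFFECT_UNITS)
    stat = StatVolume(Volume3D(z, affine), stat_type="Z")
    mask = MaskVolume.from_data(anatomy, affine)
    return effect, stat, mask


def simulate_map_family(n_maps: int = 6, shape=(16, 16, 16),
                        fwhm_vox: float = 2.0, pattern_fwhm_vox: float = 3.0,
                        pattern_amplitude: float = 2.0,
                        scale_range: tuple[float, float] = (0.5, 2.0),
                        noise_scale: float = 1.0,
                        seed: int = 0) -> list[StatVolume]:
    """Maps sharing one brainwide spatial pattern at per-map amplitudes.

    Emulates many teams analyzing the same data: map i is
    ``s_i * pattern + noise_i`` where the pattern is a smooth unit-variance
    field scaled to ``pattern_amplitude`` (in noise-sd units) and s_i is
    drawn uniformly from ``scale_range``.  Amplitude scaling drags weaker
    maps below any fixed binarization threshold while leaving the spatial
    pattern (and hence the correlation structure) intact — the regime where
    binarized-overlap and correlation summaries disagree.
    """
    rng = np.random.default_rng(seed)
    affine = default_affine(shape)
    pattern = pattern_amplitude * smooth_gaussian_field(
        shape, pattern_fwhm_vox, rng).data
    scales = rng.uniform(*scale_range, size=n_maps)
    maps = []
    for i in range(n_maps):
        noise = smooth_gaussian_field(shape, fwhm_vox, rng).data
        maps.append(StatVolume(Volume3D(scales[i] * pattern
                                        + noise_scale * noise, affine),
                               stat_type="Z"))
    return maps
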
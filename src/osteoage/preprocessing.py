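"""Bone-voxel preprocessing: isotropic resampling, HU windowing, mandible extraction.

The pipeline turns a raw CT volume into fixed-shape network inputs:

* **femur**: resample to 1 mm isotropic, window HU linearly so that
  400 HU -> 0 and 1000 HU -> 1 (values outside clamp), and fit the region
  to exactly ``112 x 128 x 128`` voxels (z, y, x).
* **mandible**: per axial slice, center-fit to ``256 x 256``, threshold at
  400 HU, clean the binary mask by morphological opening, keep only large
  connected components (dropping e.g. neck-bone fragments), mask the HU
  slice, stack a 20-slice slab and window-normalize to [0, 1], giving
  ``20 x 256 x 256``.

Cortical bone sits roughly in the 400-1000 HU band, which is why that
window isolates the age-bearing bone signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dicom_io import CTVolume

__all__ = [
    "BoneVoxel",
    "BinaryMask",
    "MODALITY_SHAPES",
    "HU_WINDOW",
    "EmptyRegionError",
    "EmptyMandibleError",
    "resample_isotropic",
    "window_normalize",
    "segment_femur",
    "morphological_open",
    "label_components",
    "retain_large_components",
    "extract_mandible",
    "fit_to_shape",
    "downsample_block_mean",
]

#: fixed output shapes (z, y, x) per modality
MODALITY_SHAPES: dict[str, tuple[int, int, int]] = {
    "femur": (112, 128, 128),
    "mandible": (20, 256, 256),
}
#: HU window mapped linearly onto [0, 1]
HU_WINDOW: tuple[float, float] = (400.0, 1000.0)
#: bone threshold for the mandible mask, HU
BONE_THRESHOLD = 400.0
#: components smaller than this fraction of the largest are discarded
MIN_COMPONENT_FRACTION = 0.1


class EmptyRegionError(ValueError):
    """Requested region lies outside the volume or holds no voxels."""


class EmptyMandibleError(ValueError):
    """No slice of the volume contains any bone voxel after masking."""


@dataclass
class BinaryMask:
    """A boolean grid with physical spacing, same shape as what it masks."""

    values: np.ndarray
    spacing: tuple[float, ...] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)


@dataclass
class BoneVoxel:
    """Fixed-shape normalized bone grid for one modality.

    Invariants are enforced on construction: the shape matches the modality
    constant exactly and every value lies in [0, 1] with no NaN.
    """

    values: np.ndarray
    modality: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.modality not in MODALITY_SHAPES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.values = np.asarray(self.values, dtype=np.float32)
        expected = MODALITY_SHAPES[self.modality]
        if self.values.shape != expected:
            raise ValueError(
                f"{self.modality} voxel must have shape {expected}, got {self.values.shape}"
            )
        if np.isnan(self.values).any():
            raise ValueError("bone voxel contains NaN")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("bone voxel intensities must lie in [0, 1]")


def resample_isotropic(
    volume: CTVolume, target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> CTVolume:
    """Trilinearly resample ``volume`` onto ``target_spacing`` (mm).

    Output dimensions are ``round(dim * spacing / target)`` per axis, so the
    physical extent is preserved to within one output voxel. A volume already
    on the target grid is returned as an untouched copy.
    """
    if any(t <= 0 for t in target_spacing):
        raise ValueError("invalid spacing: target spacing must be strictly positive")
    factors = tuple(s / t for s, t in zip(volume.spacing, target_spacing))
    if all(abs(f - 1.0) < 1e-9 for f in factors):
        return CTVolume(
            values=volume.values.copy(),
            spacing=tuple(target_spacing),
            origin=volume.origin,
            subject_id=volume.subject_id,
        )
    values = ndimage.zoom(
        volume.values.astype(np.float32), factors, order=1, mode="nearest", grid_mode=True
    )
    return CTVolume(
        values=values.astype(np.float32),
        spacing=tuple(float(t) for t in target_spacing),
        origin=volume.origin,
        subject_id=volume.subject_id,
    )


def window_normalize(
    values: np.ndarray, window: tuple[float, float] = HU_WINDOW
) -> np.ndarray:
    """Map HU linearly onto [0, 1] over ``window``, clamping outside it."""
    lo, hi = window
    out = (np.asarray(values, dtype=np.float32) - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0)


def fit_to_shape(values: np.ndarray, shape: tuple[int, ...], fill: float = 0.0) -> np.ndarray:
    """Center-crop and/or symmetrically pad ``values`` to exactly ``shape``."""
    out = np.asarray(values)
    for axis, target in enumerate(shape):
        size = out.shape[axis]
        if size > target:
            start = (size - target) // 2
            sl = [slice(None)] * out.ndim
            sl[axis] = slice(start, start + target)
            out = out[tuple(sl)]
        elif size < target:
            before = (target - size) // 2
            after = target - size - before
            pad = [(0, 0)] * out.ndim
            pad[axis] = (before, after)
            out = np.pad(out, pad, constant_values=fill)
    return out


def _auto_region(volume: CTVolume, target: tuple[int, int, int]) -> tuple[slice, slice, slice]:
    """Center the target box on the bone-bearing bounding box (whole volume
    when no voxel reaches the bone threshold)."""
    bone = volume.values >= BONE_THRESHOLD
    if bone.any():
        centers = [int(np.mean([idx.min(), idx.max()])) for idx in np.nonzero(bone)]
    else:
        centers = [s // 2 for s in volume.shape]
    slices = []
    for c, t, s in zip(centers, target, volume.shape):
        start = max(0, min(c - t // 2, s - t))
        stop = min(s, start + t)
        slices.append(slice(start, stop))
    return tuple(slices)  # type: ignore[return-value]


def segment_femur(
    volume: CTVolume,
    region: tuple[tuple[int, int], ...] | str = "auto",
    window: tuple[float, float] = HU_WINDOW,
) -> BoneVoxel:
    """Window the femur region to [0, 1] and fit it to 112 x 128 x 128.

    ``region`` is either ``"auto"`` (a box of the target size centered on the
    bone-bearing extent) or an explicit ``((z0, z1), (y0, y1), (x0, x1))``
    index box. The intensity map is ``clamp((HU - 400) / 600, 0, 1)``.
    """
    target = MODALITY_SHAPES["femur"]
    if isinstance(region, str):
        if region != "auto":
            raise ValueError(f"unknown region selector {region!r}")
        slices = _auto_region(volume, target)
    else:
        slices = tuple(slice(max(0, lo), min(s, hi)) for (lo, hi), s in zip(region, volume.shape))
        if any(sl.stop <= sl.start for sl in slices):
            raise EmptyRegionError("empty region: box lies outside the volume")
    cropped = volume.values[slices]
    if cropped.size == 0:
        raise EmptyRegionError("empty region: no voxels selected")
    values = fit_to_shape(window_normalize(cropped, window), target)
    return BoneVoxel(values=values, modality="femur", subject_id=volume.subject_id)


def _default_structure(rank: int = 2, size: int = 3) -> np.ndarray:
    return np.ones((size,) * rank, dtype=bool)


def morphological_open(mask: BinaryMask, structure: BinaryMask | np.ndarray | None = None) -> BinaryMask:
    """Erosion followed by dilation; removes objects smaller than the structure."""
    values = mask.values
    if structure is None:
        struct = _default_structure(values.ndim)
    else:
        struct = structure.values if isinstance(structure, BinaryMask) else np.asarray(structure, bool)
    if not struct.any():
        raise ValueError("structuring element must be nonempty")
    opened = ndimage.binary_opening(values, structure=struct)
    return BinaryMask(values=opened, spacing=mask.spacing)


def label_components(
    mask: BinaryMask | np.ndarray, connectivity: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Label maximal connected regions; return (labels, sizes).

    ``connectivity`` follows the usual convention: 1 = faces only
    (4-connectivity in 2D), 2 = faces + diagonals (8-connectivity in 2D).
    ``sizes[i]`` is the pixel count of label ``i + 1``; background is 0.
    """
    values = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    structure = ndimage.generate_binary_structure(values.ndim, connectivity)
    labels, n = ndimage.label(values, structure=structure)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return labels, sizes


def retain_large_components(
    labels: np.ndarray,
    sizes: np.ndarray,
    min_fraction: float = MIN_COMPONENT_FRACTION,
) -> BinaryMask:
    """Keep every component whose size is >= ``min_fraction`` of the largest.

    The largest component always survives; an empty labeling yields an empty
    mask.
    """
    if len(sizes) == 0:
        return BinaryMask(values=np.zeros_like(labels, dtype=bool))
    threshold = min_fraction * sizes.max()
    keep = np.flatnonzero(sizes >= threshold) + 1
    return BinaryMask(values=np.isin(labels, keep))


def _mandible_slice_mask(
    hu_slice: np.ndarray,
    threshold: float,
    structure: np.ndarray,
    min_fraction: float,
    connectivity: int,
) -> np.ndarray:
    mask = BinaryMask(hu_slice >= threshold)
    mask = morphological_open(mask, structure)
    labels, sizes = label_components(mask, connectivity)
    return retain_large_components(labels, sizes, min_fraction).values


def extract_mandible(
    volume: CTVolume,
    threshold: float = BONE_THRESHOLD,
    structure: np.ndarray | None = None,
    min_fraction: float = MIN_COMPONENT_FRACTION,
    connectivity: int = 2,
    window: tuple[float, float] = HU_WINDOW,
    z_stride: int = 1,
) -> BoneVoxel:
    """Extract the mandible bone slab as a 20 x 256 x 256 voxel in [0, 1].

    Per slice: center-fit to 256 x 256, threshold at 400 HU, open with a
    3 x 3 square, label 8-connected components, retain components at least
    10% the size of the largest, and multiply the surviving mask into the HU
    slice. The 20 slices centered on the bone-bearing span are stacked
    (zero-padded when fewer exist) and window-normalized like the femur.
    ``z_stride`` > 1 takes every ``z_stride``-th slice of a correspondingly
    wider central band, trading slab coverage against through-plane detail.
    """
    if z_stride < 1:
        raise ValueError("z_stride must be >= 1")
    target = MODALITY_SHAPES["mandible"]
    struct = _default_structure(2) if structure is None else np.asarray(structure, bool)

    masked = np.zeros((volume.shape[0],) + target[1:], dtype=np.float32)
    has_bone = np.zeros(volume.shape[0], dtype=bool)
    for k in range(volume.shape[0]):
        # pad with air, not zeros, so padding can never cross the threshold
        hu = fit_to_shape(volume.values[k], target[1:], fill=-1024.0)
        mask = _mandible_slice_mask(hu, threshold, struct, min_fraction, connectivity)
        if mask.any():
            has_bone[k] = True
            masked[k] = hu * mask  # zero outside bone -> windows to 0

    if not has_bone.any():
        raise EmptyMandibleError("empty mandible: no slice contains bone voxels")

    bone_idx = np.flatnonzero(has_bone)
    center = int(round((bone_idx[0] + bone_idx[-1]) / 2))
    n_slices = target[0]
    band = n_slices * z_stride
    start = max(0, min(center - band // 2, volume.shape[0] - band))
    slab = masked[start : start + band : z_stride]
    if slab.shape[0] < n_slices:
        slab = fit_to_shape(slab, (n_slices,) + target[1:])
    values = window_normalize(slab, window)
    return BoneVoxel(values=values, modality="mandible", subject_id=volume.subject_id)


def downsample_block_mean(values: np.ndarray, factors: tuple[int, ...]) -> np.ndarray:
    """Block-average ``values`` by integer ``factors`` per axis.

    Trailing partial blocks are dropped; used to bring full-size bone voxels
    down to desk-scale network input grids.
    """
    out = np.asarray(values, dtype=np.float32)
    for axis, f in enumerate(factors):
        if f < 1:
            raise ValueError("downsample factors must be >= 1")
        if f == 1:
            continue
        size = (out.shape[axis] // f) * f
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(0, size)
        out = out[tuple(sl)]
        new_shape = out.shape[:axis] + (size // f, f) + out.shape[axis + 1 :]
        out = out.reshape(new_shape).mean(axis=axis + 1)
    return out
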
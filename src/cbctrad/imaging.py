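"""Volumes, masks and the preprocessing stages of the radiomics pipeline.

The in-memory containers here are deliberately minimal: a :class:`VoxelImage`
is a 3-D scalar array plus per-axis spacing (mm) and origin, and a
:class:`ROIMask` is a binary array on the same grid.  Axis 0 is the slice
direction throughout the package (the axis whose spacing the slice-thickness
sweep varies); axes 1 and 2 are in-plane.  Voxel centres sit at
``origin + index * spacing`` (grid-node convention).

File I/O goes through SimpleITK so NIfTI (.nii/.nii.gz) and NRRD (.nrrd)
behave identically; SimpleITK's (x, y, z) metadata order is reversed to match
the numpy (slice, row, col) array order used here.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Sampling grid: voxels per axis, mm per voxel, physical origin.

    The default 0.26 mm isotropic spacing is the native slice spacing of the
    onboard CBCT protocol this package emulates; the in-plane value is assumed
    equal to it (the scanner's in-plane spacing is not published).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (0.26, 0.26, 0.26)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals (mm), got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size of the grid per axis in mm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        return float(np.prod(self.spacing))

    @property
    def center(self) -> tuple[float, float, float]:
        return tuple(o + 0.5 * e for o, e in zip(self.origin, self.extent))

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]


def _validate_grid_fields(values: np.ndarray, spacing, origin):
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError(f"expected a 3-D array, got ndim={values.ndim}")
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(s) for s in origin)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive reals (mm), got {spacing}")
    return values, spacing, origin


@dataclass
class VoxelImage:
    """A 3-D scan: scalar voxel values (scanner units) on a physical grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values, spacing, origin = _validate_grid_fields(self.values, self.spacing, self.origin)
        if not np.all(np.isfinite(values)):
            raise ValueError("image contains non-finite voxel values")
        self.values = values.astype(np.float64, copy=False)
        self.spacing = spacing
        self.origin = origin

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.values.shape, self.spacing, self.origin)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def copy_with(self, values: np.ndarray) -> "VoxelImage":
        return VoxelImage(values, self.spacing, self.origin)


@dataclass
class ROIMask:
    """A binary segmentation aligned to a :class:`VoxelImage`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values, spacing, origin = _validate_grid_fields(self.values, self.spacing, self.origin)
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be binary (values in {0, 1})")
        self.values = values.astype(bool)
        self.spacing = spacing
        self.origin = origin

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing))

    def check_aligned(self, image: VoxelImage) -> None:
        if self.values.shape != image.values.shape:
            raise ValueError(
                f"mask shape {self.values.shape} does not match image shape {image.values.shape}"
            )
        if not np.allclose(self.spacing, image.spacing):
            raise ValueError(f"mask spacing {self.spacing} differs from image spacing {image.spacing}")


@dataclass
class DiscretizedROI:
    """Fixed-bin-width gray levels over the ROI voxels.

    ``levels`` are integers in 1..Ng with level(x) = floor((x − roi_min)/w) + 1,
    anchored at the ROI minimum, so the discretisation is invariant to adding a
    constant to all intensities.
    """

    levels: np.ndarray
    n_levels: int
    bin_width: float
    roi_min: float

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.levels.size == 0:
            raise ValueError("discretised ROI is empty")
        if self.levels.min() != 1 or self.levels.max() != self.n_levels:
            raise ValueError("levels must span 1..Ng")


# --------------------------------------------------------------------------
# file I/O
# --------------------------------------------------------------------------

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".nrrd")


def _check_suffix(path: str) -> None:
    p = str(path)
    if not any(p.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise ValueError(f"unsupported volume format for {p!r}; use one of {_SUPPORTED_SUFFIXES}")


def read_volume(path: str | os.PathLike) -> VoxelImage:
    """Read a NIfTI or NRRD volume, honouring spacing and origin from the header."""
    path = str(path)
    _check_suffix(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as err:
        raise ValueError(f"failed to read {path!r}: {err}") from err
    arr = sitk.GetArrayFromImage(img)  # (z, y, x) -> our (slice, row, col)
    if arr.ndim != 3:
        raise ValueError(f"{path!r} is not a 3-D volume (ndim={arr.ndim})")
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    if any((not math.isfinite(s)) or s <= 0 for s in spacing):
        raise ValueError(f"{path!r} has non-positive spacing metadata: {spacing}")
    return VoxelImage(arr.astype(np.float64), spacing, origin)


def write_volume(image: VoxelImage, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI or NRRD (format from the file suffix)."""
    path = str(path)
    _check_suffix(path)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    img = sitk.GetImageFromArray(image.values)
    img.SetSpacing(tuple(reversed(image.spacing)))
    img.SetOrigin(tuple(reversed(image.origin)))
    sitk.WriteImage(img, path)


def read_mask(path: str | os.PathLike) -> ROIMask:
    """Read a binary mask; any non-zero voxel counts as inside."""
    vol = read_volume(path)
    return ROIMask(vol.values != 0, vol.spacing, vol.origin)


def write_mask(mask: ROIMask, path: str | os.PathLike) -> None:
    """Write a mask as unsigned 8-bit (0/1)."""
    path = str(path)
    _check_suffix(path)
    img = sitk.GetImageFromArray(mask.values.astype(np.uint8))
    img.SetSpacing(tuple(reversed(mask.spacing)))
    img.SetOrigin(tuple(reversed(mask.origin)))
    sitk.WriteImage(img, path)


def write_labels(labels: np.ndarray, grid: GridSpec, path: str | os.PathLike) -> None:
    """Write an integer label map on a grid (compartment codes)."""
    path = str(path)
    _check_suffix(path)
    img = sitk.GetImageFromArray(np.asarray(labels).astype(np.uint8))
    img.SetSpacing(tuple(reversed(grid.spacing)))
    img.SetOrigin(tuple(reversed(grid.origin)))
    sitk.WriteImage(img, path)


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

def resample_slice_thickness(
    image: VoxelImage,
    new_thickness: float,
    mask: ROIMask | None = None,
):
    """Resample the slice direction (axis 0) to a new thickness in mm.

    In-plane spacing is untouched.  The image is interpolated trilinearly
    (1-D linear along the slice axis, since the other axes are unchanged) and
    the mask, if given, with nearest-neighbour so it stays binary.  The new
    slice count is round(extent / new_thickness), which keeps the covered
    physical extent equal to the input's within one voxel.
    """
    if new_thickness <= 0:
        raise ValueError(f"new_thickness must be > 0, got {new_thickness}")
    if mask is not None:
        mask.check_aligned(image)
    old = image.spacing[0]
    n_old = image.values.shape[0]
    n_new = max(1, int(round(n_old * old / new_thickness)))
    new_spacing = (float(new_thickness), image.spacing[1], image.spacing[2])

    if n_new == n_old and math.isclose(new_thickness, old, rel_tol=1e-12):
        out_img = image.copy_with(image.values.copy())
        out_mask = None if mask is None else ROIMask(mask.values.copy(), mask.spacing, mask.origin)
    else:
        # fractional source indices of the new slice centres (node convention)
        src = np.arange(n_new) * (new_thickness / old)
        src = np.clip(src, 0, n_old - 1)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, n_old - 1)
        w = (src - lo)[:, None, None]
        vals = (1.0 - w) * image.values[lo] + w * image.values[hi]
        out_img = VoxelImage(vals, new_spacing, image.origin)
        out_mask = None
        if mask is not None:
            nn = np.rint(src).astype(int)
            out_mask = ROIMask(mask.values[nn], new_spacing, mask.origin)
    if mask is None:
        return out_img
    return out_img, out_mask


# --------------------------------------------------------------------------
# discretisation
# --------------------------------------------------------------------------

def discretize_fixed_bin_width(intensities: np.ndarray, bin_width: float) -> DiscretizedROI:
    """Discretise ROI intensities to gray levels of fixed width.

    level(x) = floor((x − min)/w) + 1; Ng is the level of the maximum, so the
    maximum always falls in its own top bin (a constant ROI has Ng = 1).
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("cannot discretise an empty ROI")
    if not np.all(np.isfinite(x)):
        raise ValueError("ROI intensities contain non-finite values")
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    roi_min = float(x.min())
    levels = np.floor((x - roi_min) / bin_width).astype(np.int64) + 1
    ng = int(levels.max())
    return DiscretizedROI(levels, ng, float(bin_width), roi_min)


# --------------------------------------------------------------------------
# spherical segmentation
# --------------------------------------------------------------------------

def sphere_radius(volume_mm3: float) -> float:
    """Radius (mm) of a sphere of the given volume."""
    return (3.0 * volume_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def make_spherical_mask(
    grid: GridSpec,
    centre: tuple[float, float, float],
    volume_mm3: float,
) -> ROIMask:
    """Rasterise a sphere of the requested volume as a binary mask.

    A voxel is inside iff its centre lies within the sphere radius of the
    requested centre (mm).  The achieved voxel volume approaches the requested
    volume as spacing shrinks; at 0.26 mm it is within a few percent for the
    standard segmentation volumes.
    """
    if volume_mm3 <= 0:
        raise ValueError(f"volume must be > 0 mm³, got {volume_mm3}")
    r = sphere_radius(volume_mm3)
    coords = [grid.axis_coordinates(a) - centre[a] for a in range(3)]
    d2 = (
        coords[0][:, None, None] ** 2
        + coords[1][None, :, None] ** 2
        + coords[2][None, None, :] ** 2
    )
    inside = d2 <= r * r * (1.0 + 1e-12)  # tolerance guards exact-boundary centres
    if not inside.any():
        raise ValueError(
            f"sphere of {volume_mm3} mm³ (r={r:.3f} mm) contains no voxel centres at "
            f"spacing {grid.spacing}; the minimum representable volume is about "
            f"{grid.voxel_volume:.4f} mm³"
        )
    return ROIMask(inside, grid.spacing, grid.origin)


def mask_bounding_box(mask: ROIMask, pad: int = 0) -> tuple[slice, slice, slice]:
    """Tight bounding-box slices of the mask, optionally padded within bounds."""
    if mask.voxel_count == 0:
        raise ValueError("empty mask has no bounding box")
    slices = ndimage.find_objects(mask.values.astype(np.int8))[0]
    out = []
    for ax, s in enumerate(slices):
        lo = max(0, s.start - pad)
        hi = min(mask.values.shape[ax], s.stop + pad)
        out.append(slice(lo, hi))
    return tuple(out)
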
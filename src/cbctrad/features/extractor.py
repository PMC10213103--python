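"""Feature extraction orchestration.

:func:`extract_all` runs the full pipeline on one image/mask pair; the
:class:`FeatureExtractor` class additionally supports batch extraction of
many ROIs on the same scan (resampling and the wavelet decomposition are then
done once per scan, which is where the time goes).

The default configuration (bin width 25, native 0.26 mm slice spacing,
wavelet on, shape on) yields exactly 842 features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..imaging import ROIMask, VoxelImage, discretize_fixed_bin_width, resample_slice_thickness
from . import names as N
from .firstorder import compute_first_order
from .shape import compute_shape
from .textures import (
    compute_glcm_features,
    compute_gldm_features,
    compute_glrlm_features,
    compute_glszm_features,
    compute_ngtdm_features,
    level_volume,
)
from .wavelet import wavelet_decompose

FeatureVector = dict  # ordered name -> value map


@dataclass(frozen=True)
class ExtractionConfig:
    """Extraction settings.

    ``slice_thickness=None`` keeps the native grid; a value in mm resamples
    the slice direction first (the standard workflow value is 0.26 mm, a
    no-op on the native grid).  ``distance`` is the GLCM offset in voxels and
    ``gldm_alpha`` the GLDM level tolerance.
    """

    bin_width: float = 25.0
    slice_thickness: float | None = None
    wavelet: bool = True
    shape: bool = True
    distance: int = 1
    gldm_alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.slice_thickness is not None and self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be > 0 mm")
        if self.distance < 1:
            raise ValueError("distance must be >= 1 voxel")


class FeatureExtractor:
    def __init__(self, config: ExtractionConfig | None = None):
        self.config = config or ExtractionConfig()

    # -- internals ---------------------------------------------------------

    def _preprocess(self, image: VoxelImage, masks: list[ROIMask]):
        cfg = self.config
        if cfg.slice_thickness is not None and not math.isclose(
            cfg.slice_thickness, image.spacing[0], rel_tol=1e-9
        ):
            image_r = resample_slice_thickness(image, cfg.slice_thickness)
            out_masks = [
                resample_slice_thickness(image, cfg.slice_thickness, m)[1] for m in masks
            ]
            return image_r, out_masks
        return image, masks

    def _intensity_classes(self, values: np.ndarray, mask: ROIMask, voxel_volume: float):
        cfg = self.config
        roi = values[mask.values]
        disc = discretize_fixed_bin_width(roi, cfg.bin_width)
        lev = level_volume(mask, disc)
        ng = disc.n_levels
        return {
            "firstorder": compute_first_order(roi, disc, voxel_volume),
            "glcm": compute_glcm_features(lev, ng, cfg.distance),
            "glrlm": compute_glrlm_features(lev, ng),
            "glszm": compute_glszm_features(lev, ng),
            "gldm": compute_gldm_features(lev, ng, cfg.gldm_alpha),
            "ngtdm": compute_ngtdm_features(lev, ng),
        }

    # -- public API --------------------------------------------------------

    def extract_batch(self, image: VoxelImage, masks: list[ROIMask]) -> list[FeatureVector]:
        """Extract features for several ROIs on the same scan."""
        cfg = self.config
        for m in masks:
            m.check_aligned(image)
            if m.voxel_count == 0:
                raise ValueError("empty mask")
        image, masks = self._preprocess(image, masks)
        bands: dict[str, np.ndarray] = {}
        if cfg.wavelet:
            bands = {k: v.values for k, v in wavelet_decompose(image).items()}
        vv = image.voxel_volume

        out = []
        for mask in masks:
            fv: FeatureVector = {}
            if cfg.shape:
                sh = compute_shape(mask)
                for n in N.SHAPE:
                    fv[f"original_shape_{n}"] = sh[n]
            per_class = self._intensity_classes(image.values, mask, vv)
            for cls in N.INTENSITY_CLASSES:
                for n in N.CLASS_NAMES[cls]:
                    fv[f"original_{cls}_{n}"] = per_class[cls][n]
            for band in N.WAVELET_BANDS if cfg.wavelet else []:
                per_class = self._intensity_classes(bands[band], mask, vv)
                for cls in N.INTENSITY_CLASSES:
                    for n in N.CLASS_NAMES[cls]:
                        fv[f"wavelet-{band}_{cls}_{n}"] = per_class[cls][n]
            out.append(fv)
        return out

    def extract(self, image: VoxelImage, mask: ROIMask) -> FeatureVector:
        return self.extract_batch(image, [mask])[0]


def extract_all(
    image: VoxelImage,
    mask: ROIMask,
    config: ExtractionConfig | None = None,
) -> FeatureVector:
    """Full radiomics extraction for one image/mask pair."""
    return FeatureExtractor(config).extract(image, mask)
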
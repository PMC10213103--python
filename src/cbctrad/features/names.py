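"""Canonical feature inventory.

Feature names follow the ``<filter>_<class>_<feature>`` convention, e.g.
``original_firstorder_Mean`` or ``wavelet-LLH_glcm_Contrast``.  The full
default extraction yields 842 features: 106 on the original image
(14 shape + 18 first order + 23 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM +
5 NGTDM) plus the 6 non-shape classes (92 features) on each of the 8
wavelet sub-bands (8 × 92 = 736).
"""

from itertools import product

SHAPE = [
    "Elongation",
    "Flatness",
    "LeastAxisLength",
    "MajorAxisLength",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "Maximum2DDiameterSlice",
    "Maximum3DDiameter",
    "MeshVolume",
    "MinorAxisLength",
    "Sphericity",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "VoxelVolume",
]

FIRSTORDER = [
    "10Percentile",
    "90Percentile",
    "Energy",
    "Entropy",
    "InterquartileRange",
    "Kurtosis",
    "Maximum",
    "MeanAbsoluteDeviation",
    "Mean",
    "Median",
    "Minimum",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "TotalEnergy",
    "Uniformity",
    "Variance",
]

GLCM = [
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
]

GLRLM = [
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]

GLSZM = [
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
]

GLDM = [
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]

NGTDM = [
    "Busyness",
    "Coarseness",
    "Complexity",
    "Contrast",
    "Strength",
]

CLASS_NAMES = {
    "shape": SHAPE,
    "firstorder": FIRSTORDER,
    "glcm": GLCM,
    "glrlm": GLRLM,
    "glszm": GLSZM,
    "gldm": GLDM,
    "ngtdm": NGTDM,
}

INTENSITY_CLASSES = ["firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm"]

WAVELET_BANDS = ["".join(c) for c in product("LH", repeat=3)]  # LLL ... HHH


def full_inventory(wavelet: bool = True, shape: bool = True) -> list[str]:
    """Ordered list of all feature names for a given configuration."""
    names: list[str] = []
    if shape:
        names += [f"original_shape_{n}" for n in SHAPE]
    for cls in INTENSITY_CLASSES:
        names += [f"original_{cls}_{n}" for n in CLASS_NAMES[cls]]
    if wavelet:
        for band in WAVELET_BANDS:
            for cls in INTENSITY_CLASSES:
                names += [f"wavelet-{band}_{cls}_{n}" for n in CLASS_NAMES[cls]]
    return names
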
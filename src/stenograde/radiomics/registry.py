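"""Frozen roster of the 2D radiomic features.

The roster is fixed so that every image yields the same 465 named values:
18 first-order + 75 texture features (24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM,
14 GLDM), each computed on the original ROI and on the four single-level
wavelet bands — 93 features x 5 image types.

Names follow the ``<image-type>_<family>_<Feature>`` scheme, e.g.
``wavelet-HH_glcm_Contrast``.
"""

from __future__ import annotations

IMAGE_TYPES: tuple[str, ...] = (
    "original",
    "wavelet-LL",
    "wavelet-LH",
    "wavelet-HL",
    "wavelet-HH",
)

FIRST_ORDER: tuple[str, ...] = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)

GLCM: tuple[str, ...] = (
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
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLRLM: tuple[str, ...] = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM: tuple[str, ...] = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

NGTDM: tuple[str, ...] = (
    "Coarseness",
    "Contrast",
    "Busyness",
    "Complexity",
    "Strength",
)

GLDM: tuple[str, ...] = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

TEXTURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "glcm": GLCM,
    "glrlm": GLRLM,
    "glszm": GLSZM,
    "ngtdm": NGTDM,
    "gldm": GLDM,
}

FAMILIES: dict[str, tuple[str, ...]] = {"firstorder": FIRST_ORDER, **TEXTURE_FAMILIES}

#: Features per image type: 18 + 24 + 16 + 16 + 5 + 14 = 93.
N_PER_IMAGE_TYPE = sum(len(v) for v in FAMILIES.values())
#: Texture features per image type: 75.
N_TEXTURE_PER_IMAGE_TYPE = sum(len(v) for v in TEXTURE_FAMILIES.values())
#: Total roster size: 93 x 5 = 465.
N_TOTAL = N_PER_IMAGE_TYPE * len(IMAGE_TYPES)


def feature_names() -> list[str]:
    """The full ordered 465-name roster."""
    return [
        f"{img}_{family}_{feat}"
        for img in IMAGE_TYPES
        for family, feats in FAMILIES.items()
        for feat in feats
    ]
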
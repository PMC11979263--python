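"""2D radiomic feature extraction for ROI images.

465 features per ROI: 18 first-order and 75 texture features (24 GLCM,
16 GLRLM, 16 GLSZM, 5 NGTDM, 14 GLDM), each computed on the original image
and on the four single-level wavelet bands. The extraction mask is the full
ROI rectangle — the pipeline is segmentation-free by design, so no lesion
mask exists. Each image type is re-discretized independently with 25 fixed
bins before its texture matrices are built.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..roi import ROIImage
from . import registry
from .features import first_order_features, texture_features
from .matrices import (
    DiscretizedImage,
    TextureMatrices,
    compute_matrices,
    discretize,
)
from .registry import (
    FAMILIES,
    IMAGE_TYPES,
    N_PER_IMAGE_TYPE,
    N_TEXTURE_PER_IMAGE_TYPE,
    N_TOTAL,
    TEXTURE_FAMILIES,
    feature_names,
)
from .wavelet import wavelet_decompose

__all__ = [
    "registry",
    "feature_names",
    "extract_features",
    "extract_feature_table",
    "wavelet_decompose",
    "discretize",
    "compute_matrices",
    "DiscretizedImage",
    "TextureMatrices",
    "N_TOTAL",
]


def _image_features(img: np.ndarray, image_type: str) -> dict[str, float]:
    disc = discretize(img)
    values = {
        f"{image_type}_firstorder_{k}": v
        for k, v in first_order_features(img, disc).items()
    }
    for family, feats in texture_features(compute_matrices(disc)).items():
        for k, v in feats.items():
            values[f"{image_type}_{family}_{k}"] = v
    return values


def extract_features(roi: ROIImage | np.ndarray) -> dict[str, float]:
    """The full ordered 465-value radiomic vector of one ROI.

    Raises if any feature comes out non-finite, naming the feature and the
    source image.
    """
    if isinstance(roi, ROIImage):
        pixels, source = roi.pixels, roi.source
    else:
        pixels, source = np.asarray(roi, dtype=float), ("?", "?", -1)
    bands = wavelet_decompose(pixels)
    values: dict[str, float] = {}
    for image_type in IMAGE_TYPES:
        img = pixels if image_type == "original" else bands[image_type.split("-")[1]]
        values.update(_image_features(img, image_type))
    assert list(values) == feature_names()
    for name, v in values.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite feature {name} on image {source}")
    return values


def extract_feature_table(rois: list[ROIImage]) -> pd.DataFrame:
    """Feature matrix for a list of ROIs, indexed by (patient, vessel, view)."""
    rows = [extract_features(r) for r in rois]
    index = pd.MultiIndex.from_tuples(
        [r.source for r in rois], names=["patient_id", "vessel_id", "view_index"]
    )
    return pd.DataFrame(rows, index=index)
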
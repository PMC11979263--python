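"""Feature formulas over intensity arrays and texture matrices.

All formulas follow the IBSI-style reference definitions used by the common
radiomics toolchains. Degenerate inputs (constant images, single-level
matrices) resolve to the documented conventional values rather than NaN.
Logarithms are base 2; zero-probability terms are excluded.
"""

from __future__ import annotations

import numpy as np

from .matrices import DiscretizedImage, TextureMatrices
from .registry import FIRST_ORDER, GLCM, GLDM, GLRLM, GLSZM, NGTDM

__all__ = [
    "first_order_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
]


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def first_order_features(
    img: np.ndarray, disc: DiscretizedImage
) -> dict[str, float]:
    x = np.asarray(img, dtype=float).ravel()
    n = x.size
    mean = x.mean()
    var = x.var()  # population variance
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    hist = np.bincount(disc.levels.ravel() - 1, minlength=disc.n_levels)
    p = hist / n
    if var > 0:
        skew = float(((x - mean) ** 3).mean() / var**1.5)
        kurt = float(((x - mean) ** 4).mean() / var**2)  # non-excess
    else:
        skew = kurt = 0.0
    out = {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float((x**2).sum()),  # unit pixel area
        "Entropy": _entropy(p),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": float(var),
        "Uniformity": float((p**2).sum()),
    }
    assert set(out) == set(FIRST_ORDER)
    return out


def glcm_features(p: np.ndarray) -> dict[str, float]:
    """Features of a normalized, symmetric, direction-averaged GLCM."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((px * i).sum())
    mu_y = float((py * i).sum())
    sig_x = float(np.sqrt((px * (i - mu_x) ** 2).sum()))
    sig_y = float(np.sqrt((py * (i - mu_y) ** 2).sum()))

    # diagonal (difference) and cross-diagonal (sum) probabilities
    k_diff = np.arange(ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[ii + jj == k].sum() for k in k_sum])

    diff_avg = float((k_diff * p_diff).sum())
    hxy = _entropy(p.ravel())
    hx = _entropy(px)
    hy = _entropy(py)
    pxpy = np.outer(px, py)
    mask = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[mask] * np.log2(pxpy[mask])).sum())
    m2 = pxpy > 0
    hxy2 = float(-(pxpy[m2] * np.log2(pxpy[m2])).sum())

    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if sig_x > 0 and sig_y > 0:
        corr = float(((p * ii * jj).sum() - mu_x * mu_y) / (sig_x * sig_y))
    else:
        corr = 1.0  # fully homogeneous image

    present = px > 0
    if present.sum() > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            q = (p[np.ix_(present, present)] / px[present, None]) @ (
                p[np.ix_(present, present)] / py[None, present]
            ).T
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eig[-2])))
    else:
        mcc = 1.0

    off = np.abs(ii - jj) > 0
    out = {
        "Autocorrelation": float((p * ii * jj).sum()),
        "ClusterProminence": float((p * (ii + jj - mu_x - mu_y) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - mu_x - mu_y) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - mu_x - mu_y) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _entropy(p_diff),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": float((p[off] / (ii - jj)[off] ** 2).sum()),
        "JointAverage": mu_x,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": _entropy(p_sum),
        "SumSquares": float((p * (ii - mu_x) ** 2).sum()),
    }
    assert set(out) == set(GLCM)
    return out


def _size_weighted(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    ng, ns = mat.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    j = np.arange(1, ns + 1)[None, :].astype(float)
    return i, j, float(mat.sum())


def glrlm_features(mat: np.ndarray, n_pixels: int) -> dict[str, float]:
    i, j, nr = _size_weighted(mat)
    pn = mat / nr
    mu_i = float((pn * i).sum())
    mu_j = float((pn * j).sum())
    out = {
        "ShortRunEmphasis": float((mat / j**2).sum() / nr),
        "LongRunEmphasis": float((mat * j**2).sum() / nr),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float(
            (mat.sum(axis=1) ** 2).sum() / nr**2
        ),
        "RunLengthNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float(
            (mat.sum(axis=0) ** 2).sum() / nr**2
        ),
        "RunPercentage": float(nr / n_pixels),
        "GrayLevelVariance": float((pn * (i - mu_i) ** 2).sum()),
        "RunVariance": float((pn * (j - mu_j) ** 2).sum()),
        "RunEntropy": _entropy(pn.ravel()),
        "LowGrayLevelRunEmphasis": float((mat / i**2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((mat * i**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((mat / (i**2 * j**2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((mat * i**2 / j**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((mat * j**2 / i**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((mat * i**2 * j**2).sum() / nr),
    }
    assert set(out) == set(GLRLM)
    return out


def glszm_features(mat: np.ndarray, n_pixels: int) -> dict[str, float]:
    i, j, nz = _size_weighted(mat)
    pn = mat / nz
    mu_i = float((pn * i).sum())
    mu_j = float((pn * j).sum())
    out = {
        "SmallAreaEmphasis": float((mat / j**2).sum() / nz),
        "LargeAreaEmphasis": float((mat * j**2).sum() / nz),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float(
            (mat.sum(axis=1) ** 2).sum() / nz**2
        ),
        "SizeZoneNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float(
            (mat.sum(axis=0) ** 2).sum() / nz**2
        ),
        "ZonePercentage": float(nz / n_pixels),
        "GrayLevelVariance": float((pn * (i - mu_i) ** 2).sum()),
        "ZoneVariance": float((pn * (j - mu_j) ** 2).sum()),
        "ZoneEntropy": _entropy(pn.ravel()),
        "LowGrayLevelZoneEmphasis": float((mat / i**2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((mat * i**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((mat / (i**2 * j**2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((mat * i**2 / j**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((mat * j**2 / i**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((mat * i**2 * j**2).sum() / nz),
    }
    assert set(out) == set(GLSZM)
    return out


def ngtdm_features(table: np.ndarray, n_pixels: int) -> dict[str, float]:
    n_i = table[:, 0]
    s_i = table[:, 1]
    levels = np.arange(1, table.shape[0] + 1, dtype=float)
    p_i = n_i / n_pixels
    present = p_i > 0
    ngp = int(present.sum())
    p, s, lv = p_i[present], s_i[present], levels[present]

    coarse_den = float((p * s).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        li, lj = np.meshgrid(lv, lv, indexing="ij")
        pi, pj = np.meshgrid(p, p, indexing="ij")
        si, sj = np.meshgrid(s, s, indexing="ij")
        contrast = float(
            (pi * pj * (li - lj) ** 2).sum()
            / (ngp * (ngp - 1))
            * s.sum()
            / n_pixels
        )
        busy_den = float(np.abs(li * pi - lj * pj).sum())
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        complexity = float(
            (np.abs(li - lj) * (pi * si + pj * sj) / (pi + pj)).sum() / n_pixels
        )
        strength = (
            float(((pi + pj) * (li - lj) ** 2).sum() / s.sum())
            if s.sum() > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    out = {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
    assert set(out) == set(NGTDM)
    return out


def gldm_features(mat: np.ndarray, n_pixels: int) -> dict[str, float]:
    i, j, nz = _size_weighted(mat)  # nz == n_pixels by construction
    pn = mat / nz
    mu_i = float((pn * i).sum())
    mu_j = float((pn * j).sum())
    out = {
        "SmallDependenceEmphasis": float((mat / j**2).sum() / nz),
        "LargeDependenceEmphasis": float((mat * j**2).sum() / nz),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nz),
        "DependenceNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float(
            (mat.sum(axis=0) ** 2).sum() / nz**2
        ),
        "GrayLevelVariance": float((pn * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((pn * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": _entropy(pn.ravel()),
        "LowGrayLevelEmphasis": float((mat / i**2).sum() / nz),
        "HighGrayLevelEmphasis": float((mat * i**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(
            (mat / (i**2 * j**2)).sum() / nz
        ),
        "SmallDependenceHighGrayLevelEmphasis": float(
            (mat * i**2 / j**2).sum() / nz
        ),
        "LargeDependenceLowGrayLevelEmphasis": float(
            (mat * j**2 / i**2).sum() / nz
        ),
        "LargeDependenceHighGrayLevelEmphasis": float(
            (mat * i**2 * j**2).sum() / nz
        ),
    }
    assert set(out) == set(GLDM)
    return out


def texture_features(tm: TextureMatrices) -> dict[str, dict[str, float]]:
    """All five texture families from one set of matrices."""
    return {
        "glcm": glcm_features(tm.glcm),
        "glrlm": glrlm_features(tm.glrlm, tm.n_pixels),
        "glszm": glszm_features(tm.glszm, tm.n_pixels),
        "ngtdm": ngtdm_features(tm.ngtdm, tm.n_pixels),
        "gldm": gldm_features(tm.gldm, tm.n_pixels),
    }
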
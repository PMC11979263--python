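"""Gray-level discretization and texture-matrix construction.

Discretization is fixed-bin-count (25 equal-width bins over the image's own
intensity range). Texture matrices follow the reference (IBSI-style) 2D
conventions:

* GLCM / GLRLM: distance 1, four directions (0, 45, 90, 135 degrees); GLCM
  matrices are symmetrized and normalized per direction, then averaged; GLRLM
  count matrices are averaged over directions after padding to a common
  maximum run length.
* GLSZM: zones are 8-connected components of constant level.
* NGTDM: per-level counts and summed absolute differences from the mean of the
  valid 8-neighborhood.
* GLDM: dependence size = 1 + number of 8-neighbors with an identical level
  (alpha = 0), so sizes run 1..9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "N_LEVELS",
    "DiscretizedImage",
    "TextureMatrices",
    "discretize",
    "compute_matrices",
]

N_LEVELS = 25

# (dr, dc) offsets: 0, 45, 90, 135 degrees at distance 1
_GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
_EIGHT_NEIGHBORS = (
    (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)
)
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class DiscretizedImage:
    """Integer gray levels 1..n_levels plus the bin edges that produced them."""

    levels: np.ndarray
    n_levels: int
    bin_edges: np.ndarray


def discretize(img: np.ndarray, n_bins: int = N_LEVELS) -> DiscretizedImage:
    """Fixed-bin-count discretization into levels 1..n_bins.

    Equal-width bins span [min, max]; the maximum-intensity pixel lands in the
    top bin. A zero-range image degenerates to all pixels at level 1.
    """
    img = np.asarray(img, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    if hi - lo <= 0:
        return DiscretizedImage(np.ones(img.shape, dtype=np.int64), n_bins, edges)
    levels = np.floor((img - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
    np.clip(levels, 1, n_bins, out=levels)
    return DiscretizedImage(levels, n_bins, edges)


@dataclass
class TextureMatrices:
    """All five texture matrices for one discretized image.

    glcm is direction-averaged and normalized (sums to 1); glrlm is a
    direction-averaged count matrix; glszm and gldm are count matrices;
    ngtdm holds per-level (count, summed-difference) columns.
    """

    glcm: np.ndarray          # (Ng, Ng), normalized
    glrlm: np.ndarray         # (Ng, max_run)
    glszm: np.ndarray         # (Ng, max_zone)
    ngtdm: np.ndarray         # (Ng, 2): n_i, s_i
    gldm: np.ndarray          # (Ng, 9)
    n_pixels: int


def _glcm(levels: np.ndarray, ng: int) -> np.ndarray:
    acc = np.zeros((ng, ng))
    for dr, dc in _GLCM_OFFSETS:
        a = levels[max(0, -dr) : levels.shape[0] - max(0, dr),
                   max(0, -dc) : levels.shape[1] - max(0, dc)]
        b = levels[max(0, dr) :, max(0, dc) :][: a.shape[0], : a.shape[1]]
        counts = np.bincount(
            ((a - 1) * ng + (b - 1)).ravel(), minlength=ng * ng
        ).reshape(ng, ng).astype(float)
        counts = counts + counts.T  # symmetrize
        total = counts.sum()
        if total > 0:
            acc += counts / total
    return acc / len(_GLCM_OFFSETS)


def _run_lengths(lines: list[np.ndarray], ng: int) -> np.ndarray:
    """Run-length count matrix for a set of 1D level sequences."""
    sep = np.full(1, -1, dtype=np.int64)
    parts: list[np.ndarray] = []
    for line in lines:
        parts.append(np.asarray(line, dtype=np.int64))
        parts.append(sep)
    flat = np.concatenate(parts[:-1]) if parts else np.empty(0, dtype=np.int64)
    if flat.size == 0:
        return np.zeros((ng, 1))
    boundaries = np.flatnonzero(np.diff(flat) != 0)
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries + 1, [flat.size]))
    run_levels = flat[starts]
    run_lengths = ends - starts
    keep = run_levels > 0
    run_levels, run_lengths = run_levels[keep], run_lengths[keep]
    max_run = int(run_lengths.max()) if run_lengths.size else 1
    mat = np.zeros((ng, max_run))
    np.add.at(mat, (run_levels - 1, run_lengths - 1), 1.0)
    return mat


def _glrlm(levels: np.ndarray, ng: int) -> np.ndarray:
    n_rows, n_cols = levels.shape
    direction_lines: list[list[np.ndarray]] = [
        [levels[r] for r in range(n_rows)],                       # 0 deg
        [levels[:, c] for c in range(n_cols)],                    # 90 deg
        [levels.diagonal(k) for k in range(-n_rows + 1, n_cols)], # 45/135 deg
        [np.fliplr(levels).diagonal(k) for k in range(-n_rows + 1, n_cols)],
    ]
    mats = [_run_lengths(lines, ng) for lines in direction_lines]
    width = max(m.shape[1] for m in mats)
    acc = np.zeros((ng, width))
    for m in mats:
        acc[:, : m.shape[1]] += m
    return acc / len(mats)


def _glszm(levels: np.ndarray, ng: int) -> np.ndarray:
    zones: list[tuple[int, int]] = []
    for lv in np.unique(levels):
        labeled, n = ndimage.label(levels == lv, structure=_STRUCT8)
        if n:
            sizes = np.bincount(labeled.ravel())[1:]
            zones.extend((int(lv), int(s)) for s in sizes)
    max_zone = max(s for _, s in zones)
    mat = np.zeros((ng, max_zone))
    for lv, s in zones:
        mat[lv - 1, s - 1] += 1.0
    return mat


def _ngtdm(levels: np.ndarray, ng: int) -> np.ndarray:
    lv = levels.astype(float)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    neighbor_sum = ndimage.correlate(lv, kernel, mode="constant", cval=0.0)
    neighbor_cnt = ndimage.correlate(
        np.ones_like(lv), kernel, mode="constant", cval=0.0
    )
    a_bar = neighbor_sum / neighbor_cnt
    diff = np.abs(lv - a_bar)
    out = np.zeros((ng, 2))
    flat_levels = levels.ravel() - 1
    out[:, 0] = np.bincount(flat_levels, minlength=ng)
    out[:, 1] = np.bincount(flat_levels, weights=diff.ravel(), minlength=ng)
    return out


def _gldm(levels: np.ndarray, ng: int) -> np.ndarray:
    dep = np.zeros(levels.shape, dtype=np.int64)
    for dr, dc in _EIGHT_NEIGHBORS:
        a = levels[max(0, -dr) : levels.shape[0] - max(0, dr),
                   max(0, -dc) : levels.shape[1] - max(0, dc)]
        b = levels[max(0, dr) :, max(0, dc) :][: a.shape[0], : a.shape[1]]
        dep[max(0, -dr) : levels.shape[0] - max(0, dr),
            max(0, -dc) : levels.shape[1] - max(0, dc)] += (a == b)
    size = dep + 1  # center pixel always depends on itself: sizes 1..9
    mat = np.zeros((ng, 9))
    np.add.at(mat, (levels.ravel() - 1, size.ravel() - 1), 1.0)
    return mat


def compute_matrices(d: DiscretizedImage) -> TextureMatrices:
    """All five texture matrices of one discretized image."""
    levels = d.levels
    ng = d.n_levels
    return TextureMatrices(
        glcm=_glcm(levels, ng),
        glrlm=_glrlm(levels, ng),
        glszm=_glszm(levels, ng),
        ngtdm=_ngtdm(levels, ng),
        gldm=_gldm(levels, ng),
        n_pixels=int(levels.size),
    )
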
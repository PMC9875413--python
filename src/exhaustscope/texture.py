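"""3D gray-level co-occurrence and run-length texture analysis.

Texture features operate on a *labeled ROI grid*: the scan discretized to
integer gray levels 1..n inside the mask, with 0 outside. Discretization
is fixed-bin-count over the ROI min–max, which makes every downstream
texture statistic invariant to positive affine rescaling of the ROI
intensities.

Both matrix types aggregate over the 13 unique 3D neighbor directions
(unique up to negation) at a configurable distance; GLCM is symmetrized
(each ordered pair counted both ways), matrices are summed over
directions before normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiscretizationConfig",
    "TextureConfig",
    "DegenerateTextureError",
    "DIRECTIONS_13",
    "discretize",
    "glcm",
    "glcm_features",
    "glrlm",
    "glrlm_features",
]

#: the 13 unique 3D neighbor offsets (z, y, x), non-redundant under negation
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1),
    (1, 0, 1), (1, 0, -1),
    (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


class DegenerateTextureError(ValueError):
    """Too few in-mask neighbor pairs to form a texture matrix."""


@dataclass(frozen=True)
class DiscretizationConfig:
    """Fixed-bin-count discretization over the ROI min–max range."""

    n_levels: int = 64

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")


@dataclass(frozen=True)
class TextureConfig:
    """Neighborhood definition for GLCM/GLRLM.

    ``distance`` is the offset length in voxels along each direction;
    ``directions`` default to the 13 unique 3D neighbors; GLCM is
    symmetric and matrices are averaged by summation over directions
    before normalization.
    """

    distance: int = 1
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        seen = set()
        for d in self.directions:
            if d in seen or tuple(-c for c in d) in seen:
                raise ValueError(f"direction {d} is redundant under negation")
            seen.add(d)


def discretize(
    values: np.ndarray, mask: np.ndarray, cfg: DiscretizationConfig = DiscretizationConfig()
) -> np.ndarray:
    """Map ROI voxels to integer gray levels 1..n_levels; 0 outside the mask.

    Equal-width bins span [roi_min, roi_max]; the maximum maps to
    ``n_levels``; a constant ROI maps entirely to level 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    vals = np.asarray(values, dtype=np.float64)
    roi = vals[mask]
    lo, hi = float(roi.min()), float(roi.max())
    labeled = np.zeros(vals.shape, dtype=np.int32)
    if hi == lo:
        labeled[mask] = 1
        return labeled
    n = cfg.n_levels
    lev = np.floor((vals[mask] - lo) / (hi - lo) * n).astype(np.int32) + 1
    labeled[mask] = np.clip(lev, 1, n)
    return labeled


def _crop_to_mask(labeled: np.ndarray) -> np.ndarray:
    nz = np.nonzero(labeled)
    if len(nz[0]) == 0:
        raise ValueError("empty labeled grid")
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in nz)
    return labeled[sl]


def _pair_slices(shape, offset):
    src, dst = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def glcm(labeled: np.ndarray, cfg: TextureConfig = TextureConfig()) -> np.ndarray:
    """Normalized gray-level co-occurrence matrix, aggregated over directions.

    Counts level pairs at offset ``distance * direction`` with both voxels
    inside the mask, counts each ordered pair in both directions
    (symmetric), sums over all configured directions and normalizes to
    total mass 1. Matrix indices are 0-based for levels 1..n.
    """
    labeled = _crop_to_mask(np.asarray(labeled))
    n = int(labeled.max())
    counts = np.zeros((n, n), dtype=np.float64)
    for d in cfg.directions:
        offset = tuple(int(c) * cfg.distance for c in d)
        src, dst = _pair_slices(labeled.shape, offset)
        a = labeled[src].ravel()
        b = labeled[dst].ravel()
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        idx = (a[ok] - 1) * n + (b[ok] - 1)
        binned = np.bincount(idx, minlength=n * n).reshape(n, n)
        counts += binned
        if cfg.symmetric:
            counts += binned.T
    total = counts.sum()
    if total < 2:
        raise DegenerateTextureError("fewer than 2 in-mask neighbor pairs")
    return counts / total


def _check_normalized(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("co-occurrence matrix must be square")
    if not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError(f"co-occurrence matrix must sum to 1, got {P.sum():.6g}")
    return P


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """Haralick-style statistics of a normalized co-occurrence matrix.

    Degenerate policies keep every value finite: Correlation and the two
    information measures of correlation are 0 when their denominators
    vanish, and InverseVariance — a sum over off-diagonal entries only —
    is 0 for a purely diagonal matrix (the limit of vanishing
    off-diagonal mass).
    """
    P = _check_normalized(P)
    n = P.shape[0]
    i, j = np.mgrid[1 : n + 1, 1 : n + 1]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    levels = np.arange(1, n + 1)
    mu_x = float(levels @ px)
    mu_y = float(levels @ py)
    sd_x = float(np.sqrt(((levels - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((levels - mu_y) ** 2) @ py))

    diff = np.abs(i - j)
    s = i + j
    # p_{x-y}(k), k = 0..n-1 and p_{x+y}(k), k = 2..2n
    p_diff = np.bincount(diff.ravel(), weights=P.ravel(), minlength=n)
    p_sum = np.bincount(s.ravel(), weights=P.ravel(), minlength=2 * n + 1)[2:]
    k_diff = np.arange(n)
    k_sum = np.arange(2, 2 * n + 1)

    contrast = float(((i - j) ** 2 * P).sum())
    dissimilarity = float((diff * P).sum())
    homogeneity = float((P / (1.0 + diff)).sum())
    homogeneity2 = float((P / (1.0 + (i - j) ** 2)).sum())
    off = diff > 0
    inverse_variance = float((P[off] / (i - j)[off] ** 2).sum()) if off.any() else 0.0

    autocorr = float((i * j * P).sum())
    cdev = s - mu_x - mu_y
    cluster_tendency = float((cdev**2 * P).sum())
    cluster_shade = float((cdev**3 * P).sum())
    cluster_prominence = float((cdev**4 * P).sum())
    correlation = (
        (autocorr - mu_x * mu_y) / (sd_x * sd_y) if sd_x > 0 and sd_y > 0 else 0.0
    )

    energy = float((P**2).sum())
    entropy = _entropy(P.ravel())
    diff_avg = float(k_diff @ p_diff)
    diff_var = float(((k_diff - diff_avg) ** 2) @ p_diff)
    diff_entropy = _entropy(p_diff)
    sum_avg = float(k_sum @ p_sum)
    sum_var = float(((k_sum - sum_avg) ** 2) @ p_sum)
    sum_entropy = _entropy(p_sum)

    hx, hy = _entropy(px), _entropy(py)
    outer = np.outer(px, py)
    pos = (P > 0) & (outer > 0)
    hxy1 = float(-(P[pos] * np.log2(outer[pos])).sum())
    pos2 = outer > 0
    hxy2 = float(-(outer[pos2] * np.log2(outer[pos2])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return {
        "AutoCorrelation": autocorr,
        "ClusterProminence": cluster_prominence,
        "ClusterShade": cluster_shade,
        "ClusterTendency": cluster_tendency,
        "Contrast": contrast,
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": diff_entropy,
        "DifferenceVariance": diff_var,
        "Dissimilarity": dissimilarity,
        "Energy": energy,
        "Entropy": entropy,
        "Homogeneity": homogeneity,
        "Homogeneity2": homogeneity2,
        "InformationMeasureCorr1": imc1,
        "InformationMeasureCorr2": imc2,
        "InverseVariance": inverse_variance,
        "MaxProbability": float(P.max()),
        "SumAverage": sum_avg,
        "SumEntropy": sum_entropy,
        "SumVariance": sum_var,
    }


def glrlm(labeled: np.ndarray, cfg: TextureConfig = TextureConfig()) -> np.ndarray:
    """Gray-level run-length matrix summed over the configured directions.

    Entry (g-1, l-1) counts maximal runs of ``l`` consecutive voxels of
    level ``g`` along a direction; out-of-mask voxels (level 0) break
    runs. Returned as raw counts of shape (n_levels, max_run_length).
    """
    labeled = _crop_to_mask(np.asarray(labeled))
    n = int(labeled.max())
    max_len = int(max(labeled.shape) * 2)  # diagonal runs can exceed one axis
    R = np.zeros((n, max_len), dtype=np.float64)

    coords = np.indices(labeled.shape).reshape(3, -1)
    lab = labeled.ravel()
    for d in cfg.directions:
        dz, dy, dx = d
        c0, c1, c2 = coords
        # voxels share a line iff their coordinate difference is parallel
        # to d: the three pairwise cross terms are line invariants
        u = c0 * dy - c1 * dz
        v = c0 * dx - c2 * dz
        w = c1 * dx - c2 * dy
        t = c0 * dz + c1 * dy + c2 * dx
        step = dz * dz + dy * dy + dx * dx  # t-increment between consecutive voxels
        order = np.lexsort((t, w, v, u))
        lab_s = lab[order]
        u_s, v_s, w_s, t_s = u[order], v[order], w[order], t[order]
        # run boundary: new line, non-consecutive position, or level change
        new_line = np.empty(lab_s.shape, dtype=bool)
        new_line[0] = True
        new_line[1:] = (
            (u_s[1:] != u_s[:-1])
            | (v_s[1:] != v_s[:-1])
            | (w_s[1:] != w_s[:-1])
            | (t_s[1:] != t_s[:-1] + step)
            | (lab_s[1:] != lab_s[:-1])
        )
        starts = np.flatnonzero(new_line)
        lengths = np.diff(np.append(starts, lab_s.size))
        run_levels = lab_s[starts]
        keep = run_levels > 0
        np.add.at(R, (run_levels[keep] - 1, lengths[keep] - 1), 1.0)
    if R.sum() < 1:
        raise DegenerateTextureError("no in-mask runs")
    return R[:, : int(np.flatnonzero(R.any(axis=0)).max()) + 1]


def glrlm_features(
    labeled: np.ndarray, cfg: TextureConfig = TextureConfig()
) -> dict[str, float]:
    """Standard run-length statistics of the direction-aggregated GLRLM.

    Run percentage is the number of runs divided by the number of voxel
    observations (in-mask voxels times directions).
    """
    labeled_c = _crop_to_mask(np.asarray(labeled))
    R = glrlm(labeled_c, cfg)
    n_g, n_l = R.shape
    g = np.arange(1, n_g + 1)[:, None].astype(float)
    l = np.arange(1, n_l + 1)[None, :].astype(float)
    n_runs = R.sum()
    n_obs = float((labeled_c > 0).sum()) * len(cfg.directions)

    return {
        "ShortRunEmphasis": float((R / l**2).sum() / n_runs),
        "LongRunEmphasis": float((R * l**2).sum() / n_runs),
        "GrayLevelNonuniformity": float((R.sum(axis=1) ** 2).sum() / n_runs),
        "RunLengthNonuniformity": float((R.sum(axis=0) ** 2).sum() / n_runs),
        "RunPercentage": float(n_runs / n_obs),
        "LowGrayLevelRunEmphasis": float((R / g**2).sum() / n_runs),
        "HighGrayLevelRunEmphasis": float((R * g**2).sum() / n_runs),
        "ShortRunLowGrayLevelEmphasis": float((R / (g**2 * l**2)).sum() / n_runs),
        "ShortRunHighGrayLevelEmphasis": float((R * g**2 / l**2).sum() / n_runs),
        "LongRunLowGrayLevelEmphasis": float((R * l**2 / g**2).sum() / n_runs),
        "LongRunHighGrayLevelEmphasis": float((R * g**2 * l**2).sum() / n_runs),
    }
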
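"""Intensity, shape and texture feature definitions.

All texture families operate on a gray-level volume discretized with a fixed
bin width.  Texture matrices are computed in 3-D: the co-occurrence and
run-length families use the 13 unique voxel directions (symmetric pairs
merged into a single matrix before feature computation); the size-zone,
neighborhood gray-tone difference and dependence families use the full
26-voxel neighborhood.  Degenerate cases (single gray level, zero variance)
return the documented guard values instead of NaN so that downstream feature
tables stay finite.

Feature bases per class (the union over classes, crossed with the image
types of the extraction profile, generates the complete feature-name set):

* firstorder: 18   * shape: 14    * glcm: 24    * glrlm: 16
* glszm: 16        * ngtdm: 5     * gldm: 14
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "FIRSTORDER_FEATURES",
    "SHAPE_FEATURES",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "NGTDM_FEATURES",
    "GLDM_FEATURES",
    "CLASS_FEATURES",
    "discretize",
    "firstorder_features",
    "shape_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
]

_EPS = np.spacing(1.0)

# 13 unique direction vectors (half of the 26-neighborhood)
DIRECTIONS_13 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]
OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]

FIRSTORDER_FEATURES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)
SHAPE_FEATURES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)
GLCM_FEATURES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_FEATURES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLSZM_FEATURES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
NGTDM_FEATURES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")
GLDM_FEATURES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)
CLASS_FEATURES = {
    "firstorder": FIRSTORDER_FEATURES,
    "shape": SHAPE_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
    "gldm": GLDM_FEATURES,
}


def discretize(image: np.ndarray, mask: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width discretization of masked voxels to levels 1..Ng.

    Bin edges are aligned to multiples of the bin width, so two VOIs sharing
    the same intensity scale fall into directly comparable levels.  Returns an
    integer array (0 outside the mask).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    gl = np.zeros(image.shape, dtype=np.int64)
    vals = image[mask]
    low = np.floor(vals.min() / bin_width)
    idx = np.floor(vals / bin_width) - low + 1
    gl[mask] = idx.astype(np.int64)
    return gl


# ---------------------------------------------------------------------------
# first order


def firstorder_features(values: np.ndarray, bin_width: float, voxel_volume: float) -> dict:
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    mean = x.mean()
    var = x.var()  # population variance
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    # binned probabilities for entropy/uniformity
    lo = np.floor(x.min() / bin_width)
    counts = np.bincount((np.floor(x / bin_width) - lo).astype(np.int64))
    p = counts[counts > 0] / n
    if var > 0:
        m = x - mean
        skew = np.mean(m**3) / var**1.5
        kurt = np.mean(m**4) / var**2
    else:
        skew, kurt = 0.0, 0.0
    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean())))
        if robust.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(var),
        "Uniformity": float(np.sum(p**2)),
    }


# ---------------------------------------------------------------------------
# shape


def _max_pairwise_distance(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    pts = points
    if len(pts) > 64:
        try:
            from scipy.spatial import ConvexHull

            hull = ConvexHull(pts, qhull_options="QJ")
            pts = pts[hull.vertices]
        except Exception:
            pass  # degenerate geometry: fall back to all points
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def shape_features(mask: np.ndarray, spacing) -> dict:
    """Shape descriptors of the binary VOI (independent of intensities).

    The mesh volume/area come from a marching-cubes surface of the mask;
    axis lengths from a principal-component decomposition of the voxel
    center coordinates.  The three 2-D diameters are the largest in-plane
    surface distances with the slice (z), column (x) and row (y) axis held
    fixed, respectively.
    """
    from skimage import measure

    mask = np.asarray(mask) > 0
    spacing = np.asarray(spacing, dtype=float)  # (z, y, x) in mm
    voxel_volume = float(np.prod(spacing))
    n_vox = int(mask.sum())

    padded = np.pad(mask.astype(np.uint8), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    surface_area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    mesh_volume = float(abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)

    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area

    # surface voxels in mm coordinates
    eroded = ndimage.binary_erosion(mask)
    surf = mask & ~eroded
    coords = np.argwhere(surf) * spacing
    max3d = _max_pairwise_distance(coords)

    surf_idx = np.argwhere(surf)

    def _planar(axis: int, keep: tuple[int, int]) -> float:
        best = 0.0
        for plane in np.unique(surf_idx[:, axis]):
            pts = surf_idx[surf_idx[:, axis] == plane][:, keep] * spacing[list(keep)]
            best = max(best, _max_pairwise_distance(pts))
        return best

    max2d_slice = _planar(0, (1, 2))   # fixed z: axial plane
    max2d_column = _planar(2, (0, 1))  # fixed x
    max2d_row = _planar(1, (0, 2))     # fixed y

    centers = np.argwhere(mask) * spacing
    if len(centers) > 1:
        eig = np.sort(np.linalg.eigvalsh(np.cov(centers.T)))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": n_vox * voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": max2d_slice,
        "Maximum2DDiameterColumn": max2d_column,
        "Maximum2DDiameterRow": max2d_row,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elongation,
        "Flatness": flatness,
    }


# ---------------------------------------------------------------------------
# co-occurrence (GLCM)


def _shift_pairs(gl: np.ndarray, offset):
    """Index slices of voxel pairs separated by ``offset`` (both in mask)."""
    sl_a, sl_b = [], []
    for d, size in zip(offset, gl.shape):
        if d >= 0:
            sl_a.append(slice(0, size - d))
            sl_b.append(slice(d, size))
        else:
            sl_a.append(slice(-d, size))
            sl_b.append(slice(0, size + d))
    a = gl[tuple(sl_a)]
    b = gl[tuple(sl_b)]
    valid = (a > 0) & (b > 0)
    return a[valid], b[valid]


def glcm_matrix(gl: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence matrix merged over the 13 directions."""
    P = np.zeros((n_levels, n_levels), dtype=float)
    for off in DIRECTIONS_13:
        a, b = _shift_pairs(gl, off)
        if a.size:
            np.add.at(P, (a - 1, b - 1), 1.0)
            np.add.at(P, (b - 1, a - 1), 1.0)
    return P


def glcm_features(gl: np.ndarray, n_levels: int) -> dict:
    P = glcm_matrix(gl, n_levels)
    total = P.sum()
    if total == 0:  # single voxel VOI: no pairs at all
        return {k: 0.0 for k in GLCM_FEATURES}
    p = P / total
    Ng = n_levels
    i = np.arange(1, Ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)  # == px by symmetry
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    var_x = float(np.sum((i - mu_x) ** 2 * px))
    var_y = float(np.sum((i - mu_y) ** 2 * py))

    # p_{x+y}: k = 2..2Ng ; p_{x-y}: k = 0..Ng-1
    ks_sum = np.arange(2, 2 * Ng + 1, dtype=float)
    p_sum = np.zeros(2 * Ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    ks_diff = np.arange(0, Ng, dtype=float)
    p_diff = np.zeros(Ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    diff_avg = float(np.sum(ks_diff * p_diff))
    nz = p > 0
    hxy = float(-np.sum(p[nz] * np.log2(p[nz])))
    pxpy = np.outer(px, py)
    nzo = (pxpy > 0) & nz
    hxy1 = float(-np.sum(p[nzo] * np.log2(pxpy[nzo])))
    nzp = pxpy > 0
    hxy2 = float(-np.sum(pxpy[nzp] * np.log2(pxpy[nzp])))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0])))

    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    autocorr = float(np.sum(ii * jj * p))
    if var_x > 0 and var_y > 0:
        correlation = (autocorr - mu_x * mu_y) / np.sqrt(var_x * var_y)
    else:
        correlation = 1.0  # constant VOI: perfectly predictable neighbors

    # MCC: second-largest eigenvalue of Q
    if Ng > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = px[:, None] * py[None, :]
            W = np.where(denom > 0, p / np.where(denom > 0, denom, 1.0), 0.0)
        Q = W @ p.T
        eig = np.sort(np.abs(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, eig[-2]))) if eig.size >= 2 else 1.0
    else:
        mcc = 1.0

    off_diag = np.abs(ii - jj) > 0
    inv_var = float(np.sum(p[off_diag] / (ii - jj)[off_diag] ** 2))

    nzs = p_sum > 0
    nzd = p_diff > 0
    return {
        "Autocorrelation": autocorr,
        "ClusterProminence": float(np.sum((ii + jj - mu_x - mu_y) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - mu_x - mu_y) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - mu_x - mu_y) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-np.sum(p_diff[nzd] * np.log2(p_diff[nzd]))),
        "DifferenceVariance": float(np.sum((ks_diff - diff_avg) ** 2 * p_diff)),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / Ng) ** 2))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / Ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu_x,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(ks_sum * p_sum)),
        "SumEntropy": float(-np.sum(p_sum[nzs] * np.log2(p_sum[nzs]))),
        "SumSquares": float(np.sum((ii - mu_x) ** 2 * p)),
    }


# ---------------------------------------------------------------------------
# run length (GLRLM)


def glrlm_matrix(gl: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length matrix merged over the 13 directions.

    Entry (i, l) counts maximal runs of gray level i+1 with length l+1 along
    any of the 13 directions.
    """
    max_len = int(max(gl.shape))
    P = np.zeros((n_levels, max_len), dtype=float)
    coords = np.argwhere(gl > 0)
    coord_set = {tuple(c) for c in coords}
    levels = {tuple(c): int(gl[tuple(c)]) for c in coords}
    for off in DIRECTIONS_13:
        for c in coord_set:
            prev = (c[0] - off[0], c[1] - off[1], c[2] - off[2])
            if prev in coord_set and levels[prev] == levels[c]:
                continue  # not a run start
            length = 1
            nxt = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            while nxt in coord_set and levels[nxt] == levels[c]:
                length += 1
                nxt = (nxt[0] + off[0], nxt[1] + off[1], nxt[2] + off[2])
            P[levels[c] - 1, length - 1] += 1.0
    return P


def _size_weighted_features(P: np.ndarray, n_voxels: int, prefix: dict) -> dict:
    """Shared gray-level x size structure of the GLRLM/GLSZM/GLDM families.

    ``prefix`` maps the family-specific metric names onto the generic terms.
    """
    Ns = P.sum()
    if Ns == 0:
        return {name: 0.0 for name in prefix.values()}
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    s = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    p = P / Ns
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    mu_i = np.sum(p * i)
    mu_s = np.sum(p * s)
    nz = p > 0
    out = {
        "small": np.sum(P / s**2) / Ns,
        "large": np.sum(P * s**2) / Ns,
        "low": np.sum(P / i**2) / Ns,
        "high": np.sum(P * i**2) / Ns,
        "small_low": np.sum(P / (i**2 * s**2)) / Ns,
        "small_high": np.sum(P * i**2 / s**2) / Ns,
        "large_low": np.sum(P * s**2 / i**2) / Ns,
        "large_high": np.sum(P * i**2 * s**2) / Ns,
        "gln": np.sum(pg**2) / Ns,
        "glnn": np.sum(pg**2) / Ns**2,
        "sn": np.sum(ps**2) / Ns,
        "snn": np.sum(ps**2) / Ns**2,
        "gl_var": np.sum(p * (i - mu_i) ** 2),
        "s_var": np.sum(p * (s - mu_s) ** 2),
        "entropy": -np.sum(p[nz] * np.log2(p[nz])),
        "percentage": Ns / n_voxels,
    }
    return {name: float(out[key]) for key, name in prefix.items()}


def glrlm_features(gl: np.ndarray, n_levels: int) -> dict:
    mask_n = int((gl > 0).sum())
    P = glrlm_matrix(gl, n_levels)
    feats = _size_weighted_features(
        P,
        mask_n * len(DIRECTIONS_13),  # one run per voxel per direction at most
        {
            "small": "ShortRunEmphasis",
            "large": "LongRunEmphasis",
            "low": "LowGrayLevelRunEmphasis",
            "high": "HighGrayLevelRunEmphasis",
            "small_low": "ShortRunLowGrayLevelEmphasis",
            "small_high": "ShortRunHighGrayLevelEmphasis",
            "large_low": "LongRunLowGrayLevelEmphasis",
            "large_high": "LongRunHighGrayLevelEmphasis",
            "gln": "GrayLevelNonUniformity",
            "glnn": "GrayLevelNonUniformityNormalized",
            "sn": "RunLengthNonUniformity",
            "snn": "RunLengthNonUniformityNormalized",
            "gl_var": "GrayLevelVariance",
            "s_var": "RunVariance",
            "entropy": "RunEntropy",
            "percentage": "RunPercentage",
        },
    )
    return feats


# ---------------------------------------------------------------------------
# size zone (GLSZM)


def glszm_matrix(gl: np.ndarray, n_levels: int) -> np.ndarray:
    structure = np.ones((3, 3, 3), dtype=int)  # 26-connectivity
    max_zone = int((gl > 0).sum())
    P = np.zeros((n_levels, max_zone), dtype=float)
    for level in np.unique(gl[gl > 0]):
        labeled, n_zones = ndimage.label(gl == level, structure=structure)
        if n_zones:
            sizes = np.bincount(labeled.ravel())[1:]
            for size in sizes:
                P[level - 1, size - 1] += 1.0
    return P


def glszm_features(gl: np.ndarray, n_levels: int) -> dict:
    mask_n = int((gl > 0).sum())
    P = glszm_matrix(gl, n_levels)
    return _size_weighted_features(
        P,
        mask_n,
        {
            "small": "SmallAreaEmphasis",
            "large": "LargeAreaEmphasis",
            "low": "LowGrayLevelZoneEmphasis",
            "high": "HighGrayLevelZoneEmphasis",
            "small_low": "SmallAreaLowGrayLevelEmphasis",
            "small_high": "SmallAreaHighGrayLevelEmphasis",
            "large_low": "LargeAreaLowGrayLevelEmphasis",
            "large_high": "LargeAreaHighGrayLevelEmphasis",
            "gln": "GrayLevelNonUniformity",
            "glnn": "GrayLevelNonUniformityNormalized",
            "sn": "SizeZoneNonUniformity",
            "snn": "SizeZoneNonUniformityNormalized",
            "gl_var": "GrayLevelVariance",
            "s_var": "ZoneVariance",
            "entropy": "ZoneEntropy",
            "percentage": "ZonePercentage",
        },
    )


# ---------------------------------------------------------------------------
# neighborhood statistics shared by NGTDM and GLDM


def _neighbor_stats(gl: np.ndarray):
    """Per-voxel neighbor sum, neighbor count and same-level neighbor count."""
    mask = gl > 0
    nb_sum = np.zeros(gl.shape, dtype=float)
    nb_cnt = np.zeros(gl.shape, dtype=float)
    nb_same = np.zeros(gl.shape, dtype=float)
    for off in OFFSETS_26:
        sl_a, sl_b = [], []
        for d, size in zip(off, gl.shape):
            if d >= 0:
                sl_a.append(slice(0, size - d))
                sl_b.append(slice(d, size))
            else:
                sl_a.append(slice(-d, size))
                sl_b.append(slice(0, size + d))
        a, b = tuple(sl_a), tuple(sl_b)
        valid = mask[a] & mask[b]
        nb_sum[a][...] += np.where(valid, gl[b], 0)
        nb_cnt[a][...] += valid
        nb_same[a][...] += valid & (gl[a] == gl[b])
    return nb_sum, nb_cnt, nb_same


def ngtdm_features(gl: np.ndarray, n_levels: int) -> dict:
    mask = gl > 0
    nb_sum, nb_cnt, _ = _neighbor_stats(gl)
    has_nb = mask & (nb_cnt > 0)
    nvp = int(has_nb.sum())
    if nvp == 0:
        return {k: 0.0 for k in NGTDM_FEATURES}
    levels = gl[has_nb]
    abar = nb_sum[has_nb] / nb_cnt[has_nb]
    diff = np.abs(levels - abar)

    n_i = np.bincount(levels - 1, minlength=n_levels).astype(float)
    s_i = np.bincount(levels - 1, weights=diff, minlength=n_levels)
    p_i = n_i / nvp
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, n_levels + 1, dtype=float)

    sum_ps = float(np.sum(p_i * s_i))
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6

    if ngp > 1:
        pi_, pj_ = np.meshgrid(p_i, p_i, indexing="ij")
        ii, jj = np.meshgrid(i, i, indexing="ij")
        contrast = (
            np.sum(pi_ * pj_ * (ii - jj) ** 2) / (ngp * (ngp - 1))
        ) * (s_i.sum() / nvp)
        ipi = i * p_i
        busy_den = np.sum(
            np.abs(ipi[present][:, None] - ipi[present][None, :])
        )
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        pv, iv, sv = p_i[present], i[present], s_i[present]
        pii, pjj = np.meshgrid(pv, pv, indexing="ij")
        iii, ijj = np.meshgrid(iv, iv, indexing="ij")
        sii, sjj = np.meshgrid(sv, sv, indexing="ij")
        complexity = float(
            np.sum(np.abs(iii - ijj) * (pii * sii + pjj * sjj) / (pii + pjj)) / nvp
        )
        strength_num = float(np.sum((pii + pjj) * (iii - ijj) ** 2))
        strength = strength_num / s_i.sum() if s_i.sum() > 0 else 0.0
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0

    return {
        "Busyness": float(busyness),
        "Coarseness": float(coarseness),
        "Complexity": float(complexity),
        "Contrast": float(contrast),
        "Strength": float(strength),
    }


def gldm_features(gl: np.ndarray, n_levels: int) -> dict:
    """Gray-level dependence features.

    The dependence of a voxel is 1 + the number of 26-neighbors inside the
    mask with the same discretized level (dependence tolerance alpha = 0);
    the +1 counts the voxel itself so every voxel contributes a dependence.
    """
    mask = gl > 0
    _, _, nb_same = _neighbor_stats(gl)
    dep = (nb_same[mask] + 1).astype(int)
    levels = gl[mask]
    P = np.zeros((n_levels, 27), dtype=float)
    np.add.at(P, (levels - 1, dep - 1), 1.0)
    return _size_weighted_features(
        P,
        int(mask.sum()),
        {
            "small": "SmallDependenceEmphasis",
            "large": "LargeDependenceEmphasis",
            "low": "LowGrayLevelEmphasis",
            "high": "HighGrayLevelEmphasis",
            "small_low": "SmallDependenceLowGrayLevelEmphasis",
            "small_high": "SmallDependenceHighGrayLevelEmphasis",
            "large_low": "LargeDependenceLowGrayLevelEmphasis",
            "large_high": "LargeDependenceHighGrayLevelEmphasis",
            "gln": "GrayLevelNonUniformity",
            "gl_var": "GrayLevelVariance",
            "s_var": "DependenceVariance",
            "entropy": "DependenceEntropy",
            "sn": "DependenceNonUniformity",
            "snn": "DependenceNonUniformityNormalized",
        },
    )
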
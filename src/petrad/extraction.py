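"""Feature-extraction profile and the extraction pipeline.

The pipeline mirrors a standard radiomics preprocessing chain:

1. intensity normalization of the whole volume (z-score, times a scale),
2. resampling to isotropic voxels with a B-spline interpolator (the mask is
   resampled with nearest-neighbor),
3. image filtering: Laplacian-of-Gaussian at a list of sigma scales (mm) and
   a single-level undecimated coif1 wavelet decomposition into its eight
   sub-bands,
4. fixed-bin-width discretization per derived image, then feature
   computation per feature class.

Under the reference profile (bin width 0.25, 2x2x2 mm voxels, ten LoG sigmas
0.5-5.0 mm, coif1 wavelet) the emitted feature vector has 1781 entries:
107 from the original image (14 shape + 93 intensity/texture), 930 from the
ten LoG scales and 744 from the eight wavelet bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import SUVVolume, VOIMask
from .names import FeatureName
from . import texture

__all__ = [
    "ExtractionConfig",
    "reference_config",
    "WAVELET_BANDS",
    "reference_feature_names",
    "extract_features",
    "extract_table",
]

#: wavelet sub-band labels; letters are the low/high-pass choice applied
#: along the (z, y, x) axes in that order
WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

_INTERPOLATORS = ("sitkBSpline", "sitkLinear", "sitkNearestNeighbor")


@dataclass
class ExtractionConfig:
    """Extraction profile; defaults reproduce the reference configuration."""

    bin_width: float = 0.25
    resampled_spacing: tuple[float, float, float] | None = (2.0, 2.0, 2.0)
    interpolator: str = "sitkBSpline"
    wavelet: str = "coif1"
    log_sigmas: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)
    normalize: bool = True
    normalize_scale: float = 1.0
    image_types: tuple[str, ...] = ("original", "log", "wavelet")

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        if self.interpolator not in _INTERPOLATORS:
            raise ValueError(
                f"unknown interpolator {self.interpolator!r}; one of {_INTERPOLATORS}"
            )

    def to_dict(self) -> dict:
        """Flat key/value document using the conventional setting tokens."""
        return {
            "binWidth": self.bin_width,
            "resampledPixelSpacing": list(self.resampled_spacing)
            if self.resampled_spacing
            else None,
            "interpolator": self.interpolator,
            "wavelet": self.wavelet,
            "sigma": list(self.log_sigmas),
            "normalize": self.normalize,
            "normalizeScale": self.normalize_scale,
            "imageTypes": list(self.image_types),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExtractionConfig":
        return cls(
            bin_width=d.get("binWidth", 0.25),
            resampled_spacing=tuple(d["resampledPixelSpacing"])
            if d.get("resampledPixelSpacing")
            else None,
            interpolator=d.get("interpolator", "sitkBSpline"),
            wavelet=d.get("wavelet", "coif1"),
            log_sigmas=tuple(d.get("sigma", ())),
            normalize=d.get("normalize", True),
            normalize_scale=d.get("normalizeScale", 1.0),
            image_types=tuple(d.get("imageTypes", ("original", "log", "wavelet"))),
        )


def reference_config() -> ExtractionConfig:
    """The reference extraction profile (1781 features)."""
    return ExtractionConfig()


def reference_feature_names(config: ExtractionConfig | None = None) -> list[str]:
    """Enumerate the canonical feature names the profile will emit, in order."""
    config = config or reference_config()
    nonshape = [c for c in texture.CLASS_FEATURES if c != "shape"]
    out: list[str] = []
    if "original" in config.image_types:
        for base in texture.SHAPE_FEATURES:
            out.append(FeatureName("original", "shape", base).canonical())
        for cls in nonshape:
            for base in texture.CLASS_FEATURES[cls]:
                out.append(FeatureName("original", cls, base).canonical())
    if "log" in config.image_types:
        for sigma in config.log_sigmas:
            for cls in nonshape:
                for base in texture.CLASS_FEATURES[cls]:
                    out.append(FeatureName.for_log(sigma, cls, base).canonical())
    if "wavelet" in config.image_types:
        for band in WAVELET_BANDS:
            for cls in nonshape:
                for base in texture.CLASS_FEATURES[cls]:
                    out.append(FeatureName.for_wavelet(band, cls, base).canonical())
    return out


# ---------------------------------------------------------------------------
# preprocessing


def _normalize(image: np.ndarray, scale: float) -> np.ndarray:
    std = image.std()
    if std == 0:
        std = 1.0  # constant image: centering only
    return scale * (image - image.mean()) / std


_SITK_INTERP = {
    "sitkBSpline": "sitkBSpline",
    "sitkLinear": "sitkLinear",
    "sitkNearestNeighbor": "sitkNearestNeighbor",
}


def _resample(
    image: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    new_spacing: tuple[float, float, float],
    interpolator: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample image (requested interpolator) and mask (nearest-neighbor)."""
    import SimpleITK as sitk

    interp = getattr(sitk, _SITK_INTERP[interpolator])
    spacing_xyz = tuple(float(s) for s in spacing[::-1])
    new_xyz = tuple(float(s) for s in new_spacing[::-1])
    size_xyz = [
        max(1, int(np.ceil(n * s / ns)))
        for n, s, ns in zip(image.shape[::-1], spacing_xyz, new_xyz)
    ]

    def _run(arr, how):
        img = sitk.GetImageFromArray(arr)
        img.SetSpacing(spacing_xyz)
        res = sitk.Resample(
            img,
            size_xyz,
            sitk.Transform(),
            how,
            img.GetOrigin(),
            new_xyz,
            img.GetDirection(),
            0.0,
            sitk.sitkFloat64,
        )
        return sitk.GetArrayFromImage(res)

    new_image = _run(image.astype(np.float64), interp)
    new_mask = _run(mask.astype(np.float64), sitk.sitkNearestNeighbor) > 0.5
    return new_image, new_mask


def _log_filter(image: np.ndarray, sigma_mm: float, spacing) -> np.ndarray:
    """Scale-normalized Laplacian of Gaussian (sigma in mm)."""
    sigma_vox = [sigma_mm / s for s in spacing]
    return ndimage.gaussian_laplace(image, sigma=sigma_vox, mode="mirror") * sigma_mm**2


def _wavelet_bands(image: np.ndarray, wavelet: str) -> dict[str, np.ndarray]:
    """Single-level undecimated wavelet decomposition into 8 sub-bands."""
    import pywt

    wav = pywt.Wavelet(wavelet)
    filters = {"L": np.asarray(wav.dec_lo), "H": np.asarray(wav.dec_hi)}
    bands = {}
    for band in WAVELET_BANDS:
        out = image
        for axis, letter in enumerate(band):  # letters map to axes (z, y, x)
            out = ndimage.correlate1d(out, filters[letter], axis=axis, mode="mirror")
        bands[band] = out
    return bands


def _bbox_crop(image: np.ndarray, mask: np.ndarray, margin: int = 1):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return image[sl], mask[sl]


# ---------------------------------------------------------------------------
# extraction


def _intensity_texture(image, mask, bin_width, voxel_volume) -> dict[str, dict]:
    """All non-shape feature classes for one derived image."""
    img_c, mask_c = _bbox_crop(image, mask)
    gl = texture.discretize(img_c, mask_c, bin_width)
    n_levels = int(gl.max())
    return {
        "firstorder": texture.firstorder_features(img_c[mask_c], bin_width, voxel_volume),
        "glcm": texture.glcm_features(gl, n_levels),
        "glrlm": texture.glrlm_features(gl, n_levels),
        "glszm": texture.glszm_features(gl, n_levels),
        "ngtdm": texture.ngtdm_features(gl, n_levels),
        "gldm": texture.gldm_features(gl, n_levels),
    }


def extract_features(
    volume: SUVVolume, mask: VOIMask, config: ExtractionConfig | None = None
) -> dict[str, float]:
    """Extract the full feature vector for one volume/VOI pair.

    Returns an ordered mapping from canonical feature name to value; the
    order and cardinality match :func:`reference_feature_names` for the same
    config.
    """
    config = config or reference_config()
    mask.check_congruent(volume)

    image = volume.voxels.astype(float)
    m = mask.voxels.copy()
    spacing = volume.spacing

    if config.normalize:
        image = _normalize(image, config.normalize_scale)
    if config.resampled_spacing is not None:
        image, m = _resample(
            image, m, spacing, config.resampled_spacing, config.interpolator
        )
        spacing = tuple(config.resampled_spacing)
        if not m.any():
            raise ValueError("mask is empty after resampling; enlarge the VOI")

    voxel_volume = float(np.prod(spacing))
    out: dict[str, float] = {}
    nonshape = [c for c in texture.CLASS_FEATURES if c != "shape"]

    if "original" in config.image_types:
        shape = texture.shape_features(m, spacing)
        for base in texture.SHAPE_FEATURES:
            out[FeatureName("original", "shape", base).canonical()] = shape[base]
        feats = _intensity_texture(image, m, config.bin_width, voxel_volume)
        for cls in nonshape:
            for base in texture.CLASS_FEATURES[cls]:
                out[FeatureName("original", cls, base).canonical()] = feats[cls][base]

    if "log" in config.image_types:
        for sigma in config.log_sigmas:
            filtered = _log_filter(image, sigma, spacing)
            feats = _intensity_texture(filtered, m, config.bin_width, voxel_volume)
            for cls in nonshape:
                for base in texture.CLASS_FEATURES[cls]:
                    out[FeatureName.for_log(sigma, cls, base).canonical()] = feats[cls][base]

    if "wavelet" in config.image_types:
        for band, filtered in _wavelet_bands(image, config.wavelet).items():
            feats = _intensity_texture(filtered, m, config.bin_width, voxel_volume)
            for cls in nonshape:
                for base in texture.CLASS_FEATURES[cls]:
                    out[FeatureName.for_wavelet(band, cls, base).canonical()] = feats[cls][base]

    return out


def extract_table(cases, config: ExtractionConfig | None = None):
    """Extract features for an iterable of (patient_id, volume, mask) cases.

    Returns a pandas DataFrame indexed by patient id with canonical feature
    names as columns.
    """
    import pandas as pd

    config = config or reference_config()
    rows, ids = [], []
    for patient_id, volume, mask in cases:
        rows.append(extract_features(volume, mask, config))
        ids.append(patient_id)
    table = pd.DataFrame(rows, index=pd.Index(ids, name="patient_id"))
    return table
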
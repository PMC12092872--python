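"""PET volumes, VOI masks and SUV conversion.

Volumes are held as plain numpy arrays with millimetre spacing/origin
metadata, indexed (z, y, x).  The body-weight SUV convention is used:
voxel activity (Bq/mL) divided by the injected dose per gram of body
weight, with the dose decay-corrected to scan start using the tracer
half-life (default: 18F, 109.77 min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SUVVolume",
    "VOIMask",
    "F18_HALF_LIFE_MIN",
    "to_suv",
    "read_nifti_volume",
    "read_nifti_mask",
    "read_dicom_series",
]

#: physical half-life of fluorine-18 in minutes
F18_HALF_LIFE_MIN = 109.77


@dataclass
class SUVVolume:
    """3-D grid of SUV values with isotropic-or-not mm spacing."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("volume must be 3-D")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite values")
        if np.any(self.voxels < 0):
            raise ValueError("SUV values must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        self.origin = tuple(float(o) for o in self.origin)


@dataclass
class VOIMask:
    """Binary grid congruent with its paired :class:`SUVVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels) > 0
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.voxels.any():
            raise ValueError("mask has no foreground voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    def check_congruent(self, volume: SUVVolume) -> None:
        if self.voxels.shape != volume.voxels.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} does not match "
                f"volume shape {volume.voxels.shape}"
            )
        if not np.allclose(self.spacing, volume.spacing):
            raise ValueError("mask and volume spacings differ")


def to_suv(
    activity: np.ndarray,
    spacing,
    injected_dose_bq: float,
    body_weight_g: float,
    elapsed_min: float = 0.0,
    half_life_min: float = F18_HALF_LIFE_MIN,
    origin=(0.0, 0.0, 0.0),
) -> SUVVolume:
    """Convert an activity-concentration grid (Bq/mL) to body-weight SUV.

    SUV = activity / (decayed_dose / body_weight), where the injected dose is
    decay-corrected to the scan start: decayed_dose = dose * 2**(-elapsed/T1/2).
    Assumes unit tissue density (1 g/mL), so SUV is dimensionless.
    """
    if injected_dose_bq <= 0:
        raise ValueError("injected dose must be positive")
    if body_weight_g <= 0:
        raise ValueError("body weight must be positive")
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    activity = np.asarray(activity, dtype=float)
    if np.any(activity < 0):
        raise ValueError("negative activity concentration")
    decayed_dose = injected_dose_bq * 2.0 ** (-elapsed_min / half_life_min)
    suv = activity / (decayed_dose / body_weight_g)
    return SUVVolume(suv, spacing, origin)


# ---------------------------------------------------------------------------
# readers


def _from_nifti(path):
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    # nibabel is (x, y, z); internal layout is (z, y, x)
    data = np.transpose(data, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    return data, spacing, origin


def read_nifti_volume(path) -> SUVVolume:
    data, spacing, origin = _from_nifti(path)
    return SUVVolume(data, spacing, origin)


def read_nifti_mask(path) -> VOIMask:
    data, spacing, origin = _from_nifti(path)
    return VOIMask(data, spacing, origin)


def read_dicom_series(directory) -> SUVVolume:
    """Read a DICOM series directory into a volume (values taken as stored)."""
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise ValueError(f"no DICOM series found under {directory}")
    reader.SetFileNames(files)
    img = reader.Execute()
    data = sitk.GetArrayFromImage(img).astype(float)  # (z, y, x)
    sx, sy, sz = img.GetSpacing()
    ox, oy, oz = img.GetOrigin()
    return SUVVolume(data, (sz, sy, sx), (oz, oy, ox))
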
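"""Synthetic radiomics cohorts and PET phantoms.

The tabular generator emulates the statistical shape of a radiomics cohort
study: a near-balanced binary outcome over ~150 patients, a wide feature
matrix (hundreds to ~1800 columns) in which a small planted subset carries a
standardized mean shift between the classes, and nuisance features arranged
in equicorrelated blocks to mimic the heavy redundancy of filtered-image
features.  Feature names follow the radiomics taxonomy so the whole
downstream pipeline (name parsing included) can run on synthetic tables.

The phantom generator produces a spherical high-uptake lesion on a uniform
background with additive Gaussian noise — a minimal but sufficient fixture
for exercising the extraction pipeline end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .cohort import HIGH, LOW
from .imaging import SUVVolume, VOIMask
from .names import FeatureName

__all__ = ["SyntheticSpec", "GroundTruth", "simulate_feature_table", "simulate_phantom"]

_IMAGE_TYPES = (
    ["original"]
    + [f"wavelet-{b}" for b in ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")]
    + [
        f"log-sigma-{str(float(s)).replace('.', '-')}-mm-3D"
        for s in (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)
    ]
)
_CLASSES = ("firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating conditions for a synthetic feature table.

    Defaults are the reference study conditions: 150 patients, 400 features
    of which 10 carry a standardized mean difference of 1.0, nuisance
    features in equicorrelated blocks (rho 0.5, block size 10), balanced
    classes.
    """

    n_patients: int = 150
    n_features: int = 400
    n_informative: int = 10
    effect_size: float = 1.0
    block_rho: float = 0.5
    block_size: int = 10
    class_balance: float = 0.5
    heavy_tails: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4 or self.n_features < 1:
            raise ValueError("degenerate spec: too few patients or features")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must be in [0, n_features]")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho must be in [0, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """Planted-signal bookkeeping for a generated table."""

    informative_indices: tuple[int, ...]
    informative_names: tuple[str, ...]
    spec: SyntheticSpec

    def to_dict(self) -> dict:
        return {
            "informative_indices": list(self.informative_indices),
            "informative_names": list(self.informative_names),
            "spec": asdict(self.spec),
        }


def _feature_names(p: int) -> list[str]:
    names = []
    for i in range(p):
        image_type = _IMAGE_TYPES[i % len(_IMAGE_TYPES)]
        cls = _CLASSES[(i // len(_IMAGE_TYPES)) % len(_CLASSES)]
        names.append(FeatureName(image_type, cls, f"Synth{i:04d}").canonical())
    return names


def simulate_feature_table(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Generate (features, labels, ground truth) under the spec.

    Labels are drawn first (case-control style): ``round(n * class_balance)``
    patients are high-risk, the rest low-risk, in shuffled order.  Informative
    features are unit-variance Gaussians whose class means differ by
    ``effect_size``; nuisance features are standard Gaussians sharing a block
    factor that induces pairwise correlation ``block_rho`` within each block.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n_patients, spec.n_features, spec.n_informative

    n_high = int(round(n * spec.class_balance))
    if n_high in (0, n):
        raise ValueError("class_balance leaves one class empty at this n")
    y = np.array([HIGH] * n_high + [LOW] * (n - n_high))
    rng.shuffle(y)
    is_high = y == HIGH

    informative = np.sort(rng.choice(p, size=k, replace=False)) if k else np.array([], int)
    X = np.empty((n, p))

    def _noise(size):
        if spec.heavy_tails:
            return rng.standard_t(df=3, size=size) / np.sqrt(3.0)  # unit variance
        return rng.standard_normal(size)

    # nuisance: equicorrelated blocks over the non-informative columns
    nuisance = np.setdiff1d(np.arange(p), informative)
    for start in range(0, len(nuisance), spec.block_size):
        cols = nuisance[start : start + spec.block_size]
        shared = _noise(n)[:, None]
        eps = _noise((n, len(cols)))
        X[:, cols] = np.sqrt(spec.block_rho) * shared + np.sqrt(1 - spec.block_rho) * eps

    # informative: independent, mean +/- effect/2 by class
    shift = np.where(is_high, spec.effect_size / 2.0, -spec.effect_size / 2.0)
    for j in informative:
        X[:, j] = shift + _noise(n)

    names = _feature_names(p)
    index = pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id")
    table = pd.DataFrame(X, index=index, columns=names)
    labels = pd.Series(y, index=index, name="risk")
    truth = GroundTruth(
        informative_indices=tuple(int(j) for j in informative),
        informative_names=tuple(names[j] for j in informative),
        spec=spec,
    )
    return table, labels, truth


def simulate_phantom(
    grid: tuple[int, int, int] = (32, 32, 32),
    spacing: tuple[float, float, float] = (2.73, 2.73, 3.27),
    lesion_radius_mm: float = 12.0,
    contrast: float = 5.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    background_suv: float = 1.0,
) -> tuple[SUVVolume, VOIMask]:
    """Spherical high-uptake lesion on a uniform background.

    ``contrast`` is the lesion-to-background SUV ratio; ``noise_sd`` the
    additive Gaussian noise level in SUV units (values are clipped at 0).
    The VOI mask covers exactly the lesion sphere.
    """
    rng = np.random.default_rng(seed)
    grid = tuple(int(g) for g in grid)
    spacing = tuple(float(s) for s in spacing)
    extent = [g * s for g, s in zip(grid, spacing)]
    if 2 * lesion_radius_mm >= min(extent):
        raise ValueError(
            f"lesion diameter {2 * lesion_radius_mm} mm exceeds grid extent {extent}"
        )
    center = [(g - 1) / 2.0 * s for g, s in zip(grid, spacing)]
    zz, yy, xx = np.meshgrid(
        *[np.arange(g) * s for g, s in zip(grid, spacing)], indexing="ij"
    )
    r2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    inside = r2 <= lesion_radius_mm**2
    values = np.where(inside, background_suv * contrast, background_suv).astype(float)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=grid)
    values = np.clip(values, 0.0, None)
    return SUVVolume(values, spacing), VOIMask(inside, spacing)
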
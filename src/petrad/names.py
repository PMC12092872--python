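"""Radiomics feature-name taxonomy.

Feature names carry three pieces of information: the image type the feature
was computed on (``original``, a wavelet sub-band such as ``wavelet-LHH``, or
a Laplacian-of-Gaussian scale such as ``log-sigma-2-5-mm-3D`` for sigma
2.5 mm), the feature class (``shape``, ``firstorder`` or one of the five
texture-matrix families) and the base feature name
(``Skewness``, ``GrayLevelNonUniformity``, ...).

Two dialects are accepted on input: the canonical underscore form
``wavelet-LHH_firstorder_Skewness`` and the fully hyphenated form
``wavelet-LHH-firstorder-Skewness`` as it appears in print (including
en/em dashes and the ``first-order`` spelling).  The canonical underscore
form is always emitted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "FeatureName",
    "FeatureNameError",
    "parse_feature_name",
    "count_by_taxonomy",
    "FEATURE_CLASSES",
]

FEATURE_CLASSES = ("shape", "firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm")

_WAVELET_BAND_RE = re.compile(r"^[LH]{3}$")
_LOG_RE = re.compile(r"^log-sigma-(\d+)-(\d+)-mm-3D$")


class FeatureNameError(ValueError):
    """Raised for unparseable feature names."""


def _format_sigma(sigma: float) -> str:
    # 2.5 -> "2-5", 4.0 -> "4-0"; mirrors the printed image-type tokens
    return str(float(sigma)).replace(".", "-")


@dataclass(frozen=True)
class FeatureName:
    """Parsed (image_type, feature_class, base) triple."""

    image_type: str  # "original" | "wavelet-<band>" | "log-sigma-<s>-mm-3D"
    feature_class: str
    base: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise FeatureNameError(
                f"unknown feature class {self.feature_class!r}; "
                f"valid classes: {', '.join(FEATURE_CLASSES)}"
            )

    @property
    def image_type_group(self) -> str:
        """Coarse image-type family: 'original', 'wavelet' or 'log'."""
        return self.image_type.split("-", 1)[0]

    @property
    def sigma(self) -> float | None:
        """LoG sigma in mm, or None for non-LoG image types."""
        m = _LOG_RE.match(self.image_type)
        if m is None:
            return None
        return float(f"{m.group(1)}.{m.group(2)}")

    @property
    def wavelet_band(self) -> str | None:
        if self.image_type_group != "wavelet":
            return None
        return self.image_type.split("-", 1)[1]

    def canonical(self) -> str:
        return f"{self.image_type}_{self.feature_class}_{self.base}"

    def __str__(self) -> str:
        return self.canonical()

    @staticmethod
    def for_log(sigma: float, feature_class: str, base: str) -> "FeatureName":
        return FeatureName(f"log-sigma-{_format_sigma(sigma)}-mm-3D", feature_class, base)

    @staticmethod
    def for_wavelet(band: str, feature_class: str, base: str) -> "FeatureName":
        return FeatureName(f"wavelet-{band}", feature_class, base)


def _normalize(text: str) -> str:
    t = str(text).strip().strip("*").strip()
    # printed dialects: en/em dashes, underscores, the "first-order" spelling
    t = t.replace("–", "-").replace("—", "-").replace("_", "-")
    t = re.sub(r"first-order", "firstorder", t, flags=re.IGNORECASE)
    return t


def parse_feature_name(text: str) -> FeatureName:
    """Parse either name dialect into a :class:`FeatureName`."""
    t = _normalize(text)
    tokens = t.split("-")
    if tokens[0] == "original":
        rest = tokens[1:]
    elif tokens[0] == "wavelet":
        if len(tokens) < 3 or not _WAVELET_BAND_RE.match(tokens[1]):
            raise FeatureNameError(f"malformed wavelet feature name {text!r}")
        rest = tokens[2:]
    elif tokens[0] == "log":
        if len(tokens) < 7 or tokens[1] != "sigma" or tokens[4] != "mm" or tokens[5] != "3D":
            raise FeatureNameError(f"malformed LoG feature name {text!r}")
        rest = tokens[6:]
    else:
        raise FeatureNameError(f"unknown image type in feature name {text!r}")

    if len(rest) < 2:
        raise FeatureNameError(f"feature name {text!r} lacks class/base parts")
    feature_class, base_tokens = rest[0], rest[1:]
    base = "".join(base_tokens)  # CamelCase bases never contain separators

    if tokens[0] == "original":
        image_type = "original"
    elif tokens[0] == "wavelet":
        image_type = f"wavelet-{tokens[1]}"
    else:
        image_type = f"log-sigma-{tokens[2]}-{tokens[3]}-mm-3D"
    return FeatureName(image_type, feature_class, base)


def count_by_taxonomy(names) -> pd.DataFrame:
    """Image-type-group x feature-class contingency table.

    Rows are the coarse image-type families (original / wavelet / log),
    columns the seven feature classes; every cell is a count and the grand
    total equals ``len(names)``.  Duplicated names count once per occurrence.
    """
    parsed = [n if isinstance(n, FeatureName) else parse_feature_name(n) for n in names]
    table = pd.DataFrame(
        0,
        index=pd.Index(["original", "wavelet", "log"], name="image_type"),
        columns=pd.Index(list(FEATURE_CLASSES), name="feature_class"),
    )
    for p in parsed:
        table.loc[p.image_type_group, p.feature_class] += 1
    return table
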
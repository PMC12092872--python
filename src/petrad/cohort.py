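"""Gleason-score handling and binary risk grouping of a prostate-cancer cohort.

The Gleason score (GS) is the sum of a primary and a secondary histological
grade, each in 1-5, read from the biopsy report as a string such as ``"3+4"``.
The order of the two grades carries prognostic information at GS 7: ``3+4``
(predominantly pattern 3) is low risk, ``4+3`` is high risk.  The grouping
rule implemented here is:

* GS <= 6 (any composition)           -> low risk
* 3+4                                  -> low risk
* 4+3                                  -> high risk
* GS >= 8 (any composition)            -> high risk
* any other GS 7 composition (2+5 ...) -> undefined, raises

GS 8 compositions other than 4+4 (i.e. 3+5 / 5+3) are grouped high by the
GS >= 8 branch but emit a warning because their prognostic grouping is
debated.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "GleasonRecord",
    "GleasonParseError",
    "parse_gleason",
    "assign_risk",
    "load_cohort",
    "summarize_cohort",
    "LOW",
    "HIGH",
]

#: canonical risk labels; "high" is the positive class everywhere downstream
LOW = "low"
HIGH = "high"

_GLEASON_RE = re.compile(r"^\s*(\d+)\s*\+\s*(\d+)\s*$")


class GleasonParseError(ValueError):
    """Raised for malformed or out-of-range Gleason strings."""


@dataclass(frozen=True)
class GleasonRecord:
    """Primary grade, secondary grade and their sum (the Gleason score)."""

    primary: int
    secondary: int

    def __post_init__(self) -> None:
        for name, g in (("primary", self.primary), ("secondary", self.secondary)):
            if not 1 <= int(g) <= 5:
                raise GleasonParseError(
                    f"{name} grade {g!r} outside the valid range 1-5"
                )

    @property
    def gs(self) -> int:
        return self.primary + self.secondary

    def __str__(self) -> str:  # round-trips through parse_gleason
        return f"{self.primary}+{self.secondary}"


def parse_gleason(text: str) -> GleasonRecord:
    """Parse a ``"a+b"`` Gleason string into a :class:`GleasonRecord`.

    Whitespace around the grades is tolerated.  Raises
    :class:`GleasonParseError` naming the offending token otherwise.
    """
    m = _GLEASON_RE.match(str(text))
    if m is None:
        raise GleasonParseError(f"malformed Gleason string {text!r}")
    return GleasonRecord(int(m.group(1)), int(m.group(2)))


def assign_risk(record: GleasonRecord) -> str:
    """Map a Gleason record to the binary risk label (``"low"``/``"high"``)."""
    gs = record.gs
    pair = (record.primary, record.secondary)
    if gs <= 6:
        return LOW
    if gs == 7:
        if pair == (3, 4):
            return LOW
        if pair == (4, 3):
            return HIGH
        raise GleasonParseError(
            f"Gleason 7 composition {record} is not covered by the 3+4/4+3 rule"
        )
    # gs >= 8
    if 3 in pair:  # 3+5 / 5+3: grouped by the gs>=8 branch, never by the pair list
        warnings.warn(
            f"Gleason {record} grouped high-risk by the GS>=8 rule; "
            "this composition has a debated prognostic grouping",
            stacklevel=2,
        )
    return HIGH


def load_cohort(path) -> pd.DataFrame:
    """Read a delimited cohort file with columns patient_id, gleason[, scanner].

    The risk column is always derived from the gleason column via
    :func:`assign_risk`; a risk column present in the input is ignored.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"patient_id", "gleason"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort file is missing columns: {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient ids: {dupes}")
    records = [parse_gleason(g) for g in df["gleason"]]
    df = df.copy()
    df["primary_grade"] = [r.primary for r in records]
    df["secondary_grade"] = [r.secondary for r in records]
    df["gs"] = [r.gs for r in records]
    df["risk"] = [assign_risk(r) for r in records]
    if "scanner" not in df.columns:
        df["scanner"] = ""
    return df


def summarize_cohort(cohort: pd.DataFrame | Iterable[GleasonRecord]) -> dict:
    """Counts by risk group, by GS and by scanner.

    Accepts either the DataFrame produced by :func:`load_cohort` or a plain
    iterable of :class:`GleasonRecord`.  Both risk levels are always reported,
    even when one of them is empty.
    """
    if not isinstance(cohort, pd.DataFrame):
        records = list(cohort)
        cohort = pd.DataFrame(
            {
                "patient_id": [str(i) for i in range(len(records))],
                "gs": [r.gs for r in records],
                "risk": [assign_risk(r) for r in records],
                "scanner": "",
            }
        )
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    risk_counts = cohort["risk"].value_counts().to_dict()
    summary = {
        "n": int(len(cohort)),
        "risk": {LOW: int(risk_counts.get(LOW, 0)), HIGH: int(risk_counts.get(HIGH, 0))},
        "gs": {int(k): int(v) for k, v in cohort["gs"].value_counts().sort_index().items()},
        "scanner": {
            str(k): int(v)
            for k, v in cohort["scanner"].value_counts().sort_index().items()
        },
    }
    assert summary["risk"][LOW] + summary["risk"][HIGH] == summary["n"]
    return summary
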
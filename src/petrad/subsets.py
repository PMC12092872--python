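"""Construction of the 13 feature subsets from the frequency table.

Eleven subsets keep features whose selection frequency meets a threshold
(90, 80, ..., 10, 5, 0 percent; the 0% subset keeps every feature that was
ever selected).  The ``finetuning`` subset keeps mid-band features
(frequency in [30, 70): 30 included, 70 excluded) that are not redundant
with the stable ``features70`` subset, redundancy being measured as the
repetition-averaged absolute Pearson correlation against the reference
members.  The ``features7030r`` subset is the union of ``features70`` and
``finetuning`` (disjoint by construction, so sizes add).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSubset",
    "DEFAULT_THRESHOLDS",
    "threshold_subsets",
    "avg_reference_pcc",
    "build_finetuning",
    "build_union_subset",
    "build_all_subsets",
]

DEFAULT_THRESHOLDS = (90, 80, 70, 60, 50, 40, 30, 20, 10, 5, 0)


@dataclass(frozen=True)
class FeatureSubset:
    """A named, ordered feature list together with the rule that produced it."""

    name: str
    rule: dict
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"subset {self.name!r} contains duplicate members")

    def __len__(self) -> int:
        return len(self.members)

    def to_dict(self) -> dict:
        return {"name": self.name, "rule": self.rule, "members": list(self.members)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSubset":
        return cls(d["name"], d["rule"], tuple(d["members"]))


def _ordered(freq: pd.Series, names) -> tuple[str, ...]:
    """Stable ordering: descending frequency, then feature name."""
    return tuple(sorted(names, key=lambda f: (-freq[f], f)))


def threshold_subsets(
    freq: pd.Series, thresholds=DEFAULT_THRESHOLDS
) -> list[FeatureSubset]:
    """One subset per threshold t: features with frequency >= t (and > 0)."""
    freq = pd.Series(freq, dtype=float)
    out = []
    for t in thresholds:
        members = freq.index[(freq >= t) & (freq > 0)]
        out.append(
            FeatureSubset(
                name=f"features{int(t)}",
                rule={"kind": "frequency_threshold", "threshold": float(t)},
                members=_ordered(freq, members),
            )
        )
    return out


def avg_reference_pcc(
    candidates,
    reference: FeatureSubset,
    table: pd.DataFrame,
    plan,
    aggregate: str = "max",
) -> pd.Series:
    """Repetition-averaged correlation of each candidate with the reference.

    Per repetition, the absolute Pearson correlation between the candidate
    and every reference member is computed on that repetition's training
    rows and aggregated (``max`` by default: a candidate correlated with any
    stable feature is redundant; ``mean`` optional).  The per-repetition
    values are then averaged over all repetitions of the plan.  A candidate
    with zero variance on some training split contributes 0 for that
    repetition, with a warning.
    """
    candidates = list(candidates)
    if len(reference.members) == 0:
        raise ValueError("reference subset is empty")
    overlap = set(candidates) & set(reference.members)
    if overlap:
        raise ValueError(f"candidates overlap the reference subset: {sorted(overlap)}")
    if aggregate not in ("max", "mean"):
        raise ValueError("aggregate must be 'max' or 'mean'")

    ref = table[list(reference.members)].to_numpy(dtype=float)
    cand = table[candidates].to_numpy(dtype=float)
    per_rep = np.zeros((plan.reps, len(candidates)))
    for rep in range(plan.reps):
        rows = plan.train[rep]
        R = ref[rows] - ref[rows].mean(axis=0)
        C = cand[rows] - cand[rows].mean(axis=0)
        r_sd = np.sqrt((R**2).sum(axis=0))
        c_sd = np.sqrt((C**2).sum(axis=0))
        zero = c_sd == 0
        if zero.any():
            bad = [candidates[i] for i in np.where(zero)[0]]
            warnings.warn(
                f"repetition {rep}: zero-variance candidates {bad}; PCC set to 0"
            )
        denom = np.outer(np.where(c_sd > 0, c_sd, 1.0), np.where(r_sd > 0, r_sd, 1.0))
        corr = np.abs(C.T @ R) / denom  # candidates x reference members
        corr[zero, :] = 0.0
        per_rep[rep] = corr.max(axis=1) if aggregate == "max" else corr.mean(axis=1)
    return pd.Series(per_rep.mean(axis=0), index=candidates, name="avg_pcc")


def build_finetuning(
    freq: pd.Series,
    pcc: pd.Series,
    pcc_cutoff: float = 0.3,
    band: tuple[float, float] = (30.0, 70.0),
) -> FeatureSubset:
    """Mid-band features decorrelated from the stable subset.

    Members have frequency in [band[0], band[1]) — the lower bound included,
    the upper excluded — and an average PCC strictly below the cutoff.
    """
    freq = pd.Series(freq, dtype=float)
    pcc = pd.Series(pcc, dtype=float)
    in_band = freq.index[(freq >= band[0]) & (freq < band[1])]
    missing = set(in_band) - set(pcc.index)
    if missing:
        raise ValueError(f"PCC records missing for band features: {sorted(missing)}")
    members = [f for f in in_band if pcc[f] < pcc_cutoff]
    return FeatureSubset(
        name="finetuning",
        rule={
            "kind": "band_decorrelated",
            "band": [float(band[0]), float(band[1])],
            "pcc_cutoff": float(pcc_cutoff),
        },
        members=_ordered(freq, members),
    )


def build_union_subset(
    features70: FeatureSubset, finetuning: FeatureSubset
) -> FeatureSubset:
    """Union of the stable and finetuning subsets (features70 order first)."""
    overlap = set(features70.members) & set(finetuning.members)
    if overlap:
        raise ValueError(
            f"inconsistent inputs: subsets overlap on {sorted(overlap)}"
        )
    return FeatureSubset(
        name="features7030r",
        rule={"kind": "union", "of": [features70.name, finetuning.name]},
        members=tuple(features70.members) + tuple(finetuning.members),
    )


def build_all_subsets(
    freq: pd.Series,
    table: pd.DataFrame,
    plan,
    pcc_cutoff: float = 0.3,
    aggregate: str = "max",
) -> list[FeatureSubset]:
    """The full 13-subset family (11 thresholds + finetuning + the union)."""
    by_threshold = threshold_subsets(freq)
    by_name = {s.name: s for s in by_threshold}
    band = freq.index[(freq >= 30) & (freq < 70)]
    if len(band) and len(by_name["features70"]):
        pcc = avg_reference_pcc(band, by_name["features70"], table, plan, aggregate)
        fine = build_finetuning(freq, pcc, pcc_cutoff=pcc_cutoff)
    else:
        fine = FeatureSubset(
            "finetuning",
            {"kind": "band_decorrelated", "band": [30.0, 70.0], "pcc_cutoff": pcc_cutoff},
            tuple(),
        )
    union = build_union_subset(by_name["features70"], fine)
    return by_threshold + [union, fine]
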
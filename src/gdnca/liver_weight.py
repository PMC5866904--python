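"""Liver-lobe weight arithmetic for the rat partial-hepatectomy model.

The rat liver is dissected into five lobes (left lateral, median, right,
caudate, paracaval).  Graded hepatectomy removes defined lobe combinations:
a 70% hepatectomy resects the left lateral and median lobes, a 90%
hepatectomy additionally the right lobe.  This module computes relative lobe
weights, combined resected fractions, and the post-operative regeneration
rate of the remnant liver relative to an unresected reference liver.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from gdnca.simulate import ValidationError

LOBES = ("left_lateral", "median", "right", "caudate", "paracaval")

#: Mean explanted lobe weights (g) of unresected adult male Sprague-Dawley
#: rats (~300 g body weight), usable as a reference liver for regeneration
#: arithmetic when no per-animal pre-operative liver weight exists.
REFERENCE_LOBE_WEIGHTS_G = {
    "left_lateral": 3.98,
    "median": 4.26,
    "right": 2.23,
    "caudate": 0.82,
    "paracaval": 1.42,
}
REFERENCE_TOTAL_WEIGHT_G = 12.87

#: Mean remnant liver weights (g) at post-operative day 2 in the same model.
POD2_REMNANT_WEIGHT_G = {"hep70": 8.49, "hep90": 4.82}


@dataclass(frozen=True)
class LiverWeightRecord:
    """Lobe-wise and total explanted liver weights of one animal (grams)."""

    lobe_weights: Mapping[str, float]
    total_weight: float
    group: str = "control"

    def __post_init__(self) -> None:
        unknown = set(self.lobe_weights) - set(LOBES)
        if unknown:
            raise ValidationError(f"unknown lobe names: {sorted(unknown)}")
        if any(w <= 0 for w in self.lobe_weights.values()):
            raise ValidationError("lobe weights must be strictly positive")
        if self.total_weight <= 0:
            raise ValidationError("total weight must be strictly positive")
        if self.group == "control" and set(self.lobe_weights) == set(LOBES):
            lobe_sum = sum(self.lobe_weights.values())
            if abs(lobe_sum - self.total_weight) / self.total_weight > 0.05:
                raise ValidationError(
                    "lobe weights differ from the total by more than the 5% "
                    f"dissection-loss tolerance (sum {lobe_sum:.2f} g vs total "
                    f"{self.total_weight:.2f} g)"
                )


def relative_lobe_weights(
    record: LiverWeightRecord, rounded: bool = False
) -> dict[str, float]:
    """Percent weight of each dissected lobe relative to the total liver.

    ``relative weight (%) = 100 × lobe (g) / total (g)``.  Reporting rounds
    to one decimal (``rounded=True``); internal arithmetic is unrounded.
    """
    out = {
        lobe: 100.0 * weight / record.total_weight
        for lobe, weight in record.lobe_weights.items()
    }
    if rounded:
        out = {lobe: round(v, 1) for lobe, v in out.items()}
    return out


def combined_relative_weight(record: LiverWeightRecord, lobes: Iterable[str]) -> float:
    """Percent weight of a set of lobes combined (e.g. the resected mass)."""
    lobes = tuple(lobes)
    if not lobes:
        raise ValidationError("lobe set must be non-empty")
    missing = set(lobes) - set(record.lobe_weights)
    if missing:
        raise ValidationError(f"lobes not present in record: {sorted(missing)}")
    return 100.0 * sum(record.lobe_weights[l] for l in lobes) / record.total_weight


def regeneration_rate(remnant_weight: float, reference_total_weight: float) -> float:
    """Remnant liver weight as a percentage of the reference total liver weight."""
    if remnant_weight <= 0 or reference_total_weight <= 0:
        raise ValidationError("weights must be strictly positive")
    return 100.0 * remnant_weight / reference_total_weight


# -- tabular IO --------------------------------------------------------------

def records_to_frame(records: Sequence[LiverWeightRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"group": r.group, "total_weight_g": r.total_weight}
        for lobe in LOBES:
            row[f"{lobe}_g"] = r.lobe_weights.get(lobe)
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_frame(frame: pd.DataFrame) -> list[LiverWeightRecord]:
    records = []
    for _, row in frame.iterrows():
        lobes = {
            lobe: float(row[f"{lobe}_g"])
            for lobe in LOBES
            if f"{lobe}_g" in frame.columns and pd.notna(row[f"{lobe}_g"])
        }
        records.append(
            LiverWeightRecord(
                lobe_weights=lobes,
                total_weight=float(row["total_weight_g"]),
                group=str(row.get("group", "control")),
            )
        )
    return records


def write_records_csv(records: Sequence[LiverWeightRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[LiverWeightRecord]:
    return records_from_frame(pd.read_csv(path))
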
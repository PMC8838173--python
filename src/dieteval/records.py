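"""Record schema and JSON-lines I/O.

A *record* is one photographed dish/beverage or one barcode scan; it contains
one or more *segments* (distinct edible components), each with a label, a food
type, a weight in grams and a per-segment nutrient vector.  The same schema
serves both the gold-standard (weighed-diary) file and the tool-output file:

    {"record_id": ..., "record_kind": "food"|"beverage",
     "entry_mode": "photo"|"scan",
     "segments": [{"label", "food_type", "weight_g",
                   "nutrients": {"energy_kcal","fat_g","carb_g",
                                 "protein_g","fiber_g","alcohol_g"}}]}

``record_type`` (composite/simple food/beverage stratum) is optional in the
file; when absent it is derived from the segment count.  Composed beverages
are frequently recorded as a single mixed segment (coffee *with* milk), so the
generator writes the stratum explicitly rather than relying on the count rule.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator

NUTRIENTS = ("energy_kcal", "fat_g", "carb_g", "protein_g", "fiber_g", "alcohol_g")

RECORD_TYPES = ("composite_food", "simple_food", "composite_beverage", "simple_beverage")


class NutrientVector(BaseModel):
    """Energy (kcal) and macronutrients (g) of one segment or one record total."""

    energy_kcal: float = 0.0
    fat_g: float = 0.0
    carb_g: float = 0.0
    protein_g: float = 0.0
    fiber_g: float = 0.0
    alcohol_g: float = 0.0

    @field_validator(*NUTRIENTS)
    @classmethod
    def _finite_nonneg(cls, v: float) -> float:
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"nutrient values must be finite and >= 0, got {v}")
        return v

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in NUTRIENTS], dtype=float)

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector(**{k: getattr(self, k) + getattr(other, k) for k in NUTRIENTS})

    @classmethod
    def from_per100g(cls, per100g: "NutrientVector | dict", weight_g: float) -> "NutrientVector":
        """Scale a per-100 g composition to a segment weight."""
        if isinstance(per100g, NutrientVector):
            per100g = per100g.model_dump()
        return cls(**{k: per100g[k] * weight_g / 100.0 for k in NUTRIENTS})


class Segment(BaseModel):
    label: str
    food_type: str
    weight_g: float = Field(ge=0)
    nutrients: NutrientVector = Field(default_factory=NutrientVector)

    @field_validator("weight_g")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("segment weight must be finite")
        return v


class Record(BaseModel):
    record_id: str
    record_kind: Literal["food", "beverage"]
    entry_mode: Literal["photo", "scan"] = "photo"
    record_type: Optional[
        Literal["composite_food", "simple_food", "composite_beverage", "simple_beverage"]
    ] = None
    segments: list[Segment]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def total_nutrients(self) -> NutrientVector:
        total = NutrientVector()
        for seg in self.segments:
            total = total + seg.nutrients
        return total

    def stratum(self) -> str:
        """Record stratum, preferring the explicit field over the count rule."""
        if self.record_type is not None:
            return self.record_type
        return classify_record_type(self.n_segments, self.record_kind)


def classify_record_type(n_segments: int, record_kind: str) -> str:
    """Derive the stratum from the reference segment count.

    Foods: >=3 segments composite, 1-2 simple.  Beverages: >=2 composite,
    exactly 1 simple.  Composed beverages recorded as one mixed segment are
    *not* recoverable by this rule — carry the stratum explicitly for those.
    """
    if n_segments < 1:
        raise ValueError("a record must have at least one segment")
    if record_kind == "food":
        return "composite_food" if n_segments >= 3 else "simple_food"
    if record_kind == "beverage":
        return "composite_beverage" if n_segments >= 2 else "simple_beverage"
    raise ValueError(f"unknown record_kind {record_kind!r}")


def read_records(path: str | Path) -> list[Record]:
    """Read a JSON-lines record file; raises with the offending line number."""
    records: list[Record] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(Record.model_validate(json.loads(line)))
            except Exception as exc:  # re-raise with location
                raise ValueError(f"{path}:{lineno}: invalid record: {exc}") from exc
    return records


def write_records(records: Iterable[Record], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.model_dump(exclude_none=True), sort_keys=True) + "\n")


def records_to_frame(records: Sequence[Record]) -> "pd.DataFrame":
    """Flatten records to one row per segment (for inspection / reporting)."""
    import pandas as pd

    rows = []
    for rec in records:
        for idx, seg in enumerate(rec.segments):
            rows.append(
                {
                    "record_id": rec.record_id,
                    "record_kind": rec.record_kind,
                    "entry_mode": rec.entry_mode,
                    "record_type": rec.stratum(),
                    "segment_idx": idx,
                    "label": seg.label,
                    "food_type": seg.food_type,
                    "weight_g": seg.weight_g,
                    **seg.nutrients.model_dump(),
                }
            )
    return pd.DataFrame(rows)
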
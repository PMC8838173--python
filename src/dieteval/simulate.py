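"""Synthetic validation-study generator.

Emulates the statistical structure of a weighed-diary validation study so
every pipeline stage is testable without the (unavailable) raw records: a
reference study of photographed/scanned records in four strata (defaults
63 composite foods / 63 simple foods / 30 composite beverages / 33 simple
beverages, 15 scans, about 352 reference segments), and a simulated tool
observation of it with omissions, intrusions, taxonomic label confusion and
multiplicative log-normal weight noise.

Defaults mirror the reference study's observed rates: per-segment omission
probability 0.02, per-record intrusion probability 5/189 (intrusions drawn
from condiments & sauces — the salad-dressing pattern), grade probabilities
per stratum matching the observed exact/close/far/mismatch mix (composite
beverages exact-match ~= 0.42), systematic weight overestimation for meat,
fish, egg and potato/legume groups, and error-free barcode-scan records.

All randomness flows from one ``numpy`` Generator; the same seed reproduces
the study byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import NutrientVector, Record, Segment
from .taxonomy import FoodTaxonomy, load_fixture_taxonomy

__all__ = [
    "StudyConfig",
    "ErrorModel",
    "load_fixture_composition",
    "generate_reference",
    "simulate_app",
    "simulate_calibration_pairs",
]

#: segment-count distributions per stratum: (values, probabilities); means
#: 3.3 / 1.25 / 1.067 / 1 reproduce the reference study's 352-segment total
SEGMENT_COUNT_DIST = {
    "composite_food": ((3, 4), (0.7, 0.3)),
    "simple_food": ((1, 2), (0.75, 0.25)),
    "composite_beverage": ((1, 2), (28 / 30, 2 / 30)),
    "simple_beverage": ((1,), (1.0,)),
}

#: beverage groups that get confused with one another in mismatches
BEVERAGE_GROUPS = ("NaNs beverages", "NaS beverages", "Alcoholic beverages", "Juice")


@dataclass(frozen=True)
class StudyConfig:
    """Study composition: record counts per stratum, scan fraction, seed."""

    n_composite_food: int = 63
    n_simple_food: int = 63
    n_composite_beverage: int = 30
    n_simple_beverage: int = 33
    scan_fraction: float = 15 / 189  # scans only among simple records
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_composite_food", "n_simple_food", "n_composite_beverage", "n_simple_beverage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.scan_fraction <= 1.0:
            raise ValueError("scan_fraction must lie in [0, 1]")

    @property
    def n_records(self) -> int:
        return (self.n_composite_food + self.n_simple_food
                + self.n_composite_beverage + self.n_simple_beverage)


@dataclass(frozen=True)
class ErrorModel:
    """Tool error process applied to a reference study (photo records only).

    ``grade_probs`` gives per-stratum probabilities of E/C/F/M for each found
    segment; ``group_bias`` multiplies the geometric-mean weight of segments
    in the named food groups; ``weight_sigma`` is the log-normal SD of the
    multiplicative weight error.  ``heavy_tail`` mixes in a wider log-normal
    component to reproduce extreme individual errors.  Scan records are
    error-free by construction.
    """

    p_omit: float = 0.02  # per reference segment
    p_intrude: float = 5 / 189  # per food record
    intrusion_group: str = "Condiments & sauces"
    grade_probs: dict = field(
        default_factory=lambda: {
            "composite_food": (0.901, 0.069, 0.020, 0.010),
            "simple_food": (0.962, 0.038, 0.0, 0.0),
            "composite_beverage": (0.419, 0.387, 0.0, 0.194),
            "simple_beverage": (0.939, 0.0, 0.0, 0.061),
        }
    )
    weight_sigma: float = 0.35
    group_bias: dict = field(
        default_factory=lambda: {
            "Meat & poultry": 1.25,
            "Fish & seafood": 1.25,
            "Eggs & meat substitutes": 1.20,
            "Potatoes, legumes & beans": 1.15,
        }
    )
    heavy_tail: bool = False
    heavy_tail_prob: float = 0.05
    heavy_sigma: float = 0.8

    def __post_init__(self) -> None:
        for p in (self.p_omit, self.p_intrude, self.heavy_tail_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for stratum, probs in self.grade_probs.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"grade probabilities for {stratum} must sum to 1")

    @classmethod
    def noiseless(cls) -> "ErrorModel":
        """All error probabilities zero, zero weight noise: perfect round trip."""
        return cls(
            p_omit=0.0,
            p_intrude=0.0,
            grade_probs={s: (1.0, 0.0, 0.0, 0.0) for s in SEGMENT_COUNT_DIST},
            weight_sigma=0.0,
            group_bias={},
        )


def load_fixture_composition() -> pd.DataFrame:
    """Bundled synthetic per-100 g composition table (invented, physiologic)."""
    path = resources.files("dieteval.data").joinpath("composition_fixture.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, comment="#")


def _sample_weight(rng: np.random.Generator, typical: float) -> float:
    """Serving weight around the item's typical value (log-normal, CV ~25%)."""
    return float(typical * rng.lognormal(mean=0.0, sigma=0.25))


def generate_reference(
    cfg: StudyConfig,
    tax: Optional[FoodTaxonomy] = None,
    composition: Optional[pd.DataFrame] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[Record]:
    """Generate the gold-standard (weighed-diary) side of a synthetic study.

    Stratum constraints hold by construction (composite foods get >=3
    segments, simple beverages exactly 1, ...); nutrient vectors are
    weight x per-100 g composition / 100; scans occur only among simple
    records.  Deterministic given ``cfg.seed`` (or an explicit ``rng``).
    """
    tax = tax if tax is not None else load_fixture_taxonomy()
    comp = composition if composition is not None else load_fixture_composition()
    if comp.empty:
        raise ValueError("empty composition table")
    unknown = set(comp["food_type"]) - tax.types
    if unknown:
        raise ValueError(f"composition table references unknown food types: {sorted(unknown)}")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    foods = comp[comp["kind"] == "food"].reset_index(drop=True)
    bevs = comp[comp["kind"] == "beverage"].reset_index(drop=True)
    if foods.empty or bevs.empty:
        raise ValueError("composition table needs both food and beverage items")

    strata = (
        ["composite_food"] * cfg.n_composite_food
        + ["simple_food"] * cfg.n_simple_food
        + ["composite_beverage"] * cfg.n_composite_beverage
        + ["simple_beverage"] * cfg.n_simple_beverage
    )
    # scans only among simple records
    simple_idx = [i for i, s in enumerate(strata) if s.startswith("simple")]
    n_scans = min(round(cfg.scan_fraction * len(strata)), len(simple_idx))
    scan_set = set(rng.choice(simple_idx, size=n_scans, replace=False)) if n_scans else set()

    records: list[Record] = []
    for i, stratum in enumerate(strata):
        kind = "food" if stratum.endswith("food") else "beverage"
        pool = foods if kind == "food" else bevs
        values, probs = SEGMENT_COUNT_DIST[stratum]
        n_seg = int(rng.choice(values, p=probs))
        rows = pool.iloc[rng.choice(len(pool), size=n_seg, replace=n_seg > len(pool))]
        segments = []
        for _, item in rows.iterrows():
            w = _sample_weight(rng, item["typical_weight_g"])
            segments.append(
                Segment(
                    label=item["label"],
                    food_type=item["food_type"],
                    weight_g=w,
                    nutrients=NutrientVector.from_per100g(
                        {k: item[k] for k in NutrientVector.model_fields}, w
                    ),
                )
            )
        records.append(
            Record(
                record_id=f"R{i:04d}",
                record_kind=kind,
                entry_mode="scan" if i in scan_set else "photo",
                record_type=stratum,
                segments=segments,
            )
        )
    return records


def _items_of_type(comp: pd.DataFrame, food_type: str) -> pd.DataFrame:
    return comp[comp["food_type"] == food_type]


def _confused_type(
    rng: np.random.Generator,
    true_type: str,
    tax: FoodTaxonomy,
    comp: pd.DataFrame,
    same_group: bool,
    beverage: bool,
) -> Optional[str]:
    """Draw a wrong food type, same group (far) or different group (mismatch)."""
    group, _ = tax.roll_up(true_type)
    if same_group:
        candidates = [t for t in sorted(tax.types)
                      if t != true_type and tax.group_of(t) == group]
    elif beverage:
        # liquids get confused with other beverage groups
        candidates = [t for t in sorted(tax.types)
                      if tax.group_of(t) != group and tax.group_of(t) in BEVERAGE_GROUPS]
        if not candidates:
            candidates = [t for t in sorted(tax.types) if tax.group_of(t) != group]
    else:
        candidates = [t for t in sorted(tax.types) if tax.group_of(t) != group]
    candidates = [t for t in candidates if not _items_of_type(comp, t).empty]
    if not candidates:
        return None
    return str(rng.choice(candidates))


def simulate_app(
    reference: Sequence[Record],
    em: ErrorModel,
    tax: Optional[FoodTaxonomy] = None,
    composition: Optional[pd.DataFrame] = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[Record], pd.DataFrame]:
    """Simulate the tool's observation of a reference study.

    Returns the tool-side records plus a ground-truth link table
    (record_id, ref_idx, app_idx, grade, flags) that lets downstream stages
    bypass automatic linking.  Omitted segments appear in neither; intruded
    segments get app_idx only (ref_idx -1, grade "I").
    """
    tax = tax if tax is not None else load_fixture_taxonomy()
    comp = composition if composition is not None else load_fixture_composition()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    intrusion_pool = comp[comp["food_type"].map(lambda t: tax.group_of(t)) == em.intrusion_group]

    app_records: list[Record] = []
    link_rows: list[dict] = []
    for rec in reference:
        stratum = rec.stratum()
        app_segments: list[Segment] = []
        for ref_idx, seg in enumerate(rec.segments):
            if rec.entry_mode == "scan":
                app_segments.append(seg.model_copy(deep=True))
                link_rows.append(_link(rec, ref_idx, len(app_segments) - 1, "E", ""))
                continue
            if rng.random() < em.p_omit:
                continue  # omission: no app segment, no link row
            grade = str(rng.choice(["E", "C", "F", "M"], p=em.grade_probs[stratum]))
            flags = ""
            app_type = seg.food_type
            label = seg.label
            item = None
            if grade == "C":
                flags = str(rng.choice(["too_generic", "slight_variant", "overlooked_ingredient"]))
            elif grade in ("F", "M"):
                wrong = _confused_type(
                    rng, seg.food_type, tax, comp,
                    same_group=(grade == "F"), beverage=rec.record_kind == "beverage",
                )
                if wrong is None:  # taxonomy offers no such confusion; degrade to close
                    grade, flags = "C", "slight_variant"
                else:
                    app_type = wrong
                    item = _items_of_type(comp, wrong).iloc[0]
                    label = item["label"]

            bias = em.group_bias.get(tax.group_of(seg.food_type), 1.0)
            sigma = em.weight_sigma
            if em.heavy_tail and rng.random() < em.heavy_tail_prob:
                sigma = em.heavy_sigma
            noise = rng.lognormal(mean=0.0, sigma=sigma) if sigma > 0 else 1.0
            est_w = seg.weight_g * bias * noise

            if item is None:  # same-type label: tool uses the matching composition
                nutrients = NutrientVector(
                    **{k: getattr(seg.nutrients, k) * est_w / seg.weight_g
                       for k in NutrientVector.model_fields}
                )
            else:
                nutrients = NutrientVector.from_per100g(
                    {k: item[k] for k in NutrientVector.model_fields}, est_w
                )
            app_segments.append(
                Segment(label=label, food_type=app_type, weight_g=est_w, nutrients=nutrients)
            )
            link_rows.append(_link(rec, ref_idx, len(app_segments) - 1, grade, flags))

        if (rec.record_kind == "food" and rec.entry_mode == "photo"
                and not intrusion_pool.empty and rng.random() < em.p_intrude):
            item = intrusion_pool.iloc[int(rng.integers(len(intrusion_pool)))]
            w = _sample_weight(rng, item["typical_weight_g"])
            app_segments.append(
                Segment(
                    label=item["label"],
                    food_type=item["food_type"],
                    weight_g=w,
                    nutrients=NutrientVector.from_per100g(
                        {k: item[k] for k in NutrientVector.model_fields}, w
                    ),
                )
            )
            link_rows.append(_link(rec, -1, len(app_segments) - 1, "I", ""))

        app_records.append(
            Record(
                record_id=rec.record_id,
                record_kind=rec.record_kind,
                entry_mode=rec.entry_mode,
                record_type=rec.record_type,
                segments=app_segments,
            )
        )
    links = pd.DataFrame(link_rows, columns=["record_id", "ref_idx", "app_idx", "grade", "flags"])
    return app_records, links


def _link(rec: Record, ref_idx: int, app_idx: int, grade: str, flags: str) -> dict:
    return {
        "record_id": rec.record_id,
        "ref_idx": ref_idx,
        "app_idx": app_idx,
        "grade": grade,
        "flags": flags,
    }


def simulate_calibration_pairs(
    n: int,
    alpha: float,
    beta: float,
    s0: float,
    s1: float,
    seed: int | np.random.Generator = 0,
    x_median: float = 250.0,
    x_log_sigma: float = 0.7,
    zero_mass: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (x, y) from the agreement model y = alpha + beta*x + (s0+s1*x)*eps.

    True values x are log-normal (median ``x_median``, log-SD ``x_log_sigma``
    — an energy-like right-skewed distribution); ``zero_mass`` puts a point
    mass at x = 0, as for alcohol where most records contain none.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = x_median * rng.lognormal(mean=0.0, sigma=x_log_sigma, size=n)
    if zero_mass > 0:
        x[rng.random(n) < zero_mass] = 0.0
    sigma = np.maximum(s0 + s1 * x, 0.0)
    y = alpha + beta * x + sigma * rng.standard_normal(n)
    return x, y
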
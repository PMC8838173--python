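"""Hierarchical food taxonomy: types nest in groups, groups in categories.

The classification stage of a dietary-assessment validation compares labels at
three granularities (in the reference study 37 food types, 23 food groups and
7 food categories, the coarsest mirroring the Swiss food pyramid).  Mixed
segments — e.g. a potato gratin — are assigned to the type of the ingredient
contributing the most energy.

The bundled taxonomy (``load_fixture_taxonomy``) is a synthetic fixture: it has
the study's 37/23/7 shape and the published food-group names, but the type
level beneath the groups is invented because no public type list exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

__all__ = [
    "FoodTaxonomy",
    "Ingredient",
    "TaxonomyError",
    "DuplicateTypeError",
    "EmptyTableError",
    "UnknownTypeError",
    "load_taxonomy",
    "load_fixture_taxonomy",
    "assign_mixed_segment",
]


class TaxonomyError(ValueError):
    """Base class for taxonomy validation failures."""


class DuplicateTypeError(TaxonomyError):
    """A food type is listed under two different groups (or a group under two categories)."""


class EmptyTableError(TaxonomyError):
    """The taxonomy table has no rows."""


class UnknownTypeError(KeyError):
    """A label is not a type of this taxonomy."""


@dataclass(frozen=True)
class FoodTaxonomy:
    """Validated three-level hierarchy with total roll-up maps.

    Invariants (enforced at construction): every type maps to exactly one
    group and every group to exactly one category; the maps are surjective,
    so ``q_t >= q_g >= q_c >= 1``.
    """

    type_to_group: Mapping[str, str]
    group_to_category: Mapping[str, str]

    types: frozenset = field(init=False)
    groups: frozenset = field(init=False)
    categories: frozenset = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "types", frozenset(self.type_to_group))
        object.__setattr__(self, "groups", frozenset(self.group_to_category))
        object.__setattr__(self, "categories", frozenset(self.group_to_category.values()))
        if not self.types:
            raise EmptyTableError("taxonomy has no food types")
        missing = set(self.type_to_group.values()) - self.groups
        if missing:
            raise TaxonomyError(f"groups without a category: {sorted(missing)}")
        orphan = self.groups - set(self.type_to_group.values())
        if orphan:
            raise TaxonomyError(f"groups with no type beneath them: {sorted(orphan)}")

    @property
    def q_t(self) -> int:
        return len(self.types)

    @property
    def q_g(self) -> int:
        return len(self.groups)

    @property
    def q_c(self) -> int:
        return len(self.categories)

    def roll_up(self, food_type: str) -> tuple[str, str]:
        """Return ``(group, category)`` for a food type."""
        try:
            group = self.type_to_group[food_type]
        except KeyError:
            raise UnknownTypeError(food_type) from None
        return group, self.group_to_category[group]

    def group_of(self, food_type: str) -> str:
        return self.roll_up(food_type)[0]

    def category_of(self, food_type: str) -> str:
        return self.roll_up(food_type)[1]

    def level_label(self, food_type: str, level: str) -> str:
        """Map a type to its label at ``level`` in {'type','group','category'}."""
        if level == "type":
            if food_type not in self.types:
                raise UnknownTypeError(food_type)
            return food_type
        group, category = self.roll_up(food_type)
        if level == "group":
            return group
        if level == "category":
            return category
        raise ValueError(f"unknown level {level!r}")

    def n_labels(self, level: str) -> int:
        return {"type": self.q_t, "group": self.q_g, "category": self.q_c}[level]


@dataclass(frozen=True)
class Ingredient:
    """One weighed ingredient of a mixed segment."""

    label: str
    food_type: str
    weight: float  # grams
    energy_density: float  # kcal per 100 g

    def __post_init__(self) -> None:
        if not (self.weight > 0 and self.weight < float("inf")):
            raise ValueError(f"ingredient weight must be positive and finite, got {self.weight}")
        if not (self.energy_density >= 0 and self.energy_density < float("inf")):
            raise ValueError(f"energy density must be finite and >= 0, got {self.energy_density}")

    @property
    def energy_kcal(self) -> float:
        return self.weight * self.energy_density / 100.0


TableLike = Union[str, Path, pd.DataFrame, Iterable[tuple]]


def load_taxonomy(table: TableLike) -> FoodTaxonomy:
    """Build a validated :class:`FoodTaxonomy` from a ``type,group,category`` table.

    ``table`` may be a CSV path (UTF-8, header ``type,group,category``), a
    DataFrame with those columns, or an iterable of (type, group, category)
    rows.  Raises :class:`DuplicateTypeError` if a type appears under two
    different groups, :class:`EmptyTableError` on an empty table.
    """
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table, comment="#")
    elif isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.DataFrame(list(table), columns=["type", "group", "category"])
    required = {"type", "group", "category"}
    if not required.issubset(df.columns):
        raise TaxonomyError(f"taxonomy table must have columns {sorted(required)}")
    if df.empty:
        raise EmptyTableError("taxonomy table is empty")

    type_to_group: dict[str, str] = {}
    group_to_category: dict[str, str] = {}
    for row in df.itertuples(index=False):
        t, g, c = str(row.type), str(row.group), str(row.category)
        if t in type_to_group and type_to_group[t] != g:
            raise DuplicateTypeError(
                f"type {t!r} listed under groups {type_to_group[t]!r} and {g!r}"
            )
        if g in group_to_category and group_to_category[g] != c:
            raise DuplicateTypeError(
                f"group {g!r} listed under categories {group_to_category[g]!r} and {c!r}"
            )
        type_to_group[t] = g
        group_to_category[g] = c
    return FoodTaxonomy(type_to_group=type_to_group, group_to_category=group_to_category)


def load_fixture_taxonomy() -> FoodTaxonomy:
    """Load the bundled synthetic 37-type / 23-group / 7-category fixture taxonomy."""
    path = resources.files("dieteval.data").joinpath("taxonomy_fixture.csv")
    with resources.as_file(path) as p:
        return load_taxonomy(p)


def assign_mixed_segment(ingredients: Sequence[Ingredient]) -> str:
    """Food type of a mixed segment: the ingredient with the highest total energy.

    Energy is total kcal (weight x kcal/100 g).  Ties are broken
    deterministically: larger weight wins, then lexicographically smallest
    label — so the result is invariant under input-order permutation.
    """
    if not ingredients:
        raise ValueError("assign_mixed_segment requires at least one ingredient")
    best = min(ingredients, key=lambda ing: (-ing.energy_kcal, -ing.weight, ing.label))
    return best.food_type
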
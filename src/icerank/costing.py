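"""Ingredients-based unit costing and cross-country/year standardization.

Workforce ingredients are inflated to the reference year with a consumer
price index and re-referenced to a common annual-wage anchor; non-workforce
ingredients (materials such as books and toys) pass through unchanged. CPI
and wage tables are configuration, never fetched at runtime.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import yaml

__all__ = [
    "IngredientCategory",
    "CostIngredient",
    "StandardizationParams",
    "MissingTableEntryError",
    "unit_cost_per_child",
    "inflate_to_reference",
    "standardize_unit_cost",
    "load_params_yaml",
    "read_ingredients_csv",
]


class IngredientCategory(str, enum.Enum):
    WORKFORCE = "workforce"
    NON_WORKFORCE = "non_workforce"


@dataclass(frozen=True)
class CostIngredient:
    name: str
    category: IngredientCategory
    amount: float

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"ingredient {self.name!r}: amount must be >= 0")


class MissingTableEntryError(KeyError):
    """A required (country, year) key is absent from a CPI or wage table."""


@dataclass(frozen=True)
class StandardizationParams:
    """Reference year/wage anchor plus CPI and local-wage lookup tables."""

    reference_year: int
    reference_wage: float
    cpi_table: Mapping[str, Mapping[int, float]]
    local_wage_table: Mapping[str, Mapping[int, float]]

    def __post_init__(self) -> None:
        if self.reference_wage <= 0:
            raise ValueError("reference_wage must be > 0")
        for country, by_year in self.cpi_table.items():
            for year, value in by_year.items():
                if value <= 0:
                    raise ValueError(f"CPI({country}, {year}) must be > 0")
        for country, by_year in self.local_wage_table.items():
            for year, value in by_year.items():
                if value <= 0:
                    raise ValueError(f"wage({country}, {year}) must be > 0")

    def cpi(self, country: str, year: int) -> float:
        try:
            return self.cpi_table[country][year]
        except KeyError:
            raise MissingTableEntryError(f"CPI table has no entry for ({country}, {year})") from None

    def local_wage(self, country: str, year: int) -> float:
        try:
            return self.local_wage_table[country][year]
        except KeyError:
            raise MissingTableEntryError(f"wage table has no entry for ({country}, {year})") from None


def unit_cost_per_child(total_cost: float, n_children: int) -> float:
    """Total programme cost divided by number of children targeted."""
    if total_cost < 0:
        raise ValueError("total_cost must be >= 0")
    if n_children < 1:
        raise ValueError("no beneficiaries: n_children must be >= 1")
    return total_cost / n_children


def inflate_to_reference(
    amount: float,
    country: str,
    year_from: int,
    params: StandardizationParams,
) -> float:
    """Rescale an amount to reference-year terms by the CPI ratio."""
    ratio = params.cpi(country, params.reference_year) / params.cpi(country, year_from)
    return amount * ratio


def standardize_unit_cost(
    ingredients: Iterable[CostIngredient],
    country: str,
    cost_year: int,
    n_children: int,
    params: StandardizationParams,
) -> float:
    """Standardized cost per child in reference-year, reference-wage terms.

    Workforce amounts are CPI-inflated to the reference year then scaled by
    reference_wage / local_wage(country, reference_year); non-workforce
    amounts pass through unchanged (already comparable across settings).
    Both steps are multiplicative scalars, so their order does not affect
    the result.
    """
    ingredients = list(ingredients)
    if not ingredients:
        raise ValueError("empty ingredient list")
    if n_children < 1:
        raise ValueError("no beneficiaries: n_children must be >= 1")

    total = 0.0
    for ing in ingredients:
        if ing.category is IngredientCategory.WORKFORCE:
            inflated = inflate_to_reference(ing.amount, country, cost_year, params)
            wage_ratio = params.reference_wage / params.local_wage(
                country, params.reference_year
            )
            total += inflated * wage_ratio
        else:
            total += ing.amount
    return total / n_children


def load_params_yaml(path: Union[str, Path]) -> StandardizationParams:
    """Read standardization parameters from a YAML config file.

    Expected keys: reference_year, reference_wage, cpi_table
    (country -> year -> index) and local_wage_table (country -> year -> wage).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return StandardizationParams(
        reference_year=int(doc["reference_year"]),
        reference_wage=float(doc["reference_wage"]),
        cpi_table={
            str(c): {int(y): float(v) for y, v in by_year.items()}
            for c, by_year in doc.get("cpi_table", {}).items()
        },
        local_wage_table={
            str(c): {int(y): float(v) for y, v in by_year.items()}
            for c, by_year in doc.get("local_wage_table", {}).items()
        },
    )


def read_ingredients_csv(path: Union[str, Path]) -> dict[str, list[tuple[CostIngredient, str, int]]]:
    """Read an ingredients CSV (arm_id, ingredient_name, category, amount,
    country, cost_year) grouped by arm_id."""
    import pandas as pd

    frame = pd.read_csv(path)
    required = {"arm_id", "ingredient_name", "category", "amount", "country", "cost_year"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"ingredients table missing columns: {sorted(missing)}")
    grouped: dict[str, list[tuple[CostIngredient, str, int]]] = {}
    for _, row in frame.iterrows():
        ing = CostIngredient(
            name=str(row["ingredient_name"]),
            category=IngredientCategory(str(row["category"])),
            amount=float(row["amount"]),
        )
        grouped.setdefault(str(row["arm_id"]), []).append(
            (ing, str(row["country"]), int(row["cost_year"]))
        )
    return grouped
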
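"""Domain types, validation, and portfolio serialization.

The central object is the :class:`InterventionArm`: one study arm with a
cost record and one or more domain-specific standardized effect estimates
(Cohen's *d* with a 95% uncertainty range). Portfolios (lists of arms) can
be round-tripped through a long-format CSV (one row per effect) or an
equivalent nested JSON document.

Validation never raises on bad data: :func:`validate_portfolio` returns a
list of findings so callers can report every violation at once.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

__all__ = [
    "DomainName",
    "Domain",
    "EffectEstimate",
    "CostRecord",
    "InterventionArm",
    "SchemeKind",
    "CostBasis",
    "WeightScheme",
    "AggregateEffect",
    "ICERResult",
    "Finding",
    "validate_portfolio",
    "portfolio_to_frame",
    "frame_to_portfolio",
    "write_portfolio_csv",
    "read_portfolio_csv",
    "portfolio_to_json",
    "portfolio_from_json",
    "PORTFOLIO_COLUMNS",
]


class DomainName(str, enum.Enum):
    """Developmental domains assessed in children under three."""

    COGNITIVE = "cognitive"
    LANGUAGE = "language"
    EXPRESSIVE_LANGUAGE = "expressive_language"
    RECEPTIVE_LANGUAGE = "receptive_language"
    FINE_MOTOR = "fine_motor"
    GROSS_MOTOR = "gross_motor"
    MOTOR = "motor"
    SOCIOEMOTIONAL = "socioemotional"


@dataclass(frozen=True, order=True)
class Domain:
    """A developmental domain, optionally qualified by a study subgroup.

    The subgroup qualifier distinguishes multiple estimates for the same
    domain within one arm (e.g. ``cognitive`` results reported separately
    for an iron-deficient and a non-iron-deficient subgroup).
    """

    name: DomainName
    subgroup: str = ""

    def label(self) -> str:
        if self.subgroup:
            return f"{self.name.value} ({self.subgroup})"
        return self.name.value


@dataclass(frozen=True)
class EffectEstimate:
    """One standardized (Cohen's *d*) effect with its 95% uncertainty range."""

    domain: Domain
    estimate: float
    lower: float
    upper: float
    significant: bool = False


@dataclass(frozen=True)
class CostRecord:
    """Intervention cost in study-local currency-year USD and 2010 reference USD.

    ``total_cost`` may be missing (some studies report only per-child
    figures). Amounts are stored at full precision; rounding happens only
    at display time.
    """

    per_child_local: Optional[float] = None
    per_child_standardized: Optional[float] = None
    total_cost: Optional[float] = None
    n_children: Optional[int] = None
    country: str = ""
    cost_year: Optional[int] = None

    def per_child(self, basis: "CostBasis") -> float:
        value = (
            self.per_child_local
            if basis is CostBasis.LOCAL
            else self.per_child_standardized
        )
        if value is None:
            raise ValueError(f"no per-child cost on the {basis.value} basis")
        return value


@dataclass(frozen=True)
class InterventionArm:
    """A study arm: identification, cost record, and reported effects.

    ``league_eligible`` marks arms that enter ICER league tables; it is
    carried as data because the inclusion rule is not computable from the
    arm itself.
    """

    arm_id: str
    study_label: str
    country: str
    study_year: Optional[int]
    cost: CostRecord
    effects: tuple[EffectEstimate, ...]
    year_imputed: bool = False
    league_eligible: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", tuple(self.effects))


class SchemeKind(str, enum.Enum):
    AVERAGED = "averaged"
    SUMMED = "summed"
    CUSTOM = "custom"


class CostBasis(str, enum.Enum):
    LOCAL = "local"
    STANDARDIZED = "standardized"


@dataclass(frozen=True)
class WeightScheme:
    """Non-negative weights over an arm's (domain, subgroup) effect keys."""

    kind: SchemeKind
    weights: dict[Domain, float]

    def weight_for(self, domain: Domain) -> float:
        try:
            return self.weights[domain]
        except KeyError:
            raise KeyError(f"no weight for effect {domain.label()!r}") from None


@dataclass(frozen=True)
class AggregateEffect:
    """Weighted benefit with bound-wise propagated uncertainty range."""

    point: float
    lower: float
    upper: float
    scheme_kind: SchemeKind


@dataclass(frozen=True)
class ICERResult:
    """Incremental cost-effectiveness ratio for one arm under one scheme/basis.

    ``point``/``lower``/``upper`` are unrounded dollars per SD. ``upper`` is
    +inf with ``upper_unbounded`` set when the benefit's lower bound is
    non-positive; all three are NaN when the arm is dominated.
    """

    arm_id: str
    point: float
    lower: float
    upper: float
    cost_basis: CostBasis
    scheme_kind: SchemeKind
    effect: AggregateEffect
    cost_per_child: float
    upper_unbounded: bool = False
    dominated: bool = False
    rank: Optional[int] = None
    study_label: str = ""


@dataclass(frozen=True)
class Finding:
    """One validation violation, addressed by arm and field path."""

    arm_id: str
    field_path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.arm_id}] {self.field_path}: {self.message}"


def _finite(*values: Optional[float]) -> bool:
    return all(v is not None and math.isfinite(v) for v in values)


def validate_portfolio(arms: Iterable[InterventionArm]) -> list[Finding]:
    """Check every type invariant; return one finding per violation.

    Returns an empty list iff the portfolio is valid. Findings are emitted
    in arm order, so permuting the input permutes the findings without
    changing their content.
    """
    arms = list(arms)
    findings: list[Finding] = []
    seen_ids: set[str] = set()

    for arm in arms:
        if arm.arm_id in seen_ids:
            findings.append(Finding(arm.arm_id, "arm_id", "duplicate arm_id"))
        seen_ids.add(arm.arm_id)

        if not arm.effects:
            findings.append(Finding(arm.arm_id, "effects", "arm has no effects"))

        seen_domains: set[Domain] = set()
        for i, eff in enumerate(arm.effects):
            path = f"effects[{i}]"
            if not isinstance(eff.domain.name, DomainName):
                findings.append(
                    Finding(arm.arm_id, f"{path}.domain", "unknown domain name")
                )
            if eff.domain in seen_domains:
                findings.append(
                    Finding(
                        arm.arm_id,
                        f"{path}.domain",
                        f"duplicate (domain, subgroup) pair {eff.domain.label()!r}",
                    )
                )
            seen_domains.add(eff.domain)
            if not _finite(eff.estimate, eff.lower, eff.upper):
                findings.append(
                    Finding(arm.arm_id, path, "non-finite effect value")
                )
                continue
            if not (eff.lower <= eff.estimate <= eff.upper):
                findings.append(
                    Finding(
                        arm.arm_id,
                        path,
                        f"bounds not ordered: lower={eff.lower} "
                        f"estimate={eff.estimate} upper={eff.upper}",
                    )
                )

        cost = arm.cost
        for name in ("per_child_local", "per_child_standardized", "total_cost"):
            value = getattr(cost, name)
            if value is not None and (not math.isfinite(value) or value < 0):
                findings.append(
                    Finding(arm.arm_id, f"cost.{name}", f"negative or non-finite: {value}")
                )
        if (
            cost.total_cost is not None
            and cost.n_children is not None
            and cost.per_child_local is not None
            and cost.n_children > 0
        ):
            implied = cost.total_cost / cost.n_children
            if abs(implied - cost.per_child_local) > 0.5:
                findings.append(
                    Finding(
                        arm.arm_id,
                        "cost.per_child_local",
                        f"inconsistent with total/n ({implied:.2f} vs "
                        f"{cost.per_child_local})",
                    )
                )

    return findings


# ---------------------------------------------------------------------------
# Serialization: long-format CSV and nested JSON
# ---------------------------------------------------------------------------

PORTFOLIO_COLUMNS = [
    "arm_id",
    "study_label",
    "country",
    "study_year",
    "year_imputed",
    "total_cost",
    "per_child_local",
    "per_child_standardized",
    "league_eligible",
    "domain",
    "subgroup",
    "estimate",
    "lower",
    "upper",
    "significant",
]


def portfolio_to_frame(arms: Iterable[InterventionArm]) -> pd.DataFrame:
    """Long-format frame: one row per effect, arm fields repeated."""
    rows = []
    for arm in arms:
        for eff in arm.effects:
            rows.append(
                {
                    "arm_id": arm.arm_id,
                    "study_label": arm.study_label,
                    "country": arm.country,
                    "study_year": arm.study_year,
                    "year_imputed": arm.year_imputed,
                    "total_cost": arm.cost.total_cost,
                    "per_child_local": arm.cost.per_child_local,
                    "per_child_standardized": arm.cost.per_child_standardized,
                    "league_eligible": arm.league_eligible,
                    "domain": eff.domain.name.value,
                    "subgroup": eff.domain.subgroup,
                    "estimate": eff.estimate,
                    "lower": eff.lower,
                    "upper": eff.upper,
                    "significant": eff.significant,
                }
            )
    return pd.DataFrame(rows, columns=PORTFOLIO_COLUMNS)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def _opt_int(value) -> Optional[int]:
    f = _opt_float(value)
    return None if f is None else int(f)


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"true", "1", "yes"}
    return bool(value)


def frame_to_portfolio(frame: pd.DataFrame) -> list[InterventionArm]:
    missing = [c for c in PORTFOLIO_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"portfolio table missing columns: {missing}")

    arms: list[InterventionArm] = []
    for arm_id, group in frame.groupby("arm_id", sort=False):
        first = group.iloc[0]
        effects = tuple(
            EffectEstimate(
                domain=Domain(
                    DomainName(row["domain"]),
                    "" if pd.isna(row["subgroup"]) else str(row["subgroup"]),
                ),
                estimate=float(row["estimate"]),
                lower=float(row["lower"]),
                upper=float(row["upper"]),
                significant=_as_bool(row["significant"]),
            )
            for _, row in group.iterrows()
        )
        arms.append(
            InterventionArm(
                arm_id=str(arm_id),
                study_label=str(first["study_label"]),
                country=str(first["country"]),
                study_year=_opt_int(first["study_year"]),
                year_imputed=_as_bool(first["year_imputed"]),
                cost=CostRecord(
                    per_child_local=_opt_float(first["per_child_local"]),
                    per_child_standardized=_opt_float(first["per_child_standardized"]),
                    total_cost=_opt_float(first["total_cost"]),
                    country=str(first["country"]),
                    cost_year=_opt_int(first["study_year"]),
                ),
                effects=effects,
                league_eligible=_as_bool(first["league_eligible"]),
            )
        )
    return arms


def write_portfolio_csv(arms: Iterable[InterventionArm], path: Union[str, Path]) -> None:
    portfolio_to_frame(arms).to_csv(path, index=False)


def read_portfolio_csv(path: Union[str, Path]) -> list[InterventionArm]:
    frame = pd.read_csv(path, dtype={"subgroup": str, "country": str}, keep_default_na=True)
    frame["subgroup"] = frame["subgroup"].fillna("")
    return frame_to_portfolio(frame)


def portfolio_to_json(arms: Iterable[InterventionArm]) -> str:
    """Nested JSON document: one object per arm with an effects array."""
    doc = []
    for arm in arms:
        doc.append(
            {
                "arm_id": arm.arm_id,
                "study_label": arm.study_label,
                "country": arm.country,
                "study_year": arm.study_year,
                "year_imputed": arm.year_imputed,
                "league_eligible": arm.league_eligible,
                "cost": {
                    "total_cost": arm.cost.total_cost,
                    "per_child_local": arm.cost.per_child_local,
                    "per_child_standardized": arm.cost.per_child_standardized,
                    "n_children": arm.cost.n_children,
                    "country": arm.cost.country,
                    "cost_year": arm.cost.cost_year,
                },
                "effects": [
                    {
                        "domain": eff.domain.name.value,
                        "subgroup": eff.domain.subgroup,
                        "estimate": eff.estimate,
                        "lower": eff.lower,
                        "upper": eff.upper,
                        "significant": eff.significant,
                    }
                    for eff in arm.effects
                ],
            }
        )
    return json.dumps(doc, indent=2)


def portfolio_from_json(text: str) -> list[InterventionArm]:
    doc = json.loads(text)
    arms = []
    for obj in doc:
        cost = obj.get("cost", {})
        arms.append(
            InterventionArm(
                arm_id=obj["arm_id"],
                study_label=obj.get("study_label", ""),
                country=obj.get("country", ""),
                study_year=obj.get("study_year"),
                year_imputed=bool(obj.get("year_imputed", False)),
                league_eligible=bool(obj.get("league_eligible", True)),
                cost=CostRecord(
                    per_child_local=_opt_float(cost.get("per_child_local")),
                    per_child_standardized=_opt_float(cost.get("per_child_standardized")),
                    total_cost=_opt_float(cost.get("total_cost")),
                    n_children=_opt_int(cost.get("n_children")),
                    country=cost.get("country", ""),
                    cost_year=_opt_int(cost.get("cost_year")),
                ),
                effects=tuple(
                    EffectEstimate(
                        domain=Domain(DomainName(e["domain"]), e.get("subgroup", "")),
                        estimate=float(e["estimate"]),
                        lower=float(e["lower"]),
                        upper=float(e["upper"]),
                        significant=bool(e.get("significant", False)),
                    )
                    for e in obj["effects"]
                ),
            )
        )
    return arms
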
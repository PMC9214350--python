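"""ICER computation, interval propagation, display rounding, and ranking.

ICER = (C_i - C_0) / (B_i - B_0): incremental cost per SD of aggregate
developmental benefit. Because the bundled study data are already
control-relative, the status quo defaults to (C_0, B_0) = (0, 0), but the
API accepts explicit baselines. Uncertainty ranges map inversely onto the
ICER: the effect's upper bound gives the ICER's lower bound and vice versa,
with the cost treated as fixed.

Display rounding is banker's (half-to-even) on decimal-snapped values:
money to whole dollars, effects to two decimals. Ratios of printed
two-decimal effects and whole-dollar costs land exactly on .5 boundaries
(e.g. 99/0.40 = 247.5), and half-to-even is the unique convention
consistent with all published league-table cells. Everything upstream of
display stays at full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .core_model import (
    AggregateEffect,
    CostBasis,
    ICERResult,
    InterventionArm,
    SchemeKind,
)
from .effects import aggregate, make_scheme

__all__ = [
    "DominatedError",
    "LeagueTable",
    "MonteCarloInterval",
    "round_display",
    "icer_point",
    "icer_interval",
    "evaluate_arm",
    "rank_arms",
    "monte_carlo_interval",
]


class DominatedError(ValueError):
    """The incremental benefit is non-positive; no meaningful ICER exists."""


def round_display(value: float, decimals: int = 0) -> Union[int, float]:
    """Round for display: money to whole dollars (decimals=0, returns int),
    effects to 2 decimals (returns float). Half-to-even on the decimal-
    snapped value, so exact .5 ratios of printed inputs round predictably
    regardless of binary float error.
    """
    if not math.isfinite(value):
        raise ValueError(f"cannot display non-finite value {value}")
    # Snap accumulated binary error back to the intended decimal value; all
    # upstream inputs have <= 2 decimals so 12 places is far beyond exact.
    snapped = Decimal(repr(round(value, 12)))
    quantum = Decimal(1).scaleb(-decimals)
    rounded = snapped.quantize(quantum, rounding=ROUND_HALF_EVEN)
    return float(rounded) if decimals > 0 else int(rounded)


def icer_point(
    cost_i: float,
    cost_0: float = 0.0,
    benefit_i: float = 0.0,
    benefit_0: float = 0.0,
) -> float:
    """(cost_i - cost_0) / (benefit_i - benefit_0) at full precision."""
    delta_benefit = benefit_i - benefit_0
    if delta_benefit <= 0:
        raise DominatedError(
            f"incremental benefit {delta_benefit} is non-positive; ICER undefined"
        )
    return (cost_i - cost_0) / delta_benefit


def icer_interval(
    delta_cost: float, benefit: AggregateEffect
) -> tuple[float, float]:
    """95% UR of the ICER: (delta_cost / benefit.upper, delta_cost / benefit.lower).

    If the benefit's lower bound is non-positive the upper ICER bound is
    unbounded (+inf). If even the upper benefit bound is non-positive the
    whole interval is undefined (dominated).
    """
    if delta_cost < 0:
        raise ValueError("delta_cost must be >= 0")
    if benefit.upper <= 0:
        raise DominatedError("benefit upper bound non-positive; interval undefined")
    lower = delta_cost / benefit.upper
    upper = math.inf if benefit.lower <= 0 else delta_cost / benefit.lower
    return lower, upper


def evaluate_arm(
    arm: InterventionArm,
    scheme_kind: Union[SchemeKind, str],
    cost_basis: Union[CostBasis, str],
    cost_0: float = 0.0,
    benefit_0: float = 0.0,
) -> ICERResult:
    """Aggregate the arm's effects and compute its ICER with UR.

    Dominated arms (aggregate benefit <= 0) come back flagged with NaN
    values rather than raising, so portfolio evaluation never aborts.
    """
    scheme_kind = SchemeKind(scheme_kind)
    cost_basis = CostBasis(cost_basis)
    scheme = make_scheme(scheme_kind, arm.effects)
    benefit = aggregate(arm.effects, scheme)
    cost = arm.cost.per_child(cost_basis)

    try:
        point = icer_point(cost, cost_0, benefit.point, benefit_0)
        lower, upper = icer_interval(cost - cost_0, benefit)
    except DominatedError:
        return ICERResult(
            arm_id=arm.arm_id,
            point=math.nan,
            lower=math.nan,
            upper=math.nan,
            cost_basis=cost_basis,
            scheme_kind=scheme_kind,
            effect=benefit,
            cost_per_child=cost,
            dominated=True,
            study_label=arm.study_label,
        )
    return ICERResult(
        arm_id=arm.arm_id,
        point=point,
        lower=lower,
        upper=upper,
        cost_basis=cost_basis,
        scheme_kind=scheme_kind,
        effect=benefit,
        cost_per_child=cost,
        upper_unbounded=math.isinf(upper),
        dominated=False,
        study_label=arm.study_label,
    )


@dataclass(frozen=True)
class LeagueTable:
    """Arms ranked by ascending point ICER; dominated arms listed apart."""

    scheme_kind: SchemeKind
    cost_basis: CostBasis
    rows: tuple[ICERResult, ...]
    dominated: tuple[ICERResult, ...] = ()

    def to_frame(self):
        """Display-rounded table mirroring the published column order."""
        import pandas as pd

        records = []
        for r in self.rows:
            records.append(
                {
                    "rank": r.rank,
                    "arm_id": r.arm_id,
                    "study_label": r.study_label,
                    "effect": round_display(r.effect.point, 2),
                    "effect_lower": round_display(r.effect.lower, 2),
                    "effect_upper": round_display(r.effect.upper, 2),
                    "cost_per_child": round_display(r.cost_per_child),
                    "icer": round_display(r.point),
                    "icer_lower": round_display(r.lower),
                    "icer_upper": (
                        None if r.upper_unbounded else round_display(r.upper)
                    ),
                    "cost_basis": r.cost_basis.value,
                    "scheme": r.scheme_kind.value,
                    "dominated": r.dominated,
                }
            )
        for r in self.dominated:
            records.append(
                {
                    "rank": None,
                    "arm_id": r.arm_id,
                    "study_label": r.study_label,
                    "effect": round_display(r.effect.point, 2),
                    "effect_lower": round_display(r.effect.lower, 2),
                    "effect_upper": round_display(r.effect.upper, 2),
                    "cost_per_child": round_display(r.cost_per_child),
                    "icer": None,
                    "icer_lower": None,
                    "icer_upper": None,
                    "cost_basis": r.cost_basis.value,
                    "scheme": r.scheme_kind.value,
                    "dominated": True,
                }
            )
        return pd.DataFrame.from_records(records)


def rank_arms(results: Iterable[ICERResult]) -> LeagueTable:
    """Sort by ascending unrounded point ICER and assign ranks 1..n.

    Ties break by lower per-child cost, then lexicographic arm_id. All
    inputs must share one scheme kind and one cost basis. Dominated
    results are excluded from ranking and carried separately.
    """
    results = list(results)
    if results:
        schemes = {r.scheme_kind for r in results}
        bases = {r.cost_basis for r in results}
        if len(schemes) > 1 or len(bases) > 1:
            raise ValueError(
                f"mixed scheme/basis in ranking input: {sorted(s.value for s in schemes)} "
                f"/ {sorted(b.value for b in bases)}"
            )
        scheme_kind, cost_basis = results[0].scheme_kind, results[0].cost_basis
    else:
        scheme_kind, cost_basis = SchemeKind.AVERAGED, CostBasis.STANDARDIZED

    live = [r for r in results if not r.dominated]
    dominated = tuple(r for r in results if r.dominated)
    live.sort(key=lambda r: (r.point, r.cost_per_child, r.arm_id))
    ranked = tuple(replace(r, rank=i + 1) for i, r in enumerate(live))
    return LeagueTable(
        scheme_kind=scheme_kind,
        cost_basis=cost_basis,
        rows=ranked,
        dominated=dominated,
    )


@dataclass(frozen=True)
class MonteCarloInterval:
    """Percentile ICER interval from normal resampling of the effects.

    Extension beyond the published interval arithmetic: effects are assumed
    Normal(estimate, UR width / 3.92). Draws with non-positive aggregate
    benefit yield no ratio; their count is reported, never silently dropped.
    """

    lower: float
    upper: float
    n_samples: int
    n_nonpositive: int

    def __iter__(self):
        return iter((self.lower, self.upper))


def monte_carlo_interval(
    arm: InterventionArm,
    scheme_kind: Union[SchemeKind, str],
    cost_basis: Union[CostBasis, str],
    n_samples: int = 10_000,
    seed: Optional[int] = None,
) -> MonteCarloInterval:
    """Empirical 2.5th/97.5th percentile ICER interval under normal effects."""
    if seed is None:
        raise ValueError("a seed is required for reproducible Monte Carlo intervals")
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    scheme_kind = SchemeKind(scheme_kind)
    cost_basis = CostBasis(cost_basis)
    for eff in arm.effects:
        if eff.upper < eff.lower:
            raise ValueError(f"effect {eff.domain.label()!r} has upper < lower")

    scheme = make_scheme(scheme_kind, arm.effects)
    weights = np.array([scheme.weight_for(e.domain) for e in arm.effects])
    means = np.array([e.estimate for e in arm.effects])
    sds = np.array([(e.upper - e.lower) / 3.92 for e in arm.effects])
    cost = arm.cost.per_child(cost_basis)

    rng = np.random.default_rng(seed)
    draws = rng.normal(means, sds, size=(n_samples, len(arm.effects)))
    benefits = draws @ weights
    positive = benefits > 0
    n_nonpositive = int(n_samples - positive.sum())
    if positive.sum() == 0:
        raise DominatedError("no draw produced a positive aggregate benefit")
    ratios = cost / benefits[positive]
    lower, upper = np.percentile(ratios, [2.5, 97.5])
    return MonteCarloInterval(
        lower=float(lower),
        upper=float(upper),
        n_samples=n_samples,
        n_nonpositive=n_nonpositive,
    )
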
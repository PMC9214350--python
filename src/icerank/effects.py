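"""Aggregation of domain-specific effects into a single weighted benefit.

The benefit of an arm is the weighted sum of its reported standardized
effects, B = sum(w_d * Z_d). Two presets are provided: "averaged" weights
every reported effect 1/D (D = number reported for that arm) and "summed"
weights every effect 1. Uncertainty ranges propagate bound-wise: the lower
(upper) bound of the aggregate is the weighted sum of the lower (upper)
bounds. All arithmetic stays at full precision; rounding is a display
concern (see :mod:`icerank.cea`).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Union

from .core_model import (
    AggregateEffect,
    Domain,
    EffectEstimate,
    SchemeKind,
    WeightScheme,
)

__all__ = ["make_scheme", "custom_scheme", "aggregate"]


def make_scheme(
    kind: Union[SchemeKind, str], effects: Iterable[EffectEstimate]
) -> WeightScheme:
    """Build a preset weight scheme for an arm's reported effects."""
    kind = SchemeKind(kind)
    effects = list(effects)
    if not effects:
        raise ValueError("cannot build a weight scheme for an empty effect list")
    if kind is SchemeKind.AVERAGED:
        w = 1.0 / len(effects)
    elif kind is SchemeKind.SUMMED:
        w = 1.0
    else:
        raise ValueError("custom schemes require an explicit weight map; use custom_scheme()")
    return WeightScheme(kind=kind, weights={e.domain: w for e in effects})


def custom_scheme(weights: Mapping[Domain, float]) -> WeightScheme:
    """Explicit non-negative weight map (policymaker priorities)."""
    if not weights:
        raise ValueError("empty weight map")
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be >= 0")
    if all(w == 0 for w in weights.values()):
        raise ValueError("at least one weight must be > 0")
    return WeightScheme(kind=SchemeKind.CUSTOM, weights=dict(weights))


def aggregate(
    effects: Iterable[EffectEstimate], scheme: WeightScheme
) -> AggregateEffect:
    """Weighted benefit with bound-wise propagated uncertainty range.

    Every effect must have a weight in the scheme; weights must be
    non-negative with at least one positive.
    """
    effects = list(effects)
    if not effects:
        raise ValueError("no effects to aggregate")
    weights = [scheme.weight_for(e.domain) for e in effects]
    if any(w < 0 for w in weights):
        raise ValueError("weights must be >= 0")
    if all(w == 0 for w in weights):
        raise ValueError("all weights are zero")

    point = sum(w * e.estimate for w, e in zip(weights, effects))
    lower = sum(w * e.lower for w, e in zip(weights, effects))
    upper = sum(w * e.upper for w, e in zip(weights, effects))
    return AggregateEffect(point=point, lower=lower, upper=upper, scheme_kind=scheme.kind)
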
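"""Bundled study portfolio and synthetic portfolio generation.

The packaged fixture holds 16 intervention arms from 15 early-parenting /
psychosocial-stimulation studies, transcribed exactly as published
(effects, 95% URs, significance markers, local and LMIC-standardized
per-child costs); 12 arms are league-eligible. A checksum guards against
silent fixture edits.

:func:`generate_portfolio` draws structurally similar synthetic portfolios
(domain counts, normal effect estimates with symmetric 95% URs, positive
per-child costs) with analytically implied ICER ground truth attached, for
property tests that need known answers.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .core_model import (
    CostRecord,
    Domain,
    DomainName,
    EffectEstimate,
    InterventionArm,
    frame_to_portfolio,
)

__all__ = [
    "FixtureError",
    "load_paper_dataset",
    "load_expected_league",
    "n_studies",
    "SyntheticConfig",
    "SyntheticPortfolio",
    "generate_portfolio",
]

_PORTFOLIO_FILE = "study_portfolio.csv"
_EXPECTED_FILE = "league_expected.csv"

_PORTFOLIO_SHA256 = "4c49e53ac27e091dc9fa53b1848eea4fab4c7514a3c5785b55d18be72a1fbf92"
_EXPECTED_SHA256 = "1068f31f422cf2a81c9571ced3ed541da0e64d3dcf8357919a338b33ee0a867f"


class FixtureError(RuntimeError):
    """The packaged fixture does not match its recorded checksum."""


def _read_packaged(name: str, sha256: str) -> bytes:
    data = (resources.files("icerank") / "data" / name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != sha256:
        raise FixtureError(
            f"packaged fixture {name} is corrupted: sha256 {digest} != {sha256}"
        )
    return data


def load_paper_dataset() -> list[InterventionArm]:
    """All 16 bundled intervention arms, exactly as published."""
    import io

    data = _read_packaged(_PORTFOLIO_FILE, _PORTFOLIO_SHA256)
    frame = pd.read_csv(io.BytesIO(data), dtype={"subgroup": str}, keep_default_na=True)
    frame["subgroup"] = frame["subgroup"].fillna("")
    return frame_to_portfolio(frame)


def load_expected_league() -> pd.DataFrame:
    """Published league-table cells (display-rounded) for golden comparison."""
    import io

    data = _read_packaged(_EXPECTED_FILE, _EXPECTED_SHA256)
    return pd.read_csv(io.BytesIO(data))


def n_studies(arms: list[InterventionArm]) -> int:
    """Distinct source studies (multiple arms of one study share a citation)."""
    return len({arm.study_label.split(" (")[0] for arm in arms})


# ---------------------------------------------------------------------------
# Synthetic portfolios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticConfig:
    """Sampling parameters for synthetic portfolios.

    Effects: true d ~ Uniform(effect_mean_range), standard error
    se ~ Uniform(effect_se_range), UR = d +/- 1.96*se. Per-child costs are
    lognormal(cost_log_mean, cost_log_sd). A seed is mandatory.
    """

    n_arms: int
    seed: int
    domains_per_arm: tuple[int, int] = (1, 4)
    effect_mean_range: tuple[float, float] = (0.05, 1.2)
    effect_se_range: tuple[float, float] = (0.05, 0.3)
    cost_log_mean: float = 4.5
    cost_log_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.n_arms < 0:
            raise ValueError("n_arms must be >= 0")
        if self.seed is None:
            raise ValueError("seed is required")
        lo, hi = self.domains_per_arm
        if not (1 <= lo <= hi):
            raise ValueError("domains_per_arm must be a non-empty range of counts >= 1")
        for name in ("effect_mean_range", "effect_se_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty")


@dataclass(frozen=True)
class SyntheticPortfolio:
    """Generated arms plus analytically implied ICERs per arm.

    ``ground_truth[arm_id][scheme]`` holds the ICER computed by direct
    arithmetic from the sampled values (cost / mean(d) and cost / sum(d)),
    independent of the evaluation pipeline.
    """

    arms: list[InterventionArm]
    ground_truth: dict[str, dict[str, float]]


def generate_portfolio(config: SyntheticConfig) -> SyntheticPortfolio:
    """Draw a reproducible synthetic portfolio with known ICERs."""
    rng = np.random.default_rng(config.seed)
    domain_pool = list(DomainName)
    arms: list[InterventionArm] = []
    truth: dict[str, dict[str, float]] = {}

    for i in range(config.n_arms):
        lo, hi = config.domains_per_arm
        n_domains = int(rng.integers(lo, hi + 1))
        names = rng.choice(len(domain_pool), size=n_domains, replace=False)
        effects = []
        ds = []
        for j in sorted(names):
            d = float(rng.uniform(*config.effect_mean_range))
            se = float(rng.uniform(*config.effect_se_range))
            effects.append(
                EffectEstimate(
                    domain=Domain(domain_pool[j]),
                    estimate=d,
                    lower=d - 1.96 * se,
                    upper=d + 1.96 * se,
                    significant=d - 1.96 * se > 0,
                )
            )
            ds.append(d)
        cost = float(rng.lognormal(config.cost_log_mean, config.cost_log_sd))
        arm_id = f"synthetic_{i:04d}"
        arms.append(
            InterventionArm(
                arm_id=arm_id,
                study_label=f"Synthetic study {i}",
                country="Synthetica",
                study_year=2010,
                cost=CostRecord(
                    per_child_local=cost,
                    per_child_standardized=cost,
                    country="Synthetica",
                    cost_year=2010,
                ),
                effects=tuple(effects),
                league_eligible=True,
            )
        )
        total = sum(ds)
        truth[arm_id] = {
            "averaged": cost / (total / len(ds)),
            "summed": cost / total,
        }
    return SyntheticPortfolio(arms=arms, ground_truth=truth)
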
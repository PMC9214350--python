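"""Cell-level comparison of computed league tables against published values.

Evaluates the bundled portfolio under both weight schemes and both cost
bases, display-rounds every cell, and diffs it against the packaged
expected table: 48 point ICERs, 96 UR bounds, 48 ranks, plus the effect
cells. Used by the ``reproduce-paper`` command and the regression tests.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cea import evaluate_arm, rank_arms, round_display
from .core_model import CostBasis, InterventionArm, SchemeKind
from .datasets import load_expected_league, load_paper_dataset

__all__ = ["CellDiff", "GoldenReport", "compare_league"]


@dataclass(frozen=True)
class CellDiff:
    scheme: str
    basis: str
    arm_id: str
    cell: str
    expected: float
    computed: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.scheme}/{self.basis} {self.arm_id} {self.cell}: "
            f"expected {self.expected}, computed {self.computed}"
        )


@dataclass(frozen=True)
class GoldenReport:
    n_icers: int
    n_icers_matched: int
    n_bounds: int
    n_bounds_matched: int
    n_ranks: int
    n_ranks_matched: int
    n_effect_cells: int
    n_effect_cells_matched: int
    diffs: tuple[CellDiff, ...]

    @property
    def ok(self) -> bool:
        return not self.diffs

    def summary(self) -> str:
        return (
            f"{self.n_icers_matched}/{self.n_icers} ICERs, "
            f"{self.n_bounds_matched}/{self.n_bounds} bounds, "
            f"{self.n_ranks_matched}/{self.n_ranks} ranks, "
            f"{self.n_effect_cells_matched}/{self.n_effect_cells} effect cells matched"
        )


def compare_league(
    arms: list[InterventionArm] | None = None,
    schemes: tuple[SchemeKind, ...] = (SchemeKind.AVERAGED, SchemeKind.SUMMED),
    bases: tuple[CostBasis, ...] = (CostBasis.STANDARDIZED, CostBasis.LOCAL),
) -> GoldenReport:
    """Diff computed display-rounded league tables against published cells."""
    if arms is None:
        arms = load_paper_dataset()
    expected = load_expected_league()
    eligible = [a for a in arms if a.league_eligible]

    diffs: list[CellDiff] = []
    counts = {k: [0, 0] for k in ("icer", "bound", "rank", "effect")}

    def check(kind: str, scheme: str, basis: str, arm_id: str, cell: str, exp, got):
        counts[kind][0] += 1
        if got == exp:
            counts[kind][1] += 1
        else:
            diffs.append(CellDiff(scheme, basis, arm_id, cell, exp, got))

    for scheme in schemes:
        exp_block = expected[expected["scheme"] == scheme.value].set_index("arm_id")
        for basis in bases:
            prefix = "std" if basis is CostBasis.STANDARDIZED else "local"
            results = [evaluate_arm(a, scheme, basis) for a in eligible]
            table = rank_arms(results)
            for row in table.rows:
                exp_row = exp_block.loc[row.arm_id]
                sc, bs = scheme.value, basis.value
                check("icer", sc, bs, row.arm_id, "icer",
                      int(exp_row[f"{prefix}_icer"]), round_display(row.point))
                check("bound", sc, bs, row.arm_id, "icer_lower",
                      int(exp_row[f"{prefix}_icer_lower"]), round_display(row.lower))
                check("bound", sc, bs, row.arm_id, "icer_upper",
                      int(exp_row[f"{prefix}_icer_upper"]), round_display(row.upper))
                check("rank", sc, bs, row.arm_id, "rank",
                      int(exp_row[f"{prefix}_rank"]), row.rank)
                if basis is bases[0]:  # effect cells are basis-independent
                    check("effect", sc, bs, row.arm_id, "effect",
                          float(exp_row["effect"]), round_display(row.effect.point, 2))
                    check("effect", sc, bs, row.arm_id, "effect_lower",
                          float(exp_row["effect_lower"]), round_display(row.effect.lower, 2))
                    check("effect", sc, bs, row.arm_id, "effect_upper",
                          float(exp_row["effect_upper"]), round_display(row.effect.upper, 2))

    return GoldenReport(
        n_icers=counts["icer"][0],
        n_icers_matched=counts["icer"][1],
        n_bounds=counts["bound"][0],
        n_bounds_matched=counts["bound"][1],
        n_ranks=counts["rank"][0],
        n_ranks_matched=counts["rank"][1],
        n_effect_cells=counts["effect"][0],
        n_effect_cells_matched=counts["effect"][1],
        diffs=tuple(diffs),
    )
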
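"""Item-screening cascade and short-form selection.

Screening runs in two stages on an initial 3PL fit:

1. Remove local-dependence violators (marginal-residual diagnostics) and
   items with a negative estimated slope; fix guessing parameters that are
   not significantly different from zero at zero.
2. Refit the surviving items under those constraints, then remove items
   whose slope is not significantly greater than zero or falls below the
   slope floor (default 0.71, the slope whose factor-analytic communality
   is 0.15).

The short form takes the ``k`` retained items with the highest average
information over a reference ability range, ties broken by larger slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import diagnostics
from .estimation import FitConfig, FitResult, ResponseMatrix, fit_3pl, refit_with_constraints, wald_tests
from .information import average_information
from .irt_core import ItemBank

__all__ = ["ScreeningConfig", "ItemVerdict", "SelectionReport", "screen_items", "select_short_form"]

RULES = ("LD", "negative_slope", "slope_not_significant", "slope_below_threshold")


@dataclass(frozen=True)
class ScreeningConfig:
    """Thresholds of the screening cascade."""

    z_threshold: float = 3.0
    slope_threshold: float = 0.71
    alpha: float = 0.05
    min_joint_n: int = diagnostics.DEFAULT_MIN_JOINT_N
    check_triplets: bool = True

    def __post_init__(self) -> None:
        if self.z_threshold <= 0 or self.slope_threshold <= 0 or not 0 < self.alpha < 1:
            raise ValueError("screening thresholds must be positive (alpha in (0,1))")


@dataclass(frozen=True)
class ItemVerdict:
    item_id: str
    verdict: str  # "retained" | "removed"
    rule: str | None  # one of RULES when removed
    stage: int | None  # 1 or 2 when removed


@dataclass
class SelectionReport:
    """Per-item screening verdicts plus the retained and short-form sets."""

    per_item: list[ItemVerdict]
    retained: list[str]
    short_form: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [v.item_id for v in self.per_item]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate verdicts")
        for v in self.per_item:
            if v.verdict == "removed" and v.rule not in RULES:
                raise ValueError(f"unknown removal rule {v.rule!r}")
        if not set(self.short_form) <= set(self.retained):
            raise ValueError("short form must be a subset of the retained items")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"item_id": v.item_id, "verdict": v.verdict, "rule": v.rule, "stage": v.stage}
                for v in self.per_item
            ]
        )

    def removal_counts(self) -> pd.DataFrame:
        """Accounting table: removals per rule (retained last)."""
        df = self.to_frame()
        counts = df[df.verdict == "removed"].groupby("rule").size()
        rows = [{"rule": r, "n_removed": int(counts.get(r, 0))} for r in RULES]
        rows.append({"rule": "retained", "n_removed": int((df.verdict == "retained").sum())})
        return pd.DataFrame(rows)


def screen_items(
    responses: ResponseMatrix,
    fit_config: FitConfig | None = None,
    screening: ScreeningConfig | None = None,
    topics: dict[str, str] | None = None,
) -> tuple[SelectionReport, FitResult]:
    """Run the full screening cascade; returns the report and the final fit.

    Raises ``ValueError("bank exhausted")`` if fewer than two items survive.
    """
    fit_config = fit_config or FitConfig()
    cfg = screening or ScreeningConfig()
    removed: dict[str, tuple[str, int]] = {}

    fit1 = fit_3pl(responses, fit_config, topics=topics)

    # Stage 1a: local dependence.
    residuals = diagnostics.pair_residuals(fit1, responses, cfg.min_joint_n)
    if cfg.check_triplets:
        residuals = residuals + diagnostics.triplet_residuals(
            fit1, responses, cfg.min_joint_n
        )
    slopes = {it.item_id: it.a for it in fit1.bank}
    for item in diagnostics.flag_local_dependence(residuals, cfg.z_threshold, slopes):
        removed[item] = ("LD", 1)

    # Stage 1b: negative estimated slope.
    for it in fit1.bank:
        if it.item_id not in removed and it.a < 0:
            removed[it.item_id] = ("negative_slope", 1)

    survivors = [i for i in responses.item_ids if i not in removed]
    if len(survivors) < 2:
        raise ValueError("bank exhausted: fewer than 2 items survive stage 1")

    # Stage 1c: guessing parameters not significantly different from 0 -> fix at 0.
    wald1 = wald_tests(fit1, cfg.alpha)
    fix_c = [
        i for i in survivors if wald1.loc[i, "c_verdict"] in ("not_significant", "fixed")
    ]

    fit2 = refit_with_constraints(
        responses, fit1, fix_c_items=fix_c,
        remove_items=[i for i in responses.item_ids if i in removed],
        config=fit_config,
    )

    # Stage 2: slope screening on the refit.
    wald2 = wald_tests(fit2, cfg.alpha)
    for it in fit2.bank:
        if it.a < 0:
            removed[it.item_id] = ("negative_slope", 2)
        elif it.a < cfg.slope_threshold:
            removed[it.item_id] = ("slope_below_threshold", 2)
        elif not wald2.loc[it.item_id, "a_significantly_positive"]:
            removed[it.item_id] = ("slope_not_significant", 2)

    retained = [i for i in responses.item_ids if i not in removed]
    if len(retained) < 2:
        raise ValueError("bank exhausted: fewer than 2 items survive stage 2")

    if len(retained) < fit2.n_items:
        final_fit = refit_with_constraints(
            responses, fit2,
            remove_items=[i for i in responses.item_ids if i in removed],
            config=fit2.config,
        )
    else:
        final_fit = fit2

    per_item = [
        ItemVerdict(i, "removed", *removed[i]) if i in removed
        else ItemVerdict(i, "retained", None, None)
        for i in responses.item_ids
    ]
    return SelectionReport(per_item=per_item, retained=retained), final_fit


def select_short_form(
    fit_or_bank: FitResult | ItemBank,
    k: int,
    avg_range: tuple[float, float] = (-4.0, 4.0),
) -> list[str]:
    """Pick the ``k`` items with the highest average information.

    Ranking key: average information over ``avg_range`` (descending), then
    larger slope, then item id.  Returned in the bank's item order.
    """
    bank = fit_or_bank.bank if isinstance(fit_or_bank, FitResult) else fit_or_bank
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(bank):
        raise ValueError(f"k={k} exceeds the {len(bank)} available items")
    ranked = sorted(
        bank,
        key=lambda it: (-average_information(it, avg_range), -it.a, it.item_id),
    )
    chosen = {it.item_id for it in ranked[:k]}
    return [i for i in bank.item_ids if i in chosen]
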
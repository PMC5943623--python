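"""Synthetic crowdsourced response data with the structure the model assumes.

The generator stands in for undeposited crowdsourcing data and emulates
its documented statistical structure: a mostly-easy, discriminating item
bank (difficulties centred below zero), respondent abilities drawn from
normal populations (optionally mean-shifted by demographic stratum), a
balanced-incomplete-block administration (items split into groups, each
respondent answering a fixed number of groups), responses drawn from 3PL
item characteristic curves, and quality-control side-channels (a repeated
question and two catch questions) with injectable failure rates.

Default rates: 5% inconsistent repeat answers and 3% per-catch failures,
giving an expected exclusion fraction of about 10.6%, in line with the
reported worst-case exclusion of 10.8% in comparable crowdsourced tasks.
Everything is deterministic under the design seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .estimation import ResponseMatrix
from .irt_core import ItemBank, ItemParameters, icc_3pl_matrix
from .response_qc import QCRecord

__all__ = [
    "StratumSpec",
    "BlockDesignSpec",
    "QCSpec",
    "SimulationDesign",
    "BlockAssignment",
    "generate_item_bank",
    "simulate_abilities",
    "assign_blocks",
    "simulate_responses",
    "inject_qc_failures",
    "simulate_study",
]

_TOPICS = ("heart_failure", "diabetes", "cancer", "hypertension", "copd", "liver_failure")


@dataclass(frozen=True)
class StratumSpec:
    """A demographic stratum modeled as an ability mean-shift."""

    label: str
    mean_shift: float = 0.0
    proportion: float = 1.0


@dataclass(frozen=True)
class BlockDesignSpec:
    """Block administration: items split into groups, persons get a subset."""

    n_groups: int = 3
    items_per_group: int = 6
    groups_per_person: int = 2


@dataclass(frozen=True)
class QCSpec:
    """Failure rates of the quality-control side-channels."""

    p_inconsistent_repeat: float = 0.05
    p_fail_catch: float = 0.03


@dataclass(frozen=True)
class SimulationDesign:
    """Full specification of one synthetic study.

    Defaults mirror a per-topic crowdsourced task: 18 mostly-easy items in
    3 groups of 6, 400 respondents each administered 2 of the 3 groups,
    slopes ~ LogNormal(log 1.2, 0.4), difficulties ~ N(-1, 1), guessing ~
    U(0, 0.25), a single unshifted stratum, and the default QC failure
    rates.
    """

    n_items: int = 18
    n_persons: int = 400
    slope_meanlog: float = math.log(1.2)
    slope_sdlog: float = 0.4
    difficulty_mean: float = -1.0
    difficulty_sd: float = 1.0
    guessing_low: float = 0.0
    guessing_high: float = 0.25
    guessing_fixed_zero: bool = False
    strata: tuple[StratumSpec, ...] = (StratumSpec("all"),)
    block_design: BlockDesignSpec | None = BlockDesignSpec()
    qc: QCSpec = QCSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(s.proportion for s in self.strata) - 1.0) > 1e-9:
            raise ValueError("stratum proportions must sum to 1")
        if self.block_design is not None:
            bd = self.block_design
            if bd.n_groups * bd.items_per_group != self.n_items:
                raise ValueError(
                    "block design inconsistent: n_groups * items_per_group != n_items"
                )
            if not 1 <= bd.groups_per_person <= bd.n_groups:
                raise ValueError("groups_per_person outside [1, n_groups]")
        for p in (self.qc.p_inconsistent_repeat, self.qc.p_fail_catch):
            if not 0.0 <= p <= 1.0:
                raise ValueError("QC probabilities must lie in [0, 1]")
        if not (self.slope_sdlog >= 0 and self.difficulty_sd >= 0):
            raise ValueError("distribution scales must be nonnegative")
        if not 0 <= self.guessing_low <= self.guessing_high < 1:
            raise ValueError("guessing range must satisfy 0 <= lo <= hi < 1")


@dataclass(frozen=True)
class BlockAssignment:
    """Which items each person is administered."""

    mask: np.ndarray  # (persons, items) bool
    item_groups: np.ndarray  # group index per item
    person_groups: np.ndarray  # (persons, groups_per_person) group indices


def _rng(design: SimulationDesign, seed: int | None, stream: int) -> np.random.Generator:
    base = design.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence([int(base), stream]))


def generate_item_bank(design: SimulationDesign, seed: int | None = None) -> ItemBank:
    """Draw an item bank from the design's generating distributions."""
    rng = _rng(design, seed, 1)
    a = rng.lognormal(design.slope_meanlog, design.slope_sdlog, design.n_items)
    b = rng.normal(design.difficulty_mean, design.difficulty_sd, design.n_items)
    if design.guessing_fixed_zero:
        c = np.zeros(design.n_items)
    else:
        c = rng.uniform(design.guessing_low, design.guessing_high, design.n_items)
    width = max(2, len(str(design.n_items)))
    items = [
        ItemParameters(
            item_id=f"item{j + 1:0{width}d}",
            a=float(a[j]),
            b=float(b[j]),
            c=float(c[j]),
            topic=_TOPICS[j % len(_TOPICS)],
        )
        for j in range(design.n_items)
    ]
    return ItemBank(items, {"source": "synthetic", "seed": int(seed if seed is not None else design.seed)})


def simulate_abilities(
    design: SimulationDesign, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw person abilities theta ~ N(stratum shift, 1) with stratum labels.

    Stratum sizes follow the design proportions by largest-remainder
    rounding; persons are then shuffled so strata interleave.
    """
    rng = _rng(design, seed, 2)
    n = design.n_persons
    if n == 0:
        return np.empty(0), np.empty(0, dtype=object)
    exact = np.array([s.proportion * n for s in design.strata])
    counts = np.floor(exact).astype(int)
    for k in np.argsort(-(exact - counts))[: n - counts.sum()]:
        counts[k] += 1
    labels = np.repeat([s.label for s in design.strata], counts)
    shifts = np.repeat([s.mean_shift for s in design.strata], counts)
    perm = rng.permutation(n)
    labels, shifts = labels[perm], shifts[perm]
    theta = shifts + rng.standard_normal(n)
    return theta, labels


def assign_blocks(
    design: SimulationDesign, n_persons: int | None = None, seed: int | None = None
) -> BlockAssignment:
    """Assign each person a uniform random subset of item groups.

    Items are partitioned into contiguous groups in bank order; each person
    receives the union of ``groups_per_person`` distinct groups.  Without a
    block design, administration is complete.
    """
    n_persons = design.n_persons if n_persons is None else n_persons
    if design.block_design is None:
        return BlockAssignment(
            mask=np.ones((n_persons, design.n_items), dtype=bool),
            item_groups=np.zeros(design.n_items, dtype=int),
            person_groups=np.zeros((n_persons, 1), dtype=int),
        )
    bd = design.block_design
    rng = _rng(design, seed, 3)
    item_groups = np.repeat(np.arange(bd.n_groups), bd.items_per_group)
    person_groups = np.empty((n_persons, bd.groups_per_person), dtype=int)
    mask = np.zeros((n_persons, design.n_items), dtype=bool)
    for p in range(n_persons):
        chosen = np.sort(rng.choice(bd.n_groups, size=bd.groups_per_person, replace=False))
        person_groups[p] = chosen
        mask[p] = np.isin(item_groups, chosen)
    return BlockAssignment(mask=mask, item_groups=item_groups, person_groups=person_groups)


def simulate_responses(
    bank: ItemBank,
    abilities: Sequence[float],
    block_assignment: BlockAssignment | None = None,
    seed: int | None = None,
    person_ids: Sequence[str] | None = None,
) -> ResponseMatrix:
    """Draw dichotomous responses from the 3PL curves.

    Each administered (person, item) cell is an independent Bernoulli draw
    with probability given by the item characteristic curve at the person's
    ability; unadministered cells are NaN.
    """
    theta = np.asarray(abilities, dtype=float)
    n_persons = theta.size
    rng = np.random.default_rng(np.random.SeedSequence([int(seed or 0), 4]))
    P = icc_3pl_matrix(bank.a, bank.b, bank.c, theta).T  # (persons, items)
    mask = (
        block_assignment.mask
        if block_assignment is not None
        else np.ones((n_persons, len(bank)), dtype=bool)
    )
    draws = rng.random((n_persons, len(bank)))
    data = np.where(mask, (draws < P).astype(float), np.nan)
    if person_ids is None:
        width = max(4, len(str(n_persons)))
        person_ids = [f"p{j + 1:0{width}d}" for j in range(n_persons)]
    return ResponseMatrix(list(person_ids), bank.item_ids, data)


def inject_qc_failures(
    matrix: ResponseMatrix, design: SimulationDesign, seed: int | None = None
) -> tuple[ResponseMatrix, list[QCRecord]]:
    """Attach quality-control side-records to a response matrix.

    For each person, one administered item is re-presented: the second
    answer disagrees with the first with probability
    ``p_inconsistent_repeat``.  Two catch questions are answered, each
    incorrectly with probability ``p_fail_catch``.  Failures are drawn
    independently of ability.  The response matrix itself is unchanged.
    """
    rng = _rng(design, seed, 5)
    records = []
    adm = matrix.administered
    for row, person in enumerate(matrix.person_ids):
        candidates = np.flatnonzero(adm[row])
        j = int(rng.choice(candidates))
        first = int(matrix.data[row, j])
        inconsistent = rng.random() < design.qc.p_inconsistent_repeat
        second = 1 - first if inconsistent else first
        catches = tuple(bool(rng.random() >= design.qc.p_fail_catch) for _ in range(2))
        records.append(
            QCRecord(
                person_id=person,
                repeat_item=matrix.item_ids[j],
                repeat_pair=(first, second),
                catch_answers=catches,
            )
        )
    return matrix, records


def simulate_study(design: SimulationDesign, seed: int | None = None):
    """Generate a full synthetic study: bank, abilities, blocks, responses, QC.

    Returns a dict with keys ``bank``, ``theta``, ``labels``, ``blocks``,
    ``responses`` and ``qc_records``; all randomness derives from the single
    seed.
    """
    base = design.seed if seed is None else seed
    bank = generate_item_bank(design, base)
    theta, labels = simulate_abilities(design, base)
    blocks = assign_blocks(design, design.n_persons, base)
    responses = simulate_responses(bank, theta, blocks, seed=base)
    responses, qc_records = inject_qc_failures(responses, design, base)
    return {
        "bank": bank,
        "theta": theta,
        "labels": labels,
        "blocks": blocks,
        "responses": responses,
        "qc_records": qc_records,
    }
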
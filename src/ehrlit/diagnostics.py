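"""Local-independence diagnostics via marginal residuals.

The 3PL model assumes responses to different items are conditionally
independent given ability.  Violations are detected by comparing, for each
pair (and triplet) of items, the observed proportion of respondents
answering all of them correctly with the model-implied proportion

    E[all correct] = sum_k w(theta_k) * prod_i p_i(theta_k)

marginalized over the ability prior.  The standardized residual

    z = (observed - expected) * sqrt(n) / sqrt(expected * (1 - expected))

is approximately standard normal when the model holds; item sets with
|z| above a threshold (default 3) flag a local-dependence violation, and a
minimal covering set of items is nominated for removal.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .estimation import FitResult, ResponseMatrix, _PCLIP
from .irt_core import icc_3pl_matrix

__all__ = [
    "MarginalResidual",
    "pair_residuals",
    "triplet_residuals",
    "flag_local_dependence",
    "residuals_to_frame",
]

DEFAULT_MIN_JOINT_N = 30


@dataclass(frozen=True)
class MarginalResidual:
    """Observed vs model-implied all-correct proportion for an item set."""

    item_set: tuple[str, ...]
    observed: float
    expected: float
    n: int
    z: float  # NaN when n < the joint-sample floor ("insufficient")

    @property
    def insufficient(self) -> bool:
        return np.isnan(self.z)


def _model_pieces(fit: FitResult, responses: ResponseMatrix):
    common = [i for i in responses.item_ids if i in set(fit.item_ids)]
    if not common:
        raise ValueError("fit and responses share no items")
    sub = responses.subset_items(common)
    bank = fit.bank.subset(common)
    # align bank to the response-matrix item order
    order = {i: k for k, i in enumerate(bank.item_ids)}
    grid = fit.config.grid()
    P = np.clip(
        icc_3pl_matrix(bank.a, bank.b, bank.c, grid.nodes), _PCLIP, 1 - _PCLIP
    )
    P = P[[order[i] for i in sub.item_ids]]
    X1 = np.where(sub.administered & (sub.data == 1), 1.0, 0.0)
    M = sub.administered.astype(float)
    return sub.item_ids, P, grid.weights, X1, M


def _residual(obs, exp, n):
    if 0.0 < exp < 1.0:
        return (obs - exp) * np.sqrt(n) / np.sqrt(exp * (1.0 - exp))
    return np.nan


def pair_residuals(
    fit: FitResult, responses: ResponseMatrix, min_joint_n: int = DEFAULT_MIN_JOINT_N
) -> list[MarginalResidual]:
    """Marginal residuals of every item pair (all-correct margin).

    Pairs administered jointly to fewer than ``min_joint_n`` persons are
    returned with ``z = NaN`` (insufficient sample for the normal
    approximation).
    """
    item_ids, P, w, X1, M = _model_pieces(fit, responses)
    E = (P * w[None, :]) @ P.T  # pairwise expected all-correct
    C = X1.T @ X1
    N = M.T @ M
    out = []
    for i, k in combinations(range(len(item_ids)), 2):
        n = int(N[i, k])
        obs = C[i, k] / n if n else np.nan
        exp = float(E[i, k])
        z = _residual(obs, exp, n) if n >= min_joint_n else np.nan
        out.append(MarginalResidual((item_ids[i], item_ids[k]), obs, exp, n, z))
    return out


def triplet_residuals(
    fit: FitResult, responses: ResponseMatrix, min_joint_n: int = DEFAULT_MIN_JOINT_N
) -> list[MarginalResidual]:
    """Marginal residuals of every item triplet (all-correct margin)."""
    item_ids, P, w, X1, M = _model_pieces(fit, responses)
    n_items = len(item_ids)
    out = []
    for i, k in combinations(range(n_items), 2):
        if k + 1 >= n_items:
            continue
        idx = np.arange(k + 1, n_items)
        E = ((P[i] * P[k] * w)[None, :] @ P[idx].T).ravel()
        cnt = (X1[:, i] * X1[:, k]) @ X1[:, idx]
        nadm = (M[:, i] * M[:, k]) @ M[:, idx]
        for pos, l in enumerate(idx):
            n = int(nadm[pos])
            obs = cnt[pos] / n if n else np.nan
            exp = float(E[pos])
            z = _residual(obs, exp, n) if n >= min_joint_n else np.nan
            out.append(
                MarginalResidual((item_ids[i], item_ids[k], item_ids[l]), obs, exp, n, z)
            )
    return out


def flag_local_dependence(
    residuals: Iterable[MarginalResidual],
    z_threshold: float = 3.0,
    slopes: Mapping[str, float] | None = None,
) -> list[str]:
    """Nominate a minimal item-removal set covering all flagged item sets.

    Greedy cover: repeatedly remove the item appearing in the most flagged
    sets, breaking ties by lower slope (when ``slopes`` is given) and then
    by item id, until no flagged set survives intact.
    """
    flagged = [
        set(r.item_set)
        for r in residuals
        if not np.isnan(r.z) and abs(r.z) > z_threshold
    ]
    removed: list[str] = []
    while flagged:
        counts: dict[str, int] = {}
        for s in flagged:
            for item in s:
                counts[item] = counts.get(item, 0) + 1
        best = min(
            counts,
            key=lambda i: (
                -counts[i],
                slopes.get(i, np.inf) if slopes else np.inf,
                i,
            ),
        )
        removed.append(best)
        flagged = [s for s in flagged if best not in s]
    return sorted(removed)


def residuals_to_frame(residuals: Sequence[MarginalResidual],
                       z_threshold: float = 3.0) -> pd.DataFrame:
    """Tabular residual report (the CSV export schema)."""
    return pd.DataFrame(
        {
            "item_set": ["|".join(r.item_set) for r in residuals],
            "observed": [r.observed for r in residuals],
            "expected": [r.expected for r in residuals],
            "n": [r.n for r in residuals],
            "z": [r.z for r in residuals],
            "flagged": [
                (not np.isnan(r.z)) and abs(r.z) > z_threshold for r in residuals
            ],
        }
    )
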
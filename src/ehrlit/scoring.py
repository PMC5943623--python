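"""Respondent scoring: EAP ability estimates and stratum summaries.

Given a calibrated item bank, a respondent's ability is scored by the
posterior mean (expected a posteriori, EAP) of ``theta`` under the
standard normal population prior:

    EAP = sum_k w_k L(theta_k) theta_k / sum_k w_k L(theta_k)

with the posterior SD as its uncertainty.  EAP remains finite for
all-correct and all-incorrect patterns, where maximum-likelihood scoring
diverges, and is interpreted relative to the calibration population: a
score of 0 is the average respondent of the population the bank was
calibrated on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimation import ResponseMatrix, _PCLIP
from .irt_core import AbilityGrid, ItemBank, icc_3pl_matrix

__all__ = ["PersonScore", "eap_ability", "score_table"]


@dataclass(frozen=True)
class PersonScore:
    """Raw and model-based scores for one respondent."""

    person_id: str
    raw_correct: int
    administered: int
    percent: float  # unrounded; display-rounding is left to the writers
    eap_ability: float
    eap_se: float
    strata: dict | None = None


def _posterior_moments(L: np.ndarray, grid: AbilityGrid) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and SD per row of a (persons, nodes) likelihood matrix."""
    post = L * grid.weights[None, :]
    post /= post.sum(axis=1, keepdims=True)
    mean = post @ grid.nodes
    var = post @ grid.nodes**2 - mean**2
    return mean, np.sqrt(np.maximum(var, 0.0))


def _likelihood_matrix(bank: ItemBank, data: np.ndarray, grid: AbilityGrid) -> np.ndarray:
    P = np.clip(icc_3pl_matrix(bank.a, bank.b, bank.c, grid.nodes), _PCLIP, 1 - _PCLIP)
    adm = ~np.isnan(data)
    X1 = np.where(adm & (data == 1), 1.0, 0.0)
    X0 = np.where(adm & (data == 0), 1.0, 0.0)
    LL = X1 @ np.log(P) + X0 @ np.log1p(-P)
    LL -= LL.max(axis=1, keepdims=True)
    return np.exp(LL)


def eap_ability(
    bank: ItemBank, responses: Sequence[float], grid: AbilityGrid | None = None
) -> tuple[float, float]:
    """EAP ability estimate and posterior SD for one response vector.

    ``responses`` aligns with the bank (1/0/NaN).  With no administered
    items the posterior equals the prior, so the prior moments (approximately
    0 and 1 on the default grid) are returned.
    """
    grid = grid or AbilityGrid.normal()
    x = np.asarray(responses, dtype=float).reshape(1, -1)
    if x.shape[1] != len(bank):
        raise ValueError("response vector does not align with the bank")
    mean, sd = _posterior_moments(_likelihood_matrix(bank, x, grid), grid)
    return float(mean[0]), float(sd[0])


def score_table(
    bank: ItemBank,
    responses: ResponseMatrix,
    strata: pd.DataFrame | Mapping[str, Mapping[str, str]] | None = None,
    grid: AbilityGrid | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Score every respondent and summarize by demographic stratum.

    Parameters
    ----------
    bank
        Calibrated item bank (parameters fixed).
    responses
        Response matrix; items must be a subset of the bank.
    strata
        Optional per-person labels: a DataFrame indexed by person_id with one
        column per stratifying variable (education, age band, gender, ...).

    Returns
    -------
    scores
        Per-person frame: raw_correct, administered, percent, eap_ability,
        eap_se, plus any strata columns.
    stratum_means
        Per-(variable, level) mean percent-correct and mean EAP ability with
        group sizes, or ``None`` when no strata were given.
    """
    lut = {it.item_id: it for it in bank.subset(responses.item_ids)}
    aligned = ItemBank([lut[i] for i in responses.item_ids])

    grid = grid or AbilityGrid.normal()
    adm = responses.administered
    raw = np.nansum(np.where(adm, responses.data, 0.0), axis=1).astype(int)
    n_adm = adm.sum(axis=1)
    mean, sd = _posterior_moments(
        _likelihood_matrix(aligned, responses.data, grid), grid
    )
    scores = pd.DataFrame(
        {
            "person_id": responses.person_ids,
            "raw_correct": raw,
            "administered": n_adm,
            "percent": np.where(n_adm > 0, raw / np.maximum(n_adm, 1) * 100.0, np.nan),
            "eap_ability": mean,
            "eap_se": sd,
        }
    ).set_index("person_id")

    if strata is None:
        return scores, None
    strata_df = (
        strata if isinstance(strata, pd.DataFrame) else pd.DataFrame.from_dict(strata, orient="index")
    )
    strata_df = strata_df.reindex(scores.index)
    scores = scores.join(strata_df)
    summaries = []
    for var in strata_df.columns:
        grp = scores.dropna(subset=[var]).groupby(var, observed=True)
        agg = grp.agg(
            n=("percent", "size"),
            mean_percent=("percent", "mean"),
            mean_eap=("eap_ability", "mean"),
        )
        agg.insert(0, "variable", var)
        agg.index.name = "level"
        summaries.append(agg.reset_index())
    stratum_means = pd.concat(summaries, ignore_index=True)[
        ["variable", "level", "n", "mean_percent", "mean_eap"]
    ]
    return scores, stratum_means
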
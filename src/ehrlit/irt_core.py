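"""Core three-parameter-logistic (3PL) item response model.

The 3PL model describes the probability that a respondent with latent
ability ``theta`` answers a dichotomous item correctly:

    p(theta) = c + (1 - c) / (1 + exp(-a * (theta - b)))

where ``a`` is the discrimination (slope), ``b`` the difficulty (the
ability at which the probability is halfway between the lower asymptote
and 1), and ``c`` the guessing parameter (lower asymptote).  The slope is
in the logistic metric: no scaling constant appears inside the item
characteristic curve.  The classical logistic-to-normal-ogive constant
D = 1.7 is used only when converting a slope to a factor-analytic
communality (:func:`slope_to_communality`), which is the convention under
which a slope of 0.71 corresponds to a communality of 0.15.

Abilities are identified by anchoring the population to a standard normal
distribution; :class:`AbilityGrid` carries the quadrature representation
of that prior used throughout the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "SCALING_D",
    "ItemParameters",
    "ItemBank",
    "AbilityGrid",
    "icc_3pl",
    "icc_3pl_matrix",
    "pattern_loglik",
    "slope_to_communality",
    "communality_to_slope",
]

#: Logistic-to-normal-ogive scaling constant.
SCALING_D = 1.7

_BANK_COLUMNS = ["item_id", "topic", "a", "b", "c"]


@dataclass(frozen=True)
class ItemParameters:
    """Parameters of a single 3PL item.

    Parameters
    ----------
    item_id
        Unique identifier of the item.
    a
        Discrimination slope (logistic metric, unitless).
    b
        Difficulty, in units of the population ability SD.
    c
        Guessing probability (lower asymptote), in ``[0, 1)``.
    topic
        Optional disease-category label.
    """

    item_id: str
    a: float
    b: float
    c: float = 0.0
    topic: str | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError(f"item {self.item_id!r}: a and b must be finite")
        if not 0.0 <= self.c < 1.0:
            raise ValueError(
                f"item {self.item_id!r}: guessing parameter c={self.c} outside [0, 1)"
            )


@dataclass
class ItemBank:
    """Ordered collection of :class:`ItemParameters` with provenance metadata."""

    items: list[ItemParameters]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item_ids in bank: {dup}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[ItemParameters]:
        return iter(self.items)

    def __getitem__(self, item_id: str) -> ItemParameters:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def a(self) -> np.ndarray:
        return np.array([it.a for it in self.items], dtype=float)

    @property
    def b(self) -> np.ndarray:
        return np.array([it.b for it in self.items], dtype=float)

    @property
    def c(self) -> np.ndarray:
        return np.array([it.c for it in self.items], dtype=float)

    def subset(self, item_ids: Iterable[str]) -> "ItemBank":
        """Bank restricted to ``item_ids``, preserving the bank's order."""
        keep = set(item_ids)
        missing = keep - set(self.item_ids)
        if missing:
            raise KeyError(f"items not in bank: {sorted(missing)}")
        return ItemBank(
            [it for it in self.items if it.item_id in keep], dict(self.metadata)
        )

    def without(self, item_ids: Iterable[str]) -> "ItemBank":
        drop = set(item_ids)
        return self.subset([i for i in self.item_ids if i not in drop])

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"item_id": it.item_id, "topic": it.topic, "a": it.a, "b": it.b, "c": it.c}
                for it in self.items
            ],
            columns=_BANK_COLUMNS,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, metadata: dict | None = None) -> "ItemBank":
        items = [
            ItemParameters(
                item_id=str(row.item_id),
                a=float(row.a),
                b=float(row.b),
                c=float(row.c),
                topic=None if pd.isna(row.topic) else str(row.topic),
            )
            for row in frame.itertuples()
        ]
        return cls(items, metadata or {})

    def to_json(self, path) -> None:
        payload = {
            "metadata": self.metadata,
            "items": [
                {"item_id": it.item_id, "topic": it.topic, "a": it.a, "b": it.b, "c": it.c}
                for it in self.items
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ItemBank":
        with open(path) as fh:
            payload = json.load(fh)
        if isinstance(payload, list):  # bare array form
            payload = {"metadata": {}, "items": payload}
        items = [
            ItemParameters(
                item_id=str(d["item_id"]),
                a=float(d["a"]),
                b=float(d["b"]),
                c=float(d["c"]),
                topic=d.get("topic"),
            )
            for d in payload["items"]
        ]
        return cls(items, payload.get("metadata", {}))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ItemBank":
        return cls.from_frame(pd.read_csv(path, dtype={"item_id": str}))


@dataclass(frozen=True)
class AbilityGrid:
    """Quadrature grid over the latent ability scale.

    Nodes are strictly increasing ability values; weights are prior-density
    masses normalized to sum to one.  The default grid places equally spaced
    nodes under a standard normal prior, which anchors the ability metric to
    the respondent population (mean 0, SD 1).
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.size < 2 or np.any(np.diff(nodes) <= 0):
            raise ValueError("grid nodes must be strictly increasing, length >= 2")
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("grid weights must be nonnegative with positive sum")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights / weights.sum())

    @classmethod
    def normal(cls, n: int = 61, bounds: tuple[float, float] = (-6.0, 6.0)) -> "AbilityGrid":
        """Equally spaced nodes on ``bounds`` with N(0,1) density weights."""
        nodes = np.linspace(bounds[0], bounds[1], n)
        return cls(nodes, norm.pdf(nodes))

    @property
    def mean(self) -> float:
        return float(self.weights @ self.nodes)

    @property
    def sd(self) -> float:
        m = self.mean
        return float(np.sqrt(self.weights @ (self.nodes - m) ** 2))


def icc_3pl(params: ItemParameters, theta) -> np.ndarray | float:
    """Item characteristic curve: probability of a correct response at ``theta``.

    Computes ``c + (1 - c) / (1 + exp(-a (theta - b)))``.  ``theta`` may be a
    scalar or array; non-finite values raise.
    """
    theta_arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta_arr)):
        raise ValueError("theta must be finite")
    p = params.c + (1.0 - params.c) * expit(params.a * (theta_arr - params.b))
    return float(p) if np.isscalar(theta) or theta_arr.ndim == 0 else p


def icc_3pl_matrix(a: np.ndarray, b: np.ndarray, c: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Vectorized ICC for an item bank: returns an (items, nodes) matrix."""
    a = np.asarray(a, float)[:, None]
    b = np.asarray(b, float)[:, None]
    c = np.asarray(c, float)[:, None]
    return c + (1.0 - c) * expit(a * (nodes[None, :] - b))


def pattern_loglik(bank: ItemBank, responses: Sequence[float], theta: float) -> float:
    """Log-likelihood of one person's response pattern at ability ``theta``.

    ``responses`` is aligned with the bank: 1 correct, 0 incorrect, NaN not
    administered.  By local independence the log-likelihood is the sum over
    administered items of ``log p`` or ``log(1 - p)``; missing-by-design
    entries contribute nothing.
    """
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    x = np.asarray(responses, dtype=float)
    if x.shape != (len(bank),):
        raise ValueError(
            f"response vector length {x.size} does not match bank size {len(bank)}"
        )
    mask = ~np.isnan(x)
    if not mask.any():
        raise ValueError("all responses missing: at least one administered item required")
    p = np.clip(
        icc_3pl_matrix(bank.a, bank.b, bank.c, np.array([float(theta)]))[:, 0],
        1e-12,
        1 - 1e-12,
    )
    ll = np.where(x == 1, np.log(p), np.log1p(-p))
    return float(ll[mask].sum())


def slope_to_communality(a: float) -> float:
    """Communality implied by a logistic discrimination slope.

    Under the factor-analytic parameterization, the normal-ogive loading is
    ``lambda = (a/D) / sqrt(1 + (a/D)^2)`` with D = 1.7, and the communality
    is ``lambda^2`` — the proportion of the item's (latent continuous)
    variance explained by the ability factor.  A slope of 0.71 maps to a
    communality of 0.15, the screening floor used in item selection.
    """
    if not math.isfinite(a):
        raise ValueError("slope must be finite")
    ad = a / SCALING_D
    lam = ad / math.sqrt(1.0 + ad * ad)
    return lam * lam


def communality_to_slope(h2: float) -> float:
    """Inverse of :func:`slope_to_communality` on the nonnegative branch."""
    if not 0.0 <= h2 < 1.0:
        raise ValueError("communality must lie in [0, 1)")
    lam2 = h2
    return SCALING_D * math.sqrt(lam2 / (1.0 - lam2))
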
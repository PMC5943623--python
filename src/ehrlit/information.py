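"""Item and test information functions and standard-error curves.

Test information at ability ``theta`` is the reciprocal of the squared
standard error of the ability estimate, ``I(theta) = 1 / SE(theta)^2``,
and is additive over items.  For the 3PL model the (Birnbaum) item
information is

    I_i(theta) = a^2 * ((p - c) / (1 - c))^2 * (1 - p) / p

which for ``c = 0`` reduces to ``a^2 * p * (1 - p)`` with maximum
``a^2 / 4`` at ``theta = b``.  An instrument is conventionally judged
adequate where information exceeds 4, i.e. where the SE of the ability
estimate is below 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .irt_core import ItemBank, ItemParameters, icc_3pl_matrix

__all__ = [
    "InformationCurve",
    "default_grid",
    "item_information",
    "test_information",
    "info_summaries",
    "curve_without_items",
    "average_information",
    "plot_curves",
]


def default_grid(n: int = 401, bounds: tuple[float, float] = (-4.0, 4.0)) -> np.ndarray:
    """Default display grid: 401 equally spaced abilities on [-4, 4]."""
    return np.linspace(bounds[0], bounds[1], n)


@dataclass(frozen=True)
class InformationCurve:
    """I(theta) on an ability grid with SE(theta) = 1 / sqrt(I(theta))."""

    grid: np.ndarray
    info: np.ndarray
    se: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.info) < 0):
            raise ValueError("information must be nonnegative")


def item_information(params: ItemParameters, theta) -> np.ndarray | float:
    """Birnbaum 3PL item information at ``theta`` (scalar or array)."""
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    p = icc_3pl_matrix(
        np.array([params.a]), np.array([params.b]), np.array([params.c]), theta_arr
    )[0]
    p = np.clip(p, 1e-12, 1 - 1e-12)
    info = params.a**2 * ((p - params.c) / (1 - params.c)) ** 2 * (1 - p) / p
    info = np.maximum(info, 0.0)
    return float(info[0]) if np.isscalar(theta) or np.ndim(theta) == 0 else info


def _bank_information(bank: ItemBank, grid: np.ndarray) -> np.ndarray:
    p = np.clip(icc_3pl_matrix(bank.a, bank.b, bank.c, grid), 1e-12, 1 - 1e-12)
    c = bank.c[:, None]
    a = bank.a[:, None]
    return np.maximum(a**2 * ((p - c) / (1 - c)) ** 2 * (1 - p) / p, 0.0)


def test_information(bank: ItemBank, grid: np.ndarray | None = None) -> InformationCurve:
    """Test information curve: pointwise sum of item informations."""
    if len(bank) == 0:
        raise ValueError("empty item bank")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    info = _bank_information(bank, grid).sum(axis=0)
    with np.errstate(divide="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(np.where(info > 0, info, 1.0)), np.inf)
    return InformationCurve(grid=grid, info=info, se=se)


def _interp_crossing(x0, y0, x1, y1, level):
    if y1 == y0:
        return x0
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def info_summaries(
    curve: InformationCurve,
    threshold: float = 4.0,
    avg_range: tuple[float, float] = (-4.0, 4.0),
    density_weighted: bool = False,
) -> dict:
    """Headline summaries of an information curve.

    Returns the maximum information and its ability location, the maximal
    contiguous ability interval where information exceeds ``threshold``
    (endpoints linearly interpolated between grid nodes; ``None`` when the
    threshold is never attained), and the average information over
    ``avg_range`` (unweighted by default; optionally weighted by the
    standard normal ability density).
    """
    g, f = np.asarray(curve.grid), np.asarray(curve.info)
    if avg_range[0] < g[0] - 1e-12 or avg_range[1] > g[-1] + 1e-12:
        raise ValueError("curve grid does not cover avg_range")
    k = int(np.argmax(f))
    above = f > threshold
    intervals: list[tuple[float, float]] = []
    i = 0
    n = len(g)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            lo = g[i] if i == 0 else _interp_crossing(g[i - 1], f[i - 1], g[i], f[i], threshold)
            hi = g[j] if j == n - 1 else _interp_crossing(g[j], f[j], g[j + 1], f[j + 1], threshold)
            intervals.append((float(lo), float(hi)))
            i = j + 1
        else:
            i += 1
    interval = max(intervals, key=lambda t: t[1] - t[0]) if intervals else None

    xs = np.linspace(avg_range[0], avg_range[1], 401)
    vals = np.interp(xs, g, f)
    if density_weighted:
        from scipy.stats import norm

        w = norm.pdf(xs)
        avg = float((vals * w).sum() / w.sum())
    else:
        avg = float(vals.mean())
    return {
        "max_info": float(f[k]),
        "argmax": float(g[k]),
        "above_threshold_interval": interval,
        "average_info": avg,
    }


def curve_without_items(
    bank: ItemBank, excluded: Iterable[str], grid: np.ndarray | None = None
) -> InformationCurve:
    """Test information of the bank with ``excluded`` items removed."""
    reduced = bank.without(excluded)
    if len(reduced) == 0:
        raise ValueError("cannot exclude every item from the bank")
    return test_information(reduced, grid)


def average_information(
    params: ItemParameters, avg_range: tuple[float, float] = (-4.0, 4.0), n: int = 401
) -> float:
    """Unweighted mean item information over ``avg_range``."""
    xs = np.linspace(avg_range[0], avg_range[1], n)
    return float(np.mean(item_information(params, xs)))


def plot_curves(
    curves: Mapping[str, InformationCurve],
    path,
    threshold: float | None = 4.0,
    title: str = "Test information",
) -> None:
    """Render labelled information curves to ``path`` (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, curve in curves.items():
        ax.plot(curve.grid, curve.info, label=label)
    if threshold is not None:
        ax.axhline(threshold, color="grey", ls=":", lw=1,
                   label=f"I = {threshold:g} (SE = {1/np.sqrt(threshold):.2g})")
    ax.set_xlabel(r"ability $\theta$")
    ax.set_ylabel(r"information $I(\theta)$")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
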
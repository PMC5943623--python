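"""Marginal maximum likelihood estimation of the 3PL model via EM.

The fitting routine integrates the person abilities out of the likelihood
over a fixed quadrature grid (standard normal prior) and alternates:

* E-step — posterior weights of each person over the grid nodes, giving
  expected per-node counts of administered and correct responses per item;
* M-step — bounded per-item maximization of the expected complete-data
  log-likelihood (L-BFGS-B with analytic gradients).

Missing responses are missing-by-design (block administration) and are
ignorable: they simply contribute nothing to any likelihood term.  The
guessing parameter is box-constrained (default [0, 0.5]) to tame the
well-known 3PL instability; it can be fixed to zero per item.  Standard
errors come from a central-difference Hessian of the marginal
log-likelihood at the solution, computed efficiently by caching per-item
likelihood contributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .irt_core import AbilityGrid, ItemBank, ItemParameters, icc_3pl_matrix

__all__ = [
    "ResponseMatrix",
    "FitConfig",
    "FitResult",
    "DegenerateItemError",
    "fit_3pl",
    "wald_tests",
    "refit_with_constraints",
]

log = logging.getLogger(__name__)

_PCLIP = 1e-10


class DegenerateItemError(ValueError):
    """An item's slope is unidentified (all responses correct or incorrect)."""


@dataclass
class ResponseMatrix:
    """Persons x items dichotomous response matrix with missing-by-design cells.

    ``data`` is a float array with entries 1 (correct), 0 (incorrect) or NaN
    (not administered).
    """

    person_ids: list[str]
    item_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.person_ids = [str(p) for p in self.person_ids]
        self.item_ids = [str(i) for i in self.item_ids]
        data = np.asarray(self.data, dtype=float)
        if data.shape != (len(self.person_ids), len(self.item_ids)):
            raise ValueError("data shape does not match id lists")
        vals = data[~np.isnan(data)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("responses must be 0, 1 or NaN")
        if len(set(self.person_ids)) != len(self.person_ids):
            raise ValueError("person_ids not unique")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("item_ids not unique")
        self.data = data

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def administered(self) -> np.ndarray:
        """Boolean mask of administered (person, item) cells."""
        return ~np.isnan(self.data)

    def validate(self) -> None:
        """Enforce the structural invariants (raise on violation)."""
        adm = self.administered
        empty_persons = [p for p, ok in zip(self.person_ids, adm.any(axis=1)) if not ok]
        if empty_persons:
            raise ValueError(f"persons with no administered items: {empty_persons[:5]}")
        empty_items = [i for i, ok in zip(self.item_ids, adm.any(axis=0)) if not ok]
        if empty_items:
            raise ValueError(f"items with no responses: {empty_items[:5]}")

    def subset_items(self, item_ids: Iterable[str]) -> "ResponseMatrix":
        keep = [i for i in self.item_ids if i in set(item_ids)]
        idx = [self.item_ids.index(i) for i in keep]
        return ResponseMatrix(list(self.person_ids), keep, self.data[:, idx].copy())

    def subset_persons(self, person_ids: Iterable[str]) -> "ResponseMatrix":
        keep = set(person_ids)
        rows = [k for k, p in enumerate(self.person_ids) if p in keep]
        return ResponseMatrix(
            [self.person_ids[k] for k in rows], list(self.item_ids), self.data[rows].copy()
        )

    # -- long-format conversion (the on-disk schema) ----------------------

    def to_long(self) -> pd.DataFrame:
        """Long-format frame with columns person_id, item_id, response."""
        rows, cols = np.nonzero(self.administered)
        return pd.DataFrame(
            {
                "person_id": [self.person_ids[r] for r in rows],
                "item_id": [self.item_ids[c] for c in cols],
                "response": self.data[rows, cols].astype(int),
            }
        )

    @classmethod
    def from_long(cls, frame: pd.DataFrame) -> "ResponseMatrix":
        dup = frame.duplicated(subset=["person_id", "item_id"])
        if dup.any():
            first = frame.loc[dup.idxmax()]
            raise ValueError(
                f"duplicate (person, item) pair: ({first.person_id}, {first.item_id})"
            )
        persons = list(dict.fromkeys(frame["person_id"].astype(str)))
        items = list(dict.fromkeys(frame["item_id"].astype(str)))
        data = np.full((len(persons), len(items)), np.nan)
        pidx = {p: k for k, p in enumerate(persons)}
        iidx = {i: k for k, i in enumerate(items)}
        for p, i, r in frame[["person_id", "item_id", "response"]].itertuples(index=False):
            data[pidx[str(p)], iidx[str(i)]] = float(r)
        return cls(persons, items, data)


@dataclass(frozen=True)
class FitConfig:
    """Configuration of one MML-EM fit."""

    quadrature_points: int = 61
    quadrature_range: tuple[float, float] = (-6.0, 6.0)
    max_em_iterations: int = 500
    convergence_tol: float = 1e-4
    guessing_upper_bound: float = 0.5
    fix_c_to_zero: bool | frozenset = False
    slope_bounds: tuple[float, float] = (-8.0, 20.0)
    difficulty_bounds: tuple[float, float] = (-6.0, 6.0)
    use_guessing_prior: bool = False
    guessing_prior_ab: tuple[float, float] = (2.0, 10.0)
    compute_se: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.quadrature_points < 21:
            raise ValueError("quadrature_points must be >= 21")
        if isinstance(self.fix_c_to_zero, (set, list, tuple)):
            object.__setattr__(self, "fix_c_to_zero", frozenset(self.fix_c_to_zero))

    def c_fixed_mask(self, item_ids: Sequence[str]) -> np.ndarray:
        if isinstance(self.fix_c_to_zero, bool):
            return np.full(len(item_ids), self.fix_c_to_zero)
        return np.array([i in self.fix_c_to_zero for i in item_ids])

    def grid(self) -> AbilityGrid:
        return AbilityGrid.normal(self.quadrature_points, self.quadrature_range)


@dataclass
class FitResult:
    """Estimates, standard errors and convergence record of an MML-EM fit."""

    bank: ItemBank
    standard_errors: pd.DataFrame | None
    loglik: float
    converged: bool
    n_iterations: int
    n_persons: int
    n_items: int
    config: FitConfig
    loglik_history: list[float] = field(default_factory=list)

    @property
    def item_ids(self) -> list[str]:
        return self.bank.item_ids


def _expected_loglik_terms(x, nodes, r, m, c_fixed, prior):
    """Negative expected complete-data log-likelihood and gradient for one item."""
    if c_fixed:
        a, b = x
        c = 0.0
    else:
        a, b, c = x
    q = expit(a * (nodes - b))
    p = np.clip(c + (1.0 - c) * q, _PCLIP, 1.0 - _PCLIP)
    f = -(r * np.log(p) + (m - r) * np.log1p(-p)).sum()
    dfdp = -(r / p - (m - r) / (1.0 - p))
    qd = q * (1.0 - q)
    ga = (dfdp * (1.0 - c) * qd * (nodes - b)).sum()
    gb = (dfdp * (1.0 - c) * qd * -a).sum()
    if c_fixed:
        return f, np.array([ga, gb])
    gc = (dfdp * (1.0 - q)).sum()
    if prior is not None:
        # Optional stabilizing Beta(alpha, beta) log-prior on c.
        al, be = prior
        cc = np.clip(c, 1e-6, 1 - 1e-6)
        f -= (al - 1) * np.log(cc) + (be - 1) * np.log1p(-cc)
        gc -= (al - 1) / cc - (be - 1) / (1 - cc)
    return f, np.array([ga, gb, gc])


def _person_node_loglik(X1, X0, logP, log1P):
    """(persons, nodes) log-likelihood matrix from masked response indicators."""
    return X1 @ logP + X0 @ log1P


def _marginal_loglik(LL, logw):
    return float(logsumexp(LL + logw[None, :], axis=1).sum())


def _check_degenerate(matrix: ResponseMatrix) -> None:
    adm = matrix.administered
    with np.errstate(invalid="ignore"):
        n_correct = np.nansum(matrix.data, axis=0)
    n_adm = adm.sum(axis=0)
    for j, item in enumerate(matrix.item_ids):
        if n_adm[j] == 0:
            raise DegenerateItemError(f"item {item!r} has no responses")
        if n_correct[j] == 0 or n_correct[j] == n_adm[j]:
            kind = "correct" if n_correct[j] else "incorrect"
            raise DegenerateItemError(
                f"item {item!r} answered {kind} by every respondent; "
                "slope is unidentified"
            )


def _initial_values(matrix: ResponseMatrix, c_fixed: np.ndarray,
                    init: ItemBank | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_items = matrix.n_items
    if init is not None:
        lut = {it.item_id: it for it in init}
        a = np.array([lut[i].a if i in lut else 1.0 for i in matrix.item_ids])
        b = np.array([lut[i].b if i in lut else 0.0 for i in matrix.item_ids])
        c = np.array([lut[i].c if i in lut else 0.1 for i in matrix.item_ids])
    else:
        with np.errstate(invalid="ignore"):
            phat = np.nanmean(matrix.data, axis=0)
        phat = np.clip(phat, 0.02, 0.98)
        a = np.ones(n_items)
        b = -np.log(phat / (1 - phat))  # logit-transformed classical difficulty
        c = np.full(n_items, 0.1)
    c = np.where(c_fixed, 0.0, c)
    return a, b, c


def fit_3pl(
    responses: ResponseMatrix,
    config: FitConfig | None = None,
    init: ItemBank | None = None,
    topics: dict[str, str] | None = None,
) -> FitResult:
    """Fit the 3PL model by marginal maximum likelihood EM.

    Parameters
    ----------
    responses
        Persons x items matrix; every item must show both a correct and an
        incorrect response (otherwise :class:`DegenerateItemError`).
    config
        Quadrature, convergence and constraint settings.
    init
        Optional warm-start bank (used by constrained refits).
    topics
        Optional item_id -> topic labels carried into the estimated bank.
    """
    config = config or FitConfig()
    responses.validate()
    _check_degenerate(responses)

    grid = config.grid()
    nodes, logw = grid.nodes, np.log(grid.weights)
    adm = responses.administered
    X = responses.data
    X1 = np.where(adm & (X == 1), 1.0, 0.0)
    X0 = np.where(adm & (X == 0), 1.0, 0.0)
    Mmask = adm.astype(float)

    c_fixed = config.c_fixed_mask(responses.item_ids)
    a, b, c = _initial_values(responses, c_fixed, init)
    prior = config.guessing_prior_ab if config.use_guessing_prior else None

    a_lo, a_hi = config.slope_bounds
    b_lo, b_hi = config.difficulty_bounds
    c_hi = config.guessing_upper_bound
    a = np.clip(a, a_lo, a_hi)
    b = np.clip(b, b_lo, b_hi)
    c = np.clip(c, 0.0, c_hi)

    history: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_em_iterations + 1):
        P = np.clip(icc_3pl_matrix(a, b, c, nodes), _PCLIP, 1 - _PCLIP)
        logP, log1P = np.log(P), np.log1p(-P)
        LL = _person_node_loglik(X1, X0, logP, log1P)  # (persons, nodes)
        history.append(_marginal_loglik(LL, logw))
        A = LL + logw[None, :]
        A -= A.max(axis=1, keepdims=True)
        post = np.exp(A)
        post /= post.sum(axis=1, keepdims=True)

        R = post.T @ X1  # (nodes, items) expected correct
        Mtot = post.T @ Mmask  # (nodes, items) expected administered

        a_new, b_new, c_new = a.copy(), b.copy(), c.copy()
        for j in range(responses.n_items):
            fixed = bool(c_fixed[j])
            x0 = [a[j], b[j]] if fixed else [a[j], b[j], c[j]]
            bounds = [(a_lo, a_hi), (b_lo, b_hi)] + ([] if fixed else [(0.0, c_hi)])
            res = minimize(
                _expected_loglik_terms,
                x0,
                args=(nodes, R[:, j], Mtot[:, j], fixed, prior),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
            )
            if fixed:
                a_new[j], b_new[j] = res.x
            else:
                a_new[j], b_new[j], c_new[j] = res.x

        delta = max(
            np.abs(a_new - a).max(),
            np.abs(b_new - b).max(),
            np.abs(np.where(c_fixed, 0.0, c_new - c)).max(),
        )
        a, b, c = a_new, b_new, c_new
        if delta < config.convergence_tol:
            converged = True
            break

    P = np.clip(icc_3pl_matrix(a, b, c, nodes), _PCLIP, 1 - _PCLIP)
    LL = X1 @ np.log(P) + X0 @ np.log1p(-P)
    loglik = _marginal_loglik(LL, logw)
    history.append(loglik)

    if not converged:
        log.warning(
            "EM did not converge in %d iterations (last max change > %g)",
            config.max_em_iterations,
            config.convergence_tol,
        )

    topics = topics or {}
    bank = ItemBank(
        [
            ItemParameters(
                item_id=i, a=float(a[j]), b=float(b[j]), c=float(c[j]),
                topic=topics.get(i),
            )
            for j, i in enumerate(responses.item_ids)
        ]
    )
    se = (
        _hessian_standard_errors(X1, X0, Mmask, nodes, logw, a, b, c, c_fixed,
                                 responses.item_ids, c_upper=config.guessing_upper_bound)
        if config.compute_se
        else None
    )
    return FitResult(
        bank=bank,
        standard_errors=se,
        loglik=loglik,
        converged=converged,
        n_iterations=n_iter,
        n_persons=responses.n_persons,
        n_items=responses.n_items,
        config=config,
        loglik_history=history,
    )


def _hessian_standard_errors(X1, X0, Mmask, nodes, logw, a, b, c, c_fixed, item_ids,
                             c_upper=1.0):
    """SEs from a numerical Hessian of the marginal log-likelihood.

    By Fisher's identity the gradient of the marginal log-likelihood with
    respect to the item parameters equals the expected complete-data
    gradient under the E-step posterior, which is analytic and cheap; the
    Hessian is obtained by central-differencing that gradient.  Guessing
    parameters resting on a box boundary have no interior curvature; they
    are left out of the Hessian and reported with an NaN standard error.
    """
    n_items = len(item_ids)
    boundary_tol = 1e-6
    free: list[tuple[int, int]] = []  # (item index, param index 0=a 1=b 2=c)
    for j in range(n_items):
        free.append((j, 0))
        free.append((j, 1))
        if not c_fixed[j] and boundary_tol < c[j] < c_upper - boundary_tol:
            free.append((j, 2))
    theta0 = np.array([[a[j], b[j], c[j]][k] for j, k in free])
    h = 1e-4 * (1.0 + np.abs(theta0))

    def gradient(vec: np.ndarray) -> np.ndarray:
        av, bv, cv = a.copy(), b.copy(), c.copy()
        for u, (j, k) in enumerate(free):
            if k == 0:
                av[j] = vec[u]
            elif k == 1:
                bv[j] = vec[u]
            else:
                cv[j] = vec[u]
        Q = expit(av[:, None] * (nodes[None, :] - bv[:, None]))  # (items, nodes)
        P = np.clip(cv[:, None] + (1 - cv[:, None]) * Q, _PCLIP, 1 - _PCLIP)
        LL = X1 @ np.log(P) + X0 @ np.log1p(-P)
        A = LL + logw[None, :]
        A -= A.max(axis=1, keepdims=True)
        post = np.exp(A)
        post /= post.sum(axis=1, keepdims=True)
        R = post.T @ X1  # (nodes, items) expected correct
        W = post.T @ Mmask - R  # expected incorrect
        coef = R.T / P - W.T / (1 - P)  # (items, nodes)
        qd = Q * (1 - Q)
        g = np.empty(len(free))
        for u, (j, k) in enumerate(free):
            if k == 0:
                dp = (1 - cv[j]) * qd[j] * (nodes - bv[j])
            elif k == 1:
                dp = -(1 - cv[j]) * qd[j] * av[j]
            else:
                dp = 1 - Q[j]
            g[u] = coef[j] @ dp
        return g

    n_free = len(free)
    H = np.empty((n_free, n_free))
    for u in range(n_free):
        e = np.zeros(n_free)
        e[u] = h[u]
        H[:, u] = (gradient(theta0 + e) - gradient(theta0 - e)) / (2 * h[u])
    H = 0.5 * (H + H.T)

    info = -H
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn(
            "observed information matrix not positive definite; "
            "using pseudo-inverse for standard errors",
            RuntimeWarning,
            stacklevel=2,
        )
        cov = np.linalg.pinv(info)
        diag = np.abs(np.diag(cov))
    se_vals = np.sqrt(diag)

    table = pd.DataFrame(
        np.nan, index=pd.Index(item_ids, name="item_id"), columns=["a_se", "b_se", "c_se"]
    )
    for u, (j, k) in enumerate(free):
        table.iloc[j, k] = se_vals[u]
    return table


def wald_tests(fit: FitResult, alpha: float = 0.05) -> pd.DataFrame:
    """Per-item Wald tests of the screening hypotheses.

    Two-sided z-test of ``c = 0`` (guessing parameters not significantly
    different from zero are candidates for fixing at zero) and one-sided
    z-test of ``a > 0``.  Items with a fixed guessing parameter get the
    verdict ``"fixed"``.
    """
    if fit.standard_errors is None:
        raise ValueError("fit has no standard errors (compute_se was disabled)")
    c_fixed = fit.config.c_fixed_mask(fit.item_ids)
    z_a_crit = norm.ppf(1 - alpha)
    z_c_crit = norm.ppf(1 - alpha / 2)
    boundary_tol = 1e-6
    rows = []
    for j, item in enumerate(fit.bank):
        se = fit.standard_errors.loc[item.item_id]
        if np.isnan(se["a_se"]):
            raise ValueError(f"missing standard error for slope of item {item.item_id!r}")
        z_a = item.a / se["a_se"]
        if c_fixed[j]:
            c_verdict, z_c = "fixed", np.nan
        elif np.isnan(se["c_se"]):
            # Estimate resting on a box boundary: no interior curvature.
            # At the floor the estimate is indistinguishable from zero; at
            # the ceiling it is unambiguously away from zero.
            if item.c <= boundary_tol:
                z_c, c_verdict = 0.0, "not_significant"
            else:
                z_c, c_verdict = np.inf, "significant"
        else:
            z_c = item.c / se["c_se"]
            c_verdict = "significant" if abs(z_c) > z_c_crit else "not_significant"
        rows.append(
            {
                "item_id": item.item_id,
                "a": item.a,
                "a_se": se["a_se"],
                "a_z": z_a,
                "a_significantly_positive": bool(z_a > z_a_crit),
                "c": item.c,
                "c_se": se["c_se"],
                "c_z": z_c,
                "c_verdict": c_verdict,
            }
        )
    return pd.DataFrame(rows).set_index("item_id")


def refit_with_constraints(
    responses: ResponseMatrix,
    fit: FitResult,
    fix_c_items: Iterable[str] = (),
    remove_items: Iterable[str] = (),
    config: FitConfig | None = None,
) -> FitResult:
    """Refit after removing items and/or fixing guessing parameters to zero.

    The previous estimates warm-start the EM (with ``c`` reset to zero where
    newly fixed).  At least two items must remain.
    """
    config = config or fit.config
    remove = set(remove_items)
    keep = [i for i in responses.item_ids if i not in remove]
    if len(keep) < 2:
        raise ValueError("constraint set leaves fewer than 2 items")
    sub = responses.subset_items(keep)
    # Drop persons left with no administered items after removal.
    alive = sub.administered.any(axis=1)
    if not alive.all():
        sub = ResponseMatrix(
            [p for p, ok in zip(sub.person_ids, alive) if ok], sub.item_ids,
            sub.data[alive],
        )

    prev_fixed = config.c_fixed_mask(responses.item_ids)
    fixed_ids = {i for i, f in zip(responses.item_ids, prev_fixed) if f} | set(fix_c_items)
    new_config = replace(config, fix_c_to_zero=frozenset(i for i in fixed_ids if i in keep))

    init_items = []
    for it in fit.bank:
        if it.item_id in keep:
            c0 = 0.0 if it.item_id in fixed_ids else it.c
            init_items.append(replace(it, c=c0))
    init = ItemBank(init_items) if init_items else None
    topics = {it.item_id: it.topic for it in fit.bank if it.topic is not None}
    return fit_3pl(sub, new_config, init=init, topics=topics)
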
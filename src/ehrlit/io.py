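"""Readers and writers for every on-disk schema the pipeline uses.

Responses travel as long-format CSV (``person_id,item_id,response`` with
0/1 responses; absent rows mean not administered).  Item banks are JSON
(array of ``{item_id, topic, a, b, c}``) with a CSV mirror.  Reports are
JSON; curves, residuals and scores are CSV.  Floats in JSON artifacts are
serialized at 12 significant digits, which is enough to round-trip the
estimates and keeps artifacts byte-deterministic.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .diagnostics import MarginalResidual, residuals_to_frame
from .estimation import FitConfig, FitResult, ResponseMatrix
from .information import InformationCurve
from .irt_core import ItemBank
from .response_qc import QCRecord, QCReport
from .selection import SelectionReport

__all__ = [
    "read_responses",
    "write_responses",
    "write_bank",
    "read_bank",
    "write_fit",
    "read_fit",
    "write_residuals",
    "write_selection",
    "write_curve",
    "write_scores",
    "write_qc_records",
    "read_qc_records",
    "write_qc_report",
    "write_json",
    "load_config_file",
]

_RESPONSE_COLUMNS = ["person_id", "item_id", "response"]


def _round12(x: float) -> float:
    return float(f"{x:.12g}")


def _jsonify(obj: Any) -> Any:
    """Recursively convert to JSON-safe types with 12-significant-digit floats."""
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return None if np.isnan(x) else _round12(x)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def write_json(payload: Any, path, meta: Mapping | None = None) -> None:
    data = _jsonify(payload)
    if meta is not None and isinstance(data, dict):
        data["_meta"] = _jsonify(dict(meta))
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=False)
        fh.write("\n")


# -- responses ------------------------------------------------------------


def read_responses(path) -> ResponseMatrix:
    """Read a long-format response CSV, validating rows strictly.

    Malformed rows (response not 0/1, missing fields) and duplicate
    (person, item) pairs raise with the offending line number.
    """
    frame = pd.read_csv(path, dtype={"person_id": str, "item_id": str})
    if list(frame.columns) != _RESPONSE_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(_RESPONSE_COLUMNS)}, got {','.join(frame.columns)}"
        )
    if frame.empty:
        return ResponseMatrix([], [], np.empty((0, 0)))
    bad = frame["response"].isna() | ~frame["response"].isin([0, 1])
    if bad.any():
        line = int(frame.index[bad][0]) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: malformed response at line {line}")
    nulls = frame[["person_id", "item_id"]].isna().any(axis=1)
    if nulls.any():
        line = int(frame.index[nulls][0]) + 2
        raise ValueError(f"{path}: missing identifier at line {line}")
    dup = frame.duplicated(subset=["person_id", "item_id"])
    if dup.any():
        line = int(frame.index[dup][0]) + 2
        raise ValueError(f"{path}: duplicate (person, item) pair at line {line}")
    return ResponseMatrix.from_long(frame)


def write_responses(matrix: ResponseMatrix, path) -> None:
    matrix.to_long().to_csv(path, index=False)


# -- banks and fits -------------------------------------------------------


def write_bank(bank: ItemBank, path) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        bank.to_csv(path)
    else:
        bank.to_json(path)


def read_bank(path) -> ItemBank:
    path = Path(path)
    return ItemBank.from_csv(path) if path.suffix == ".csv" else ItemBank.from_json(path)


def write_fit(fit: FitResult, path, meta: Mapping | None = None) -> None:
    se = fit.standard_errors
    items = []
    for it in fit.bank:
        row: dict[str, Any] = {
            "item_id": it.item_id, "topic": it.topic, "a": it.a, "b": it.b, "c": it.c,
        }
        if se is not None:
            row.update(
                a_se=se.loc[it.item_id, "a_se"],
                b_se=se.loc[it.item_id, "b_se"],
                c_se=se.loc[it.item_id, "c_se"],
            )
        items.append(row)
    payload = {
        "items": items,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_iterations": fit.n_iterations,
        "n_persons": fit.n_persons,
        "n_items": fit.n_items,
        "config": dataclasses.asdict(fit.config),
    }
    write_json(payload, path, meta)


def read_fit(path) -> FitResult:
    """Rehydrate a fit report (enough for scoring, information and screening)."""
    with open(path) as fh:
        payload = json.load(fh)
    from .irt_core import ItemParameters

    items = payload["items"]
    bank = ItemBank(
        [
            ItemParameters(d["item_id"], float(d["a"]), float(d["b"]), float(d["c"]),
                           d.get("topic"))
            for d in items
        ]
    )
    if items and "a_se" in items[0]:
        se = pd.DataFrame(
            {
                "a_se": [d.get("a_se") for d in items],
                "b_se": [d.get("b_se") for d in items],
                "c_se": [d.get("c_se") for d in items],
            },
            index=pd.Index([d["item_id"] for d in items], name="item_id"),
            dtype=float,
        )
    else:
        se = None
    cfg = payload.get("config", {})
    cfg.pop("_meta", None)
    if cfg.get("fix_c_to_zero") and not isinstance(cfg["fix_c_to_zero"], bool):
        cfg["fix_c_to_zero"] = frozenset(cfg["fix_c_to_zero"])
    if "quadrature_range" in cfg:
        cfg["quadrature_range"] = tuple(cfg["quadrature_range"])
    for key in ("slope_bounds", "difficulty_bounds", "guessing_prior_ab"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    return FitResult(
        bank=bank,
        standard_errors=se,
        loglik=float(payload["loglik"]),
        converged=bool(payload["converged"]),
        n_iterations=int(payload["n_iterations"]),
        n_persons=int(payload["n_persons"]),
        n_items=int(payload["n_items"]),
        config=FitConfig(**cfg),
    )


# -- reports and curves ---------------------------------------------------


def write_residuals(residuals: list[MarginalResidual], path, z_threshold: float = 3.0) -> None:
    residuals_to_frame(residuals, z_threshold).to_csv(
        path, index=False, float_format="%.12g"
    )


def write_selection(report: SelectionReport, path, meta: Mapping | None = None) -> None:
    payload = {
        "per_item": [dataclasses.asdict(v) for v in report.per_item],
        "retained": report.retained,
        "short_form": report.short_form,
        "removal_counts": report.removal_counts().to_dict(orient="records"),
    }
    write_json(payload, path, meta)


def write_selection_table(report: SelectionReport, path) -> None:
    """Human-readable removal accounting (counts per rule)."""
    with open(path, "w") as fh:
        fh.write(report.removal_counts().to_string(index=False))
        fh.write("\n\nPer-item verdicts\n")
        fh.write(report.to_frame().to_string(index=False))
        fh.write("\n")


def write_curve(curve: InformationCurve, path) -> None:
    pd.DataFrame({"theta": curve.grid, "info": curve.info, "se": curve.se}).to_csv(
        path, index=False, float_format="%.12g"
    )


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.reset_index().to_csv(path, index=False, float_format="%.12g")


def write_qc_records(records: list[QCRecord], path) -> None:
    write_json([dataclasses.asdict(r) for r in records], path)


def read_qc_records(path) -> list[QCRecord]:
    with open(path) as fh:
        raw = json.load(fh)
    return [
        QCRecord(
            person_id=d["person_id"],
            repeat_pair=tuple(d["repeat_pair"]),
            catch_answers=tuple(bool(x) for x in d["catch_answers"]),
            repeat_item=d.get("repeat_item"),
            verdict=d.get("verdict"),
            reason=d.get("reason"),
        )
        for d in raw
    ]


def write_qc_report(report: QCReport, path, meta: Mapping | None = None) -> None:
    write_json(report.to_dict(), path, meta)


def load_config_file(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(fh)
        else:
            data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return data
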
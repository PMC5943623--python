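"""End-to-end analysis pipeline: simulate/ingest -> QC -> fit -> diagnose ->
screen -> information -> short form -> score.

Every artifact is written into the output directory as it is produced, so
a stage failure leaves the earlier artifacts on disk.  All randomness
derives from the single pipeline seed, JSON artifacts carry the
configuration hash and seed in a ``_meta`` block, and a run manifest lists
every artifact with the same stamp, making repeated runs under one seed
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as ehrio
from .estimation import FitConfig, fit_3pl
from .diagnostics import pair_residuals, triplet_residuals
from .information import curve_without_items, default_grid, info_summaries, test_information
from .irt_core import ItemBank
from .response_qc import apply_qc
from .scoring import score_table
from .selection import ItemVerdict, ScreeningConfig, SelectionReport, screen_items, select_short_form
from .synthetic_data import SimulationDesign, simulate_study

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    output_dir: str = "ehrlit_output"
    responses_path: str | None = None  # ingest mode
    qc_records_path: str | None = None
    simulate: SimulationDesign | None = None  # simulation mode
    fit: FitConfig = field(default_factory=FitConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    screening_enabled: bool = True
    qc_enabled: bool = True
    short_form_k: int = 14
    grid_bounds: tuple[float, float] = (-4.0, 4.0)
    grid_points: int = 401
    info_threshold: float = 4.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.responses_path is None and self.simulate is None:
            self.simulate = SimulationDesign(seed=self.seed)
        if self.short_form_k <= 0:
            raise ValueError("short_form_k must be positive")

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded)."""
        payload = dataclasses.asdict(self)
        for key in ("output_dir", "responses_path", "qc_records_path"):
            payload.pop(key, None)
        blob = json.dumps(ehrio._jsonify(payload), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute the pipeline; returns a name -> path mapping of artifacts."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    artifacts: dict[str, str] = {}
    run_log: list[str] = []

    def record(name: str, path: Path) -> None:
        artifacts[name] = str(path)

    def note(msg: str) -> None:
        log.info(msg)
        run_log.append(msg)

    def finish_manifest() -> None:
        relative = {name: Path(path).name for name, path in artifacts.items()}
        manifest = {"artifacts": relative, "log": run_log}
        ehrio.write_json(manifest, out / "run_manifest.json", meta)

    stage = "setup"
    try:
        # ---- acquire data -------------------------------------------------
        stage = "simulate"
        topics: dict[str, str] = {}
        strata = None
        if config.simulate is not None:
            design = dataclasses.replace(config.simulate, seed=config.seed)
            study = simulate_study(design)
            responses, qc_records = study["responses"], study["qc_records"]
            topics = {it.item_id: it.topic for it in study["bank"] if it.topic}
            strata = pd.DataFrame(
                {"stratum": study["labels"]},
                index=pd.Index(responses.person_ids, name="person_id"),
            )
            ehrio.write_bank(study["bank"], out / "true_bank.json")
            record("true_bank", out / "true_bank.json")
            ehrio.write_responses(responses, out / "responses.csv")
            record("responses", out / "responses.csv")
            ehrio.write_qc_records(qc_records, out / "qc_records.json")
            record("qc_records", out / "qc_records.json")
            note(f"simulate: {responses.n_persons} persons x {responses.n_items} items")
        else:
            responses = ehrio.read_responses(config.responses_path)
            qc_records = (
                ehrio.read_qc_records(config.qc_records_path)
                if config.qc_records_path
                else None
            )
            note(f"ingest: {responses.n_persons} persons x {responses.n_items} items")

        # ---- quality control ---------------------------------------------
        stage = "qc"
        if config.qc_enabled and qc_records is not None:
            responses, qc_report = apply_qc(responses, qc_records)
            ehrio.write_qc_report(qc_report, out / "qc_report.json", meta)
            record("qc_report", out / "qc_report.json")
            note(
                f"qc: excluded {qc_report.n_excluded}/{qc_report.n_total} "
                f"({qc_report.removal_percent:.1f}%)"
            )
        else:
            note("qc: skipped")

        # ---- fit ----------------------------------------------------------
        stage = "fit"
        fit = fit_3pl(responses, config.fit, topics=topics)
        ehrio.write_fit(fit, out / "fit_initial.json", meta)
        record("fit_initial", out / "fit_initial.json")
        note(
            f"fit: loglik={fit.loglik:.3f} converged={fit.converged} "
            f"iterations={fit.n_iterations}"
        )

        # ---- diagnostics ---------------------------------------------------
        stage = "diagnose"
        residuals = pair_residuals(fit, responses, config.screening.min_joint_n)
        if config.screening.check_triplets:
            residuals += triplet_residuals(fit, responses, config.screening.min_joint_n)
        ehrio.write_residuals(residuals, out / "residuals.csv", config.screening.z_threshold)
        record("residuals", out / "residuals.csv")
        note(f"diagnose: {len(residuals)} marginal residuals")

        # ---- screening -----------------------------------------------------
        stage = "screen"
        if config.screening_enabled:
            report, final_fit = screen_items(
                responses, config.fit, config.screening, topics=topics
            )
        else:
            report = SelectionReport(
                per_item=[ItemVerdict(i, "retained", None, None) for i in responses.item_ids],
                retained=list(responses.item_ids),
            )
            final_fit = fit
        note(f"screen: retained {len(report.retained)}/{responses.n_items} items")

        # ---- short form ----------------------------------------------------
        stage = "shortform"
        k = min(config.short_form_k, len(report.retained))
        if k < config.short_form_k:
            note(f"shortform: k clipped to {k} (only {len(report.retained)} retained)")
        report.short_form = select_short_form(final_fit, k, config.grid_bounds)
        ehrio.write_selection(report, out / "selection.json", meta)
        record("selection", out / "selection.json")
        ehrio.write_selection_table(report, out / "selection_table.txt")
        record("selection_table", out / "selection_table.txt")
        ehrio.write_fit(final_fit, out / "fit_final.json", meta)
        record("fit_final", out / "fit_final.json")
        note(f"shortform: {len(report.short_form)} items")

        # ---- information ---------------------------------------------------
        stage = "inform"
        grid = default_grid(config.grid_points, config.grid_bounds)
        full_curve = test_information(final_fit.bank, grid)
        ehrio.write_curve(full_curve, out / "information_full.csv")
        record("information_full", out / "information_full.csv")
        short_curve = test_information(final_fit.bank.subset(report.short_form), grid)
        ehrio.write_curve(short_curve, out / "information_short.csv")
        record("information_short", out / "information_short.csv")
        summaries = {
            "full": info_summaries(full_curve, config.info_threshold, config.grid_bounds),
            "short_form": info_summaries(short_curve, config.info_threshold, config.grid_bounds),
        }
        ehrio.write_json(summaries, out / "information_summaries.json", meta)
        record("information_summaries", out / "information_summaries.json")
        note(
            f"inform: full max I={summaries['full']['max_info']:.2f} at "
            f"theta={summaries['full']['argmax']:.2f}"
        )

        # ---- scoring -------------------------------------------------------
        stage = "score"
        scored_responses = responses.subset_items(final_fit.bank.item_ids)
        scores, stratum_means = score_table(final_fit.bank, scored_responses, strata)
        ehrio.write_scores(scores, out / "scores.csv")
        record("scores", out / "scores.csv")
        if stratum_means is not None:
            stratum_means.to_csv(out / "stratum_means.csv", index=False, float_format="%.12g")
            record("stratum_means", out / "stratum_means.csv")
        note(f"score: {len(scores)} respondents scored")

        finish_manifest()
        record("run_manifest", out / "run_manifest.json")
        return artifacts
    except Exception as exc:  # persist partial accounting, then re-raise
        run_log.append(f"FAILED at stage {stage}: {exc}")
        finish_manifest()
        raise PipelineError(stage, exc) from exc
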
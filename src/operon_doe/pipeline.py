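"""Single-command orchestration of the design/build/test workflow.

Stages run in order: rank parts -> build and enumerate the design space ->
D-optimal run selection -> stitch-ID assignment and picklist planning ->
(simulate or quantify) -> effect fit -> optimum prediction.  Every file
written is recorded in a JSON manifest with a SHA-256 checksum and the
seeds used, so a re-run with identical inputs is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import assembly, demo, design, doe, effects, parts, quantify, simulate
from .errors import OperonDoeError, PipelineError

logger = logging.getLogger(__name__)

MODES = ("design", "simulate", "analyse", "all")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, with explicit seeds."""

    parts_csv: Optional[str] = None          # None -> built-in synthetic demo
    design_config: dict = field(default_factory=demo.demo_design_config)
    n_runs: int = 88
    seed: int = 17
    n_starts: int = 10
    replicates: int = 3
    sim_seed: Optional[int] = None           # defaults to seed + 1
    top_k: int = 5
    channel: int = 471
    measurements_csv: Optional[str] = None   # real data for mode=analyse
    assembly: assembly.AssemblyConfig = field(default_factory=assembly.AssemblyConfig)
    outdir: str = "pipeline_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "assembly" in raw and isinstance(raw["assembly"], dict):
            raw["assembly"] = assembly.AssemblyConfig(**raw["assembly"])
        return cls(**raw)

    @property
    def simulator_seed(self) -> int:
        return self.seed + 1 if self.sim_seed is None else self.sim_seed


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, mode: str = "all") -> dict:
    """Execute the workflow and return the artifact manifest.

    ``design`` stops after the picklist; ``simulate`` adds synthetic
    measurements and titres; ``analyse`` expects a measurements CSV;
    ``all`` is design + simulate + analysis.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "mode": mode,
        "seeds": {"design": config.seed, "simulator": config.simulator_seed},
        "stages": [],
        "artifacts": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path), "sha256": _sha256(path)
        }

    def stage(name: str):
        manifest["stages"].append(name)
        logger.info("pipeline stage: %s", name)

    try:
        # --- rank ------------------------------------------------------
        stage("rank")
        if config.parts_csv:
            library = parts.load_parts(config.parts_csv)
            library = parts.rank_parts(library, parts.PartClass.PROMOTER)
            library = parts.rank_parts(library, parts.PartClass.RBS)
        else:
            library = demo.demo_library(ranked=True)
        ranked_path = outdir / "ranked_parts.csv"
        parts.export_doe_table(library, ranked_path)
        record("ranked_parts", ranked_path)

        # --- enumerate -------------------------------------------------
        stage("enumerate")
        space = design.build_design_space(library, config.design_config)
        configs = design.enumerate_configurations(space)
        space_rows = []
        for c in configs:
            row = {"config_index": c.config_index}
            for f in space.factors:
                lev = c.assignment[f.name]
                row[f.name] = (f.value_of(lev)
                               if f.kind == "discrete_numeric" else lev)
            space_rows.append(row)
        space_path = outdir / "space.csv"
        pd.DataFrame(space_rows).to_csv(space_path, index=False)
        record("space", space_path)

        # --- select ----------------------------------------------------
        stage("select")
        model = doe.ModelSpec.main_effects(space)
        reduced = doe.select_d_optimal(
            space, model, config.n_runs, seed=config.seed,
            n_starts=config.n_starts,
        )
        dtable = doe.design_table(space, reduced)
        design_path = outdir / "design.csv"
        dtable.to_csv(design_path, index=False)
        record("design", design_path)
        meta_path = outdir / "design_meta.json"
        meta_path.write_text(json.dumps({
            "criterion": "D-optimal",
            "n_runs": reduced.n_runs,
            "candidate_count": reduced.candidate_count,
            "compression_ratio": reduced.compression_ratio,
            "log_det": reduced.log_det,
            "d_efficiency": reduced.d_efficiency,
            "seed": reduced.seed,
            "n_starts": reduced.n_starts,
        }, indent=2))
        record("design_meta", meta_path)

        # --- plan ------------------------------------------------------
        stage("plan")
        constructs = [design.configuration_to_construct(space, configs[i])
                      for i in reduced.run_indices]
        constructs = assembly.assign_stitch_ids(constructs)
        contents = sorted({e for c in constructs for e in c.all_elements})
        contents += list(config.assembly.reagents)
        layout = assembly.PlateLayout.auto(contents, plate_name="source_1")
        picklist = assembly.plan_assembly(constructs, layout, config.assembly)
        picklist_path = outdir / "picklist.csv"
        assembly.write_picklist(picklist, picklist_path)
        record("picklist", picklist_path)
        dtable = dtable.assign(stitch_id=[c.stitch_id for c in constructs])
        dtable.to_csv(design_path, index=False)
        record("design", design_path)

        if mode == "design":
            return _finish(manifest, outdir)

        # --- simulate / measure ---------------------------------------
        conc, areas = demo.demo_standard_curve_points()
        curve = quantify.fit_standard_curve(conc, areas)
        if mode in ("simulate", "all"):
            stage("simulate")
            truth = simulate.calibrated_truth(
                space, reduced, replicates=config.replicates
            )
            sim = simulate.simulate_titres(
                space, reduced, truth, config.replicates,
                seed=config.simulator_seed,
            )
            measurements = simulate.raw_measurements_from_sim(sim, curve)
            meas_path = outdir / "sim_measurements.csv"
            measurements.to_csv(meas_path, index=False)
            record("sim_measurements", meas_path)
        else:
            if not config.measurements_csv:
                raise PipelineError("quantify", "mode=analyse needs measurements_csv")
            measurements = pd.read_csv(config.measurements_csv)
        if mode == "simulate":
            return _finish(manifest, outdir)

        # --- quantify --------------------------------------------------
        stage("quantify")
        titres = quantify.quantify_table(measurements, curve, config.channel)
        titres_path = outdir / "titres.csv"
        titres.to_csv(titres_path, index=False)
        record("titres", titres_path)
        summary = quantify.screen_summary(titres)
        summary_path = outdir / "screen_summary.json"
        summary_path.write_text(json.dumps({
            "n_constructs": summary.n_constructs,
            "producers": summary.producers,
            "no_growth": summary.no_growth,
            "no_product": summary.no_product,
            "failure_rate_pct": summary.failure_rate_pct,
        }, indent=2))
        record("screen_summary", summary_path)

        # --- fit -------------------------------------------------------
        stage("fit")
        joined = dtable.merge(titres, on="stitch_id", how="inner")
        fit = effects.fit_effects(joined, space, model,
                                  response="titre_mg_per_gdcw")
        summary_table = effects.effect_summary(fit, space)
        effects_path = outdir / "effects.csv"
        summary_table.table.to_csv(effects_path, index=False)
        record("effects", effects_path)

        # --- predict ---------------------------------------------------
        stage("predict")
        predictions = effects.predict_optimum(fit, space, top_k=config.top_k)
        pred_path = outdir / "predictions.csv"
        effects.prediction_table(predictions, space).to_csv(pred_path, index=False)
        record("predictions", pred_path)
        return _finish(manifest, outdir)
    except PipelineError:
        raise
    except OperonDoeError as exc:
        current = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise PipelineError(current, str(exc)) from exc


def _finish(manifest: dict, outdir: Path) -> dict:
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    manifest["manifest_path"] = str(path)
    return manifest
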
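"""End-to-end pipeline: genotype table -> consensus -> policy -> prediction
-> calling -> report table."""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import calling, model, panel as panel_mod, simulate
from .calling import PhenotypeReport

log = logging.getLogger("evcolor")

REPORT_COLUMNS = [
    "sample_id",
    "eye_call", "eye_probability", "eye_accuracy",
    "hair_call", "hair_category_probability", "light_probability", "hair_accuracy",
    "caveats", "flags",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``model_source`` is either ``"fit"`` (fit the three prediction models on
    a synthetic reference panel generated with ``seed``) or a directory of
    coefficient files named ``eye.model``, ``hair.model``, ``shade.model``.
    """

    input_path: str | Path
    output_path: str | Path
    panel_path: str | Path | None = None
    calling_config_path: str | Path | None = None
    model_source: str | Path = "fit"
    reference_n: int = 5000
    seed: int = 1
    imputation: str = "zero"
    detection_threshold: float = panel_mod.DETECTION_THRESHOLD


def get_models(
    source: str | Path,
    panel: Sequence[panel_mod.MarkerDef],
    *,
    reference_n: int = 5000,
    seed: int = 1,
) -> dict[str, model.MLRModel]:
    """Obtain the three prediction models, either by fitting to a synthetic
    reference panel or by loading coefficient files from a directory."""
    if source == "fit":
        cfg = simulate.default_sim_config(panel, n_individuals=reference_n, seed=seed)
        ref = simulate.simulate_reference_panel(cfg, panel)
        models = {}
        for task in ("eye", "hair", "shade"):
            spec = model.default_spec(task, panel)
            models[task] = model.fit_mlr(
                ref.task_dosages(spec), ref.labels[task], spec,
                provenance=f"fitted on synthetic reference panel (n={reference_n}, seed={seed})",
            )
        return models
    source = Path(source)
    models = {}
    for task in ("eye", "hair", "shade"):
        path = source / f"{task}.model"
        if not path.exists():
            raise FileNotFoundError(f"coefficient file {path} not found")
        models[task] = model.load_model(path)
    return models


def predict_sample(
    consensus: panel_mod.ConsensusProfile,
    panel: Sequence[panel_mod.MarkerDef],
    models: dict[str, model.MLRModel],
    table: calling.HairDecisionTable,
    lookup: calling.AccuracyLookup,
    *,
    imputation: str = "zero",
) -> PhenotypeReport:
    """Policy, prediction and calling for one consensus profile."""
    decision = model.missing_marker_policy(consensus, panel)
    by_id = panel_mod.marker_map(panel)

    eye_call = None
    if decision.eye_allowed:
        dos, mask, ids = panel_mod.encode_dosage(consensus, "eye", panel)
        pv = model.predict_proba(models["eye"], dos, decision)
        eye_call = calling.call_eye(pv, lookup)

    hair_call = None
    if decision.hair_allowed:
        vectors = {}
        for task in ("hair", "shade"):
            dos, mask, ids = panel_mod.encode_dosage(consensus, task, panel)
            dos = model.resolve_dosages(
                dos, mask, strategy=imputation, panel_by_id=by_id, marker_ids=ids
            )
            vectors[task] = model.predict_proba(models[task], dos, decision)
        hair_call = calling.call_hair(vectors["hair"], vectors["shade"], table, lookup)

    return calling.build_report(
        consensus.sample_id, decision, eye_call, hair_call, flags=consensus.flags
    )


def run_pipeline(config: RunConfig) -> list[PhenotypeReport]:
    """Parse -> consensus -> policy -> predict -> call -> report.

    Reads the replicate genotype TSV, merges replicates per sample, applies
    the missing-marker policy and the prediction models, and writes the
    report table.  Logs per-sample QC flags, drop-out resolutions and
    refusals.  Parse errors propagate (the CLI maps them to a nonzero exit
    status).
    """
    pan = panel_mod.load_panel(config.panel_path)
    table, lookup, _ = calling.load_calling_config(config.calling_config_path)
    models = get_models(
        config.model_source, pan, reference_n=config.reference_n, seed=config.seed
    )

    replicates = panel_mod.read_genotype_table(config.input_path, pan)
    by_sample: dict[str, list] = defaultdict(list)
    for rep in replicates:
        by_sample[rep.sample_id].append(rep)

    reports = []
    for sid in sorted(by_sample):
        consensus = panel_mod.consensus_merge(
            by_sample[sid], pan, detection_threshold=config.detection_threshold
        )
        for flag in consensus.flags:
            log.info("%s: %s", sid, flag)
        report = predict_sample(
            consensus, pan, models, table, lookup, imputation=config.imputation
        )
        for caveat in report.caveats:
            log.info("%s: %s", sid, caveat)
        reports.append(report)

    write_report(reports, config.output_path)
    return reports


def write_report(reports: Sequence[PhenotypeReport], path: str | Path) -> None:
    """Write the report TSV (deterministic ordering by sample id); refused
    tasks render as "-"."""
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in sorted(reports, key=lambda r: r.sample_id):
            if r.eye is not None:
                eye = [r.eye.label, f"{r.eye.probability:.3f}", f"{r.eye.accuracy:g}"]
            else:
                eye = ["-", "-", "-"]
            if r.hair is not None:
                hair = [
                    r.hair.label, f"{r.hair.probability:.3f}",
                    f"{r.hair.light:.3f}", f"{r.hair.accuracy:g}",
                ]
            else:
                hair = ["-", "-", "-", "-"]
            fh.write(
                "\t".join(
                    [r.sample_id] + eye + hair
                    + ["; ".join(r.caveats) or "-", "; ".join(r.flags) or "-"]
                )
                + "\n"
            )


def read_report(path: str | Path) -> list[dict[str, str]]:
    """Read a written report back into row dictionaries (round-trip aid)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]


__all__ = [
    "RunConfig",
    "REPORT_COLUMNS",
    "get_models",
    "predict_sample",
    "run_pipeline",
    "write_report",
    "read_report",
]
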
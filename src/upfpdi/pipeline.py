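"""End-to-end analysis pipeline.

Chains the stages — reference loading, cohort filtering, recipe
disaggregation, NOVA/UPF energy share, servings and index scoring, the
misreporting covariate, and the survey-weighted statistics — and writes the
three published table shapes (descriptives by index quintile, index
regressions, component associations) plus a machine-readable run manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from pydantic import BaseModel

from . import nova as nova_mod
from . import survey as survey_mod
from .misreporting import KJ_PER_MJ, compute_misreporting
from .reference import KJ_PER_KCAL, load_reference_tables
from .scoring import INDEX_TYPES, score_population
from .survey import SurveyDesign

log = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Configuration for one pipeline run."""

    data_dir: Path
    output_dir: Path
    scheme_config: Path | None = None
    weighted_quintiles: bool = True
    transpose_regression: bool = False
    rao_scott: bool = False
    seed: int | None = None


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage name
        raise StageError(name, exc) from exc


def analyze_dataset(
    bundle,
    recall: pd.DataFrame,
    participants: pd.DataFrame,
    design: SurveyDesign,
    weighted_quintiles: bool = True,
    manifest: dict | None = None,
):
    """Data stages from in-memory inputs: filter, disaggregate, UPF share,
    scores, misreporting.  Returns (analysis table, design, scores)."""
    manifest = manifest if manifest is not None else {"stages": {}}

    participants, ledger = _stage("filter_cohort", survey_mod.filter_cohort, participants)
    manifest["stages"]["filter_cohort"] = ledger
    recall = recall[recall["participant_id"].isin(participants.index)]
    design = design.subset(participants.index)

    items = _stage("disaggregate", nova_mod.disaggregate, recall, bundle.recipes, bundle.composition)
    manifest["stages"]["disaggregate"] = {
        "n_items_in": int(len(recall)),
        "n_items_out": int(len(items)),
    }

    def upf_stage():
        classified = nova_mod.classify(items, bundle.nova)
        return nova_mod.upf_energy_share(classified)

    upf = _stage("upf_share", upf_stage).set_index("participant_id")
    manifest["stages"]["upf_share"] = {"n": int(len(upf))}

    def score_stage():
        weights = design.person_weight if weighted_quintiles else None
        return score_population(items, bundle.collapsed_apportionment(), bundle.scheme, weights)

    scores = _stage("score", score_stage)
    manifest["stages"]["score"] = {"n": int(len(scores.indices))}

    def misreport_stage():
        return compute_misreporting(participants, upf["total_energy_kj"], design.person_weight)

    ei_bmr = _stage("misreporting", misreport_stage)

    table = participants.join(upf, how="inner")
    table = table.join(scores.to_table().set_index("participant_id"), how="inner")
    table["ei_bmr_ratio"] = ei_bmr
    if "energy_kcal" not in table.columns:
        table["energy_kcal"] = table["total_energy_kj"] / KJ_PER_KCAL
    design = design.subset(table.index)
    manifest["stages"]["analysis_table"] = {"n": int(len(table))}
    return table, design, scores


def build_analysis_table(config: RunConfig) -> tuple[pd.DataFrame, SurveyDesign, dict, object]:
    """Run the data stages and return (analysis table, design, manifest, bundle)."""
    manifest: dict = {"config": json.loads(config.model_dump_json()), "stages": {}}

    bundle = _stage("load_reference", load_reference_tables, config.data_dir, config.scheme_config)
    manifest["stages"]["load_reference"] = {
        "n_foods": int(len(bundle.composition)),
        "n_recipes": int(bundle.composition["is_recipe"].sum()),
    }

    def load_recall():
        return nova_mod.validate_recall(pd.read_csv(Path(config.data_dir) / "recall.csv"))

    recall = _stage("load_recall", load_recall)

    def load_people():
        part = pd.read_csv(Path(config.data_dir) / "participants.csv").set_index("participant_id")
        wdf = pd.read_csv(Path(config.data_dir) / "weights.csv").set_index("participant_id")
        design = SurveyDesign(wdf["person_weight"], wdf.drop(columns=["person_weight"]))
        return part, design

    participants, design = _stage("load_participants", load_people)
    manifest["stages"]["load_participants"] = {"n": int(len(participants))}

    table, design, scores = analyze_dataset(
        bundle, recall, participants, design, config.weighted_quintiles, manifest
    )
    return table, design, manifest, (bundle, scores)


def run_pipeline(config: RunConfig, stages: str = "all") -> dict:
    """Execute the pipeline and write outputs; returns the manifest.

    ``stages='score'`` stops after writing the UPF-share and score tables;
    ``stages='all'`` additionally runs the survey statistics and writes the
    three result table shapes and the moderation table.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, design, manifest, (bundle, scores) = build_analysis_table(config)

    upf_out = table[["total_energy_kj", "pct_energy_upf"]].copy()
    upf_out["total_energy_kcal"] = upf_out.pop("total_energy_kj") / KJ_PER_KCAL
    upf_out.reset_index().to_csv(out / "upf_share.csv", index=False)
    scores.to_table().to_csv(out / "scores.csv", index=False)
    scores.cutpoints_to_yaml(out / "cutpoints.yaml")

    if stages == "all":
        for index_type in INDEX_TYPES:
            t1 = _stage(
                "table1",
                survey_mod.quintile_table,
                table,
                design,
                index_type,
                config.rao_scott,
            )
            t1.to_csv(out / f"table1_{index_type}.csv", index=False)
        t2 = _stage(
            "table2", survey_mod.fit_index_models, table, design, config.transpose_regression
        )
        t2.to_csv(out / "table2.csv", index=False)
        t3 = _stage("table3", survey_mod.component_associations, table, design, bundle.scheme)
        t3.to_csv(out / "table3.csv", index=False)
        mod = _stage("moderation", survey_mod.moderation_models, table, design)
        mod.to_csv(out / "moderation.csv", index=False)
        manifest["stages"]["results"] = {
            "table2_rows": int(len(t2)),
            "table3_rows": int(len(t3)),
            "moderation_rows": int(len(mod)),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    log.info("pipeline complete: outputs in %s", out)
    return manifest
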
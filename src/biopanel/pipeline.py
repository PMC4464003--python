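"""End-to-end driver: standardize -> filter -> GA search -> rank/merge ->
forward selection -> backward elimination -> APIS split -> calibrate ->
bootstrap -> random-model null.

Every stage writes its artifact into the run directory and records a
content hash in ``manifest.json``; a rerun with the same configuration
and seed reproduces all artifacts bit-for-bit.  Each stage derives its
random stream from the single global seed plus a fixed per-stage offset,
so toggling one stage never perturbs another stage's randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .data_model import (AnalysisSpec, FeatureTable, filter_missing,
                         read_feature_table, write_feature_table,
                         z_standardize)
from .ga import search
from .glm import fit_logistic
from .selection import (FeatureRanking, SelectionAudit, backward_eliminate,
                        forward_select, merge_correlated)
from .validation import (NullExperiment, SplitPlan, bootstrap_evaluate,
                         build_apis, calibrate, random_model_null)

log = logging.getLogger("biopanel")

STAGES = ("simulate", "standardize", "filter", "search", "rank", "select",
          "eliminate", "split", "calibrate", "bootstrap", "null")

# per-stage seed offsets (global seed + offset -> stage stream)
SEED_OFFSETS = {"simulate": 11, "search": 23, "select": 101, "eliminate": 202,
                "split": 307, "bootstrap": 401, "null": 503}


@dataclass
class PipelineConfig:
    """Everything one run needs: contrast spec, cohort config, paths."""

    analysis: AnalysisSpec = field(default_factory=AnalysisSpec)
    cohort: synthetic.CohortConfig | None = None
    input_csv: str | None = None
    modality_tsv: str | None = None
    outdir: str = "biopanel_run"
    stages: tuple[str, ...] = STAGES
    scaled_down: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.cohort is None and self.input_csv is None:
            raise ValueError("either a cohort config or an input CSV is needed")

    def effective_spec(self) -> AnalysisSpec:
        """Scaled-down searches trade exhaustiveness for desk-scale runtime."""
        spec = self.analysis
        if self.scaled_down:
            spec = spec.replace(
                n_ga_models=min(spec.n_ga_models, 100),
                ga_generations=min(spec.ga_generations, 50),
                n_bootstrap=min(spec.n_bootstrap, 200),
                n_random_models=min(spec.n_random_models, 200))
        return spec

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        analysis = AnalysisSpec(**raw.get("analysis", {}))
        cohort = None
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "n_per_class" in c:
                c["n_per_class"] = tuple(
                    (str(k), int(v)) for k, v in dict(c["n_per_class"]).items())
            if "planted" in c:
                c["planted"] = tuple(
                    synthetic.PlantedFeature(
                        index=int(p["index"]),
                        contrast=tuple(p["contrast"]),
                        delta=float(p["delta"]),
                        sign=int(p.get("sign", 1)))
                    for p in c["planted"])
            for key in ("missing_rates", "modality_fractions"):
                if key in c:
                    c[key] = tuple((str(k), float(v))
                                   for k, v in dict(c[key]).items())
            cohort = synthetic.CohortConfig(**c)
        return cls(analysis=analysis, cohort=cohort,
                   input_csv=raw.get("input_csv"),
                   modality_tsv=raw.get("modality_tsv"),
                   outdir=raw.get("outdir", "biopanel_run"),
                   stages=tuple(raw.get("stages", STAGES)),
                   scaled_down=bool(raw.get("scaled_down", False)))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """Mutable state threaded through the stages of one run."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.spec = config.effective_spec()
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"stages": {}, "seed": self.spec.rng_seed,
                               "scaled_down": config.scaled_down}
        self.full_table: FeatureTable | None = None
        self.truth: synthetic.GroundTruth | None = None
        self.standardized: FeatureTable | None = None
        self.contrast_table: FeatureTable | None = None
        self.selection_table: FeatureTable | None = None
        self.models = None
        self.freqs = None
        self.ranking: FeatureRanking | None = None
        self.fs_model = None
        self.final_model = None
        self.split: SplitPlan | None = None
        self.calibrated = None
        self.report = None
        self.test_report = None
        self.null: NullExperiment | None = None

    def _record(self, stage: str, elapsed: float, artifacts: list[Path],
                **info) -> None:
        self.manifest["stages"][stage] = {
            "elapsed_s": round(elapsed, 3),
            "artifacts": {p.name: _sha256(p) for p in artifacts},
            **info,
        }
        log.info("stage %-11s %6.2fs %s", stage, elapsed, info)


def run_pipeline(config: PipelineConfig) -> PipelineRun:
    """Execute the enabled stages in order; see the module docstring."""
    run = PipelineRun(config)
    spec = run.spec
    seed = spec.rng_seed
    out = run.outdir
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                if config.cohort is None:
                    continue
                cohort = dataclasses.replace(
                    config.cohort, seed=(seed + SEED_OFFSETS["simulate"]) % 2**31)
                run.full_table, run.truth = synthetic.generate_cohort(cohort)
                csv = out / "cohort.csv"
                write_feature_table(run.full_table, csv,
                                    out / "modality.tsv")
                run.truth.to_json(out / "ground_truth.json")
                run._record(stage, time.perf_counter() - t0,
                            [csv, out / "ground_truth.json"],
                            n_subjects=run.full_table.n_subjects,
                            n_features=run.full_table.n_features)
            elif stage == "standardize":
                if run.full_table is None:
                    run.full_table = read_feature_table(config.input_csv,
                                                        config.modality_tsv)
                run.standardized = z_standardize(run.full_table)
                csv = out / "standardized.csv"
                write_feature_table(run.standardized, csv)
                run._record(stage, time.perf_counter() - t0, [csv])
            elif stage == "filter":
                two = run.standardized.restrict_classes(spec.classes)
                run.contrast_table, drop_log = filter_missing(two, spec)
                csv = out / "filtered.csv"
                write_feature_table(run.contrast_table, csv)
                drop_path = out / "dropped_features.tsv"
                drop_log.to_csv(drop_path, sep="\t", index=False)
                # the most-incomplete subjects sit out of feature
                # selection; they are re-examined later as APIS
                # candidates (emulating a study whose selection cohort
                # required broad data availability)
                miss = run.contrast_table.missing_mask.mean(axis=1)
                order = sorted(run.contrast_table.subject_ids,
                               key=lambda s: (miss[s], str(s)))
                n_sel = max(4, int(round(spec.selection_missing_quantile
                                         * len(order))))
                chosen = set(order[:n_sel])
                sel_ids = [s for s in run.contrast_table.subject_ids
                           if s in chosen]
                run.selection_table = run.contrast_table.subset(
                    subjects=sel_ids)
                run._record(stage, time.perf_counter() - t0, [csv, drop_path],
                            n_features=run.contrast_table.n_features,
                            n_dropped=len(drop_log),
                            n_selection_subjects=len(sel_ids))
            elif stage == "search":
                sspec = spec.replace(
                    rng_seed=(seed + SEED_OFFSETS["search"]) % 2**31)
                run.models, run.freqs = search(run.selection_table, sspec)
                chrom = pd.DataFrame(
                    [{"run": m.run_index, "genes": ";".join(m.genes),
                      "fitness": m.fitness} for m in run.models])
                cpath = out / "chromosomes.tsv"
                chrom.to_csv(cpath, sep="\t", index=False)
                fpath = out / "frequencies.tsv"
                run.freqs.to_frame().to_csv(fpath, sep="\t")
                run._record(stage, time.perf_counter() - t0, [cpath, fpath],
                            n_models=len(run.models),
                            best_fitness=max(m.fitness for m in run.models))
            elif stage == "rank":
                run.ranking = merge_correlated(run.freqs,
                                               run.selection_table, spec)
                rpath = out / "ranking.tsv"
                run.ranking.to_frame().to_csv(rpath, sep="\t", index=False)
                run._record(stage, time.perf_counter() - t0, [rpath],
                            n_ranked=len(run.ranking.entries),
                            n_merged=len(run.ranking.merge_log))
            elif stage == "select":
                sspec = spec.replace(
                    rng_seed=(seed + SEED_OFFSETS["select"]) % 2**31)
                audit = SelectionAudit()
                run.fs_model = forward_select(run.ranking,
                                              run.selection_table, sspec,
                                              audit=audit)
                apath = out / "forward_audit.tsv"
                audit.to_frame().to_csv(apath, sep="\t", index=False)
                run._record(stage, time.perf_counter() - t0, [apath],
                            model=run.fs_model.features)
            elif stage == "eliminate":
                sspec = spec.replace(
                    rng_seed=(seed + SEED_OFFSETS["eliminate"]) % 2**31)
                audit = SelectionAudit()
                run.final_model = backward_eliminate(
                    run.fs_model, run.selection_table, sspec, audit=audit)
                apath = out / "backward_audit.tsv"
                audit.to_frame().to_csv(apath, sep="\t", index=False)
                mpath = out / "final_model.json"
                run.final_model.to_json(mpath)
                run._record(stage, time.perf_counter() - t0, [apath, mpath],
                            model=run.final_model.features)
            elif stage == "split":
                if run.final_model.size == 0:
                    log.warning("final model is intercept-only; split uses "
                                "the selection population only")
                run.split = build_apis(
                    run.standardized, run.final_model,
                    run.selection_table.subject_ids, spec,
                    seed=(seed + SEED_OFFSETS["split"]) % 2**31)
                spath = out / "split.json"
                with open(spath, "w") as fh:
                    json.dump({
                        "feature_selection": list(map(str, run.split.feature_selection_ids)),
                        "apis": list(map(str, run.split.apis_ids)),
                        "calibration": list(map(str, run.split.calibration_ids)),
                        "test": list(map(str, run.split.test_ids)),
                    }, fh, indent=1)
                run._record(stage, time.perf_counter() - t0, [spath],
                            n_calibration=len(run.split.calibration_ids),
                            n_test=len(run.split.test_ids))
            elif stage == "calibrate":
                cal_table = run.standardized.subset(
                    subjects=run.split.calibration_ids)
                run.calibrated = calibrate(run.final_model.features, cal_table,
                                           spec, reference=run.final_model)
                mpath = out / "calibrated_model.json"
                run.calibrated.to_json(mpath)
                run._record(stage, time.perf_counter() - t0, [mpath])
            elif stage == "bootstrap":
                cal_table = run.standardized.subset(
                    subjects=run.split.calibration_ids)
                run.report = bootstrap_evaluate(
                    run.calibrated, cal_table, spec,
                    seed=(seed + SEED_OFFSETS["bootstrap"]) % 2**31)
                jpath = out / "calibration_report.json"
                run.report.to_json(jpath)
                run.report.roc_to_csv(out / "calibration_roc.csv")
                arts = [jpath, out / "calibration_roc.csv"]
                if run.split.test_ids:
                    test_table = run.standardized.subset(
                        subjects=run.split.test_ids)
                    from .data_model import complete_case_subset
                    test_cc = complete_case_subset(
                        test_table, run.calibrated.features, min_per_class=1)
                    probs = run.calibrated.predict_prob(test_cc)
                    from .glm import classification_metrics
                    run.test_report = classification_metrics(
                        probs.to_numpy(),
                        test_cc.binary_labels(spec).to_numpy(),
                        spec.classification_threshold)
                    tpath = out / "test_report.json"
                    run.test_report.to_json(tpath)
                    run.test_report.roc_to_csv(out / "test_roc.csv")
                    arts += [tpath, out / "test_roc.csv"]
                run._record(stage, time.perf_counter() - t0, arts)
            elif stage == "null":
                cal_table = run.standardized.subset(
                    subjects=run.split.calibration_ids)
                run.null = random_model_null(
                    run.calibrated, run.report, cal_table,
                    run.contrast_table.feature_names, spec,
                    seed=(seed + SEED_OFFSETS["null"]) % 2**31,
                    n_bootstrap=min(spec.n_bootstrap, 200)
                    if config.scaled_down else None)
                dpath = out / "null_densities.csv"
                run.null.densities().to_csv(dpath, index=False)
                npath = out / "null_summary.json"
                with open(npath, "w") as fh:
                    json.dump({
                        "prob_outperform_accuracy":
                            run.null.prob_outperform_accuracy,
                        "prob_outperform_auc": run.null.prob_outperform_auc,
                        "band_accuracy": run.null.band_accuracy,
                        "band_auc": run.null.band_auc,
                        "proposed_accuracy": run.null.proposed_accuracy,
                        "proposed_auc": run.null.proposed_auc,
                    }, fh, indent=1)
                run._record(stage, time.perf_counter() - t0, [dpath, npath])
        except Exception as exc:
            record = {"stage": stage, "error": type(exc).__name__,
                      "message": str(exc)}
            with open(out / "error.json", "w") as fh:
                json.dump(record, fh, indent=1)
            raise RuntimeError(f"pipeline halted at stage {stage!r}: {exc}") \
                from exc
    with open(out / "manifest.json", "w") as fh:
        json.dump(run.manifest, fh, indent=1, sort_keys=True)
    return run
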
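"""End-to-end experiment orchestration.

``run_experiment`` wires the stages together: simulate cohorts -> select
features per modality -> repeated-holdout evaluation per modality ->
train final per-modality models -> equal-weight ensemble evaluation on a
held-out ensemble cohort -> external-cohort evaluation.  Every artifact
(metrics, ROC curves, selection audits, manifest) is written to the
output directory and is regenerable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import EvalConfig, SvmConfig, repeated_holdout_evaluation, \
    train_modality_model, predict_probability, predict_label, \
    confusion_metrics, roc_and_auc
from .cohort import CohortConfig, ModalitySpec, generate_external_cohort, \
    generate_multimodal_cohort
from .ensemble import EnsembleWeights, enumerate_combinations, evaluate_combination
from .errors import ConfigError, StageError
from .io import combination_report_frame, write_json, write_metrics_csv, \
    write_roc_csv
from .selection import SelectionConfig, select_features

log = logging.getLogger("roifuse")

__all__ = ["ExperimentConfig", "run_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete description of one experiment run.

    ``selection_overrides`` maps a modality name to a SelectionConfig that
    replaces the shared default for that modality.  The master ``seed``
    deterministically derives every stage seed.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    selection_overrides: dict = field(default_factory=dict)
    svm: SvmConfig = field(default_factory=SvmConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    weight_scheme: str = "equal"
    seed: int = 0

    def __post_init__(self):
        if self.weight_scheme != "equal":
            raise ConfigError("ExperimentConfig.weight_scheme must be 'equal'")
        for name in self.selection_overrides:
            if name not in [m.name for m in self.cohort.modalities]:
                raise ConfigError(
                    f"ExperimentConfig.selection_overrides names unknown modality {name!r}")

    def selection_for(self, modality: str) -> SelectionConfig:
        return self.selection_overrides.get(modality, self.selection)

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "selection": self.selection.to_dict(),
            "selection_overrides": {k: v.to_dict()
                                    for k, v in self.selection_overrides.items()},
            "svm": self.svm.to_dict(),
            "eval": self.eval.to_dict(),
            "weight_scheme": self.weight_scheme,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        cohort = dict(data.get("cohort", {}))
        if "modalities" in cohort:
            cohort["modalities"] = tuple(ModalitySpec(**m) for m in cohort["modalities"])
        overrides = {k: SelectionConfig(**v)
                     for k, v in data.get("selection_overrides", {}).items()}
        eval_cfg = dict(data.get("eval", {}))
        if "fpr_grid" in eval_cfg:
            eval_cfg["fpr_grid"] = tuple(eval_cfg["fpr_grid"])
        return cls(
            cohort=CohortConfig(**cohort),
            selection=SelectionConfig(**data.get("selection", {})),
            selection_overrides=overrides,
            svm=SvmConfig(**data.get("svm", {})),
            eval=EvalConfig(**eval_cfg),
            weight_scheme=data.get("weight_scheme", "equal"),
            seed=int(data.get("seed", 0)),
        )


def _derive_seeds(master: int, modalities) -> dict:
    """Named per-stage seeds from the master seed (all below 2**31)."""
    rng = np.random.default_rng(np.random.SeedSequence(master))
    names = ["training_cohort", "ensemble_cohort"]
    names += [f"selection_{m}" for m in modalities]
    names += [f"eval_{m}" for m in modalities]
    names += ["svm"]
    return {n: int(rng.integers(0, 2**31)) for n in names}


def _stage(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(name, exc) from exc
    log.info("stage %-22s %8.2f s", name, time.perf_counter() - t0)
    return out


def run_experiment(config: ExperimentConfig, out_dir) -> dict:
    """Run the full pipeline and write the report bundle to ``out_dir``.

    Returns a summary dict mirroring the written artifacts.  Two runs
    with the same config and seed produce byte-identical metric files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    modalities = [m.name for m in config.cohort.modalities]
    seeds = _derive_seeds(config.seed, modalities)
    for stage, s in sorted(seeds.items()):
        log.info("derived seed %-22s %d", stage, s)

    manifest = {
        "package": "roifuse",
        "version": __version__,
        "config": config.to_dict(),
        "master_seed": config.seed,
        "derived_seeds": seeds,
    }
    write_json(manifest, out / "manifest.json")

    train_cfg = dataclasses.replace(config.cohort, seed=seeds["training_cohort"])
    ens_cfg = dataclasses.replace(config.cohort, seed=seeds["ensemble_cohort"])
    training = _stage("simulate_training", generate_multimodal_cohort, train_cfg)
    ensemble_cohort = _stage("simulate_ensemble", generate_multimodal_cohort, ens_cfg)
    external = _stage("simulate_external", generate_external_cohort, train_cfg)

    summary: dict = {"modalities": {}, "seeds": seeds}
    models = {}
    for m in modalities:
        sel_cfg = dataclasses.replace(config.selection_for(m),
                                      seed=seeds[f"selection_{m}"])
        sel = _stage(f"select_{m}", select_features, training[m], sel_cfg)
        write_json(sel.to_dict(), out / f"selection_{m}.json")

        ev_cfg = dataclasses.replace(config.eval, seed=seeds[f"eval_{m}"])
        svm_cfg = dataclasses.replace(config.svm, seed=seeds["svm"])
        agg, _ = _stage(f"evaluate_{m}", repeated_holdout_evaluation,
                        training[m], sel.selected, svm_cfg, ev_cfg)
        write_json(agg.to_dict(), out / f"metrics_{m}.json")
        write_metrics_csv(agg, out / f"metrics_{m}.csv")
        write_roc_csv(agg, out / f"roc_{m}.csv")

        models[m] = _stage(f"train_final_{m}", train_modality_model,
                           training[m], sel.selected, svm_cfg)
        summary["modalities"][m] = {
            "selected": list(sel.selected),
            "n_removed": len(sel.removed),
            "holdout": agg.to_dict(),
        }

    if len(modalities) >= 2:
        singles, combos = _stage("ensemble", enumerate_combinations,
                                 models, ensemble_cohort)
        frame = combination_report_frame(
            singles, combos)
        frame.to_csv(out / "ensemble_report.csv", index=False)
        write_json({r["modalities"]: r for r in frame.to_dict("records")},
                   out / "ensemble_report.json")
        summary["ensemble"] = frame.to_dict("records")

        ext_singles, ext_combos = _stage("external", enumerate_combinations,
                                         models, external)
        ext_frame = combination_report_frame(ext_singles, ext_combos)
        ext_frame.to_csv(out / "external_report.csv", index=False)
        write_json({r["modalities"]: r for r in ext_frame.to_dict("records")},
                   out / "external_report.json")
        summary["external"] = ext_frame.to_dict("records")
    else:
        log.info("single modality configured; ensemble stage skipped")
        m = modalities[0]
        res = _stage("external", evaluate_combination, models, external,
                     EnsembleWeights((m,), (1.0,)))
        write_json({m: {**res.metrics, "auc": res.auc,
                        "n_subjects": len(res.subject_ids)}},
                   out / "external_report.json")
        summary["external"] = [{**res.metrics, "auc": res.auc, "modalities": m}]

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n")
    return summary
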
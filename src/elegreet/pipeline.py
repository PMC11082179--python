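"""End-to-end orchestration: load/simulate -> filter -> analyse -> report.

A single :class:`PipelineConfig` (usually read from YAML) names either real
input tables or synthetic-generation parameters, plus the knobs of every
stage.  :func:`run_all` executes the stages in analysis order — validation,
case exclusions, repertoire, gesture classification, modality deviation,
bigram extraction, the two collocation analyses, and the mixed models —
persisting every stage's outputs under the output directory and recording
counts at each filter in a machine-readable manifest.  One config seed
drives derived per-stage substreams, so a rerun of the same config is
reproducible file-for-file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .records import to_frame, validate_records
from .io import apply_exclusions, load_signals, write_signals
from .repertoire import build_repertoire, cumulative_curve, AcuityModel, olfactory_summary
from .gestures import (
    classify_gestures,
    verdicts_to_frame,
    modality_deviation,
    attention_shares,
    tail_assessment,
)
from .collocation import extract_bigrams, mdca, collocation_report
from .sociality import nn_matrix
from .models import (
    ModelSpec,
    fit_binomial_glmm,
    fit_multinomial_attention,
    build_combination_frame,
    combination_spec,
    reduced_spec,
    lrt,
    vif,
    marginal_r2,
)
from .simulate import SimulationParams, generate_signals, generate_scans, write_truth

log = logging.getLogger("elegreet")

TAIL_TYPES = ("Tail-on-Side", "Tail-Raise", "Tail-Stiff", "Tail-Waggling")


@dataclass
class PipelineConfig:
    """Everything one analysis run needs; either real paths or synthetic."""

    signals_path: str | None = None
    signals_dialect: str = "csv"
    scans_path: str | None = None
    synthetic: dict | None = None
    max_distance_m: float = 100.0
    require_awareness: bool = True
    chance_p: float = 0.5
    alpha: float = 0.05
    mdca_mode: str = "both"  # ordered | all | both
    n_permutations: int = 100
    run_models: bool = True
    n_boot: int = 0
    run_stability: bool = False
    out_dir: str = "elegreet_out"
    seed: int = 0

    def __post_init__(self):
        if self.signals_path is None and self.synthetic is None:
            raise ValueError("config needs signals_path or synthetic parameters")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sim_params(config: PipelineConfig) -> SimulationParams:
    kwargs = dict(config.synthetic or {})
    kwargs.setdefault("seed", config.seed)
    return SimulationParams(**kwargs)


def run_all(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report dict (also written as JSON).

    A stage failure raises :class:`StageError` naming the stage; outputs of
    completed stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"counts": {}, "warnings": []}
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
    }
    stage = "load"
    try:
        scans = None
        truth = None
        if config.synthetic is not None:
            params = _sim_params(config)
            records, truth = generate_signals(params)
            scans = generate_scans(params)
            sexes = dict(params.individuals)
            write_signals(records, out / "signals.csv")
            scans.to_csv(out / "scans.csv", index=False)
            write_truth(truth, out / "truth.json")
        else:
            records = load_signals(config.signals_path, config.signals_dialect)
            sexes = None
            if config.scans_path:
                scans = pd.read_csv(config.scans_path)
        report["counts"]["loaded"] = len(records)

        stage = "validate"
        records = validate_records(records)

        stage = "exclusions"
        retained, excl = apply_exclusions(
            records,
            max_distance_m=config.max_distance_m,
            require_awareness=config.require_awareness,
        )
        excl.to_json(out / "exclusions.json")
        report["counts"]["retained"] = len(retained)
        report["counts"]["excluded"] = excl.by_reason
        write_signals(retained, out / "signals_retained.csv")

        stage = "repertoire"
        rep = build_repertoire(retained)
        rep.to_csv(out / "repertoire.csv", index=False)
        curve = cumulative_curve(
            retained, n_permutations=config.n_permutations, seed=config.seed + 10
        )
        curve.to_csv(out / "cumulative_curve.csv", index=False)
        acuity = AcuityModel()
        report["repertoire"] = {
            "n_types": int(len(rep)),
            "n_included": int(rep["included"].sum()) if len(rep) else 0,
            "detection_distance_2_5m_object": acuity.reported_distance(2.5),
            "detection_distance_1m_object": acuity.reported_distance(1.0),
        }
        if truth is not None:
            from .records import EventRecord

            events = [EventRecord(**e) for e in truth["events"]]
            report["repertoire"]["olfactory_summary"] = olfactory_summary(events)

        stage = "gestures"
        verdicts = classify_gestures(
            retained, chance_p=config.chance_p, alpha=config.alpha
        )
        vframe = verdicts_to_frame(verdicts)
        vframe.to_csv(out / "gesture_verdicts.csv", index=False)
        shares = attention_shares(retained)
        shares.to_csv(out / "attention_shares.csv", index=False)
        deviation = modality_deviation(
            retained, modalities=("silent_visual", "audible", "tactile")
        )
        deviation.to_csv(out / "modality_deviation.csv", index=False)
        report["gestures"] = {
            "n_gesture_types": int((vframe["verdict"] == "gesture").sum()),
            "n_not_gesture": int((vframe["verdict"] == "not_gesture").sum()),
            "n_insufficient": int((vframe["verdict"] == "insufficient_data").sum()),
        }
        report["modality_shares_attending"] = {
            row.modality: round(100.0 * row.share_attending)
            for row in shares.itertuples()
            if row.modality in ("silent_visual", "audible", "tactile")
        }
        df_ret = to_frame(retained)
        report["counts"]["modality_analysis_cases"] = int(
            (
                (df_ret["category"] == "body_act")
                & df_ret["recipient_attending"].isin(("yes", "no"))
                & df_ret["modality"].isin(("silent_visual", "audible", "tactile"))
            ).sum()
        )
        if df_ret["signal_type"].isin(TAIL_TYPES).any():
            tails = tail_assessment(retained, TAIL_TYPES)
            tails["deviation"].to_csv(out / "tail_deviation.csv", index=False)
            tails["distance_profile"].to_csv(
                out / "tail_distance_profile.csv", index=False
            )
            report["counts"]["tail_assessment_cases"] = tails["n_cases"]

        stage = "collocation"
        results = {}
        bigrams_ordered = extract_bigrams(retained, "ordered_first_overlap")
        bigrams_all = extract_bigrams(retained, "all_cooccurring")
        report["counts"]["bigrams_ordered"] = int(len(bigrams_ordered))
        report["counts"]["bigrams_all"] = int(len(bigrams_all))
        if len(bigrams_ordered) == 0:
            report["warnings"].append("no overlapping signals: MDCA empty")
        else:
            if config.mdca_mode in ("ordered", "both"):
                results["ordered"] = mdca(bigrams_ordered)
                results["ordered"].to_csv(out / "mdca1_ordered.csv", index=False)
            if config.mdca_mode in ("all", "both"):
                results["all"] = mdca(bigrams_all)
                results["all"].to_csv(out / "mdca2_all.csv", index=False)
            if len(results) == 2:
                collocation_report(results["ordered"], results["all"]).to_csv(
                    out / "mdca_report.csv", index=False
                )
            bigrams_ordered.to_csv(out / "bigrams_ordered.csv", index=False)
            bigrams_all.to_csv(out / "bigrams_all.csv", index=False)

        stage = "models"
        if config.run_models:
            models_report = {}
            mfit = fit_multinomial_attention(retained)
            models_report["modality_attention"] = _fit_payload(mfit)
            mfit.summary().to_csv(out / "model_modality_attention.csv")
            if len(bigrams_ordered) > 0 and sexes is not None and scans is not None:
                nn = nn_matrix(scans)
                frame = build_combination_frame(
                    bigrams_ordered, retained, sexes, nn
                )
                for label, response in (
                    ("order", "vocal_first"),
                    ("rumble_earflap", "is_rumble_earflap"),
                ):
                    if frame[response].nunique() < 2:
                        report["warnings"].append(
                            f"combination model {label!r} skipped: "
                            "constant response"
                        )
                        continue
                    spec = combination_spec(response)
                    fit = fit_binomial_glmm(frame, spec)
                    red = fit_binomial_glmm(
                        frame, reduced_spec(spec, spec.fixed)
                    )
                    chi2, dfree, p = lrt(fit, red)
                    payload = _fit_payload(fit)
                    payload["lrt"] = {"chi2": chi2, "df": dfree, "p": p}
                    payload["vif"] = vif(frame, spec.fixed).to_dict()
                    payload["marginal_r2"] = marginal_r2(fit)
                    models_report[label] = payload
                    fit.summary().to_csv(out / f"model_{label}.csv")
            elif len(bigrams_ordered) == 0:
                report["warnings"].append(
                    "combination models skipped: no bigrams"
                )
            report["models"] = models_report
    except Exception as err:  # noqa: BLE001 - re-raised with stage context
        (out / "report.json").write_text(
            json.dumps({"failed_stage": stage, **report}, indent=2, default=str)
        )
        raise StageError(stage, err) from err

    report["manifest"] = manifest
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.info("pipeline complete: %s", out / "report.json")
    return report


def _fit_payload(fit) -> dict:
    return {
        "estimates": fit.params.round(6).to_dict(),
        "se": fit.se.round(6).to_dict(),
        "method": fit.method,
        "converged": fit.converged,
        "notes": list(fit.notes),
        "loglik": fit.loglik,
    }
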
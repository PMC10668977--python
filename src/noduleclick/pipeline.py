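"""End-to-end orchestration: segmentation → features → invasiveness call.

`run_recognition` drives a batch of clicked CT cases through the
segment-with-fallback path, radiomics extraction, and (optionally) a fitted
ensemble classifier, collecting per-case provenance and metrics into an
`EvaluationReport`.  `run_cross_validation` is the stratified k-fold harness
for the classifier on a labelled feature table (five folds by default, the
standard evaluation at 160:30 imbalance — plain random folds could easily go
single-class in the minority).

Reports are plain dicts serialisable to JSON, and every summary metric is
recomputable from the stored per-case records.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .beed import BeedClassifier, confusion_metrics, mask_metrics, train_beed
from .calibration import ThresholdCalibration
from .candidate_fusion import segment_with_fallback
from .ct_io import BinaryMask, CTSlice, HUImage, to_hounsfield
from .radiomics import extract_features
from .tm_segmentation import ClickSeed


@dataclass
class RunConfig:
    """Knobs of an end-to-end run; the seed is echoed into every report."""

    alpha: float = 2.0
    base_kind: str = "RF"
    feature_method: str | None = None
    k: int | None = None
    criterion: float = 0.5
    folds: int = 5
    seed: int = 0
    fallback: str = "multialpha"  # or "none"
    output_dir: str | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass(frozen=True)
class Case:
    """One clicked CT case; truth mask and label are optional ground truth."""

    hu: HUImage
    lung: BinaryMask
    seed: ClickSeed
    truth: BinaryMask | None = None
    label: int | None = None
    case_id: str = ""


def case_from_phantom(ct: CTSlice, lung: BinaryMask, truth: BinaryMask,
                      seed: ClickSeed, label: int | None = None,
                      case_id: str = "") -> Case:
    return Case(to_hounsfield(ct), lung, seed, truth, label, case_id)


def run_recognition(
    cases: Sequence[Case],
    calib: ThresholdCalibration | None = None,
    model: BeedClassifier | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Segment, featurise and classify a batch of cases.

    Per-case failures are recorded in the report and the run continues.
    Returns the report dict (also written to ``config.output_dir`` if set).
    """
    config = config or RunConfig()
    if calib is None:
        calib = ThresholdCalibration.default(alpha=config.alpha)
    records = []
    for i, case in enumerate(cases):
        rec: dict = {"case_id": case.case_id or f"case{i}"}
        try:
            from .candidate_fusion import CandidateSet

            provider = None if config.fallback == "multialpha" else (
                lambda hu, s: CandidateSet([]))
            result = segment_with_fallback(case.hu, case.lung, case.seed, calib,
                                           provider=provider)
            rec["provenance"] = result.provenance.value
            rec["threshold"] = result.threshold_used
            rec["is_null"] = result.is_null
            rec["mask_area"] = result.mask.area
            if case.truth is not None and not result.is_null:
                seg = mask_metrics(result.mask, case.truth)
                rec["segmentation"] = {k: seg.as_dict()[k]
                                       for k in ("dice", "precision", "recall", "f_measure")}
            if model is not None and not result.is_null:
                feats = extract_features(case.hu, result.mask)
                row = pd.DataFrame([feats])
                rec["predicted_label"] = int(model.predict(row)[0])
                rec["score"] = float(model.decision_function(row)[0])
                if case.label is not None:
                    rec["true_label"] = int(case.label)
        except Exception as exc:  # noqa: BLE001 - per-case isolation is the contract
            rec["error"] = f"{type(exc).__name__}: {exc}"
            rec["traceback"] = traceback.format_exc(limit=3)
        records.append(rec)

    report = {
        "config": config.as_dict(),
        "n_cases": len(records),
        "n_fallback": sum(r.get("provenance") == "FALLBACK" for r in records),
        "n_errors": sum("error" in r for r in records),
        "cases": records,
    }
    dices = [r["segmentation"]["dice"] for r in records if "segmentation" in r]
    if dices:
        report["mean_dice"] = float(np.mean(dices))
    labelled = [r for r in records if "true_label" in r and "predicted_label" in r]
    if labelled:
        met = confusion_metrics([r["true_label"] for r in labelled],
                                [r["predicted_label"] for r in labelled],
                                scores=[r["score"] for r in labelled]
                                if len({r["true_label"] for r in labelled}) == 2 else None)
        report["classification"] = met.as_dict()
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "recognition_report.json").write_text(json.dumps(report, indent=2))
    return report


def run_cross_validation(
    table: pd.DataFrame,
    folds: int = 5,
    config: RunConfig | None = None,
    label_col: str = "label",
) -> dict:
    """Stratified k-fold evaluation of the ensemble classifier on a table."""
    config = config or RunConfig(folds=folds)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = table[label_col].to_numpy().astype(int)
    if min(np.bincount(y)) < folds:
        raise ValueError("each class needs at least one sample per fold")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    per_fold = []
    pooled_true, pooled_pred, pooled_score = [], [], []
    for f, (tr, te) in enumerate(skf.split(table.drop(columns=[label_col]), y)):
        model = train_beed(table.iloc[tr], base_kind=config.base_kind,
                           feature_method=config.feature_method, k=config.k,
                           seed=config.seed, criterion=config.criterion,
                           label_col=label_col)
        Xte = table.iloc[te].drop(columns=[label_col])
        pred = model.predict(Xte)
        score = model.decision_function(Xte)
        met = confusion_metrics(y[te], pred,
                                scores=score if len(np.unique(y[te])) == 2 else None)
        per_fold.append({"fold": f, "n_test": len(te), **met.as_dict()})
        pooled_true.extend(y[te])
        pooled_pred.extend(pred)
        pooled_score.extend(score)
    pooled = confusion_metrics(pooled_true, pooled_pred, scores=pooled_score)
    report = {
        "config": config.as_dict(),
        "folds": per_fold,
        "pooled": pooled.as_dict(),
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "cv_report.json").write_text(json.dumps(report, indent=2))
    return report
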
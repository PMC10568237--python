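"""End-to-end evaluation protocols on cohorts of rhythm blocks.

Two experiments mirror how the detectors are used:

- DSP: the spike threshold is fixed at 50 ms; the decision threshold on the
  mean abnormal-change ratio is a free parameter chosen by experiment, so
  the protocol first calibrates it (Youden-optimal sweep) on a disjoint
  labelled calibration cohort, then classifies the evaluation cohort.
- ML: a subject-wise split, frame-level training, frame predictions on the
  held-out subjects and a per-block majority vote.

Both return confusion counts at the levels the statistics are reported on.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import config as _cfg
from .dsp_detector import calibrate_decision_threshold, classify_dsp
from .hrv_features import extract_dataset
from .metrics import ConfusionCounts
from .ml_classifier import (
    FittedModel,
    SplitPlan,
    check_no_leakage,
    make_split,
    predict_frames,
    train,
    vote,
)
from .signal_io import Rhythm, RhythmBlock
from .synthetic import make_cohort


def cohort_mean_ratios(
    blocks: list[RhythmBlock], cfg: _cfg.PipelineConfig
) -> pd.DataFrame:
    """Mean abnormal-change ratio and truth label per classifiable block."""
    rows = []
    for block in blocks:
        decision = classify_dsp(block.recording, cfg)
        if decision.unclassifiable:
            continue
        rows.append(
            {
                "block_id": block.recording.record_id,
                "subject_id": block.recording.subject_id,
                "label": block.label.value,
                "mean_ratio": decision.mean_ratio,
            }
        )
    return pd.DataFrame(rows)


def calibrate_dsp_on_cohort(
    n_subjects: int,
    seed: int,
    cfg: _cfg.PipelineConfig = _cfg.PipelineConfig(),
    prevalence: float = 0.5,
) -> float:
    """Youden-optimal decision threshold from a synthetic labelled cohort."""
    blocks, _ = make_cohort(n_subjects, prevalence, seed)
    ratios = cohort_mean_ratios(blocks, cfg)
    threshold, _ = calibrate_decision_threshold(
        ratios["mean_ratio"].to_numpy(),
        (ratios["label"] == Rhythm.AFIB.value).to_numpy(),
    )
    return threshold


@dataclass
class DSPExperiment:
    decisions: pd.DataFrame
    counts: ConfusionCounts
    decision_threshold: float
    n_unclassifiable: int


def run_dsp_experiment(
    blocks: list[RhythmBlock],
    cfg: _cfg.PipelineConfig = _cfg.PipelineConfig(),
    decision_threshold: float | None = None,
) -> DSPExperiment:
    """Classify every block with the spike-ratio method and score it.

    ``decision_threshold`` overrides the config default (e.g. a calibrated
    value); unclassifiable blocks are excluded from the counts and tallied.
    """
    threshold = cfg.decision_threshold if decision_threshold is None else decision_threshold
    ratios = cohort_mean_ratios(blocks, cfg)
    pred = np.where(
        ratios["mean_ratio"] > threshold, Rhythm.AFIB.value, Rhythm.NSR.value
    )
    decisions = ratios.assign(predicted=pred)
    counts = ConfusionCounts.from_labels(decisions["label"], decisions["predicted"])
    return DSPExperiment(
        decisions=decisions,
        counts=counts,
        decision_threshold=threshold,
        n_unclassifiable=len(blocks) - len(ratios),
    )


@dataclass
class MLExperiment:
    plan: SplitPlan
    model: FittedModel
    frame_predictions: pd.DataFrame
    vote_predictions: pd.DataFrame
    frame_counts: ConfusionCounts
    vote_counts: ConfusionCounts
    leakage_violations: int


def run_ml_experiment(
    blocks: list[RhythmBlock],
    cfg: _cfg.PipelineConfig = _cfg.PipelineConfig(),
    model: str = "rf",
    seed: int = 0,
    rows: pd.DataFrame | None = None,
) -> MLExperiment:
    """Subject-wise train/test of one classifier plus vote aggregation.

    ``rows`` may carry a pre-extracted feature table to avoid recomputing
    it when several models are compared on the same cohort.
    """
    if rows is None:
        rows = extract_dataset(blocks, cfg)
    plan = make_split(rows, cfg.split_fraction, seed)
    fitted = train(rows, plan, model, cfg, seed)
    test_rows = rows[rows["subject_id"].isin(plan.test_subjects)]
    preds = predict_frames(fitted, test_rows)
    votes = vote(preds)
    return MLExperiment(
        plan=plan,
        model=fitted,
        frame_predictions=preds,
        vote_predictions=votes,
        frame_counts=ConfusionCounts.from_labels(preds["label"], preds["predicted"]),
        vote_counts=ConfusionCounts.from_labels(votes["label"], votes["predicted"]),
        leakage_violations=check_no_leakage(rows, plan),
    )
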
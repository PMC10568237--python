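"""Frame-level rhythm classifiers on HRV features, with subject-wise splits
and sample-level vote aggregation.

Splitting is always by subject: a person contributes frames to exactly one
side, so 60% of subjects generally is not 60% of the rows. Frame
predictions on a block are combined by majority vote; an exact tie is
called AFIB (screening favours sensitivity; configurable).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import config as _cfg
from .hrv_features import FEATURE_COLUMNS
from .signal_io import Rhythm

_PERSIST_VERSION = 1

MODEL_NAMES = ("rf", "svm", "knn")


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint subject-wise train/test partition."""

    train_subjects: frozenset
    test_subjects: frozenset
    fraction: float

    def __post_init__(self):
        if self.train_subjects & self.test_subjects:
            raise ValueError("train and test subjects overlap")


@dataclass
class FittedModel:
    estimator: object
    model_name: str
    feature_order: tuple[str, ...]
    seed: int
    config_hash: str = ""


def make_split(rows: pd.DataFrame, fraction: float = _cfg.DEFAULT_SPLIT_FRACTION,
               seed: int = 0) -> SplitPlan:
    """Deterministic subject-wise split; ``fraction`` of subjects train."""
    subjects = sorted(rows["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for a subject-wise split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(subjects))
    n_train = int(round(fraction * len(subjects)))
    n_train = min(max(n_train, 1), len(subjects) - 1)
    train = frozenset(subjects[i] for i in perm[:n_train])
    test = frozenset(subjects[i] for i in perm[n_train:])
    return SplitPlan(train, test, fraction)


def check_no_leakage(rows: pd.DataFrame, plan: SplitPlan) -> int:
    """Number of subjects with rows on both sides of the split (must be 0)."""
    in_train = set(rows.loc[rows["subject_id"].isin(plan.train_subjects), "subject_id"])
    in_test = set(rows.loc[rows["subject_id"].isin(plan.test_subjects), "subject_id"])
    return len(in_train & in_test)


def _build_estimator(model: str, cfg: _cfg.PipelineConfig, seed: int):
    if model == "rf":
        return RandomForestClassifier(
            n_estimators=cfg.rf_n_estimators,
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        )
    if model == "svm":
        # calibrated wrapper supplies predict_proba for the vote scores
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", CalibratedClassifierCV(
                    SVC(C=cfg.svm_c, gamma="scale", random_state=seed),
                    ensemble=False,
                )),
            ]
        )
    if model == "knn":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("knn", KNeighborsClassifier(n_neighbors=cfg.knn_k)),
            ]
        )
    raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")


def train(
    rows: pd.DataFrame,
    plan: SplitPlan,
    model: str = "rf",
    cfg: _cfg.PipelineConfig = _cfg.PipelineConfig(),
    seed: int = 0,
) -> FittedModel:
    """Fit a classifier on the training subjects' rows.

    Any scaling is fitted inside the estimator pipeline on training rows
    only. Raises on an empty or single-class training set.
    """
    tr = rows[rows["subject_id"].isin(plan.train_subjects)]
    if tr.empty:
        raise ValueError("empty training set")
    y = (tr["label"] == Rhythm.AFIB.value).to_numpy()
    if y.all() or not y.any():
        raise ValueError("training set must contain both classes")
    X = tr[FEATURE_COLUMNS].to_numpy(dtype=float)
    est = _build_estimator(model, cfg, seed)
    est.fit(X, y)
    return FittedModel(est, model, tuple(FEATURE_COLUMNS), seed, cfg.config_hash())


def predict_frames(model: FittedModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Per-frame predictions: one row per input row, deterministic.

    Returns a frame with ``predicted`` (NSR/AFIB) and ``score`` (positive-
    class probability) plus the identifying columns carried through.
    """
    missing = [c for c in model.feature_order if c not in rows.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    if rows.empty:
        return pd.DataFrame(
            columns=["subject_id", "block_id", "frame_start_s", "predicted", "score"]
        )
    X = rows[list(model.feature_order)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature rows contain non-finite values")
    prob = model.estimator.predict_proba(X)[:, list(model.estimator.classes_).index(True)]
    hard = model.estimator.predict(X)  # estimator's own tie handling
    pred = np.where(hard, Rhythm.AFIB.value, Rhythm.NSR.value)
    out = rows[[c for c in ("subject_id", "block_id", "frame_start_s", "label")
                if c in rows.columns]].copy()
    out["predicted"] = pred
    out["score"] = prob
    return out


def vote(preds: pd.DataFrame, tie_afib: bool = True) -> pd.DataFrame:
    """Majority vote per block over frame predictions.

    A block is AFIB when more than half its frames are AFIB; an exact tie
    goes to AFIB when ``tie_afib`` (the default).
    """
    if preds.empty:
        raise ValueError("no frame predictions to vote on")
    rows = []
    for block_id, grp in preds.groupby("block_id", sort=True):
        n = len(grp)
        n_afib = int((grp["predicted"] == Rhythm.AFIB.value).sum())
        if 2 * n_afib > n:
            label = Rhythm.AFIB.value
        elif 2 * n_afib == n:
            label = Rhythm.AFIB.value if tie_afib else Rhythm.NSR.value
        else:
            label = Rhythm.NSR.value
        row = {
            "block_id": block_id,
            "predicted": label,
            "n_frames": n,
            "n_afib_frames": n_afib,
        }
        for carry in ("subject_id", "label"):
            if carry in grp.columns:
                row[carry] = grp[carry].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def save_model(model: FittedModel, path: str | Path) -> None:
    joblib.dump(
        {
            "format_version": _PERSIST_VERSION,
            "model_name": model.model_name,
            "feature_order": list(model.feature_order),
            "seed": model.seed,
            "config_hash": model.config_hash,
            "estimator": model.estimator,
        },
        path,
    )


def load_model(path: str | Path) -> FittedModel:
    blob = joblib.load(path)
    if blob.get("format_version") != _PERSIST_VERSION:
        raise ValueError("unsupported model archive version")
    return FittedModel(
        estimator=blob["estimator"],
        model_name=blob["model_name"],
        feature_order=tuple(blob["feature_order"]),
        seed=blob["seed"],
        config_hash=blob.get("config_hash", ""),
    )
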
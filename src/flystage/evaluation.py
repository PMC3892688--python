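"""Accuracy criteria and cross-validation harness for stage annotation.

Three nested criteria score a predicted annotation against a manual one:

* sub-stage accuracy (``acc_substage``): stage *and* early/late sub-stage
  must both match;
* stage accuracy (``acc_stage``): the integer stage must match, sub-stage
  ignored;
* plus-minus-sub-stage accuracy (``acc_pm_substage``): the prediction may
  be off by at most one half-stage step — e.g. truth 7E accepts 6L, 7E, 7L.

Each image scores 0 or 1 per criterion, so for any dataset
``acc_substage <= acc_stage <= acc_pm_substage``.

The half-stage arithmetic maps (stage, substage) to an index
``2 * stage + (0 for E, 1 for L)``.  The edge stages 3 and 17 carry no
sub-stage; they are scored at stage resolution and sit one half-step from
their refined neighbours (stage 3 next to 4E, stage 17 next to 16L).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import PoolSpec, StageAnnotation, annotate_images, build_pool
from .gabor import GroupStructure
from .image_io import STAGES, SUBSTAGED_STAGES
from .learners import SolverConfig


def half_stage_index(stage: int, substage: str | None) -> int:
    """Half-stage coordinate: 2*stage for E, 2*stage + 1 for L.

    The edge stages collapse onto the half-step adjacent to their refined
    neighbour: stage 3 behaves as a late half (next to 4E) and stage 17 as
    an early half (next to 16L).
    """
    if stage == 3:
        return 2 * 3 + 1
    if stage == 17:
        return 2 * 17
    if substage not in ("E", "L"):
        raise ValueError(f"stage {stage} requires an E/L sub-stage, got {substage!r}")
    return 2 * stage + (0 if substage == "E" else 1)


def _coerce(pred_or_stage, substage=None) -> tuple[int, str | None]:
    if isinstance(pred_or_stage, StageAnnotation):
        return pred_or_stage.stage, pred_or_stage.substage
    return int(pred_or_stage), substage


def score_stage(pred, truth_stage: int, pred_substage=None, truth_substage=None) -> int:
    """1 iff the integer stages match (sub-stage ignored)."""
    ps, _ = _coerce(pred, pred_substage)
    return int(ps == int(truth_stage))


def score_substage(pred, truth_stage: int, pred_substage=None, truth_substage=None) -> int:
    """1 iff stage and sub-stage both match.

    Edge stages (3, 17) have no sub-stage and are scored at stage
    resolution; the same fallback applies when the manual annotation
    carries no sub-stage.
    """
    ps, psub = _coerce(pred, pred_substage)
    ts = int(truth_stage)
    if ps != ts:
        return 0
    if ts not in SUBSTAGED_STAGES or truth_substage is None:
        return 1
    return int(psub == truth_substage)


def score_pm_substage(pred, truth_stage: int, pred_substage=None, truth_substage=None) -> int:
    """1 iff the prediction is within one half-stage step of the truth.

    A refined truth stage without a manual sub-stage is treated as spanning
    both of its halves (the prediction may sit within one half-step of
    either).
    """
    ps, psub = _coerce(pred, pred_substage)
    h_pred = half_stage_index(ps, psub)
    ts = int(truth_stage)
    if ts in SUBSTAGED_STAGES and truth_substage is None:
        h_candidates = (2 * ts, 2 * ts + 1)
    else:
        h_candidates = (half_stage_index(ts, truth_substage),)
    return int(min(abs(h_pred - h) for h in h_candidates) <= 1)


@dataclass(frozen=True)
class EvaluationReport:
    """The three accuracies plus per-stage breakdown and confusion counts."""

    acc_substage: float
    acc_stage: float
    acc_pm_substage: float
    per_stage_accuracy: dict[int, float]
    confusion: pd.DataFrame = field(repr=False)
    n_images: int = 0

    def __post_init__(self) -> None:
        if not (
            -1e-12 <= self.acc_substage <= self.acc_stage <= self.acc_pm_substage <= 1 + 1e-12
        ):
            raise ValueError("accuracy criteria must nest: substage <= stage <= pm_substage")

    def to_dict(self) -> dict:
        return {
            "acc_substage": self.acc_substage,
            "acc_stage": self.acc_stage,
            "acc_pm_substage": self.acc_pm_substage,
            "per_stage_accuracy": {str(k): v for k, v in self.per_stage_accuracy.items()},
            "n_images": self.n_images,
        }

    def summary(self) -> str:
        lines = [
            f"images evaluated        : {self.n_images}",
            f"sub-stage accuracy      : {100 * self.acc_substage:6.2f} %",
            f"stage accuracy          : {100 * self.acc_stage:6.2f} %",
            f"+/- sub-stage accuracy  : {100 * self.acc_pm_substage:6.2f} %",
            "per-stage accuracy:",
        ]
        for s, a in sorted(self.per_stage_accuracy.items()):
            lines.append(f"  stage {s:2d}: {100 * a:6.2f} %")
        return "\n".join(lines)


def evaluate_annotations(
    pred_stages: np.ndarray,
    pred_substages: list,
    truth_stages: np.ndarray,
    truth_substages: list,
) -> EvaluationReport:
    """Score parallel arrays of predicted and true (stage, substage) pairs."""
    pred_stages = np.asarray(pred_stages, dtype=int)
    truth_stages = np.asarray(truth_stages, dtype=int)
    n = len(pred_stages)
    if not (n == len(pred_substages) == len(truth_stages) == len(truth_substages)):
        raise ValueError("prediction and truth arrays must have equal length")
    s_sub = s_stage = s_pm = 0
    for ps, psub, ts, tsub in zip(pred_stages, pred_substages, truth_stages, truth_substages):
        s_sub += score_substage(ps, ts, psub, tsub)
        s_stage += score_stage(ps, ts, psub, tsub)
        s_pm += score_pm_substage(ps, ts, psub, tsub)
    confusion = pd.DataFrame(
        0, index=list(STAGES), columns=list(STAGES), dtype=int
    )
    for ps, ts in zip(pred_stages, truth_stages):
        confusion.loc[ts, ps] += 1
    per_stage = {}
    for s in STAGES:
        row = confusion.loc[s]
        total = int(row.sum())
        if total:
            per_stage[s] = float(row[s]) / total
    return EvaluationReport(
        acc_substage=s_sub / n,
        acc_stage=s_stage / n,
        acc_pm_substage=s_pm / n,
        per_stage_accuracy=per_stage,
        confusion=confusion,
        n_images=n,
    )


def _substage_list(df: pd.DataFrame, column: str) -> list:
    return [None if (v is None or v == "" or pd.isna(v)) else str(v) for v in df[column]]


def evaluate_dataframe(pred: pd.DataFrame, truth: pd.DataFrame) -> EvaluationReport:
    """Score an annotation table against a truth table (aligned by position)."""
    return evaluate_annotations(
        pred["stage"].to_numpy(),
        _substage_list(pred, "substage"),
        truth["stage"].to_numpy(),
        _substage_list(truth, "substage"),
    )


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    truth_substages: list,
    spec: PoolSpec = PoolSpec(),
    k_or_holdout: float | int = 0.3,
    seed: int = 0,
    groups: GroupStructure | None = None,
    solver_config: SolverConfig = SolverConfig(max_iter=150, tol=1e-5),
) -> EvaluationReport:
    """Hold-out or k-fold cross-validation of the full annotation pipeline.

    A float ``k_or_holdout`` in (0, 1) holds out that fraction of images
    (stratified); an integer >= 2 runs stratified k-fold.  Each training
    portion gets its own pool built from ``spec``; accuracies aggregate
    over all held-out predictions.  Deterministic given ``seed``.
    """
    from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation needs at least two classes")
    if isinstance(k_or_holdout, float):
        if not 0 < k_or_holdout < 1:
            raise ValueError("hold-out fraction must be in (0, 1)")
        splits = StratifiedShuffleSplit(
            n_splits=1, test_size=k_or_holdout, random_state=seed
        ).split(np.zeros_like(y, dtype=float).reshape(-1, 1), y)
        min_needed = 2
    else:
        k = int(k_or_holdout)
        if k < 2:
            raise ValueError("k-fold requires k >= 2")
        offending = [int(c) for c, n in zip(classes, counts) if n < k]
        if offending:
            raise ValueError(f"classes with fewer samples than k={k}: {offending}")
        splits = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed).split(
            np.zeros_like(y, dtype=float).reshape(-1, 1), y
        )
    all_pred_stage, all_pred_sub, all_true_stage, all_true_sub = [], [], [], []
    for train_idx, test_idx in splits:
        pool = build_pool(
            X[train_idx], y[train_idx], spec=spec, groups=groups,
            classes=classes, solver_config=solver_config,
        )
        ann = annotate_images(pool, X[test_idx], thirds=False)
        all_pred_stage.extend(ann["stage"].tolist())
        all_pred_sub.extend(_substage_list(ann, "substage"))
        all_true_stage.extend(y[test_idx].tolist())
        all_true_sub.extend(truth_substages[i] for i in test_idx)
    return evaluate_annotations(
        np.array(all_pred_stage), all_pred_sub, np.array(all_true_stage), all_true_sub
    )
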
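"""Model-pool construction and confidence-weighted voting for stage annotation.

The annotation system does not rely on a single classifier.  It builds a
pool of diverse one-vs-rest linear models — every combination of

* 7 learning algorithms (linear SVM plus lasso / group-lasso /
  sparse-group-lasso with least-square and logistic losses),
* 5 training-set ratios (50% to 90%), and
* 30 random stratified train/validation partitions per ratio,

1050 models in the default configuration.  Each member carries a
*confidence* ``a_i``: its multiclass accuracy on its own validation split.
Splits are shared across algorithms within a (ratio, partition) cell, so
algorithm disagreement can be measured on identical data.

To annotate an image, every member votes for one stage and the votes are
accumulated, weighted by confidence, into a 15-bin histogram ``H`` over
stages 3..17.  The histogram drives all annotation levels:

* stage ``S`` = argmax of ``H`` (ties toward the smaller stage);
* sub-stage: for stages 4–16, early (E) when the lower neighbour out-votes
  the upper one (``H(S-1) > H(S+1)``), late (L) otherwise;
* stage score ``SS = S + 0.5 (H(S+1) - H(S-1)) / (H(S-1) + H(S+1))``,
  a continuous value in ``[S - 0.5, S + 0.5]`` used to order embryos by
  estimated developmental time (``SS = S`` when both neighbours are empty);
* sub-sub-stage: within each (stage, sub-stage) cohort, sorting by stage
  score and splitting into thirds gives the a/b/c refinement.

The stage-score expression above is this package's declared convention: it
lies within half a stage of ``S``, increases when the later neighbour gains
votes, and reduces to ``S`` for a symmetric histogram.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from .gabor import GroupStructure
from .image_io import SUBSTAGED_STAGES
from .learners import OneVsRestModel, LinearModel, SolverConfig, fit_one_vs_rest

#: the seven algorithm configurations of the pool, name -> (loss, regularizer)
ALGORITHMS: dict[str, tuple[str, str]] = {
    "svm_hinge_l2": ("hinge", "l2"),
    "lasso_ls": ("least_square", "l1"),
    "lasso_logistic": ("logistic", "l1"),
    "group_ls": ("least_square", "group_l1l2"),
    "group_logistic": ("logistic", "group_l1l2"),
    "sparse_group_ls": ("least_square", "sparse_group"),
    "sparse_group_logistic": ("logistic", "sparse_group"),
}

DEFAULT_TRAINING_RATIOS = (0.5, 0.6, 0.7, 0.8, 0.9)
DEFAULT_N_PARTITIONS = 30


class AnnotationError(ValueError):
    """Raised for unusable voting histograms or pool/feature mismatches."""


@dataclass(frozen=True)
class PoolSpec:
    """Blueprint for a model pool.

    ``size`` = len(algorithms) x len(training_ratios) x n_partitions
    (7 x 5 x 30 = 1050 by default).  ``master_seed`` fully determines every
    split and solver seed derived from the spec.
    """

    algorithms: tuple[str, ...] = tuple(ALGORITHMS)
    training_ratios: tuple[float, ...] = DEFAULT_TRAINING_RATIOS
    n_partitions: int = DEFAULT_N_PARTITIONS
    master_seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms {sorted(unknown)}")
        for r in self.training_ratios:
            if not 0.0 < r < 1.0:
                raise ValueError(f"training ratio {r} not in (0, 1)")
        if self.n_partitions < 1:
            raise ValueError("n_partitions must be >= 1")
        object.__setattr__(self, "algorithms", tuple(self.algorithms))
        object.__setattr__(self, "training_ratios", tuple(float(r) for r in self.training_ratios))

    @property
    def size(self) -> int:
        return len(self.algorithms) * len(self.training_ratios) * self.n_partitions

    def to_dict(self) -> dict:
        return {
            "algorithms": list(self.algorithms),
            "training_ratios": list(self.training_ratios),
            "n_partitions": self.n_partitions,
            "master_seed": self.master_seed,
        }


def enumerate_pool_plan(spec: PoolSpec):
    """Yield one (algorithm, ratio_index, partition_index, seed) per member.

    Split seeds depend only on (master_seed, ratio index, partition index),
    never on the algorithm, so all algorithms of a cell share the split.
    """
    for ri, ratio in enumerate(spec.training_ratios):
        for p in range(spec.n_partitions):
            seed = int(
                np.random.SeedSequence([spec.master_seed, ri, p]).generate_state(1)[0]
                % (2**31 - 1)
            )
            for algo in spec.algorithms:
                yield algo, ri, ratio, p, seed


@dataclass(frozen=True)
class PoolMember:
    """One trained one-vs-rest model with provenance and vote confidence."""

    ovr: OneVsRestModel = field(repr=False)
    confidence: float
    algorithm: str
    training_ratio: float
    partition_index: int
    seed: int
    feature_mean: np.ndarray = field(repr=False, default=None)
    feature_scale: np.ndarray = field(repr=False, default=None)
    train_indices: np.ndarray = field(repr=False, default=None)
    val_indices: np.ndarray = field(repr=False, default=None)
    excluded: bool = False
    note: str = ""

    def standardize(self, X: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return np.asarray(X, dtype=float)
        return (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.ovr.predict(self.standardize(X))


@dataclass(frozen=True)
class ModelPool:
    """The full trained pool plus the class alphabet it votes over."""

    members: tuple[PoolMember, ...]
    classes: np.ndarray
    spec: PoolSpec
    feature_dim: int

    @property
    def active_members(self) -> tuple[PoolMember, ...]:
        return tuple(m for m in self.members if not m.excluded)

    @property
    def confidences(self) -> np.ndarray:
        return np.array([m.confidence for m in self.active_members])


@dataclass(frozen=True)
class PredictionHistogram:
    """Confidence-weighted vote counts per stage."""

    stages: np.ndarray
    votes: np.ndarray

    def __post_init__(self) -> None:
        if len(self.stages) != len(self.votes):
            raise ValueError("stages and votes must align")
        if np.any(np.asarray(self.votes) < 0):
            raise ValueError("votes must be non-negative")

    def vote_for(self, stage: int) -> float:
        idx = np.where(self.stages == stage)[0]
        return float(self.votes[idx[0]]) if idx.size else 0.0

    @property
    def total(self) -> float:
        return float(np.sum(self.votes))


@dataclass(frozen=True)
class StageAnnotation:
    """Stage plus optional refinements for one image.

    ``substage`` and ``stage_score`` exist only for stages 4-16; the score
    lies in ``[stage - 0.5, stage + 0.5]`` and is below the integer stage
    exactly when the sub-stage is early (E).
    """

    stage: int
    substage: str | None = None
    stage_score: float | None = None
    third: str | None = None
    source_id: str = ""


def _stratified_split(y: np.ndarray, ratio: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    try:
        splitter = StratifiedShuffleSplit(n_splits=1, train_size=ratio, random_state=seed)
        train_idx, val_idx = next(splitter.split(np.zeros((len(y), 1)), y))
    except ValueError:
        # corpus too small for sklearn's one-per-class stratification of
        # both parts: split each class separately, keeping at least one
        # training sample per class
        rng = np.random.default_rng(seed)
        train_parts, val_parts = [], []
        for c in np.unique(y):
            idx = rng.permutation(np.where(y == c)[0])
            n_tr = int(np.clip(round(ratio * idx.size), 1, idx.size))
            train_parts.append(idx[:n_tr])
            val_parts.append(idx[n_tr:])
        train_idx = np.concatenate(train_parts)
        val_idx = np.concatenate(val_parts)
    return np.sort(train_idx), np.sort(val_idx)


def build_pool(
    X: np.ndarray,
    y: np.ndarray,
    spec: PoolSpec = PoolSpec(),
    groups: GroupStructure | None = None,
    classes: np.ndarray | None = None,
    standardize: bool = True,
    lambda_fraction: float = 0.01,
    solver_config: SolverConfig = SolverConfig(max_iter=150, tol=1e-5),
    verbose: bool = False,
) -> ModelPool:
    """Train every pool member on deterministic stratified splits.

    For each (ratio, partition) cell one stratified train/validation split
    is drawn from ``spec.master_seed``; every algorithm is trained on the
    same split, with per-feature standardization fitted on the training
    part.  Member confidence is its validation accuracy.  A member whose
    training part misses a class entirely is flagged ``excluded`` and never
    votes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if classes is None:
        classes = np.unique(y)
    classes = np.sort(np.asarray(classes))
    counts = {int(c): int(np.sum(y == c)) for c in classes}
    thin = [c for c, k in counts.items() if k < 2]
    if thin:
        warnings.warn(f"classes with < 2 samples: {thin}", stacklevel=2)

    members: list[PoolMember] = []
    ovr_cache_key = None
    for algo, ri, ratio, p, seed in enumerate_pool_plan(spec):
        if ovr_cache_key != (ri, p):
            train_idx, val_idx = _stratified_split(y, ratio, seed)
            ovr_cache_key = (ri, p)
            if standardize:
                mean = X[train_idx].mean(axis=0)
                scale = X[train_idx].std(axis=0)
                scale = np.where(scale > 0, scale, 1.0)
            else:
                mean = np.zeros(X.shape[1])
                scale = np.ones(X.shape[1])
            Xtr = (X[train_idx] - mean) / scale
            Xval = (X[val_idx] - mean) / scale
            ytr, yval = y[train_idx], y[val_idx]
        loss, reg = ALGORITHMS[algo]
        missing = [int(c) for c in classes if not np.any(ytr == c)]
        if missing:
            members.append(
                PoolMember(
                    ovr=None, confidence=0.0, algorithm=algo, training_ratio=ratio,
                    partition_index=p, seed=seed, feature_mean=mean, feature_scale=scale,
                    train_indices=train_idx, val_indices=val_idx, excluded=True,
                    note=f"training split lacks classes {missing}",
                )
            )
            continue
        cfg = replace(solver_config, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ovr = fit_one_vs_rest(
                Xtr, ytr, loss, reg, groups=groups, config=cfg, classes=classes,
                lambda1=None if reg in ("l1", "sparse_group") else 0.0,
                lambda2=None if reg in ("l2", "group_l1l2", "sparse_group") else 0.0,
            )
        if len(yval):
            confidence = float(np.mean(ovr.predict(Xval) == yval))
        else:
            confidence = float(np.mean(ovr.predict(Xtr) == ytr))
        members.append(
            PoolMember(
                ovr=ovr, confidence=confidence, algorithm=algo, training_ratio=ratio,
                partition_index=p, seed=seed, feature_mean=mean, feature_scale=scale,
                train_indices=train_idx, val_indices=val_idx,
            )
        )
        if verbose:
            print(f"  [{len(members)}/{spec.size}] {algo} ratio={ratio} part={p} "
                  f"acc={confidence:.3f}")
    return ModelPool(
        members=tuple(members), classes=classes, spec=spec, feature_dim=X.shape[1]
    )


def member_predictions(pool: ModelPool, X: np.ndarray) -> np.ndarray:
    """(n_active_members, n_samples) matrix of multiclass predictions."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != pool.feature_dim:
        raise AnnotationError(
            f"feature dimension {X.shape[1]} does not match pool ({pool.feature_dim})"
        )
    if not pool.active_members:
        raise AnnotationError("pool has no active members")
    return np.vstack([m.predict(X) for m in pool.active_members])


def vote(pool: ModelPool, features: np.ndarray) -> PredictionHistogram:
    """Confidence-weighted voting histogram for a single feature vector."""
    if not pool.active_members:
        raise AnnotationError("pool has no active members")
    preds = member_predictions(pool, features)[:, 0]
    conf = pool.confidences
    votes = np.zeros(len(pool.classes))
    for c_idx, c in enumerate(pool.classes):
        votes[c_idx] = conf[preds == c].sum()
    return PredictionHistogram(stages=pool.classes.copy(), votes=votes)


def vote_matrix(pool: ModelPool, X: np.ndarray) -> np.ndarray:
    """(n_samples, n_classes) histogram matrix for a whole feature matrix."""
    preds = member_predictions(pool, X)
    conf = pool.confidences
    H = np.zeros((preds.shape[1], len(pool.classes)))
    for c_idx, c in enumerate(pool.classes):
        H[:, c_idx] = conf @ (preds == c)
    return H


def annotate(histogram: PredictionHistogram) -> StageAnnotation:
    """Derive stage, sub-stage and stage score from a voting histogram."""
    votes = np.asarray(histogram.votes, dtype=float)
    if not np.any(votes > 0):
        raise AnnotationError("all-zero voting histogram")
    idx = int(np.argmax(votes))  # ties resolve to the smaller stage
    stage = int(histogram.stages[idx])
    if stage not in SUBSTAGED_STAGES:
        return StageAnnotation(stage=stage)
    lower = histogram.vote_for(stage - 1)
    upper = histogram.vote_for(stage + 1)
    if lower + upper == 0:
        score = float(stage)
    else:
        score = stage + 0.5 * (upper - lower) / (lower + upper)
    substage = "E" if lower > upper else "L"
    return StageAnnotation(stage=stage, substage=substage, stage_score=score)


def annotate_images(
    pool: ModelPool,
    X: np.ndarray,
    source_ids: list[str] | None = None,
    thirds: bool = True,
) -> pd.DataFrame:
    """Annotate a feature matrix; returns one row per image.

    Columns: ``image, stage, substage, stage_score, third, top3_stages,
    top3_votes``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    H = vote_matrix(pool, X)
    anns = []
    for i in range(X.shape[0]):
        hist = PredictionHistogram(stages=pool.classes, votes=H[i])
        ann = annotate(hist)
        sid = source_ids[i] if source_ids is not None else str(i)
        anns.append(replace(ann, source_id=sid))
    if thirds:
        anns = assign_thirds(anns)
    order = np.argsort(-H, axis=1, kind="stable")[:, :3]
    rows = []
    for i, ann in enumerate(anns):
        rows.append(
            {
                "image": ann.source_id,
                "stage": ann.stage,
                "substage": ann.substage or "",
                "stage_score": "" if ann.stage_score is None else f"{ann.stage_score:.6f}",
                "third": ann.third or "",
                "top3_stages": ";".join(str(int(pool.classes[j])) for j in order[i]),
                "top3_votes": ";".join(f"{H[i, j]:.6f}" for j in order[i]),
            }
        )
    return pd.DataFrame(rows)


def assign_thirds(annotations: list[StageAnnotation]) -> list[StageAnnotation]:
    """Split each (stage, substage) cohort into thirds a/b/c by stage score.

    Cohorts are sorted ascending by score (stable, input order breaks
    ties); sizes split as evenly as possible with remainders going to the
    earliest groups.  Annotations without a sub-stage (stages 3 and 17)
    keep ``third = None``.
    """
    out = list(annotations)
    cohorts: dict[tuple[int, str], list[int]] = {}
    for i, ann in enumerate(out):
        if ann.substage is None or ann.stage_score is None:
            continue
        cohorts.setdefault((ann.stage, ann.substage), []).append(i)
    for key, idxs in cohorts.items():
        # idxs is already in input order; stable sort keeps it as tie-break
        ranked = sorted(idxs, key=lambda i: out[i].stage_score)
        n = len(ranked)
        q, r = divmod(n, 3)
        sizes = [q + 1] * r + [q] * (3 - r)
        labels = []
        for label, size in zip("abc", sizes):
            labels.extend([label] * size)
        for i, label in zip(ranked, labels):
            out[i] = replace(out[i], third=label)
    return out


def disagreement_rate(pool: ModelPool, X: np.ndarray, y: np.ndarray | None = None) -> float:
    """Fraction of (split, validation sample) pairs where the algorithms differ.

    For every (ratio, partition) cell with at least two algorithms, each
    algorithm predicts the cell's validation samples; a sample counts as a
    disagreement when the predictions are not all identical.  Pooled over
    all cells.
    """
    X = np.asarray(X, dtype=float)
    cells: dict[tuple[float, int], list[PoolMember]] = {}
    for m in pool.active_members:
        cells.setdefault((m.training_ratio, m.partition_index), []).append(m)
    n_pairs = 0
    n_disagree = 0
    multi = False
    for members in cells.values():
        if len({m.algorithm for m in members}) < 2:
            continue
        multi = True
        val_idx = members[0].val_indices
        preds = np.vstack([m.predict(X[val_idx]) for m in members])
        differs = np.any(preds != preds[0], axis=0)
        n_pairs += differs.size
        n_disagree += int(differs.sum())
    if not multi:
        raise ValueError("disagreement rate undefined for a single-algorithm pool")
    return n_disagree / n_pairs


# --------------------------------------------------------------------------
# pool persistence


def save_pool(pool: ModelPool, path: str | Path) -> None:
    """Write a pool archive: JSON manifest + one npz of member weights."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "spec": pool.spec.to_dict(),
        "classes": [int(c) for c in pool.classes],
        "feature_dim": pool.feature_dim,
        "members": [],
    }
    arrays = {}
    for i, m in enumerate(pool.members):
        entry = {
            "index": i,
            "algorithm": m.algorithm,
            "loss": ALGORITHMS[m.algorithm][0],
            "regularizer": ALGORITHMS[m.algorithm][1],
            "solver": (m.ovr.models[0].solver if m.ovr is not None else ""),
            "training_ratio": m.training_ratio,
            "partition_index": m.partition_index,
            "seed": m.seed,
            "confidence": m.confidence,
            "excluded": m.excluded,
            "note": m.note,
        }
        manifest["members"].append(entry)
        if m.ovr is None:
            continue
        arrays[f"m{i}_W"] = np.vstack([lm.weights for lm in m.ovr.models])
        arrays[f"m{i}_b"] = np.array([lm.intercept for lm in m.ovr.models])
        arrays[f"m{i}_mean"] = m.feature_mean
        arrays[f"m{i}_scale"] = m.feature_scale
        arrays[f"m{i}_train"] = m.train_indices
        arrays[f"m{i}_val"] = m.val_indices
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    np.savez_compressed(path / "members.npz", **arrays)


def load_pool(path: str | Path) -> ModelPool:
    """Reconstruct a :class:`ModelPool` from :func:`save_pool` output."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    data = np.load(path / "members.npz")
    classes = np.array(manifest["classes"])
    members = []
    for entry in manifest["members"]:
        i = entry["index"]
        if entry["excluded"]:
            members.append(
                PoolMember(
                    ovr=None, confidence=0.0, algorithm=entry["algorithm"],
                    training_ratio=entry["training_ratio"],
                    partition_index=entry["partition_index"], seed=entry["seed"],
                    excluded=True, note=entry["note"],
                )
            )
            continue
        W = data[f"m{i}_W"]
        b = data[f"m{i}_b"]
        loss, reg = ALGORITHMS[entry["algorithm"]]
        models = tuple(
            LinearModel(weights=W[k], intercept=float(b[k]), loss_name=loss,
                        regularizer_name=reg, solver=entry.get("solver", ""))
            for k in range(W.shape[0])
        )
        ovr = OneVsRestModel(classes=classes.copy(), models=models)
        members.append(
            PoolMember(
                ovr=ovr, confidence=entry["confidence"], algorithm=entry["algorithm"],
                training_ratio=entry["training_ratio"],
                partition_index=entry["partition_index"], seed=entry["seed"],
                feature_mean=data[f"m{i}_mean"], feature_scale=data[f"m{i}_scale"],
                train_indices=data[f"m{i}_train"], val_indices=data[f"m{i}_val"],
                excluded=False, note=entry["note"],
            )
        )
    spec = PoolSpec(
        algorithms=tuple(manifest["spec"]["algorithms"]),
        training_ratios=tuple(manifest["spec"]["training_ratios"]),
        n_partitions=manifest["spec"]["n_partitions"],
        master_seed=manifest["spec"]["master_seed"],
    )
    return ModelPool(
        members=tuple(members), classes=classes, spec=spec,
        feature_dim=int(manifest["feature_dim"]),
    )
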
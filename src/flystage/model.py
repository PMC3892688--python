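"""High-level modelling interface: build from data, fit, inspect results.

:class:`StageAnnotationModel` bundles a labelled feature set (or raw
images) with a pool blueprint; :meth:`~StageAnnotationModel.fit` trains the
pool and returns a :class:`StageAnnotationResults` object that carries the
trained members, their validation confidences, diagnostics and annotation
methods — the fit/results split familiar from statistical modelling
packages.

Example
-------
>>> from flystage import synthetic, model
>>> corpus = synthetic.generate(synthetic.SyntheticSpec(n_per_stage=6, seed=0))
>>> m = model.StageAnnotationModel.from_images(
...     corpus.images, corpus.stages,
...     pool_spec=model.PoolSpec(algorithms=("lasso_logistic",),
...                              training_ratios=(0.7,), n_partitions=2))
>>> res = m.fit()
>>> ann = res.annotate(m.features)          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gabor
from .ensemble import (
    ModelPool,
    PoolSpec,
    annotate_images,
    build_pool,
    disagreement_rate,
)
from .evaluation import EvaluationReport, evaluate_annotations, _substage_list
from .gabor import GroupStructure
from .learners import SolverConfig


class StageAnnotationModel:
    """A stage-annotation problem: features, labels and a pool blueprint.

    Parameters
    ----------
    features : (n, d) array
        One texture feature vector per image.
    stages : (n,) int array
        Ground-truth stage labels in {3,...,17}.
    groups : GroupStructure, optional
        Region grouping of the features (required by the group-sparse
        algorithms; inferred automatically by the image constructors).
    pool_spec : PoolSpec
        Which algorithms / ratios / partitions to train.
    """

    def __init__(
        self,
        features: np.ndarray,
        stages: np.ndarray,
        groups: GroupStructure | None = None,
        pool_spec: PoolSpec = PoolSpec(),
        solver_config: SolverConfig = SolverConfig(max_iter=150, tol=1e-5),
        standardize: bool = True,
        source_ids: list[str] | None = None,
    ) -> None:
        self.features = np.asarray(features, dtype=float)
        self.stages = np.asarray(stages, dtype=int)
        if self.features.shape[0] != self.stages.shape[0]:
            raise ValueError("features and stages must have the same length")
        self.groups = groups
        self.pool_spec = pool_spec
        self.solver_config = solver_config
        self.standardize = standardize
        self.source_ids = source_ids

    @classmethod
    def from_images(
        cls,
        images,
        stages,
        bank: gabor.LogGaborFilterBank | None = None,
        **kwargs,
    ) -> "StageAnnotationModel":
        """Extract log-Gabor features from images and build the model."""
        X, groups = gabor.extract_feature_matrix(images, bank)
        return cls(X, stages, groups=groups, **kwargs)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, image_root=None, bank=None, **kwargs
    ) -> "StageAnnotationModel":
        """Build from a label table (columns ``image,stage,...``) on disk."""
        from .image_io import load_image

        from pathlib import Path

        root = Path(image_root) if image_root is not None else Path(".")
        images = [load_image(root / p) for p in df["image"]]
        m = cls.from_images(images, df["stage"].to_numpy(), bank=bank, **kwargs)
        m.source_ids = df["image"].tolist()
        return m

    def fit(self, verbose: bool = False) -> "StageAnnotationResults":
        """Train every pool member; returns the results object."""
        pool = build_pool(
            self.features,
            self.stages,
            spec=self.pool_spec,
            groups=self.groups,
            standardize=self.standardize,
            solver_config=self.solver_config,
            verbose=verbose,
        )
        return StageAnnotationResults(model=self, pool=pool)


@dataclass
class StageAnnotationResults:
    """Trained pool plus annotation, evaluation and summary methods."""

    model: StageAnnotationModel
    pool: ModelPool = field(repr=False)

    @property
    def confidences(self) -> np.ndarray:
        """Validation accuracy of each active member (its vote weight)."""
        return self.pool.confidences

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Ensemble stage prediction (argmax of the voting histogram)."""
        return self.annotate(features, thirds=False)["stage"].to_numpy()

    def annotate(
        self, features: np.ndarray, source_ids=None, thirds: bool = True
    ) -> pd.DataFrame:
        """Full annotation table: stage, sub-stage, stage score, thirds."""
        return annotate_images(self.pool, features, source_ids=source_ids, thirds=thirds)

    def evaluate(
        self, features: np.ndarray, stages: np.ndarray, substages=None
    ) -> EvaluationReport:
        """Score annotations of ``features`` against ground truth."""
        ann = self.annotate(features, thirds=False)
        if substages is None:
            substages = [None] * len(stages)
        return evaluate_annotations(
            ann["stage"].to_numpy(),
            _substage_list(ann, "substage"),
            np.asarray(stages, dtype=int),
            list(substages),
        )

    def disagreement_rate(self) -> float:
        """Algorithm disagreement on shared validation splits."""
        return disagreement_rate(self.pool, self.model.features)

    def summary(self) -> str:
        """Text table of pool composition and per-algorithm confidence."""
        members = self.pool.active_members
        lines = [
            "Stage annotation ensemble",
            "=" * 60,
            f"pool members (active/planned) : {len(members)}/{self.pool.spec.size}",
            f"stage classes                 : "
            f"{int(self.pool.classes.min())}..{int(self.pool.classes.max())} "
            f"({len(self.pool.classes)})",
            f"feature dimension             : {self.pool.feature_dim}",
            f"training ratios               : "
            + ", ".join(f"{r:g}" for r in self.pool.spec.training_ratios),
            f"partitions per ratio          : {self.pool.spec.n_partitions}",
            f"master seed                   : {self.pool.spec.master_seed}",
            "-" * 60,
            f"{'algorithm':<24}{'members':>8}{'mean conf':>12}{'sd':>8}",
        ]
        for algo in self.pool.spec.algorithms:
            confs = [m.confidence for m in members if m.algorithm == algo]
            if not confs:
                continue
            lines.append(
                f"{algo:<24}{len(confs):>8}{np.mean(confs):>12.3f}{np.std(confs):>8.3f}"
            )
        lines.append("-" * 60)
        lines.append(
            f"{'pool overall':<24}{len(members):>8}{np.mean(self.confidences):>12.3f}"
            f"{np.std(self.confidences):>8.3f}"
        )
        return "\n".join(lines)
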
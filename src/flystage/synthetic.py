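"""Synthetic embryo-image generator for end-to-end pipeline validation.

Real training corpora of staged in situ images are large external
databases; this module renders a stand-in corpus whose appearance varies
monotonically with a latent developmental-time parameter ``t`` in [0, 1],
so the whole pipeline — texture features, sparse learners, voting,
stage-score ordering and GEM series — can be exercised and validated
without any external data.

Each of the 15 stage classes (3..17) owns an equal sub-interval of
[0, 1]; an image's ``t`` is drawn uniformly within its stage's interval,
and its true sub-stage is E in the lower half of the interval, L in the
upper.  The renderer is a pure function of ``t``:

* an elliptical "embryo" on a white background (dark stain convention:
  lower intensity = more signal);
* a texture field whose dominant spatial frequency interpolates
  geometrically across ``texture_freq_range`` with ``t`` — a proxy for the
  morphological texture change that log-Gabor features pick up;
* an expression band whose anterior–posterior position interpolates from
  ``band_start`` to ``band_end`` with ``t`` — a proxy for germ-band-like
  movement that region-level (group-sparse) features pick up;
* Gaussian pixel noise, clipped to [0, 1].

With ``noise_sd = 0`` two images at the same ``t`` are identical, and the
band centroid is strictly monotone in ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import STANDARD_SHAPE, STAGES, save_image, write_label_table


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic corpus."""

    n_per_stage: int = 40
    stages: tuple[int, ...] = STAGES
    noise_sd: float = 0.05
    seed: int = 0
    band_start: float = 0.15
    band_end: float = 0.85
    texture_freq_range: tuple[float, float] = (0.03, 0.18)
    height: int = STANDARD_SHAPE[0]
    width: int = STANDARD_SHAPE[1]

    def __post_init__(self) -> None:
        if self.n_per_stage < 1:
            raise ValueError("n_per_stage must be >= 1")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"invalid stages {sorted(bad)}; valid range is 3..17")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "stages", tuple(sorted(self.stages)))


@dataclass(frozen=True)
class SyntheticCorpus:
    """Rendered images plus full ground truth."""

    images: np.ndarray = field(repr=False)  # (n, height, width) in [0, 1]
    stages: np.ndarray
    substages: tuple[str | None, ...]
    t: np.ndarray
    spec: SyntheticSpec

    def __len__(self) -> int:
        return self.images.shape[0]

    def labels(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image": [f"embryo_{i:04d}.png" for i in range(len(self))],
                "stage": self.stages,
                "substage": [None] * len(self),
                "t": self.t,
                "substage_truth": [s or "" for s in self.substages],
            }
        )


def stage_interval(stage: int) -> tuple[float, float]:
    """The sub-interval of latent time [0, 1] owned by a stage class."""
    i = STAGES.index(stage)
    k = len(STAGES)
    return i / k, (i + 1) / k


def true_substage(stage: int, t: float) -> str | None:
    """E in the lower half of the stage's interval, L in the upper.

    Edge stages 3 and 17 carry no sub-stage.
    """
    if stage in (3, 17):
        return None
    lo, hi = stage_interval(stage)
    return "E" if t < (lo + hi) / 2.0 else "L"


def render_embryo(t: float, spec: SyntheticSpec = SyntheticSpec()) -> np.ndarray:
    """Deterministic noise-free embryo image at latent time ``t``."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("latent time t must lie in [0, 1]")
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # elliptical embryo occupying most of the frame
    ry, rx = 0.42 * h, 0.47 * w
    ellipse = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
    mask = np.clip(1.0 - ellipse, 0.0, 1.0)
    mask = np.minimum(mask * 8.0, 1.0)  # soft edge, flat interior

    img = np.ones((h, w))
    body = 0.85
    # texture: dominant frequency sweeps geometrically with t
    f_lo, f_hi = spec.texture_freq_range
    freq = f_lo * (f_hi / f_lo) ** t
    texture = 0.08 * np.sin(2.0 * np.pi * freq * xx) * np.sin(2.0 * np.pi * freq * yy)
    # expression band: anterior-posterior position interpolates with t
    band_col = (spec.band_start + (spec.band_end - spec.band_start) * t) * (w - 1)
    band = 0.55 * np.exp(-((xx - band_col) ** 2) / (2.0 * 14.0**2))
    interior = np.clip(body - texture - band, 0.0, 1.0)
    img = mask * interior + (1.0 - mask) * img
    return np.clip(img, 0.0, 1.0)


def generate(spec: SyntheticSpec = SyntheticSpec()) -> SyntheticCorpus:
    """Render a labelled corpus, fully reproducible from ``spec.seed``.

    Latent times are drawn uniformly within each stage's interval; images
    are rendered deterministically from ``t`` and perturbed with Gaussian
    noise of sd ``spec.noise_sd`` (clipped to [0, 1]).
    """
    rng = np.random.default_rng(spec.seed)
    stages_out, subs, ts, imgs = [], [], [], []
    for stage in spec.stages:
        lo, hi = stage_interval(stage)
        t_draws = np.sort(rng.uniform(lo, hi, size=spec.n_per_stage))
        for t in t_draws:
            img = render_embryo(float(t), spec)
            if spec.noise_sd > 0:
                img = np.clip(img + rng.normal(0.0, spec.noise_sd, size=img.shape), 0.0, 1.0)
            imgs.append(img)
            stages_out.append(stage)
            subs.append(true_substage(stage, float(t)))
            ts.append(float(t))
    return SyntheticCorpus(
        images=np.array(imgs),
        stages=np.array(stages_out, dtype=int),
        substages=tuple(subs),
        t=np.array(ts),
        spec=spec,
    )


def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> Path:
    """Write PNGs plus a ``labels.csv`` in the canonical label schema.

    The ``substage`` column is left empty (it is what the pipeline must
    infer); the generator's ground truth goes into ``substage_truth`` and
    ``t``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = corpus.labels()
    for name, img in zip(labels["image"], corpus.images):
        save_image(img, out_dir / name)
    write_label_table(labels, out_dir / "labels.csv")
    return out_dir / "labels.csv"
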
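"""Genomewide-expression-map (GEM) composites.

A GEM summarizes the spatial distribution of gene expression across many
embryos of the same developmental moment: all standardized images of a
group (a stage, a sub-stage, or a stage-score bin) are aggregated pixel by
pixel and normalized into one composite.  Because in situ stains render
expression as dark signal on a light embryo, intensities are inverted
before averaging so that high values mean strong expression; the mean map
is then min–max rescaled to [0, 1] so composites from groups of different
sizes are contrast-comparable.

Series of GEMs at increasing stage resolution (stage → sub-stage →
score bins) visualize how global gene activity shifts along the
anterior–posterior axis over developmental time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import StageAnnotation
from .image_io import EmbryoImage, SUBSTAGED_STAGES, save_image


@dataclass(frozen=True)
class ExpressionMap:
    """One normalized composite expression map."""

    pixels: np.ndarray = field(repr=False)
    n_images: int
    group_label: str

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("an expression map aggregates at least one image")
        px = np.asarray(self.pixels, dtype=float)
        if px.min() < -1e-12 or px.max() > 1 + 1e-12:
            raise ValueError("expression map intensities must lie in [0, 1]")


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, EmbryoImage) else np.asarray(img, dtype=float)


def build_gem(images: list, group_label: str = "") -> ExpressionMap:
    """Pixelwise mean of inverted intensities, min–max rescaled to [0, 1].

    All images must share the standardized geometry.  A constant mean map
    (no contrast) maps to all zeros.
    """
    if len(images) == 0:
        raise ValueError(f"empty image group {group_label!r}")
    shape = _pixels(images[0]).shape
    acc = np.zeros(shape)
    for img in images:
        px = _pixels(img)
        if px.shape != shape:
            raise ValueError("all images in a GEM group must share dimensions")
        acc += 1.0 - px  # invert: dark stain -> high signal
    acc /= len(images)
    lo, hi = float(acc.min()), float(acc.max())
    if hi > lo:
        acc = (acc - lo) / (hi - lo)
    else:
        acc = np.zeros_like(acc)
    return ExpressionMap(pixels=acc, n_images=len(images), group_label=group_label)


def _group_key(ann: StageAnnotation, granularity: str, n_bins: int):
    if granularity == "stage":
        return (ann.stage,)
    if granularity == "substage":
        if ann.stage not in SUBSTAGED_STAGES:
            return (ann.stage, "")
        return (ann.stage, ann.substage)
    if granularity == "score_bins":
        if ann.stage not in SUBSTAGED_STAGES or ann.stage_score is None:
            return (ann.stage, 0)
        # score in [stage - 0.5, stage + 0.5] -> bin 0..n_bins-1
        frac = np.clip((ann.stage_score - (ann.stage - 0.5)), 0.0, 1.0 - 1e-12)
        return (ann.stage, int(frac * n_bins))
    raise ValueError(f"unknown granularity {granularity!r}")


def build_gem_series(
    images: list,
    annotations: list[StageAnnotation],
    granularity: str = "stage",
    n_bins: int = 8,
) -> list[ExpressionMap]:
    """One GEM per populated group, in developmental order.

    ``granularity`` is ``stage``, ``substage`` (E before L) or
    ``score_bins`` (``n_bins`` equal-width stage-score bins per stage).
    Empty groups are skipped.
    """
    if len(images) != len(annotations):
        raise ValueError("images and annotations must align")
    groups: dict[tuple, list] = {}
    for img, ann in zip(images, annotations):
        groups.setdefault(_group_key(ann, granularity, n_bins), []).append(img)

    def order(key):
        if granularity == "substage":
            sub_rank = {"": 0, "E": 0, "L": 1}
            return (key[0], sub_rank[key[1]])
        return key

    series = []
    for key in sorted(groups, key=order):
        label = "stage" + "-".join(str(k) for k in key if k != "")
        series.append(build_gem(groups[key], group_label=label))
    return series


def signal_centroid(gem: ExpressionMap) -> float:
    """Column (anterior–posterior) centroid of the map's signal mass."""
    weights = gem.pixels.sum(axis=0)
    total = weights.sum()
    if total == 0:
        return (gem.pixels.shape[1] - 1) / 2.0
    return float(np.arange(gem.pixels.shape[1]) @ weights / total)


def export_gem_series(
    series: list[ExpressionMap], out_dir: str | Path, montage: bool = False
) -> pd.DataFrame:
    """Write one PNG per map plus a manifest CSV; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, gem in enumerate(series):
        name = f"gem_{i:03d}_{gem.group_label}.png"
        save_image(gem.pixels, out_dir / name)
        rows.append({"group_label": gem.group_label, "n_images": gem.n_images, "path": name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    if montage and series:
        stacked = np.vstack([np.pad(g.pixels, ((2, 2), (0, 0)), constant_values=1.0)
                             for g in series])
        save_image(stacked, out_dir / "montage.png")
    return manifest
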
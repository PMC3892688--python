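"""Loading, validation and standardization of embryo expression images.

The annotation pipeline assumes standardized input: lateral-view embryo
images that have been aligned and scaled to 128 x 320 pixels (anterior at
the left, dorsal up).  This module converts arbitrary 8/16-bit PNG/TIFF/JPEG
input into that canonical representation -- a float grid of intensities in
[0, 1] -- and reads/writes the accompanying stage-label tables.

Stages follow the standard morphological staging of Drosophila
embryogenesis.  The first three stages differ only in nucleus count, which
is not visible in whole-mount in situ images, so they are collapsed into a
single class labelled stage 3; the usable stage alphabet is {3, ..., 17}.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

#: canonical standardized image size (rows, columns)
STANDARD_SHAPE = (128, 320)

#: valid stage labels: stages 1-2 are merged into 3
STAGES = tuple(range(3, 18))

#: stages that carry an early/late sub-stage refinement
SUBSTAGED_STAGES = tuple(range(4, 17))

#: ITU-R BT.601 luminance weights for grayscale conversion
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class ImageValidationError(ValueError):
    """Raised when an input image or label table violates the contracts."""


@dataclass(frozen=True)
class EmbryoImage:
    """A standardized grayscale embryo image.

    Attributes
    ----------
    pixels : ndarray of shape (height, width)
        Intensities in [0, 1]; row 0 is the top of the image, column 0 the
        anterior (left) end of the standardized embryo.
    source_id : str
        Opaque identifier (usually the originating file name).
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ImageValidationError(
                f"embryo image must be a non-empty 2-D grid, got shape {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ImageValidationError("embryo image contains non-finite intensities")
        if px.min() < -1e-12 or px.max() > 1 + 1e-12:
            raise ImageValidationError(
                "embryo image intensities must lie in [0, 1]; "
                f"got range [{px.min():.4g}, {px.max():.4g}]"
            )
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_standard(self) -> bool:
        return self.pixels.shape == STANDARD_SHAPE


@dataclass(frozen=True)
class LabeledImage:
    """An embryo image together with its ground-truth stage annotation."""

    image: EmbryoImage
    stage: int
    substage: str | None = None

    def __post_init__(self) -> None:
        validate_stage_label(self.stage, self.substage)


def validate_stage_label(stage: int, substage: str | None = None, *, row: object = None) -> None:
    """Check a (stage, substage) pair against the stage alphabet.

    Stages 1 and 2 are never valid labels (they are encoded as 3) and the
    edge stages 3 and 17 carry no early/late sub-stage.
    """
    where = "" if row is None else f" (row {row})"
    if stage not in STAGES:
        raise ImageValidationError(
            f"stage {stage!r} outside the valid alphabet {{3,...,17}}{where}; "
            "note stages 1-3 must be encoded as 3"
        )
    if substage is not None:
        if substage not in ("E", "L"):
            raise ImageValidationError(f"substage must be 'E' or 'L', got {substage!r}{where}")
        if stage not in SUBSTAGED_STAGES:
            raise ImageValidationError(
                f"stage {stage} has no sub-stage refinement{where}"
            )


def _to_grayscale_unit(raw: np.ndarray) -> np.ndarray:
    """Collapse channels by luminance and rescale integer dtypes to [0, 1]."""
    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr.astype(float) @ _LUMA_WEIGHTS
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ImageValidationError(f"unsupported channel count {arr.shape[2]}")
    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        scale = float(np.iinfo(np.asarray(raw).dtype).max)
        arr = arr.astype(float) / scale
    else:
        arr = arr.astype(float)
    return np.clip(arr, 0.0, 1.0)


def load_image(path: str | Path, enforce_size: bool = True) -> EmbryoImage:
    """Load a PNG/TIFF/JPEG image as a standardized :class:`EmbryoImage`.

    Color input is converted to grayscale by luminance weighting
    (0.299 R + 0.587 G + 0.114 B) and intensities are rescaled to [0, 1].
    With ``enforce_size`` the image is resampled (bilinear) to 128 x 320 if
    its dimensions differ.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific messages
        raise OSError(f"cannot decode image file {path}: {exc}") from exc
    if raw.size == 0:
        raise ImageValidationError(f"zero-area image: {path}")
    gray = _to_grayscale_unit(raw)
    if gray.ndim != 2:
        raise ImageValidationError(f"expected a 2-D image after conversion: {path}")
    if enforce_size and gray.shape != STANDARD_SHAPE:
        gray = resize(gray, STANDARD_SHAPE, order=1, mode="edge", anti_aliasing=True)
        gray = np.clip(gray, 0.0, 1.0)
    return EmbryoImage(pixels=gray, source_id=path.name)


def save_image(image: EmbryoImage | np.ndarray, path: str | Path) -> None:
    """Write an image (intensities in [0, 1]) as an 8-bit grayscale PNG."""
    px = image.pixels if isinstance(image, EmbryoImage) else np.asarray(image, dtype=float)
    quantized = np.round(np.clip(px, 0.0, 1.0) * 255.0).astype(np.uint8)
    iio.imwrite(Path(path), quantized)


def load_label_table(path: str | Path) -> pd.DataFrame:
    """Read a stage-label CSV with columns ``image,stage,substage``.

    ``substage`` may be empty; extra columns (e.g. a latent-time column from
    the synthetic generator) are carried through untouched.  Stage values
    are validated against {3,...,17} and sub-stages against {E, L} on stages
    4-16; a violation raises :class:`ImageValidationError` naming the row.
    """
    df = pd.read_csv(path, dtype={"image": str})
    required = {"image", "stage"}
    missing = required - set(df.columns)
    if missing:
        raise ImageValidationError(f"label table {path} lacks columns {sorted(missing)}")
    if "substage" not in df.columns:
        df["substage"] = pd.NA
    stages = pd.to_numeric(df["stage"], errors="coerce")
    for i, s in enumerate(stages):
        if pd.isna(s) or float(s) != int(s):
            raise ImageValidationError(f"non-integer stage {df['stage'].iloc[i]!r} (row {i})")
        sub = df["substage"].iloc[i]
        sub = None if pd.isna(sub) or sub == "" else str(sub)
        validate_stage_label(int(s), sub, row=i)
    df["stage"] = stages.astype(int)
    df["substage"] = df["substage"].map(
        lambda v: None if pd.isna(v) or v == "" else str(v)
    )
    return df


def write_label_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a label table in the canonical CSV schema."""
    out = df.copy()
    out["substage"] = out["substage"].map(lambda v: "" if v is None or pd.isna(v) else v)
    out.to_csv(path, index=False)


def load_corpus(
    label_table: str | Path, image_root: str | Path | None = None, enforce_size: bool = True
) -> tuple[list[EmbryoImage], pd.DataFrame]:
    """Load every image referenced by a label table.

    Relative image paths are resolved against ``image_root`` (default: the
    directory containing the table).
    """
    table_path = Path(label_table)
    root = Path(image_root) if image_root is not None else table_path.parent
    df = load_label_table(table_path)
    images = []
    for rel in df["image"]:
        p = Path(rel)
        images.append(load_image(p if p.is_absolute() else root / p, enforce_size=enforce_size))
    return images, df
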